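"""Time integration of the coupled tumor/immune system.

Couples the size-structured growth-division-death equation for the tumor
cell density n(t, z) with the radial drift-diffusion equation for the
immune concentration c(t, x):

    dn/dt + d(V n)/dz = Q(n) - mubar_c(t) n,     mubar_c = integral(delta c),
    dc/dt + div(c chi mu1 grad Phi - D grad c) = mu1 R - gamma c,

with the chemoattractive potential Phi fixed in time (computed once; the
mass factor mu1(t) scales the drift).  The size axis uses the same upwind
flux and division quadrature as the eigenproblem module, stepped explicitly
under a transport CFL bound; the stiff immune equation is stepped by
backward Euler.  Running to large times, the death rate settles on the
leading eigenvalue, the size profile on the eigenprofile, and the mass
mu1(t) on the value the power-dichotomy procedure predicts — the
cross-validation of the equilibrium machinery.

Units: sizes z in micron^3, tumor mass mu1 in mm^3, times in days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse

from .equilibrium import EquilibriumResult, mass_to_diameter
from .fields import (
    MM3_PER_UM3,
    FormFunction,
    ImmuneParameters,
    RadialGrid,
    ScalarField,
    concentration_system,
    solve_chemo_potential,
    _tridiag_solve,
)
from .size_dynamics import GrowthDivisionSpec, SizeGrid

__all__ = [
    "SimulationState",
    "TimeSeries",
    "EvolutionError",
    "NotStationaryError",
    "run_evolution",
    "compare_with_prediction",
    "default_initial_state",
]

#: default initial cell volume: one spherical cell of radius 15 micron
INITIAL_CELL_VOLUME_UM3 = 4.0 / 3.0 * math.pi * 15.0 ** 3   # = 14137.2


class EvolutionError(RuntimeError):
    """Time integration became unstable; carries the last valid state."""

    def __init__(self, message, state=None, series=None):
        super().__init__(message)
        self.state = state
        self.series = series


class NotStationaryError(RuntimeError):
    """The run has not reached a quasi-steady state."""


@dataclass
class SimulationState:
    """Tumor size density, immune concentration and the current time."""

    n: np.ndarray                 # size density on the SizeGrid (1/micron^3)
    c: np.ndarray                 # immune concentration on the RadialGrid
    t: float = 0.0                # days


@dataclass
class TimeSeries:
    """Recorded moments of the coupled run."""

    times: np.ndarray
    mu0: np.ndarray               # total cell number
    mu1: np.ndarray               # tumor mass (mm^3)
    mubar_c: np.ndarray           # induced death rate (1/day)
    diameter: np.ndarray          # equivalent-sphere diameter (mm)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.times, "mu0": self.mu0,
                             "mu1": self.mu1, "mubar_c": self.mubar_c,
                             "diameter": self.diameter})


def default_initial_state(size_grid: SizeGrid, radial_grid: RadialGrid,
                          n_cells: float = 1.0,
                          z0: float = INITIAL_CELL_VOLUME_UM3
                          ) -> SimulationState:
    """``n_cells`` cells concentrated in the size cell nearest z0; no immune cells."""
    n = np.zeros(size_grid.n_cells)
    i0 = int(np.argmin(np.abs(size_grid.z - z0)))
    n[i0] = n_cells / size_grid.h
    return SimulationState(n=n, c=np.zeros(radial_grid.n_cells), t=0.0)


def run_evolution(spec: GrowthDivisionSpec,
                  size_grid: SizeGrid,
                  params: ImmuneParameters,
                  delta: FormFunction,
                  sigma: FormFunction,
                  radial_grid: RadialGrid,
                  ics: SimulationState | None = None,
                  horizon: float = 500.0,
                  dt: float = 0.1,
                  cfl: float = 0.9,
                  record_every: int = 1,
                  potential: ScalarField | None = None
                  ) -> tuple[TimeSeries, SimulationState]:
    """Integrate the coupled system up to ``horizon`` days.

    The step is reduced automatically to satisfy the explicit transport
    bound dt <= cfl * h / max V.  Returns the recorded moment time series
    and the final state.  Raises EvolutionError (carrying the last valid
    state) on NaN or significant negative mass.
    """
    h = size_grid.h
    z = size_grid.z
    a = spec.a(z)
    Vh = spec.V(size_grid.z_half)
    dt_stab = cfl * h / float(np.max(Vh))
    steps_hint = max(1, math.ceil(horizon / min(dt, dt_stab)))
    dt_eff = horizon / steps_hint
    # division gain matrix: gain_i = h sum_j a_j k(z_i|z_j) n_j
    K = spec.kernel.discrete(size_grid)
    if scipy.sparse.issparse(K):
        G = (K.multiply(a[None, :]) * h).tocsr()
    else:
        G = h * (K * a[None, :])
    phi = potential if potential is not None else solve_chemo_potential(
        radial_grid, params.K, sigma)
    delta_r = delta(radial_grid.centers)
    areas = radial_grid.areas

    state = ics if ics is not None else default_initial_state(
        size_grid, radial_grid)
    n = state.n.astype(float).copy()
    c = state.c.astype(float).copy()
    t = state.t

    rec_t, rec_m0, rec_m1, rec_mc, rec_d = [], [], [], [], []

    def mass_mm3(nv: np.ndarray) -> float:
        return MM3_PER_UM3 * h * float(np.dot(z, nv))

    def record(tt, nv, mubar):
        m1 = mass_mm3(nv)
        rec_t.append(tt)
        rec_m0.append(h * float(np.sum(nv)))
        rec_m1.append(m1)
        rec_mc.append(mubar)
        rec_d.append(mass_to_diameter(m1))

    mubar = float(np.sum(areas * delta_r * c))
    record(t, n, mubar)
    n_floor = -1e-10
    for step in range(1, steps_hint + 1):
        mubar = float(np.sum(areas * delta_r * c))
        # explicit size step: upwind transport + division + immune death
        F = Vh * n
        dn = -(F - np.concatenate(([0.0], F[:-1]))) / h \
            + (G @ n) - (a + mubar) * n
        n_new = n + dt_eff * dn
        if not np.all(np.isfinite(n_new)) or \
                np.min(n_new) < n_floor * max(1.0, float(np.max(n_new))):
            raise EvolutionError(
                f"size density became unstable at t={t:.3f} "
                f"(min n {np.min(n_new):.3e})",
                state=SimulationState(n, c, t),
                series=_series(rec_t, rec_m0, rec_m1, rec_mc, rec_d))
        n = np.maximum(n_new, 0.0)
        mu1 = mass_mm3(n)
        # implicit immune step: (1/dt + A) c_new = c/dt + mu1 R
        lower, diag, upper, source = concentration_system(
            radial_grid, params, phi, mu1)
        c = _tridiag_solve(lower, diag + 1.0 / dt_eff, upper,
                           source + c / dt_eff)
        if not np.all(np.isfinite(c)):
            raise EvolutionError(
                f"immune concentration became non-finite at t={t:.3f}",
                state=SimulationState(n, c, t),
                series=_series(rec_t, rec_m0, rec_m1, rec_mc, rec_d))
        c = np.maximum(c, 0.0)
        t = step * dt_eff
        if step % record_every == 0 or step == steps_hint:
            record(t, n, float(np.sum(areas * delta_r * c)))

    return (_series(rec_t, rec_m0, rec_m1, rec_mc, rec_d),
            SimulationState(n, c, t))


def _series(t, m0, m1, mc, d) -> TimeSeries:
    return TimeSeries(np.asarray(t), np.asarray(m0), np.asarray(m1),
                      np.asarray(mc), np.asarray(d))


def compare_with_prediction(run: TimeSeries,
                            prediction: EquilibriumResult,
                            drift_tol: float = 1e-5) -> float:
    """Relative discrepancy E = |mu1_final - mu1_predicted| / mu1_final.

    Requires the run to be quasi-steady: the relative excursion of mu1 over
    the last 10% of the horizon must stay below ``drift_tol``.
    """
    m = run.mu1
    if m.size < 10:
        raise NotStationaryError("time series too short to assess drift")
    tail = m[run.times >= run.times[-1] - 0.1 * (run.times[-1] - run.times[0])]
    mu1_f = float(m[-1])
    if mu1_f <= 0:
        raise NotStationaryError("final mass is not positive")
    drift = float((np.max(tail) - np.min(tail)) / mu1_f)
    if drift > drift_tol:
        raise NotStationaryError(
            f"run is not stationary: relative mu1 drift {drift:.3e} over the "
            f"last 10% of the horizon exceeds {drift_tol:g}")
    return abs(mu1_f - prediction.mu1) / mu1_f
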