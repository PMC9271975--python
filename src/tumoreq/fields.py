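"""Stationary chemoattractive potential and immune concentration on the disk.

The tumor sits at the origin of a disk-shaped domain; immune effector cells
diffuse (coefficient D), drift up the gradient of a chemoattractive
potential Phi (chemotactic coefficient chi, scaled by the tumor mass mu1),
die at rate gamma and are recruited proportionally to mu1:

    gamma C - div(D grad C) + mu1 div(chi C grad Phi) = mu1 R,   C|boundary = 0,
    -K lap Phi = sigma - <sigma>,   zero-flux boundary, zero-mean gauge,

where sigma and the killing-efficacy weight delta are centered Gaussian form
functions.  With centered form functions, constant influx R and a disk
domain, the stationary problem is radially symmetric, so both equations are
solved by a 1-D radial finite-volume scheme (cell areas 2 pi r dr, advective
fluxes upwinded by the face drift velocity).  The induced death rate on the
tumor is the delta-weighted disk integral of C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import scipy.linalg

__all__ = [
    "RadialGrid",
    "FormFunction",
    "ImmuneParameters",
    "ScalarField",
    "solve_chemo_potential",
    "solve_immune_concentration",
    "effective_death_rate",
    "FieldSolveError",
]

#: volume conversion used whenever cell-scale volumes (micron^3) meet
#: tissue-scale masses (mm^3)
MM3_PER_UM3 = 1e-9


class FieldSolveError(RuntimeError):
    """A stationary field solve failed or violated the scheme's guarantees."""


@dataclass(frozen=True)
class RadialGrid:
    """Uniform radial finite-volume grid on the disk of given radius.

    Cell m (m = 1..M) spans [r_{m-1/2}, r_{m+1/2}] with r_{1/2} = 0 and
    r_{M+1/2} = radius; unknowns live at the cell centers.  Disk-area
    quadrature weights are 2 pi r_m dr (exact for the annulus areas).
    """

    radius: float = 1.0
    n_cells: int = 100

    def __post_init__(self):
        if self.radius <= 0 or self.n_cells < 3:
            raise ValueError("need radius > 0 and at least 3 radial cells")

    @property
    def dr(self) -> float:
        return self.radius / self.n_cells

    @property
    def faces(self) -> np.ndarray:
        return np.linspace(0.0, self.radius, self.n_cells + 1)

    @property
    def centers(self) -> np.ndarray:
        f = self.faces
        return 0.5 * (f[:-1] + f[1:])

    @property
    def areas(self) -> np.ndarray:
        """Annulus areas pi (r_{m+1/2}^2 - r_{m-1/2}^2) = 2 pi r_m dr."""
        f = self.faces
        return math.pi * (f[1:] ** 2 - f[:-1] ** 2)

    def disk_integral(self, values: np.ndarray) -> float:
        return float(np.sum(self.areas * values))

    def disk_average(self, values: np.ndarray) -> float:
        return self.disk_integral(values) / (math.pi * self.radius ** 2)


@dataclass(frozen=True)
class FormFunction:
    """Centered Gaussian form function A/(2 pi theta^2) exp(-r^2 / 2 theta^2).

    ``amplitude`` tunes the strength (its disk integral for width << radius),
    ``width`` the radius of influence.
    """

    amplitude: float
    width: float

    def __post_init__(self):
        if self.amplitude < 0 or self.width <= 0:
            raise ValueError("form function needs amplitude >= 0, width > 0")

    def __call__(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        return (self.amplitude / (2.0 * math.pi * self.width ** 2)
                * np.exp(-0.5 * (r / self.width) ** 2))


@dataclass(frozen=True)
class ImmuneParameters:
    """Biophysical parameters of the immune compartment.

    chi       chemotactic coefficient (mm^2 mmol^-1 day^-1)
    D         effector-cell diffusion (mm^2/day)
    gamma     effector-cell death rate (1/day)
    K         potential diffusion coefficient (mm^2/day)
    R_influx  influx rate of effector cells per unit tumor mass; a constant
              or a radial profile callable r -> rate
    """

    chi: float
    D: float
    gamma: float
    K: float
    R_influx: float | Callable[[np.ndarray], np.ndarray]

    def __post_init__(self):
        for name in ("chi", "D", "gamma", "K"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def R_profile(self, r: np.ndarray) -> np.ndarray:
        if callable(self.R_influx):
            return np.asarray(self.R_influx(r), dtype=float)
        return np.full_like(np.asarray(r, dtype=float), float(self.R_influx))


@dataclass
class ScalarField:
    """Radially symmetric scalar field sampled at the cell centers."""

    values: np.ndarray
    grid: RadialGrid
    kind: str = "concentration"      # or "potential"

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({"r": self.grid.centers,
                      self.kind: self.values}).to_csv(path, index=False)


def _tridiag_solve(lower, diag, upper, rhs):
    ab = np.zeros((3, diag.size))
    ab[0, 1:] = upper[:-1]
    ab[1, :] = diag
    ab[2, :-1] = lower[1:]
    return scipy.linalg.solve_banded((1, 1), ab, rhs)


def solve_chemo_potential(grid: RadialGrid, K: float,
                          sigma: FormFunction) -> ScalarField:
    """Stationary chemoattractive potential on the disk.

    Solves -K lap Phi = sigma - <sigma> with zero-flux boundary, where
    <sigma> is the disk average (the mean-zero right-hand side makes the
    Neumann problem solvable); the solution is gauge-fixed to zero disk mean.
    """
    if K <= 0:
        raise ValueError("K must be positive")
    r_c, f, dr = grid.centers, grid.faces, grid.dr
    rhs_pt = sigma(r_c)
    rhs_pt = rhs_pt - grid.disk_average(rhs_pt)
    # cell balance: -K [r Phi']_{m-1/2}^{m+1/2} = rhs_m * r_m * dr
    M = grid.n_cells
    r_in, r_out = f[:-1], f[1:]
    lower = np.zeros(M)
    diag = np.zeros(M)
    upper = np.zeros(M)
    # interior faces carry -K r_f (Phi_{m+1} - Phi_m)/dr; outer face zero flux,
    # inner face r = 0 has zero area
    co = K * r_out / dr
    ci = K * r_in / dr
    co[-1] = 0.0
    diag[:] = co + ci
    upper[:-1] = -co[:-1]
    lower[1:] = -ci[1:]
    b = rhs_pt * r_c * dr
    # the system has the constant nullspace; pin the first unknown and let
    # compatibility (zero-mean rhs) make the rest consistent, then re-gauge
    diag0, upper0, b0 = diag.copy(), upper.copy(), b.copy()
    diag0[0] = 1.0
    upper0[0] = 0.0
    b0[0] = 0.0
    phi = _tridiag_solve(lower, diag0, upper0, b0)
    if not np.all(np.isfinite(phi)):
        raise FieldSolveError("potential solve produced non-finite values")
    phi = phi - grid.disk_average(phi)
    return ScalarField(phi, grid, kind="potential")


def concentration_system(grid: RadialGrid, params: ImmuneParameters,
                         potential: ScalarField, mu1: float):
    """Tridiagonal operator and source of the stationary immune equation.

    Returns (lower, diag, upper, source) such that the stationary problem
    reads  A C = source  per unit cell area, i.e. row m encodes
    gamma C_m + (1/(r_m dr)) [r J]_{m-1/2}^{m+1/2} = mu1 R_m with the flux
    J = mu1 chi C dPhi/dr - D dC/dr, first-order upwinded in the drift and
    with the Dirichlet value C = 0 on the outer boundary.  Shared by the
    stationary solver and the implicit time stepper of the evolution module.
    """
    if mu1 < 0:
        raise ValueError("mu1 must be nonnegative")
    if potential.grid is not grid and (
            potential.grid.n_cells != grid.n_cells
            or potential.grid.radius != grid.radius):
        raise ValueError("potential was computed on a different grid")
    M, dr = grid.n_cells, grid.dr
    r_c, f = grid.centers, grid.faces
    phi = potential.values
    area = r_c * dr                       # cell area / (2 pi)
    # face drift velocities v = mu1 chi dPhi/dr at interior faces; the outer
    # face has zero potential gradient (zero-flux condition on Phi)
    v_int = mu1 * params.chi * (phi[1:] - phi[:-1]) / dr     # faces 1..M-1
    r_int = f[1:-1]
    lower = np.zeros(M)
    diag = np.full(M, params.gamma)
    upper = np.zeros(M)
    # interior faces: J r = r [ v C_up - D (C_{m+1}-C_m)/dr ]
    vp = np.maximum(v_int, 0.0)          # carries C_m outward
    vm = np.minimum(v_int, 0.0)          # carries C_{m+1} inward
    dcoef = params.D / dr
    # contribution to cell m (face m+1/2 outgoing, positive sign):
    diag[:-1] += r_int * (vp + dcoef) / area[:-1]
    upper[:-1] += r_int * (vm - dcoef) / area[:-1]
    # contribution to cell m+1 (face m+1/2 incoming, negative sign):
    diag[1:] += -r_int * (vm - dcoef) / area[1:]
    lower[1:] += -r_int * (vp + dcoef) / area[1:]
    # outer face: Dirichlet C = 0 half-cell diffusion, zero drift
    diag[-1] += f[-1] * (2.0 * params.D / dr) / area[-1]
    source = mu1 * params.R_profile(r_c)
    return lower, diag, upper, source


def solve_immune_concentration(grid: RadialGrid, params: ImmuneParameters,
                               potential: ScalarField,
                               mu1: float) -> ScalarField:
    """Stationary immune-cell concentration for a given residual mass mu1.

    Radial finite-volume solve of the drift-diffusion-reaction balance with
    homogeneous Dirichlet condition on the outer boundary; the upwinded
    advection makes the matrix an M-matrix, so the solution is nonnegative.
    """
    lower, diag, upper, source = concentration_system(
        grid, params, potential, mu1)
    C = _tridiag_solve(lower, diag, upper, source)
    if not np.all(np.isfinite(C)):
        raise FieldSolveError("concentration solve produced non-finite values")
    floor = -1e-12 * max(1.0, float(np.max(np.abs(C))))
    if np.any(C < floor):
        raise FieldSolveError(
            f"scheme violation: concentration fell below zero "
            f"(min {C.min():.3e})")
    return ScalarField(np.maximum(C, 0.0), grid, kind="concentration")


def effective_death_rate(C: ScalarField, delta: FormFunction,
                         grid: RadialGrid | None = None) -> float:
    """Induced tumor death rate: delta-weighted disk integral of C.

    This is the size-uniform killing rate mu_bar_c that the immune field
    exerts on every tumor cell.
    """
    g = grid or C.grid
    if g.n_cells != C.grid.n_cells or g.radius != C.grid.radius:
        raise ValueError("field and grid do not match")
    return g.disk_integral(delta(g.centers) * C.values)
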