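"""Power-dichotomy prediction of the immune-controlled residual tumor mass.

At equilibrium the size-uniform death rate exerted by the immune field
exactly offsets the Malthus growth rate of the tumor population:

    integral( delta(x) C_mu1(x) dx ) = lambda,

where C_mu1 solves the stationary immune equation for residual mass mu1 and
lambda is the leading eigenvalue of the growth-division operator.  Since the
induced death rate grows monotonically with the mass, the equilibrium mass
is found by bisection ("dichotomy") on mu1: the chemoattractive potential is
computed once, each trial mass costs one tridiagonal solve, and the bracket
is halved until its relative width falls below the tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .fields import (
    FormFunction,
    ImmuneParameters,
    RadialGrid,
    ScalarField,
    effective_death_rate,
    solve_chemo_potential,
    solve_immune_concentration,
)
from .size_dynamics import EigenPair

__all__ = [
    "EquilibriumResult",
    "NoEquilibriumError",
    "predict_equilibrium",
    "mass_to_diameter",
    "parameter_sweep",
]


class NoEquilibriumError(RuntimeError):
    """No equilibrium mass inside the (expanded) bracket."""


@dataclass
class EquilibriumResult:
    """Residual tumor mass at equilibrium with bisection diagnostics.

    ``mu1`` is in mm^3 and ``diameter`` is the equivalent-sphere diameter in
    mm; ``bracket_history`` records (mu_a, mu_b) at every bisection step.
    """

    mu1: float
    diameter: float
    lam: float
    bracket_history: list[tuple[float, float]] = field(default_factory=list)
    iterations: int = 0
    converged: bool = False
    profile: EigenPair | None = None


def mass_to_diameter(mu1: float) -> float:
    """Equivalent-sphere diameter d = (6 mu1 / pi)^(1/3).

    Unit-agnostic: mm^3 in gives mm out, micron^3 in gives micron out.
    """
    if mu1 < 0:
        raise ValueError("mass must be nonnegative")
    return (6.0 * mu1 / math.pi) ** (1.0 / 3.0)


def predict_equilibrium(eig: EigenPair | float,
                        params: ImmuneParameters,
                        delta: FormFunction,
                        sigma: FormFunction,
                        grid: RadialGrid,
                        bracket: tuple[float, float] = (1e-10, 10.0),
                        eps_d: float = 1e-8,
                        max_expand: int = 6,
                        potential: ScalarField | None = None,
                        check_monotone: bool = False) -> EquilibriumResult:
    """Bisection on the residual mass until the induced death rate matches lambda.

    ``eig`` may be a computed EigenPair or a bare eigenvalue.  The potential
    is solved once (or reused if supplied).  If the initial bracket does not
    straddle the root, it is expanded geometrically (factor 10 per side) up
    to ``max_expand`` times before giving up.
    """
    lam = eig.lam if isinstance(eig, EigenPair) else float(eig)
    if lam <= 0:
        raise ValueError("lambda must be positive")
    mu_a, mu_b = bracket
    if not (0 <= mu_a < mu_b):
        raise ValueError("need 0 <= mu_a < mu_b")
    phi = potential if potential is not None else solve_chemo_potential(
        grid, params.K, sigma)

    def excess(mu1: float) -> float:
        C = solve_immune_concentration(grid, params, phi, mu1)
        return effective_death_rate(C, delta) - lam

    f_a, f_b = excess(mu_a), excess(mu_b)
    if abs(f_a) <= eps_d * lam:
        d = mass_to_diameter(mu_a)
        return EquilibriumResult(mu_a, d, lam, [(mu_a, mu_b)], 0, True,
                                 eig if isinstance(eig, EigenPair) else None)
    expansions = 0
    while f_a * f_b > 0 and expansions < max_expand:
        if f_a > 0:                      # root below mu_a
            mu_a = max(mu_a / 10.0, 0.0)
            f_a = excess(mu_a)
        else:                            # f_b < 0: root above mu_b
            mu_b *= 10.0
            f_b = excess(mu_b)
        expansions += 1
    if f_a * f_b > 0:
        raise NoEquilibriumError(
            f"no sign change for mu1 in [{mu_a:g}, {mu_b:g}] after "
            f"{expansions} expansions (death-rate excess {f_a:.3e} .. "
            f"{f_b:.3e})")
    history = [(mu_a, mu_b)]
    it = 0
    last_f = None
    while (mu_b - mu_a) / max(mu_a, np.finfo(float).tiny) >= eps_d:
        it += 1
        mu1 = 0.5 * (mu_a + mu_b)
        f_m = excess(mu1)
        if check_monotone and last_f is not None and f_m < f_a:
            raise NoEquilibriumError(
                "induced death rate is not monotone over the bracket")
        if f_m < 0:
            mu_a, f_a = mu1, f_m
        else:
            mu_b, f_b = mu1, f_m
        history.append((mu_a, mu_b))
        last_f = f_m
        if it > 200:  # 2^-200 of any sane bracket; defensive only
            break
    mu1 = 0.5 * (mu_a + mu_b)
    converged = (mu_b - mu_a) / max(mu_a, np.finfo(float).tiny) < eps_d
    return EquilibriumResult(mu1, mass_to_diameter(mu1), lam, history, it,
                             converged,
                             eig if isinstance(eig, EigenPair) else None)


#: parameters a sweep may vary; "a" re-derives the eigenvalue (lambda = a for
#: the binary-division kernel with constant rates), the rest are immune-side
_SWEEPABLE = ("a", "A", "R", "gamma", "chi", "D", "K", "A_sigma")


def parameter_sweep(vary: str,
                    values: Sequence[float],
                    lam: float,
                    params: ImmuneParameters,
                    delta: FormFunction,
                    sigma: FormFunction,
                    grid: RadialGrid,
                    bracket: tuple[float, float] = (1e-10, 10.0),
                    eps_d: float = 1e-8) -> pd.DataFrame:
    """Equilibrium mass along a 1-D parameter sweep.

    Returns a tidy frame (value, mu1_mm3, diameter_mm, lam, converged,
    error).  Varying ``a`` re-derives lambda = a (constant division rate,
    binary kernel); failures are recorded per row and the sweep continues.
    The potential is reused across rows unless the sweep varies K or the
    signal shape A_sigma.
    """
    if vary not in _SWEEPABLE:
        raise ValueError(f"cannot sweep {vary!r}; one of {_SWEEPABLE}")
    rows = []
    phi_cache = None
    if vary not in ("K", "A_sigma"):
        phi_cache = solve_chemo_potential(grid, params.K, sigma)
    for v in values:
        if v <= 0:
            rows.append({"value": v, "mu1_mm3": np.nan, "diameter_mm": np.nan,
                         "lam": np.nan, "converged": False,
                         "error": "nonpositive parameter value"})
            continue
        p, d, s, lam_v = params, delta, sigma, lam
        if vary == "a":
            lam_v = v
        elif vary == "A":
            d = FormFunction(v, delta.width)
        elif vary == "A_sigma":
            s = FormFunction(v, sigma.width)
        else:
            key = "R_influx" if vary == "R" else vary
            p = ImmuneParameters(**{**_as_dict(params), key: v})
        try:
            res = predict_equilibrium(lam_v, p, d, s, grid, bracket, eps_d,
                                      potential=phi_cache)
            rows.append({"value": v, "mu1_mm3": res.mu1,
                         "diameter_mm": res.diameter, "lam": lam_v,
                         "converged": res.converged, "error": ""})
        except Exception as exc:  # record and continue
            rows.append({"value": v, "mu1_mm3": np.nan, "diameter_mm": np.nan,
                         "lam": lam_v, "converged": False, "error": str(exc)})
    return pd.DataFrame(rows)


def _as_dict(params: ImmuneParameters) -> dict:
    return {"chi": params.chi, "D": params.D, "gamma": params.gamma,
            "K": params.K, "R_influx": params.R_influx}
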