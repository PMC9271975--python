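"""Reduced tumor-growth model and synthetic mouse-cohort generator.

Neglecting the immune response and spatial structure, the tumor moments and
the immune concentration obey the closed system

    d mu0 / dt = a mu0,      d mu1 / dt = V mu0,      d c / dt = R mu1,

whose solutions are available in closed form.  The cohort generator draws
per-individual parameters (a, V, R) log-normally around population values
with a correlation between a and R on the log scale, evaluates the three
observable types (0: cell count, 1: tumor volume, 2: immune concentration)
on a sampling schedule, applies proportional measurement noise
y = f (1 + b_k eps), and left-censors observations below a limit of
quantification.  A per-individual weighted least-squares fit on the log
scale recovers (a, V, R); the population-level mixed-effects machinery used
on the real data is out of scope.

Volumes are unit-agnostic: mu1 carries the same volume unit as V (the
defaults use micron^3, with helpers to express initial conditions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.optimize

__all__ = [
    "PopulationParameters",
    "reduced_moments",
    "initial_mass",
    "simulate_cohort",
    "fit_individual",
    "DEFAULT_SCHEDULE",
]

#: observation type codes: 0 = cell count mu0, 1 = tumor volume mu1,
#: 2 = immune concentration c
OBS_TYPES = (0, 1, 2)

#: default sampling schedule (days), exposed rather than hard-coded
DEFAULT_SCHEDULE: Mapping[int, tuple[float, ...]] = {
    0: (7.0, 14.0, 21.0, 28.0),
    1: (4.0, 7.0, 11.0, 14.0, 18.0, 21.0, 25.0, 28.0),
    2: (7.0, 14.0, 21.0, 28.0),
}


@dataclass(frozen=True)
class PopulationParameters:
    """Population fixed effects, random-effect SDs, correlation and noise.

    ``omega_*`` are standard deviations of the log-scale random effects,
    ``rho_aR`` the correlation of the a and R effects, and ``b`` the
    proportional-error factors per observation type (indexed 0, 1, 2).
    Defaults are the mouse-cohort population estimates.
    """

    a_pop: float = 0.12
    V_pop: float = 816.33           # micron^3 / day
    R_pop: float = 2.2e-6
    omega_a: float = 0.20
    omega_V: float = 0.51
    omega_R: float = 0.84
    rho_aR: float = 0.8
    b: tuple[float, float, float] = (0.37, 0.17, 0.18)

    def __post_init__(self):
        if min(self.a_pop, self.V_pop, self.R_pop) <= 0:
            raise ValueError("population values must be positive")
        if min(self.omega_a, self.omega_V, self.omega_R) < 0:
            raise ValueError("random-effect SDs must be nonnegative")
        if not -1.0 < self.rho_aR < 1.0:
            raise ValueError("|rho_aR| must be < 1")

    def log_covariance(self) -> np.ndarray:
        """Covariance of (log a, log V, log R) random effects."""
        C = np.diag([self.omega_a ** 2, self.omega_V ** 2,
                     self.omega_R ** 2])
        C[0, 2] = C[2, 0] = self.rho_aR * self.omega_a * self.omega_R
        return C


def initial_mass(n_cells: float, cell_radius: float = 15.0) -> float:
    """Initial tumor volume of n spherical cells (radius in micron -> micron^3)."""
    return n_cells * 4.0 / 3.0 * math.pi * cell_radius ** 3


def reduced_moments(t, a: float, V: float, R: float,
                    ics: tuple[float, float, float] = (5e5,
                                                       initial_mass(5e5),
                                                       0.0)):
    """Closed-form (mu0, mu1, c) of the reduced growth model at times t.

    mu0 = mu0(0) e^{a t};  mu1 = mu1(0) + (V/a) mu0(0) (e^{a t} - 1);
    c = c(0) + R [ mu1(0) t + (V/a) mu0(0) ((e^{a t} - 1)/a - t) ].
    The a -> 0 limit (linear mu1, quadratic c) is handled explicitly.
    """
    t = np.asarray(t, dtype=float)
    mu0_0, mu1_0, c0 = ics
    if a != 0.0:
        eat = np.exp(a * t)
        mu0 = mu0_0 * eat
        mu1 = mu1_0 + V / a * mu0_0 * (eat - 1.0)
        c = c0 + R * (mu1_0 * t + V / a * mu0_0 * ((eat - 1.0) / a - t))
    else:
        mu0 = np.full_like(t, mu0_0)
        mu1 = mu1_0 + V * mu0_0 * t
        c = c0 + R * (mu1_0 * t + 0.5 * V * mu0_0 * t ** 2)
    return mu0, mu1, c


def simulate_cohort(pop: PopulationParameters,
                    n_mice: int,
                    schedule: Mapping[int, Sequence[float]] = DEFAULT_SCHEDULE,
                    loq: Mapping[int, float] | None = None,
                    seed: int = 0,
                    ics: tuple[float, float, float] = (5e5,
                                                       initial_mass(5e5),
                                                       0.0)
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic cohort with the study's statistical structure.

    Returns (observations, truth).  Observations is a long-format frame
    (mouse_id, type, time, value, censored, loq); censored records carry the
    censoring interval [0, loq] instead of a value (value is NaN).  Truth
    holds the per-mouse parameters actually drawn, for recovery studies.
    """
    if n_mice < 1:
        raise ValueError("need at least one mouse")
    cov = pop.log_covariance()
    # covariance validity (rho guaranteed by construction, but a custom cov
    # path may be added later)
    np.linalg.cholesky(cov + 1e-300 * np.eye(3))
    rng = np.random.default_rng(seed)
    mean = np.log([pop.a_pop, pop.V_pop, pop.R_pop])
    logs = rng.multivariate_normal(mean, cov, size=n_mice)
    theta = np.exp(logs)
    loq = dict(loq or {})
    rows = []
    for i in range(n_mice):
        a_i, V_i, R_i = theta[i]
        for k in OBS_TYPES:
            times = np.asarray(schedule.get(k, ()), dtype=float)
            if times.size == 0:
                continue
            if np.any(times < 0):
                raise ValueError("observation times must be nonnegative")
            f = reduced_moments(times, a_i, V_i, R_i, ics)[k]
            eps = rng.standard_normal(times.size)
            y = f * (1.0 + pop.b[k] * eps)
            thr = loq.get(k)
            for t_j, y_j in zip(times, y):
                censored = thr is not None and y_j < thr
                rows.append({
                    "mouse_id": i, "type": k, "time": t_j,
                    "value": np.nan if censored else y_j,
                    "censored": censored,
                    "loq": thr if censored else np.nan,
                })
    obs = pd.DataFrame(rows)
    truth = pd.DataFrame({"mouse_id": np.arange(n_mice),
                          "a": theta[:, 0], "V": theta[:, 1],
                          "R": theta[:, 2]})
    return obs, truth


def fit_individual(observations: pd.DataFrame,
                   ics: tuple[float, float, float] = (5e5,
                                                      initial_mass(5e5),
                                                      0.0),
                   b: tuple[float, float, float] = (0.37, 0.17, 0.18)
                   ) -> tuple[float, float, float]:
    """Recover (a, V, R) for one mouse by weighted log-scale least squares.

    Censored records are excluded.  Residuals are (ln y - ln f_k)/b_k — the
    log transform turns the proportional error model into approximately
    additive noise with SD b_k, so the weights are the inverse error
    factors.  Requires at least two uncensored cell-count observations at
    distinct times (the growth rate is identified from type 0 alone).
    """
    obs = observations[~observations["censored"].astype(bool)]
    obs = obs[np.isfinite(obs["value"]) & (obs["value"] > 0)]
    t0 = obs[obs["type"] == 0]
    if len(t0) < 2 or t0["time"].nunique() < 2:
        missing = [k for k in OBS_TYPES
                   if len(obs[obs["type"] == k]) == 0]
        raise ValueError(
            "need >= 2 uncensored cell-count observations at distinct times "
            f"(types without data: {missing})")
    mu0_0 = ics[0]
    # start values: log-linear regression for a, then moment matching
    tt, yy = t0["time"].to_numpy(), t0["value"].to_numpy()
    slope = np.polyfit(tt, np.log(yy / mu0_0), 1)[0]
    a0 = max(slope, 1e-3)
    t1 = obs[obs["type"] == 1]
    if len(t1):
        j = t1["time"].idxmax()
        grow = (np.exp(a0 * t1.loc[j, "time"]) - 1.0) / a0 * mu0_0
        V0 = max((t1.loc[j, "value"] - ics[1]) / max(grow, 1e-30), 1e-6)
    else:
        V0 = 1.0
    t2 = obs[obs["type"] == 2]
    if len(t2):
        j = t2["time"].idxmax()
        _, _, c_unit = reduced_moments(t2.loc[j, "time"], a0, V0, 1.0, ics)
        R0 = max(t2.loc[j, "value"] / max(float(c_unit), 1e-30), 1e-30)
    else:
        R0 = 1e-6

    types = obs["type"].to_numpy()
    times = obs["time"].to_numpy()
    values = np.log(obs["value"].to_numpy())
    weights = 1.0 / np.asarray(b, dtype=float)[types]

    def residuals(x):
        a_, V_, R_ = np.exp(x)
        m = reduced_moments(times, a_, V_, R_, ics)
        f = np.choose(types, m)
        return weights * (values - np.log(np.maximum(f, 1e-300)))

    sol = scipy.optimize.least_squares(
        residuals, x0=np.log([a0, V0, R0]), method="lm", xtol=1e-14,
        ftol=1e-14, gtol=1e-14, max_nfev=2000)
    a_hat, V_hat, R_hat = np.exp(sol.x)
    return float(a_hat), float(V_hat), float(R_hat)
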