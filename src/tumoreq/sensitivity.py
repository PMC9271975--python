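"""Global sensitivity analysis of the equilibrium tumor mass.

The equilibrium mass is viewed as a function of eight uncertain biological
inputs, mu1 = f(a, A, R, chi, D, A_sigma, gamma, K), with uniform
distributions over the literature ranges for (A, chi, D, A_sigma, gamma, K)
and log-normal distributions for the division rate a and the influx rate R.
Because mu1 is close to log-normally distributed over this space (and a
log-normal is not determined by its moments), the polynomial-chaos surrogate
is built for ln mu1:

    ln mu1(omega) ~ sum_{alpha in J} q_alpha L_alpha(theta(omega)),

where L_alpha are products of orthonormal Legendre polynomials of the inputs
mapped to the standardized cube [-1, 1]^8 through their marginal CDFs, J is
the total-degree-p multi-index set restricted to a maximum interaction
order, and the coefficients come from least squares on a space-filling
(Latin hypercube) design with a leave-one-out error estimate.  First,
second, and total Sobol indices of f = exp(surrogate) are then computed by
two-sample pick-freeze Monte Carlo estimators.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import eval_legendre, ndtr, ndtri
from scipy.stats import qmc

__all__ = [
    "Marginal",
    "Uniform",
    "LogNormal",
    "ParameterSpace",
    "default_parameter_space",
    "Surrogate",
    "SobolReport",
    "build_basis",
    "sample_parameters",
    "fit_log_surrogate",
    "sobol_indices",
    "equilibrium_model",
]


# --------------------------------------------------------------------------
# marginals and parameter space
# --------------------------------------------------------------------------

class Marginal:
    """Base class: maps the uniform unit interval to physical values."""

    def from_unit(self, u: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def to_unit(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


@dataclass(frozen=True)
class Uniform(Marginal):
    lo: float
    hi: float

    def __post_init__(self):
        if not (0 < self.lo < self.hi):
            raise ValueError("need 0 < lo < hi")

    def from_unit(self, u):
        return self.lo + (self.hi - self.lo) * np.asarray(u, dtype=float)

    def to_unit(self, x):
        return (np.asarray(x, dtype=float) - self.lo) / (self.hi - self.lo)


@dataclass(frozen=True)
class LogNormal(Marginal):
    """Log-normal marginal, truncated at the 0.1% / 99.9% quantiles.

    The truncation bounds the standardized cube so a single Legendre basis
    serves all inputs; it removes only 0.2% of the probability mass.
    """

    meanlog: float
    sdlog: float
    q_lo: float = 1e-3
    q_hi: float = 1.0 - 1e-3

    def __post_init__(self):
        if self.sdlog <= 0:
            raise ValueError("sdlog must be positive")

    def from_unit(self, u):
        q = self.q_lo + (self.q_hi - self.q_lo) * np.asarray(u, dtype=float)
        return np.exp(self.meanlog + self.sdlog * ndtri(q))

    def to_unit(self, x):
        q = ndtr((np.log(np.asarray(x, dtype=float)) - self.meanlog)
                 / self.sdlog)
        return (q - self.q_lo) / (self.q_hi - self.q_lo)


@dataclass(frozen=True)
class ParameterSpace:
    """Ordered collection of named marginals (the uncertain model inputs)."""

    names: tuple[str, ...]
    marginals: tuple[Marginal, ...]

    def __post_init__(self):
        if len(self.names) != len(self.marginals):
            raise ValueError("names and marginals must align")

    @property
    def dim(self) -> int:
        return len(self.names)

    def from_unit(self, U: np.ndarray) -> pd.DataFrame:
        U = np.atleast_2d(U)
        cols = {n: m.from_unit(U[:, i])
                for i, (n, m) in enumerate(zip(self.names, self.marginals))}
        return pd.DataFrame(cols)

    def to_standardized(self, table: pd.DataFrame) -> np.ndarray:
        """Physical values -> xi in [-1, 1]^k through the marginal CDFs."""
        out = np.empty((len(table), self.dim))
        for i, (n, m) in enumerate(zip(self.names, self.marginals)):
            out[:, i] = 2.0 * m.to_unit(table[n].to_numpy()) - 1.0
        return out


def default_parameter_space() -> ParameterSpace:
    """The eight uncertain inputs of the equilibrium model.

    Uniform ranges follow the literature table of the immune/environment
    parameters; the division rate a and the influx rate R carry the
    log-normal population distributions estimated from the mouse cohort
    (ln a ~ N(ln 0.12, 0.2^2), ln R ~ N(ln 2.2e-6, 0.84^2)).
    """
    return ParameterSpace(
        names=("a", "A", "R", "chi", "D", "A_sigma", "gamma", "K"),
        marginals=(
            LogNormal(math.log(0.12), 0.2),
            Uniform(2.0, 57.6),
            LogNormal(math.log(2.2e-6), 0.84),
            Uniform(8.64e1, 8.64e6),
            Uniform(8.64e-5, 1e-3),
            Uniform(5e-17, 6.25e-17),
            Uniform(2e-2, 1.0),
            Uniform(1e-2, 1.0),
        ))


# --------------------------------------------------------------------------
# basis and design
# --------------------------------------------------------------------------

def build_basis(k: int = 8, p: int = 5, max_interaction: int | None = 2,
                oversampling: float = 2.0) -> tuple[np.ndarray, int]:
    """Multi-index set of total degree <= p with bounded interaction order.

    Returns (indices, design_size): all alpha in N^k with sum(alpha) <= p and
    at most ``max_interaction`` nonzero components (None = unrestricted),
    plus the recommended least-squares design size
    ceil(oversampling x basis size).
    """
    if p < 1 or k < 1:
        raise ValueError("need k >= 1 and p >= 1")
    if max_interaction is None:
        max_interaction = k
    if max_interaction < 1:
        raise ValueError("max_interaction must be >= 1")
    indices = [np.zeros(k, dtype=int)]
    for order in range(1, min(max_interaction, k) + 1):
        for pos in itertools.combinations(range(k), order):
            # strictly positive degrees on `pos` summing to <= p
            for degs in _compositions_at_most(p, order):
                alpha = np.zeros(k, dtype=int)
                alpha[list(pos)] = degs
                indices.append(alpha)
    J = np.array(indices, dtype=int)
    design_size = int(math.ceil(oversampling * len(J)))
    return J, design_size


def _compositions_at_most(total: int, parts: int):
    """All tuples of `parts` positive integers with sum <= total."""
    if parts == 0:
        yield ()
        return
    for first in range(1, total - parts + 2):
        for rest in _compositions_at_most(total - first, parts - 1):
            yield (first,) + rest


def sample_parameters(space: ParameterSpace, n: int,
                      seed: int) -> pd.DataFrame:
    """Space-filling (Latin hypercube) sample of the parameter space.

    Draws a maximin-free LHS in the unit cube and maps it through each
    marginal's inverse transform; reproducible per seed.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    sampler = qmc.LatinHypercube(d=space.dim, seed=seed)
    return space.from_unit(sampler.random(n))


# --------------------------------------------------------------------------
# surrogate
# --------------------------------------------------------------------------

def _legendre_design(xi: np.ndarray, J: np.ndarray) -> np.ndarray:
    """Design matrix of orthonormal Legendre products at standardized points."""
    n, k = xi.shape
    p_max = int(J.max())
    # P[d, :, i] = orthonormal Legendre_d(xi[:, i]); weight 1/2 on [-1, 1]
    P = np.empty((p_max + 1, n, k))
    for d in range(p_max + 1):
        P[d] = math.sqrt(2 * d + 1) * eval_legendre(d, xi)
    Psi = np.ones((n, len(J)))
    for t, alpha in enumerate(J):
        for i in np.nonzero(alpha)[0]:
            Psi[:, t] *= P[alpha[i], :, i]
    return Psi


@dataclass
class Surrogate:
    """Polynomial-chaos surrogate of ln mu1 on the standardized cube."""

    space: ParameterSpace
    indices: np.ndarray                  # (n_terms, k) multi-index set
    coefficients: np.ndarray             # (n_terms,)
    loo_error: float = math.nan          # relative leave-one-out error

    def predict_xi(self, xi: np.ndarray) -> np.ndarray:
        """Evaluate ln mu1 at standardized coordinates xi in [-1, 1]^k."""
        return _legendre_design(np.atleast_2d(xi), self.indices) \
            @ self.coefficients

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Evaluate ln mu1 at physical parameter values."""
        return self.predict_xi(self.space.to_standardized(table))

    def to_json_dict(self) -> dict:
        return {"names": list(self.space.names),
                "indices": self.indices.tolist(),
                "coefficients": self.coefficients.tolist(),
                "loo_error": self.loo_error}


def fit_log_surrogate(design: pd.DataFrame, log_mu1: np.ndarray,
                      space: ParameterSpace,
                      indices: np.ndarray) -> Surrogate:
    """Least-squares fit of the Legendre expansion of ln mu1.

    ``design`` holds physical parameter values (one row per model run) and
    ``log_mu1`` the matching ln mu1 evaluations.  The relative leave-one-out
    error is computed from the hat-matrix diagonal and stored on the result.
    """
    y = np.asarray(log_mu1, dtype=float)
    if len(design) != y.size:
        raise ValueError("design and evaluations must align")
    if y.size < len(indices):
        raise ValueError(
            f"{y.size} evaluations cannot identify {len(indices)} "
            "coefficients; enlarge the design (higher oversampling)")
    xi = space.to_standardized(design)
    Psi = _legendre_design(xi, indices)
    coef, res, rank, sv = np.linalg.lstsq(Psi, y, rcond=None)
    if rank < len(indices):
        raise ValueError(
            "rank-deficient design; increase the oversampling factor")
    # leave-one-out residuals from the hat matrix diagonal
    Q, _ = np.linalg.qr(Psi)
    hat = np.sum(Q * Q, axis=1)
    resid = y - Psi @ coef
    loo = resid / np.maximum(1.0 - hat, 1e-12)
    denom = float(np.sum((y - y.mean()) ** 2))
    loo_err = float(np.sum(loo ** 2) / denom) if denom > 0 else 0.0
    return Surrogate(space, np.asarray(indices), coef, loo_err)


# --------------------------------------------------------------------------
# Sobol indices by pick-freeze Monte Carlo
# --------------------------------------------------------------------------

@dataclass
class SobolReport:
    """First, second and total Sobol indices with sampling metadata."""

    names: tuple[str, ...]
    first: dict[str, float]
    second: dict[tuple[str, str], float]
    total: dict[str, float]
    n_mc: int
    seed: int
    mean: float
    variance: float

    def to_frame(self) -> pd.DataFrame:
        rows = [{"index": n, "order": 1, "value": v}
                for n, v in self.first.items()]
        rows += [{"index": f"{i}:{j}", "order": 2, "value": v}
                 for (i, j), v in self.second.items()]
        rows += [{"index": n, "order": 0, "value": v}
                 for n, v in self.total.items()]   # order 0 marks totals
        df = pd.DataFrame(rows)
        df["kind"] = df["order"].map({1: "first", 2: "second", 0: "total"})
        return df[["index", "kind", "value"]]


def sobol_indices(f: Surrogate | Callable[[np.ndarray], np.ndarray],
                  n_mc: int = 100_000,
                  seed: int = 0,
                  names: Sequence[str] | None = None,
                  dim: int | None = None,
                  second_order: bool = True) -> SobolReport:
    """Pick-freeze Monte Carlo Sobol indices of exp(surrogate).

    Two independent samples A and B of the standardized cube are drawn; the
    first-order variance contribution of input i correlates f(A) with f at B
    whose i-th column is frozen to A's, second-order contributions freeze
    pairs (subtracting the singles), and the total index of i freezes all
    columns except the i-th.  ``f`` may be a fitted Surrogate (evaluated as
    exp(ln mu1)) or any callable on the cube (used directly).
    """
    if isinstance(f, Surrogate):
        k = f.space.dim
        names = names or f.space.names
        fun = lambda xi: np.exp(f.predict_xi(xi))
    else:
        if dim is None:
            raise ValueError("dim is required for a bare callable")
        k = dim
        names = tuple(names) if names else tuple(f"x{i}" for i in range(k))
        fun = f
    rng = np.random.default_rng(seed)
    A = rng.uniform(-1.0, 1.0, size=(n_mc, k))
    B = rng.uniform(-1.0, 1.0, size=(n_mc, k))
    fA = fun(A)
    f0 = float(np.mean(fA))
    V = float(np.mean(fA ** 2) - f0 ** 2)
    if V <= 0 or not np.isfinite(V):
        raise ValueError("degenerate output variance; check the surrogate")

    def freeze(base: np.ndarray, source: np.ndarray, cols) -> np.ndarray:
        out = base.copy()
        out[:, cols] = source[:, cols]
        return out

    Vi = np.empty(k)
    Vmi = np.empty(k)
    for i in range(k):
        Vi[i] = np.mean(fA * fun(freeze(B, A, [i]))) - f0 ** 2
        Vmi[i] = np.mean(fA * fun(freeze(A, B, [i]))) - f0 ** 2
    first = {names[i]: float(Vi[i] / V) for i in range(k)}
    total = {names[i]: float(1.0 - Vmi[i] / V) for i in range(k)}
    second = {}
    if second_order:
        for i, j in itertools.combinations(range(k), 2):
            Vij = np.mean(fA * fun(freeze(B, A, [i, j]))) - f0 ** 2 \
                - Vi[i] - Vi[j]
            second[(names[i], names[j])] = float(Vij / V)
    return SobolReport(tuple(names), first, second, total, n_mc, seed,
                       f0, V)


# --------------------------------------------------------------------------
# the model behind the design evaluations
# --------------------------------------------------------------------------

def equilibrium_model(table: pd.DataFrame,
                      radial_cells: int = 100,
                      delta_width: float = 0.1,
                      sigma_width: float = 0.1,
                      eps_d: float = 1e-8) -> np.ndarray:
    """Evaluate the equilibrium mass mu1 for each parameter row.

    Each row carries (a, A, R, chi, D, A_sigma, gamma, K); the growth rate
    is held at its population value and the division kernel is binary with
    constant rate, so the Malthus eigenvalue equals a.  Uses the full
    stationary solver (drift included) for every evaluation.
    """
    from .equilibrium import predict_equilibrium
    from .fields import (FormFunction, ImmuneParameters, RadialGrid,
                         solve_chemo_potential)

    grid = RadialGrid(1.0, radial_cells)
    out = np.empty(len(table))
    for idx, row in enumerate(table.itertuples(index=False)):
        params = ImmuneParameters(chi=row.chi, D=row.D, gamma=row.gamma,
                                  K=row.K, R_influx=row.R)
        delta = FormFunction(row.A, delta_width)
        sigma = FormFunction(row.A_sigma, sigma_width)
        phi = solve_chemo_potential(grid, row.K, sigma)
        res = predict_equilibrium(row.a, params, delta, sigma, grid,
                                  eps_d=eps_d, potential=phi)
        out[idx] = res.mu1
    return out
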