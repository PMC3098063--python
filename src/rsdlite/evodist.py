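"""Maximum-likelihood pairwise amino-acid distance.

Implements the distance stage of the ortholog pipeline: given a global
alignment of two protein sequences, estimate the expected number of amino
acid substitutions per site, t, under a reversible empirical substitution
model with optional discrete-gamma rate variation across sites.

Model
-----
The instantaneous rate matrix is Q_ij = S_ij * pi_j (i != j), with S a
symmetric exchangeability matrix and pi the stationary frequencies, scaled
so that -sum_i pi_i Q_ii = 1, i.e. t is measured in expected substitutions
per site.  Among-site rate variation follows a gamma distribution with
shape alpha and mean 1, discretized into K equal-probability categories
whose rates are the category means (alpha -> infinity or K = 1 recovers
the homogeneous model).  For an aligned column (a, b) the likelihood is

    P(a, b | t) = pi_a * (1/K) * sum_k P(a -> b | t * r_k),

and columns are independent, so the log-likelihood is a sum over the
ungapped, unambiguous columns of the alignment.  L(t) is maximized over
[0, t_max] by bounded scalar optimization.

Available exchangeability models: ``JTT`` (default, the Jones–Taylor–
Thornton matrix), ``Dayhoff``, and ``Poisson`` (uniform rates and
frequencies, which admits a 20-state Jukes–Cantor closed form useful as
an independent check).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import gamma as gamma_dist

from ._paml import N_AA, load_dat
from .pairwise import PairwiseAlignment
from .seqio import AMINO_ACIDS

__all__ = [
    "RateModel",
    "DistanceEstimate",
    "build_rate_model",
    "discrete_gamma_rates",
    "transition_matrix",
    "ml_distance",
    "jc20_distance",
    "AVAILABLE_MODELS",
]

AVAILABLE_MODELS = ("JTT", "Dayhoff", "Poisson")

_RESIDUE_INDEX: Mapping[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def discrete_gamma_rates(alpha: float, K: int) -> np.ndarray:
    """Mean rates of K equal-probability slices of Gamma(alpha, mean 1).

    Uses the identity x * f_alpha(x) = f_{alpha+1}(x) for the gamma density
    with shape alpha and rate alpha, so each slice mean is an incomplete-
    gamma difference.  Rates are renormalized to mean exactly 1.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K == 1 or math.isinf(alpha):
        return np.ones(K)
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    edges = gamma_dist.ppf(np.arange(1, K) / K, a=alpha, scale=1.0 / alpha)
    edges = np.concatenate([[0.0], edges, [np.inf]])
    upper = gamma_dist.cdf(edges[1:], a=alpha + 1, scale=1.0 / alpha)
    lower = gamma_dist.cdf(edges[:-1], a=alpha + 1, scale=1.0 / alpha)
    rates = K * (upper - lower)
    return rates / rates.mean()


@dataclass(frozen=True)
class RateModel:
    """A unit-rate reversible substitution model with discrete-gamma rates.

    Holds the scaled rate matrix Q, stationary frequencies pi, the gamma
    shape alpha with K category rates, and a cached eigendecomposition of
    Q for fast transition-matrix evaluation.
    """

    name: str
    Q: np.ndarray
    pi: np.ndarray
    alpha: float
    K: int
    category_rates: np.ndarray
    _evals: np.ndarray
    _U: np.ndarray
    _Uinv: np.ndarray

    def __post_init__(self) -> None:
        Q, pi = self.Q, self.pi
        if not np.allclose(Q.sum(axis=1), 0.0, atol=1e-10):
            raise ValueError("rows of Q must sum to 0")
        off = Q[~np.eye(N_AA, dtype=bool)]
        if (off < -1e-12).any():
            raise ValueError("off-diagonal rates must be non-negative")
        if not np.allclose(pi[:, None] * Q, (pi[:, None] * Q).T, atol=1e-10):
            raise ValueError("model is not time-reversible")
        if abs(-(pi * np.diag(Q)).sum() - 1.0) > 1e-10:
            raise ValueError("Q is not scaled to one substitution per site")
        if abs(self.category_rates.mean() - 1.0) > 1e-10:
            raise ValueError("category rates must average 1")


def build_rate_model(name: str = "JTT", alpha: float = 1.0, K: int = 4) -> RateModel:
    """Construct a named rate model with K discrete-gamma categories.

    ``alpha`` is the gamma shape (use ``math.inf`` for no rate variation);
    ``K = 1`` likewise disables heterogeneity.
    """
    canonical = {m.lower(): m for m in AVAILABLE_MODELS}
    if name.lower() not in canonical:
        raise ValueError(f"unknown model {name!r}; available: {AVAILABLE_MODELS}")
    name = canonical[name.lower()]
    if name == "Poisson":
        S = np.ones((N_AA, N_AA)) - np.eye(N_AA)
        pi = np.full(N_AA, 1.0 / N_AA)
    else:
        S, pi = load_dat(name.lower())

    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -(pi * np.diag(Q)).sum()
    Q = Q / rate

    # reversible Q is similar to a symmetric matrix: use a stable eigh
    sqrt_pi = np.sqrt(pi)
    B = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
    evals, V = np.linalg.eigh((B + B.T) / 2.0)
    U = V / sqrt_pi[:, None]
    Uinv = V.T * sqrt_pi[None, :]

    rates = discrete_gamma_rates(alpha, K)
    return RateModel(
        name=name,
        Q=Q,
        pi=pi,
        alpha=alpha,
        K=K,
        category_rates=rates,
        _evals=evals,
        _U=U,
        _Uinv=Uinv,
    )


def transition_matrix(model: RateModel, t: float, rate: float = 1.0) -> np.ndarray:
    """P(t) = exp(Q * t * rate), via the cached eigendecomposition."""
    if t < 0:
        raise ValueError("t must be non-negative")
    P = (model._U * np.exp(model._evals * t * rate)) @ model._Uinv
    return np.clip(P, 0.0, 1.0)


@dataclass(frozen=True)
class DistanceEstimate:
    """An ML distance in substitutions/site with its optimization status."""

    t_hat: float
    log_likelihood: float
    converged: bool
    n_sites: int


class NoUsableColumnsError(ValueError):
    """The alignment has no column usable for distance estimation."""


def _pattern_counts(aln: PairwiseAlignment) -> np.ndarray:
    """20x20 counts over columns with a canonical residue in both rows."""
    counts = np.zeros((N_AA, N_AA))
    for x, y in aln.columns():
        ix = _RESIDUE_INDEX.get(x)
        iy = _RESIDUE_INDEX.get(y)
        if ix is not None and iy is not None:
            counts[ix, iy] += 1
    return counts


def ml_distance(
    aln: PairwiseAlignment,
    model: RateModel,
    t_max: float = 20.0,
    tol: float = 1e-6,
) -> DistanceEstimate:
    """Maximum-likelihood distance between the two rows of an alignment.

    Columns containing a gap or an unknown residue in either row are
    excluded (complete-column deletion).  The likelihood is maximized over
    t in [0, t_max] by bounded Brent search; an estimate at the upper
    boundary is flagged ``converged=False``.
    """
    counts = _pattern_counts(aln)
    n_sites = int(counts.sum())
    if n_sites == 0:
        has_residue_overlap = any(
            x != "-" and y != "-" for x, y in aln.columns()
        )
        if has_residue_overlap:
            raise NoUsableColumnsError(
                "all residue-residue columns contain unknown residues"
            )
        raise NoUsableColumnsError("the two rows share no ungapped columns")

    weights = model.category_rates
    log_pi_term = float((counts.sum(axis=1) * np.log(model.pi)).sum())
    tiny = 1e-300

    def negloglik(t: float) -> float:
        P = np.zeros((N_AA, N_AA))
        for r in weights:
            P += transition_matrix(model, t, r)
        P /= len(weights)
        return -float((counts * np.log(P + tiny)).sum())

    res = minimize_scalar(
        negloglik, bounds=(0.0, t_max), method="bounded", options={"xatol": tol}
    )
    t_hat = float(res.x)
    best_nll = float(res.fun)
    # identical sequences: the optimum is exactly 0 but bounded search
    # cannot touch the boundary; snap when 0 is at least as good
    nll0 = negloglik(0.0)
    if nll0 <= best_nll:
        t_hat, best_nll = 0.0, nll0
    loglik = -best_nll + log_pi_term
    at_boundary = t_hat >= t_max - 10 * tol
    return DistanceEstimate(
        t_hat=t_hat,
        log_likelihood=loglik,
        converged=bool(res.success) and not at_boundary,
        n_sites=n_sites,
    )


def jc20_distance(p_hat: float) -> float:
    """20-state Jukes–Cantor closed form: the ML distance under the
    Poisson model (K=1) given a fraction ``p_hat`` of differing sites."""
    if not 0 <= p_hat < 19.0 / 20.0:
        raise ValueError("p_hat must lie in [0, 0.95) for a finite distance")
    return -(19.0 / 20.0) * math.log(1.0 - (20.0 / 19.0) * p_hat)
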