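"""Weighted-likelihood Bayesian inference for the partial-order CRM.

For each candidate ordering ``m`` the weighted likelihood of the power-model
parameter ``beta`` over the accumulated patient data ``(x_l, y_l, w_l)`` is

    L~_m(beta) = prod_l [w_l psi_m(x_l, beta)]^{y_l}
                        [1 - w_l psi_m(x_l, beta)]^{1 - y_l}.

With a proper prior g(beta) — normal with mean 0 and variance 1.34 by
default, the convention of the empiric-CRM literature — the module computes
marginal likelihoods per ordering, posterior ordering probabilities,
posterior mean of beta under the selected ordering, plug-in DLT-probability
estimates, the dose recommendation minimising |R^(d_i) - theta|, an
observed-information variance for beta, and the Monte-Carlo probability that
the lowest dose is overly toxic (the input to the safety stopping rule).

Integrals over beta are evaluated on a fixed fine trapezoid grid on
[-10, 10].  The integrand (likelihood times normal prior) is smooth and
decays to ~1e-17 of its peak at the endpoints, so the composite trapezoid
rule converges spectrally here (all Euler-Maclaurin boundary terms vanish);
the default 2001-point grid is accurate to well below 1e-8 relative and is
cheap enough to run inside a many-thousand-replicate simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .model_core import Ordering, Skeleton, psi

__all__ = [
    "PriorBeta",
    "ObservedData",
    "DecisionOutcome",
    "weighted_likelihood",
    "log_weighted_likelihood",
    "marginal_likelihood",
    "ordering_posteriors",
    "select_ordering",
    "posterior_mean_beta",
    "ml_estimate",
    "estimate_dlt_probs",
    "recommend_dose",
    "beta_variance",
    "lowest_dose_overtox_prob",
    "decide",
]

# Integration grid for all posterior quantities.
BETA_LIMIT = 10.0
N_GRID = 2001
_BETA_GRID = np.linspace(-BETA_LIMIT, BETA_LIMIT, N_GRID)
_EXP_BETA_GRID = np.exp(_BETA_GRID)

_CLIP = 1.0 - 1e-12


@dataclass(frozen=True)
class PriorBeta:
    """Normal prior on the power-model parameter beta."""

    mean: float = 0.0
    variance: float = 1.34

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError("prior variance must be positive")

    def pdf(self, beta: np.ndarray) -> np.ndarray:
        v = self.variance
        return np.exp(-((np.asarray(beta) - self.mean) ** 2) / (2.0 * v)) / np.sqrt(
            2.0 * np.pi * v
        )


@dataclass(frozen=True)
class ObservedData:
    """Accumulated (dose index, DLT indicator, weight) triples at a decision time."""

    dose_idx: tuple[int, ...] = ()
    y: tuple[int, ...] = ()
    w: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not (len(self.dose_idx) == len(self.y) == len(self.w)):
            raise ValueError("dose_idx, y, w must have equal length")
        for yl, wl in zip(self.y, self.w):
            if yl not in (0, 1):
                raise ValueError("y must be 0/1")
            if not (0.0 <= wl <= 1.0):
                raise ValueError("weights must lie in [0, 1]")
            if yl == 1 and wl != 1.0:
                raise ValueError("an observed DLT contributes with weight 1")

    def __len__(self) -> int:
        return len(self.y)

    @property
    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (
            np.asarray(self.dose_idx, dtype=int),
            np.asarray(self.y, dtype=float),
            np.asarray(self.w, dtype=float),
        )


@dataclass(frozen=True)
class DecisionOutcome:
    """Everything a dose-escalation decision produces."""

    marginals: tuple[float, ...]
    ordering_probs: tuple[float, ...]
    selected_ordering: int
    beta_hat: float
    beta_ml: float
    beta_var: float
    var_fallback: bool
    dlt_prob_hat: tuple[float, ...]
    recommended_dose: int
    overtox_prob: float


def _log_lik_grid(
    data: ObservedData, alpha_per_dose: np.ndarray, beta: np.ndarray
) -> np.ndarray:
    """log L~(beta) on a vector of beta values (vectorised over patients)."""
    x, y, w = data.arrays
    if len(data) == 0:
        return np.zeros(np.shape(beta))
    lna = np.log(alpha_per_dose[x])  # (n,)
    e = np.exp(np.asarray(beta, dtype=float))
    p = np.exp(np.multiply.outer(e, lna))  # psi, shape (..., n)
    wp = np.clip(w * p, 1e-300, _CLIP)
    return (y * np.log(wp) + (1.0 - y) * np.log1p(-wp)).sum(axis=-1)


def log_weighted_likelihood(
    beta: float, data: ObservedData, ordering: Ordering, skeleton: Skeleton
) -> float:
    """Log of the weighted likelihood at a single beta."""
    alpha = skeleton.per_ordering_alpha(ordering)
    x, y, w = data.arrays
    if len(data):
        wp = w * psi(alpha[x], beta)
        if np.any((wp >= 1.0) & (y == 0)):
            warnings.warn("weighted DLT probability reached 1 for a non-event; clipping")
    return float(_log_lik_grid(data, alpha, np.asarray(beta, dtype=float)))


def weighted_likelihood(
    beta: float, data: ObservedData, ordering: Ordering, skeleton: Skeleton
) -> float:
    """The weighted likelihood L~_m(beta | data); 1 for empty data."""
    return float(np.exp(log_weighted_likelihood(beta, data, ordering, skeleton)))


def _posterior_grid(
    data: ObservedData,
    ordering: Ordering,
    skeleton: Skeleton,
    prior: PriorBeta,
) -> tuple[np.ndarray, np.ndarray]:
    """(unnormalised posterior density on the beta grid, the grid)."""
    alpha = skeleton.per_ordering_alpha(ordering)
    ll = _log_lik_grid(data, alpha, _BETA_GRID)
    dens = np.exp(ll) * prior.pdf(_BETA_GRID)
    if not np.all(np.isfinite(dens)):
        raise FloatingPointError("non-finite posterior integrand")
    return dens, _BETA_GRID


def marginal_likelihood(
    data: ObservedData,
    ordering: Ordering,
    skeleton: Skeleton,
    prior: PriorBeta = PriorBeta(),
) -> float:
    """Integral of L~_m(beta) g(beta) over beta — the evidence for ordering m."""
    dens, grid = _posterior_grid(data, ordering, skeleton, prior)
    return float(np.trapezoid(dens, grid))


def ordering_posteriors(
    data: ObservedData,
    orderings: Sequence[Ordering],
    skeleton: Skeleton,
    prior: PriorBeta = PriorBeta(),
) -> np.ndarray:
    """Posterior probability of each ordering: p(m) * evidence_m, normalised."""
    p = np.array([o.prior_weight for o in orderings], dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("ordering prior weights must sum to 1")
    marg = np.array(
        [marginal_likelihood(data, o, skeleton, prior) for o in orderings]
    )
    num = p * marg
    tot = num.sum()
    if tot <= 0.0 or not np.isfinite(tot):
        raise ValueError("all ordering marginal likelihoods vanished")
    return num / tot


def select_ordering(posteriors: np.ndarray, rng: np.random.Generator) -> int:
    """Index of the most probable ordering; exact ties broken by a seeded draw."""
    post = np.asarray(posteriors, dtype=float)
    best = np.flatnonzero(post == post.max())
    if len(best) == 1:
        return int(best[0])
    return int(rng.choice(best))


def posterior_mean_beta(
    data: ObservedData,
    ordering: Ordering,
    skeleton: Skeleton,
    prior: PriorBeta = PriorBeta(),
) -> float:
    """Posterior mean of beta under one ordering."""
    dens, grid = _posterior_grid(data, ordering, skeleton, prior)
    z = np.trapezoid(dens, grid)
    if z <= 0.0:
        raise ValueError("degenerate posterior: zero normalising constant")
    return float(np.trapezoid(grid * dens, grid) / z)


def ml_estimate(
    data: ObservedData, ordering: Ordering, skeleton: Skeleton
) -> float:
    """Weighted maximum-likelihood estimate of beta on [-10, 10].

    Used by the safety stopping rule, which pairs the estimate with the
    observed-information variance — a likelihood-based construction.  With
    degenerate data (e.g. no events) the maximiser sits at a boundary of the
    search interval; the boundary value is returned, which drives the
    plug-in DLT probabilities to their limits as the data dictate.
    """
    alpha = skeleton.per_ordering_alpha(ordering)
    ll = _log_lik_grid(data, alpha, _BETA_GRID)
    b0 = float(_BETA_GRID[int(np.argmax(ll))])
    res = minimize_scalar(
        lambda b: -float(_log_lik_grid(data, alpha, np.asarray(b))),
        bounds=(max(b0 - 0.5, -BETA_LIMIT), min(b0 + 0.5, BETA_LIMIT)),
        method="bounded",
    )
    return float(res.x)


def estimate_dlt_probs(
    beta_hat: float, ordering: Ordering, skeleton: Skeleton
) -> np.ndarray:
    """Plug-in DLT probabilities R^(d_i) = psi_m(d_i, beta_hat), by dose index."""
    return psi(skeleton.per_ordering_alpha(ordering), beta_hat)


def recommend_dose(
    r_hat: np.ndarray, theta: float, ordering: Ordering | None = None
) -> int:
    """Dose index minimising |R^(d_i) - theta|.

    Exact ties go to the dose of lower toxicity rank under ``ordering`` (or
    lower index when no ordering is given).
    """
    r = np.asarray(r_hat, dtype=float)
    dist = np.abs(r - theta)
    tied = np.flatnonzero(dist == dist.min())
    if len(tied) == 1 or ordering is None:
        return int(tied[0])
    rank_of = {dose: r_ for r_, dose in enumerate(ordering.rank)}
    return int(min(tied, key=lambda i: rank_of[int(i)]))


def beta_variance(
    data: ObservedData,
    ordering: Ordering,
    skeleton: Skeleton,
    beta_hat: float,
    prior: PriorBeta = PriorBeta(),
    step: float = 1e-4,
) -> tuple[float, bool]:
    """Observed-information variance of beta at ``beta_hat``.

    Returns ``(v, fallback)`` where ``v = [-d^2/dbeta^2 log L~]^{-1}`` by
    central finite differences.  When the data carry no curvature (e.g. no
    events and small weights) the second derivative can be non-negative; the
    prior variance is then returned with ``fallback=True``.
    """
    if len(data) == 0:
        return prior.variance, True
    alpha = skeleton.per_ordering_alpha(ordering)
    b = np.array([beta_hat - step, beta_hat, beta_hat + step])
    ll = _log_lik_grid(data, alpha, b)
    d2 = (ll[0] - 2.0 * ll[1] + ll[2]) / step**2
    if d2 >= 0.0 or not np.isfinite(d2):
        return prior.variance, True
    return float(-1.0 / d2), False


def lowest_dose_overtox_prob(
    beta_hat: float,
    variance: float,
    ordering: Ordering,
    skeleton: Skeleton,
    lowest_dose_idx: int = 0,
    threshold: float = 0.35,
    n_draws: int = 10_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Monte-Carlo P(DLT probability at the lowest dose > threshold).

    Draws beta* ~ Normal(beta_hat, variance) and plugs each draw into the
    working model at the lowest dose.
    """
    if variance <= 0:
        raise ValueError("variance must be positive")
    if rng is None:
        rng = np.random.default_rng()
    alpha_low = skeleton.per_ordering_alpha(ordering)[lowest_dose_idx]
    draws = rng.normal(beta_hat, np.sqrt(variance), int(n_draws))
    # evaluate psi directly; exp may overflow for extreme draws, where the
    # limiting values 0/1 are exactly right
    with np.errstate(over="ignore"):
        vals = np.exp(np.exp(draws) * np.log(alpha_low))
    return float(np.mean(vals > threshold))


def decide(
    data: ObservedData,
    orderings: Sequence[Ordering],
    skeleton: Skeleton,
    theta: float,
    prior: PriorBeta = PriorBeta(),
    rng: np.random.Generator | None = None,
    lowest_dose_idx: int = 0,
    safety_threshold: float = 0.35,
    overtox_draws: int = 10_000,
) -> DecisionOutcome:
    """Run the full decision pipeline on one data snapshot."""
    if rng is None:
        rng = np.random.default_rng()
    dens = [_posterior_grid(data, o, skeleton, prior)[0] for o in orderings]
    marg = tuple(float(np.trapezoid(d, _BETA_GRID)) for d in dens)
    p = np.array([o.prior_weight for o in orderings])
    num = p * np.array(marg)
    tot = num.sum()
    if tot <= 0.0 or not np.isfinite(tot):
        raise ValueError("all ordering marginal likelihoods vanished")
    post = num / tot
    h = select_ordering(post, rng)
    beta_hat = float(np.trapezoid(_BETA_GRID * dens[h], _BETA_GRID) / marg[h])
    r_hat = estimate_dlt_probs(beta_hat, orderings[h], skeleton)
    rec = recommend_dose(r_hat, theta, orderings[h])
    # Safety quantities live in the likelihood framework: the ML estimate
    # with its observed-information variance.
    beta_ml = ml_estimate(data, orderings[h], skeleton) if len(data) else beta_hat
    v, fallback = beta_variance(data, orderings[h], skeleton, beta_ml, prior)
    overtox = lowest_dose_overtox_prob(
        beta_ml,
        v,
        orderings[h],
        skeleton,
        lowest_dose_idx=lowest_dose_idx,
        threshold=safety_threshold,
        n_draws=overtox_draws,
        rng=rng,
    )
    return DecisionOutcome(
        marginals=marg,
        ordering_probs=tuple(float(x) for x in post),
        selected_ordering=h,
        beta_hat=beta_hat,
        beta_ml=beta_ml,
        beta_var=v,
        var_fallback=fallback,
        dlt_prob_hat=tuple(float(x) for x in r_hat),
        recommended_dose=rec,
        overtox_prob=overtox,
    )
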