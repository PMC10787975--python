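"""Dose grid, toxicity orderings, skeletons, and the power working model.

The working dose-toxicity model is the one-parameter power (empiric) model

    psi_m(d_i, beta) = alpha_{mi} ** exp(beta)

where ``alpha_{m1} < ... < alpha_{mk}`` is the *skeleton* — the vector of
prior DLT-probability guesses — arranged per candidate ordering ``m``.  When
the relative toxicity of some dose pairs is unknown (a *partial order*),
several orderings are carried simultaneously, each with a prior plausibility
weight ``p(m)``.

The default design built here is the ADePT-DDR head-and-neck trial
configuration: six dose levels (-1, 0, 1, 2a, 2b, 3) of an ATR inhibitor
given with fixed-dose radiotherapy, where levels 2a (longer duration) and 2b
(higher daily dose) cannot be ranked a priori, giving two orderings with
equal prior weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DoseGrid",
    "Ordering",
    "Skeleton",
    "SkeletonCalibration",
    "psi",
    "calibrate_skeleton",
    "build_adept_design",
    "ADEPT_LABELS",
    "ADEPT_SKELETON_2DP",
]

#: Dose labels of the ADePT-DDR grid, in ordering-1 (escalation-scheme) order.
ADEPT_LABELS = ("-1", "0", "1", "2a", "2b", "3")

#: The published 2-dp skeleton for the ADePT-DDR doses under ordering 1.
ADEPT_SKELETON_2DP = (0.01, 0.04, 0.08, 0.16, 0.25, 0.35)


@dataclass(frozen=True)
class DoseGrid:
    """An ordered set of dose labels.

    The *position* of a label in ``labels`` is its dose index; orderings are
    permutations of these indices.
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) < 1:
            raise ValueError("dose grid needs at least one dose")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("dose labels must be unique")

    @property
    def k(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)


@dataclass(frozen=True)
class Ordering:
    """One candidate toxicity ordering with its prior plausibility weight.

    ``rank`` lists dose indices in increasing assumed toxicity: ``rank[r]``
    is the dose index occupying toxicity rank ``r``.
    """

    rank: tuple[int, ...]
    prior_weight: float

    def __post_init__(self) -> None:
        if sorted(self.rank) != list(range(len(self.rank))):
            raise ValueError("rank must be a permutation of 0..k-1")
        if self.prior_weight < 0:
            raise ValueError("prior_weight must be non-negative")


@dataclass(frozen=True)
class Skeleton:
    """Sorted prior DLT probabilities, assignable to doses per ordering."""

    alpha_sorted: tuple[float, ...]

    def __post_init__(self) -> None:
        a = self.alpha_sorted
        if not all(0.0 < x < 1.0 for x in a):
            raise ValueError("skeleton values must lie strictly in (0, 1)")
        if any(a[i] >= a[i + 1] for i in range(len(a) - 1)):
            raise ValueError("skeleton must be strictly increasing")

    @property
    def k(self) -> int:
        return len(self.alpha_sorted)

    def per_ordering_alpha(self, ordering: Ordering) -> np.ndarray:
        """Skeleton values indexed by dose: rank r's dose gets the r-th value."""
        alpha = np.empty(self.k)
        for r, dose_idx in enumerate(ordering.rank):
            alpha[dose_idx] = self.alpha_sorted[r]
        return alpha


@dataclass(frozen=True)
class SkeletonCalibration:
    """Indifference-interval skeleton calibration parameters.

    ``theta`` is the target DLT rate, ``delta`` the half-width of the
    indifference interval [theta-delta, theta+delta], ``nu`` the 1-based
    position of the prior guess of the target dose, and ``k`` the number of
    dose levels.
    """

    theta: float
    delta: float
    nu: int
    k: int

    def __post_init__(self) -> None:
        if not (0.0 < self.theta - self.delta and self.theta + self.delta < 1.0):
            raise ValueError("need 0 < theta-delta and theta+delta < 1")
        if not (1 <= self.nu <= self.k):
            raise ValueError("nu must lie in 1..k")


def psi(alpha_i: float, beta: float):
    """Power-model DLT probability ``alpha_i ** exp(beta)``.

    Strictly increasing in ``alpha_i`` for fixed ``beta`` and lies in (0, 1)
    whenever ``alpha_i`` does.  Accepts array arguments for either operand.
    """
    a = np.asarray(alpha_i, dtype=float)
    if np.any(a <= 0.0) or np.any(a >= 1.0):
        raise ValueError("alpha must lie strictly in (0, 1)")
    b = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(b)):
        raise ValueError("beta must be finite")
    out = np.exp(np.exp(b) * np.log(a))
    if out.ndim == 0:
        return float(out)
    return out


def calibrate_skeleton(cal: SkeletonCalibration) -> Skeleton:
    """Build a skeleton from indifference-interval spacing.

    The value at position ``nu`` is the target ``theta``; neighbours are
    spaced so that the working model is *indifferent* across adjacent doses:
    the beta that puts dose i at ``theta - delta`` puts dose i+1 at
    ``theta + delta``.  Under the power model this gives the recursions

        alpha_{i+1} = (theta + delta) ** (ln alpha_i / ln(theta - delta))
        alpha_{i-1} = (theta - delta) ** (ln alpha_i / ln(theta + delta))

    seeded at alpha_nu = theta and run upward and downward.  This is the
    standard empiric-model skeleton calibration of the CRM literature.
    """
    th, d, nu, k = cal.theta, cal.delta, cal.nu, cal.k
    lo, hi = th - d, th + d
    alpha = [0.0] * k
    alpha[nu - 1] = th
    for i in range(nu - 1, k - 1):  # ascend above the prior target dose
        alpha[i + 1] = hi ** (math.log(alpha[i]) / math.log(lo))
    for i in range(nu - 1, 0, -1):  # descend below it
        alpha[i - 1] = lo ** (math.log(alpha[i]) / math.log(hi))
    if not all(0.0 < a < 1.0 for a in alpha):
        raise ValueError("calibration left (0, 1); narrow delta or move nu")
    return Skeleton(tuple(alpha))


def build_adept_design(
    rounded: bool = True,
) -> tuple[DoseGrid, tuple[Ordering, Ordering], Skeleton]:
    """The ADePT-DDR grid, its two orderings, and its skeleton.

    Ordering 1 ranks doses (-1, 0, 1, 2a, 2b, 3); ordering 2 swaps 2a and 2b.
    Both carry prior weight 0.5.  With ``rounded`` (the default) the skeleton
    is the published 2-dp vector (0.01, 0.04, 0.08, 0.16, 0.25, 0.35), which
    is what parameterised the trial; ``rounded=False`` returns the
    full-precision calibrated values (theta=0.25, delta=0.05, nu=5).
    """
    grid = DoseGrid(ADEPT_LABELS)
    i2a, i2b = grid.index("2a"), grid.index("2b")
    rank1 = tuple(range(grid.k))
    rank2 = list(rank1)
    rank2[i2a], rank2[i2b] = rank2[i2b], rank2[i2a]
    orderings = (Ordering(rank1, 0.5), Ordering(tuple(rank2), 0.5))
    if rounded:
        skeleton = Skeleton(ADEPT_SKELETON_2DP)
    else:
        skeleton = calibrate_skeleton(
            SkeletonCalibration(theta=0.25, delta=0.05, nu=5, k=grid.k)
        )
    return grid, orderings, skeleton
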