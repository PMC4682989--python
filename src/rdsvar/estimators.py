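"""RDS point and variance estimators computed from a recruitment forest alone.

These estimators see only what a field researcher sees — the sequence of
respondents, who recruited whom, their attribute values and reported degrees
— and approximate the walk-on-network variance by replacing the (unknown)
node-level transition matrix with a category-level transition matrix
estimated from recruiter->recruit pairs:

* :func:`rds2_mean` — the inverse-degree-weighted ("RDS-II") mean.
* :func:`vhe_variance` — the algebraic Volz-Heckathorn variance estimator
  (VHE), with two optional corrections: recruitment-tree distances in place
  of interview-order distances (VHEwbc), and second/third-order transition
  matrices over value histories in place of the first-order matrix (VHEhom).
* :func:`sbe_variance` — the Salganik bootstrap (SBE), which resamples
  synthetic first-order chains from the estimated category matrix.

All of them inherit the first-order-Markov (FOM) assumption through the
category matrix; on networks where a hidden variable structures cross-group
mixing they underestimate the true sampling variance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .sampler import UNLINKED, RecruitmentForest, chain_distances

__all__ = [
    "TransitionEstimate",
    "VarianceEstimate",
    "rds2_mean",
    "estimate_transitions",
    "vhe_variance",
    "sbe_variance",
    "coverage_hit",
    "InsufficientChainsError",
]


class InsufficientChainsError(ValueError):
    """Raised when the forest has no recruiter chains of the required length."""


def rds2_mean(forest: RecruitmentForest) -> float:
    """Inverse-degree-weighted mean: sum(y_j/d_j) / sum(1/d_j).

    Reweighting undoes the degree-proportional inclusion law of the walk;
    with equal degrees this is the arithmetic mean.
    """
    d = forest.degrees().astype(float)
    if np.any(d < 1):
        raise ValueError("all degrees must be >= 1")
    y = forest.y_values().astype(float)
    w = 1.0 / d
    return float((y * w).sum() / w.sum())


def _history_states(order: int) -> tuple[str, ...]:
    return tuple("".join(bits) for bits in itertools.product("01", repeat=order))


@dataclass(frozen=True)
class TransitionEstimate:
    """Order-r category transition matrix estimated from recruiter chains.

    States are value histories of length ``order`` (most recent last), e.g.
    order 2 uses ("00", "01", "10", "11").  A history h can only move to
    histories whose prefix equals h's suffix, so higher-order matrices carry
    structural zeros (8 of 16 cells at order 2).  ``weights`` are the
    empirical frequencies of source histories among observed chains;
    ``defined`` marks rows with at least one observed transition.  Undefined
    rows that are reachable are filled from the order-1 conditional of the
    last history element (uniform if that too is unobserved) so that matrix
    powers remain stochastic; they carry zero weight.
    """

    order: int
    states: tuple[str, ...]
    matrix: np.ndarray
    counts: np.ndarray
    weights: np.ndarray
    defined: np.ndarray
    lambdas: np.ndarray = field(repr=False, default=None)

    @property
    def y(self) -> np.ndarray:
        """Attribute value carried by each history state (its last element)."""
        return np.array([float(s[-1]) for s in self.states])

    @property
    def degenerate(self) -> bool:
        """True when only one category was observed (single-y sample)."""
        ylast = self.y
        return len({ylast[i] for i in range(len(self.states)) if self.weights[i] > 0}) < 2

    def covariances(self, max_lag: int) -> np.ndarray:
        """cov(t) for t = 1..max_lag under the estimated chain.

        cov(t) = sum_h w_h y*_h [P^t y*]_h with y centered at its
        weight-averaged mean, the matrix-power form of the eigen-sum
        sum_k alpha_k^2 lambda_k^t.
        """
        ylast = self.y
        mu = float(self.weights @ ylast)
        ystar = ylast - mu
        out = np.empty(max_lag)
        v = ystar.copy()
        for t in range(1, max_lag + 1):
            v = self.matrix @ v
            out[t - 1] = float(self.weights @ (ystar * v))
        return out


def estimate_transitions(forest: RecruitmentForest, order: int = 1) -> TransitionEstimate:
    """Row-normalized tallies of order-r transitions along recruiter chains.

    Order 1 uses recruiter->recruit pairs; order 2 uses
    grandparent->parent->child triples within trees; order 3 uses 4-chains.
    """
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    parent = [r.recruiter for r in forest.records]
    y = forest.y_values()

    def ancestors(i: int, k: int) -> list[int] | None:
        out = [i]
        for _ in range(k):
            p = parent[out[-1]]
            if p is None:
                return None
            out.append(p)
        return out[::-1]  # oldest first

    states = _history_states(order)
    index = {s: i for i, s in enumerate(states)}
    n = len(states)
    counts = np.zeros((n, n))
    for i in range(forest.s):
        chain = ancestors(i, order)
        if chain is None:
            continue
        vals = "".join(str(y[j]) for j in chain)
        counts[index[vals[:-1]], index[vals[1:]]] += 1
    total = counts.sum()
    if total == 0:
        raise InsufficientChainsError(
            f"no recruiter chains of length {order + 1} in the forest"
        )

    rowsum = counts.sum(axis=1)
    defined = rowsum > 0
    matrix = np.zeros_like(counts)
    matrix[defined] = counts[defined] / rowsum[defined, None]

    # fallback for reachable-but-unobserved rows: order-1 conditional of the
    # most recent value, uniform over structurally allowed targets otherwise
    if order > 1 and not defined.all():
        fallback = _order1_rows(forest)
        for i in np.flatnonzero(~defined):
            last = states[i][-1]
            for j, sj in enumerate(states):
                if sj[:-1] == states[i][1:]:
                    matrix[i, j] = fallback[int(last)][int(sj[-1])]
    elif not defined.all():
        for i in np.flatnonzero(~defined):
            matrix[i] = 1.0 / n

    weights = rowsum / total
    lambdas = np.sort(np.real(np.linalg.eigvals(matrix)))[::-1]
    return TransitionEstimate(
        order=order, states=states, matrix=matrix, counts=counts,
        weights=weights, defined=defined, lambdas=lambdas,
    )


def _order1_rows(forest: RecruitmentForest) -> np.ndarray:
    y = forest.y_values()
    counts = np.zeros((2, 2))
    for i, j in forest.referral_pairs():
        counts[y[i], y[j]] += 1
    out = np.full((2, 2), 0.5)
    for r in range(2):
        if counts[r].sum() > 0:
            out[r] = counts[r] / counts[r].sum()
    return out


@dataclass(frozen=True)
class VarianceEstimate:
    """A point estimate with its estimated sampling variance and 95% CI."""

    method: str
    mean: float
    variance: float
    design_effect: float
    flags: tuple[str, ...] = ()

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.variance))

    @property
    def ci95(self) -> tuple[float, float]:
        half = 1.96 * self.sd
        return (self.mean - half, self.mean + half)


def _design_effect(variance: float, mean: float, s: int) -> float:
    srs = mean * (1.0 - mean) / s
    return float(variance / srs) if srs > 0 else float("nan")


def vhe_variance(
    forest: RecruitmentForest,
    distance_mode: str = "sequence",
    order: int = 1,
) -> VarianceEstimate:
    """Algebraic variance estimator from the estimated category chain.

    The estimate is the sample analog of the exact walk-variance formula:
    a degree-weighted SRS-style first term

        (1/(S-1)) sum_i pihat_i (y_i - muhat)^2,   pihat_i = d_i / sum d,

    plus (1/S^2) times the sum of estimated step covariances over all
    ordered respondent pairs, where the covariance at distance t comes from
    the order-r category chain (:meth:`TransitionEstimate.covariances`) and
    distances are interview-order gaps (``distance_mode="sequence"``, the
    classic VHE) or recruitment-tree path lengths (``"tree"``, the branching
    correction; cross-tree pairs contribute zero).  ``order`` >= 2 with tree
    distances is the higher-order-Markov variant.

    Method labels: VHE, VHEwbc (tree distances), VHEhom2/VHEhom3.
    """
    s = forest.s
    if s < 2:
        raise ValueError("need at least 2 respondents")
    mean = rds2_mean(forest)
    d = forest.degrees().astype(float)
    y = forest.y_values().astype(float)
    pihat = d / d.sum()
    ystar = y - mean
    first = float((pihat * ystar**2).sum() / (s - 1))

    flags: list[str] = []
    if order == 1 and distance_mode == "sequence":
        method = "VHE"
    elif order == 1:
        method = "VHEwbc"
    else:
        method = f"VHEhom{order}"

    try:
        est = estimate_transitions(forest, order=order)
    except InsufficientChainsError:
        if order > 1:
            raise
        est = None
        flags.append("no_referrals")

    if est is None or est.degenerate:
        if est is not None and est.degenerate:
            flags.append("degenerate_single_category")
        variance = first
        return VarianceEstimate(method=method, mean=mean, variance=variance,
                                design_effect=_design_effect(variance, mean, s),
                                flags=tuple(flags))
    if not est.defined.all():
        flags.append("undefined_rows_filled")

    dist = chain_distances(forest, mode=distance_mode)
    tri = dist[np.triu_indices(s, k=1)]
    tri = tri[tri != UNLINKED]
    if tri.size:
        max_lag = int(tri.max())
        covs = est.covariances(max_lag)
        hist = np.bincount(tri, minlength=max_lag + 1)[1:]
        pair_sum = 2.0 * float(hist @ covs)  # ordered pairs: both (i,j), (j,i)
    else:
        pair_sum = 0.0
    variance = first + pair_sum / s**2
    if variance < 0.0:
        flags.append("negative_clipped")
        variance = 0.0
    return VarianceEstimate(method=method, mean=mean, variance=variance,
                            design_effect=_design_effect(variance, mean, s),
                            flags=tuple(flags))


def sbe_variance(forest: RecruitmentForest, b: int = 1000, seed: int = 0) -> VarianceEstimate:
    """Salganik bootstrap: variance of point estimates over synthetic chains.

    Each replicate draws a synthetic chain of length S from the estimated
    first-order category matrix (initial category from observed category
    frequencies), equips each synthetic respondent with (y, degree) resampled
    uniformly from observed respondents of that category, and computes the
    RDS-II mean; the estimate is the variance across the b replicate means.
    """
    if b < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    s = forest.s
    mean = rds2_mean(forest)
    rng = np.random.default_rng(seed)
    y = forest.y_values()
    d = forest.degrees().astype(float)
    flags: list[str] = []

    try:
        est = estimate_transitions(forest, order=1)
    except InsufficientChainsError:
        est = None
        flags.append("no_referrals")

    p1 = float(y.mean())
    cats = np.empty((b, s), dtype=np.int64)
    cats[:, 0] = rng.random(b) < p1
    if est is not None and not est.degenerate:
        P = est.matrix
    else:
        P = np.eye(2)  # degenerate: chains stay in the seed category
        if est is not None:
            flags.append("degenerate_single_category")
    for t in range(1, s):
        stay0 = rng.random(b) < P[0, 0]
        stay1 = rng.random(b) < P[1, 1]
        prev = cats[:, t - 1]
        cats[:, t] = np.where(prev == 0, ~stay0, stay1)

    # resample (y, degree) uniformly within category
    invd_by_cat = [1.0 / d[y == c] if np.any(y == c) else np.array([1.0]) for c in (0, 1)]
    draws0 = rng.integers(len(invd_by_cat[0]), size=(b, s))
    draws1 = rng.integers(len(invd_by_cat[1]), size=(b, s))
    invd = np.where(cats == 0, invd_by_cat[0][draws0], invd_by_cat[1][draws1])
    num = (cats * invd).sum(axis=1)
    den = invd.sum(axis=1)
    means = num / den
    variance = float(means.var())
    return VarianceEstimate(method="SBE", mean=mean, variance=variance,
                            design_effect=_design_effect(variance, mean, s),
                            flags=tuple(flags))


def coverage_hit(estimate: VarianceEstimate, mu: float) -> bool:
    """True iff mu lies inside the estimate's 95% interval."""
    if estimate.variance < 0:
        raise ValueError("variance must be nonnegative")
    return bool(abs(estimate.mean - mu) <= 1.96 * estimate.sd)
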