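"""Random-walk and branching chain-referral (RDS) sample simulation.

A simulated sample is a :class:`RecruitmentForest`: the ordered respondent
records with recruiter links, waves, attribute values and degrees.  Two
sampling processes are provided:

* :func:`random_walk_sample` — the idealized non-branching, with-replacement
  walk whose stationary law is degree-proportional;
* :func:`rds_sample` — branching recruitment in breadth-first (coupon-wave)
  order, with the recruit-count distribution (default P(0,1,2,3 recruits) =
  1/3, 1/6, 1/6, 1/3) and with- or without-replacement neighbor draws.

Pairwise distances between respondents — the |j - i| entering every
covariance sum — come from :func:`chain_distances`, either as interview-order
gaps (the classic convention) or as path lengths in the recruitment forest
(the branching-corrected convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import deque

import numpy as np

from .graphs import Network

__all__ = [
    "RecruitmentForest",
    "Record",
    "random_walk_sample",
    "rds_sample",
    "chain_distances",
    "empirical_sampling_variance",
    "UNLINKED",
    "DEFAULT_BRANCH_PROBS",
]

#: sentinel distance for respondent pairs in different recruitment trees
UNLINKED = -1

DEFAULT_BRANCH_PROBS = (1 / 3, 1 / 6, 1 / 6, 1 / 3)


@dataclass(frozen=True)
class Record:
    node: str
    recruiter: int | None  # index into the record list, None for seeds
    wave: int
    y: int
    degree: int


@dataclass(frozen=True)
class RecruitmentForest:
    """One RDS sample: ordered respondent records with recruiter links.

    With replacement, a node may appear repeatedly; each occurrence is a
    distinct record and recruiter links refer to record positions, not nodes.
    """

    records: tuple[Record, ...]
    with_replacement: bool = True

    def __post_init__(self) -> None:
        for i, r in enumerate(self.records):
            if r.recruiter is not None:
                if not 0 <= r.recruiter < i:
                    raise ValueError(f"record {i}: recruiter must appear earlier")
                if r.wave != self.records[r.recruiter].wave + 1:
                    raise ValueError(f"record {i}: wave must increase by 1")
            elif r.wave != 0:
                raise ValueError(f"record {i}: seed records have wave 0")
        if not self.with_replacement:
            nodes = [r.node for r in self.records]
            if len(set(nodes)) != len(nodes):
                raise ValueError("repeated respondents in a without-replacement sample")

    @property
    def s(self) -> int:
        return len(self.records)

    @property
    def seeds(self) -> tuple[str, ...]:
        return tuple(r.node for r in self.records if r.recruiter is None)

    def y_values(self) -> np.ndarray:
        return np.array([r.y for r in self.records])

    def degrees(self) -> np.ndarray:
        return np.array([r.degree for r in self.records])

    def referral_pairs(self) -> list[tuple[int, int]]:
        """(recruiter index, recruit index) pairs in record order."""
        return [(r.recruiter, i) for i, r in enumerate(self.records)
                if r.recruiter is not None]

    def to_csv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("id,recruiter_id,wave,y,degree,order\n")
            for i, r in enumerate(self.records):
                rec = "" if r.recruiter is None else str(r.recruiter)
                fh.write(f"{r.node},{rec},{r.wave},{r.y},{r.degree},{i}\n")

    @classmethod
    def from_csv(cls, path: str, with_replacement: bool = True) -> "RecruitmentForest":
        import pandas as pd

        tab = pd.read_csv(path, dtype={"id": str}).sort_values("order")
        records = tuple(
            Record(
                node=str(row.id),
                recruiter=None if pd.isna(row.recruiter_id) else int(row.recruiter_id),
                wave=int(row.wave),
                y=int(row.y),
                degree=int(row.degree),
            )
            for row in tab.itertuples()
        )
        return cls(records=records, with_replacement=with_replacement)


def _stationary_seed(net: Network, rng: np.random.Generator,
                     exclude: set[str] | None = None) -> str:
    nodes = list(net.nodes)
    d = net.degrees().astype(float)
    if exclude:
        mask = np.array([n not in exclude for n in nodes])
        nodes = [n for n, keep in zip(nodes, mask) if keep]
        d = d[mask]
    if not nodes:
        raise ValueError("no nodes left to seed from")
    return nodes[rng.choice(len(nodes), p=d / d.sum())]


def random_walk_sample(net: Network, s: int, seed: int) -> RecruitmentForest:
    """Non-branching with-replacement walk of length s, stationary start."""
    net.require_connected()
    if s < 1:
        raise ValueError("s must be >= 1")
    rng = np.random.default_rng(seed)
    node = _stationary_seed(net, rng)
    records = [Record(node, None, 0, net.y[node], net.degree(node))]
    for i in range(1, s):
        nbrs = net.neighbors(node)
        node = nbrs[rng.integers(len(nbrs))]
        records.append(Record(node, i - 1, i, net.y[node], net.degree(node)))
    return RecruitmentForest(records=tuple(records), with_replacement=True)


def rds_sample(
    net: Network,
    s: int,
    branch_probs: tuple[float, ...] = DEFAULT_BRANCH_PROBS,
    with_replacement: bool = True,
    seed: int = 0,
) -> RecruitmentForest:
    """Branching RDS sample of exactly s records.

    Recruitment is breadth-first in coupon waves: each respondent draws a
    recruit count from ``branch_probs`` (for 0..3 recruits) and recruits are
    drawn uniformly from the respondent's network neighbors — any neighbor
    with replacement, uninterviewed neighbors without (count truncated to
    availability).  The initial seed is drawn from the stationary
    (degree-proportional) law; if the recruitment queue dies out before s
    records, a fresh seed is drawn the same way (without replacement:
    restricted to unsampled nodes) so the target size is always reached.
    Excess recruits once s is reached are dropped in draw order.
    """
    net.require_connected()
    if s < 1:
        raise ValueError("s must be >= 1")
    probs = np.asarray(branch_probs, dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("branch_probs must sum to 1")
    if not with_replacement and s > net.n:
        raise ValueError(f"cannot draw {s} distinct respondents from {net.n} nodes")

    rng = np.random.default_rng(seed)
    records: list[Record] = []
    sampled: set[str] = set()
    queue: deque[int] = deque()

    def add(node: str, recruiter: int | None, wave: int) -> None:
        records.append(Record(node, recruiter, wave, net.y[node], net.degree(node)))
        sampled.add(node)
        queue.append(len(records) - 1)

    add(_stationary_seed(net, rng), None, 0)
    while len(records) < s:
        if not queue:
            exclude = sampled if not with_replacement else None
            add(_stationary_seed(net, rng, exclude), None, 0)
            continue
        idx = queue.popleft()
        rec = records[idx]
        k = int(rng.choice(len(probs), p=probs))
        nbrs = net.neighbors(rec.node)
        if not with_replacement:
            nbrs = [n for n in nbrs if n not in sampled]
        for _ in range(k):
            if len(records) >= s:
                break  # truncation: drop overflow recruits in draw order
            if not with_replacement:
                nbrs = [n for n in nbrs if n not in sampled]
            if not nbrs:
                break
            add(nbrs[rng.integers(len(nbrs))], idx, rec.wave + 1)
    return RecruitmentForest(records=tuple(records), with_replacement=with_replacement)


def chain_distances(forest: RecruitmentForest, mode: str = "sequence") -> np.ndarray:
    """Pairwise distances between respondents.

    mode="sequence": |j - i| in interview order (the classic convention that
    treats the sample as a single walk).  mode="tree": undirected path length
    through the recruitment forest, so if i recruits j who recruits both k
    and l, d(i,k) = d(i,l) = d(k,l) = 2.  Pairs in different trees get the
    :data:`UNLINKED` sentinel (-1).
    """
    s = forest.s
    if mode == "sequence":
        idx = np.arange(s)
        return np.abs(idx[:, None] - idx[None, :])
    if mode != "tree":
        raise ValueError(f"unknown mode {mode!r}")
    # adjacency of the recruitment forest over record indices
    children: list[list[int]] = [[] for _ in range(s)]
    parent = [r.recruiter for r in forest.records]
    for i, p in enumerate(parent):
        if p is not None:
            children[p].append(i)
    dist = np.full((s, s), UNLINKED, dtype=np.int64)
    for src in range(s):
        dist[src, src] = 0
        frontier = deque([src])
        while frontier:
            u = frontier.popleft()
            du = dist[src, u]
            nbrs = children[u] + ([parent[u]] if parent[u] is not None else [])
            for v in nbrs:
                if dist[src, v] == UNLINKED:
                    dist[src, v] = du + 1
                    frontier.append(v)
    return dist


def empirical_sampling_variance(estimates: np.ndarray, mu: float) -> float:
    """Population sampling variance: mean squared deviation around the truth.

    This is the across-replicate MSE of the point estimator around the
    population mean mu, not the central variance of the replicate estimates.
    """
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size < 2:
        raise ValueError("need at least 2 replicate estimates")
    return float(np.mean((estimates - mu) ** 2))
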