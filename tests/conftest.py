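"""Shared fixtures and independent Monte Carlo oracles."""

from __future__ import annotations

from collections import deque

import networkx as nx
import numpy as np
import pytest

from rdsvar import BlockSpec, Network
from rdsvar.sampler import Record, RecruitmentForest
from rdsvar.spectral import StateChain


def mc_walk_variance(chain: StateChain, s: int, n_walks: int, seed: int) -> tuple[float, float]:
    """Monte Carlo oracle for the stationary-walk variance of the mean.

    Simulates ``n_walks`` independent s-step walks started from the
    stationary distribution (fully vectorized) and returns the MC estimate
    of E[(ybar - mu)^2] around the stationary mean plus its standard error.
    Independent of the spectral formula it checks.
    """
    rng = np.random.default_rng(seed)
    cum = np.cumsum(chain.P, axis=1)
    states = rng.choice(chain.n_states, size=n_walks, p=chain.pi)
    ysum = chain.y[states].astype(float)
    for _ in range(s - 1):
        u = rng.random(n_walks)
        # vectorized categorical draw: row-wise inverse CDF lookup
        states = (cum[states] < u[:, None]).sum(axis=1)
        ysum += chain.y[states]
    ybar = ysum / s
    sq = (ybar - chain.stationary_mean) ** 2
    return float(sq.mean()), float(sq.std(ddof=1) / np.sqrt(n_walks))


def simulate_category_forest(
    switch_prob: float,
    s: int,
    rng: np.random.Generator,
    branch_probs: tuple[float, ...] = (0.0, 1.0, 0.0, 0.0),
    degree: int = 2,
    p0: float = 0.5,
) -> RecruitmentForest:
    """Forest whose y-sequence is a true first-order chain on two categories.

    Each recruit's value flips its recruiter's with probability
    ``switch_prob`` (the symmetric 2-state chain); recruitment branches per
    ``branch_probs``; all degrees equal so weighting is inert.  This is the
    FOM-by-construction data generator: no network is involved, so the
    first-order assumption holds exactly.
    """
    records: list[Record] = []
    queue: deque[int] = deque()

    def add(y: int, rec: int | None, wave: int) -> None:
        records.append(Record(str(len(records)), rec, wave, int(y), degree))
        queue.append(len(records) - 1)

    add(rng.random() < p0, None, 0)
    while len(records) < s:
        if not queue:
            add(rng.random() < p0, None, 0)
            continue
        idx = queue.popleft()
        k = int(rng.choice(len(branch_probs), p=branch_probs))
        for _ in range(k):
            if len(records) >= s:
                break
            flip = rng.random() < switch_prob
            add(records[idx].y ^ flip, idx, records[idx].wave + 1)
    return RecruitmentForest(records=tuple(records))


def er_network_iid_y(n: int, p_edge: float, p_y: float, seed: int) -> Network:
    """Largest component of an ER graph with i.i.d. Bernoulli y (null fixture)."""
    from rdsvar import assign_iid_attribute

    g = nx.gnp_random_graph(n, p_edge, seed=seed)
    g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
    g = nx.relabel_nodes(g, {v: str(v) for v in g.nodes})
    net = Network(graph=g, y={v: 0 for v in g.nodes})
    return assign_iid_attribute(net, p_y, seed + 1)


@pytest.fixture
def spec_ex1() -> BlockSpec:
    """First worked example: E = F = H, so a = b = 1/3."""
    return BlockSpec(e=10, f=10, h=10)


@pytest.fixture
def spec_ex2() -> BlockSpec:
    """Second worked example: a = 1/21, b = 10/21 (F:H:E = 10:100:100)."""
    return BlockSpec(e=100, f=10, h=100)


@pytest.fixture
def triangle() -> Network:
    g = nx.Graph([("a", "b"), ("b", "c"), ("c", "a")])
    return Network(graph=g, y={"a": 1, "b": 0, "c": 1})


@pytest.fixture
def path3() -> Network:
    g = nx.Graph([("1", "2"), ("2", "3")])
    return Network(graph=g, y={"1": 0, "2": 1, "3": 0})
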