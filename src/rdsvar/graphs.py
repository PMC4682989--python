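"""Population networks with a binary attribute, file I/O, and synthetic generators.

A :class:`Network` is the population object of every downstream computation:
an undirected simple graph whose nodes carry a dichotomous attribute ``y``
(the survey variable of interest).  Networks can be read from edge lists or
GraphML, or generated synthetically:

* :func:`realize_block_network` realizes the two-variable block model in
  which a hidden variable ``z`` structures cross-group mixing on ``y`` —
  the canonical setting in which first-order (dyadic) summaries of homophily
  understate the clustering a random walk actually experiences.
* :func:`assign_iid_attribute` overwrites ``y`` with i.i.d. Bernoulli draws,
  the null fixture for the first-order-Markov diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import networkx as nx
import numpy as np

__all__ = [
    "Network",
    "BlockSpec",
    "load_network",
    "largest_component",
    "realize_block_network",
    "assign_iid_attribute",
    "write_network",
]


@dataclass(frozen=True)
class Network:
    """Undirected simple graph with a binary node attribute.

    Parameters
    ----------
    graph
        The underlying :class:`networkx.Graph`.  Self-loops and parallel
        edges are disallowed; node identifiers are treated as opaque strings.
    y
        Mapping node -> {0, 1}, defined for every node.
    z
        Optional second (hidden) binary attribute, kept for block-model
        bookkeeping; not used by any estimator.
    """

    graph: nx.Graph
    y: Mapping[str, int]
    z: Mapping[str, int] | None = None
    _nodes: tuple[str, ...] = field(init=False, repr=False, default=())

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("self-loops are not allowed")
        missing = [n for n in self.graph.nodes if n not in self.y]
        if missing:
            raise ValueError(f"nodes missing a y value: {sorted(missing)[:10]}")
        bad = [n for n in self.graph.nodes if self.y[n] not in (0, 1)]
        if bad:
            raise ValueError(f"y must be binary; offending nodes: {sorted(bad)[:10]}")
        # deterministic node order: sorted lexicographic on the string id
        object.__setattr__(self, "_nodes", tuple(sorted(self.graph.nodes, key=str)))

    @property
    def nodes(self) -> tuple[str, ...]:
        """Node identifiers in deterministic (sorted) order."""
        return self._nodes

    @property
    def n(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def m(self) -> int:
        """Total number of (undirected) edges."""
        return self.graph.number_of_edges()

    def degree(self, node: str) -> int:
        return self.graph.degree[node]

    def degrees(self) -> np.ndarray:
        """Degree vector aligned with :attr:`nodes`."""
        return np.array([self.graph.degree[n] for n in self.nodes])

    def y_vector(self) -> np.ndarray:
        """Attribute vector aligned with :attr:`nodes`."""
        return np.array([self.y[n] for n in self.nodes])

    def is_connected(self) -> bool:
        return self.n > 0 and nx.is_connected(self.graph)

    def require_connected(self) -> None:
        if not self.is_connected():
            raise ValueError(
                "operation requires a single connected component; "
                "apply largest_component() first"
            )

    def neighbors(self, node: str) -> list[str]:
        return sorted(self.graph.neighbors(node), key=str)


@dataclass(frozen=True)
class BlockSpec:
    """Tie counts of the hidden-variable block model.

    The population splits into four equally sized cells by the observed
    attribute ``y`` and a hidden attribute ``z``: (y=0,z=0), (y=0,z=1),
    (y=1,z=1), (y=1,z=0).  ``z = 1`` marks the people who form cross-``y``
    ties.  The counts are edge-endpoint (stub) totals per cell pair:

    * ``d`` — within-cell stubs of each z=0 cell (so ``d/2`` edges),
    * ``e`` — edges between the two same-``y`` cells (z=0 with z=1),
    * ``f`` — within-cell stubs of each z=1 cell (``f/2`` edges),
    * ``h`` — cross-``y`` edges (between the two z=1 cells).

    Every cell has the same total degree, which forces ``d = f + h``.
    The mixing fractions are ``a = f/(e+f+h)`` and ``b = h/(e+f+h)``.
    """

    e: int
    f: int
    h: int
    n_per_cell: int = 30

    def __post_init__(self) -> None:
        if min(self.e, self.f, self.h) < 0 or self.n_per_cell < 1:
            raise ValueError("tie counts must be nonnegative and n_per_cell >= 1")
        if self.e + self.f + self.h == 0:
            raise ValueError("at least one tie count must be positive")
        if self.a + self.b > 1 + 1e-12:
            raise ValueError("infeasible spec: a + b must not exceed 1")

    @property
    def d(self) -> int:
        """Within-cell stub count of the z=0 cells (equal total degree)."""
        return self.f + self.h

    @property
    def a(self) -> float:
        return self.f / (self.e + self.f + self.h)

    @property
    def b(self) -> float:
        return self.h / (self.e + self.f + self.h)


# cell order used everywhere: matches the 4-state transition matrix rows
CELLS = (("0", "0"), ("0", "1"), ("1", "1"), ("1", "0"))  # (y, z)


def load_network(
    path: str,
    format: str = "edgelist",
    attr_name: str = "y",
    dichotomize: Callable[[object], int] | None = None,
    attr_path: str | None = None,
) -> Network:
    """Read an undirected network with a binary node attribute.

    Edge direction is ignored (reciprocal nominations merge into one
    undirected edge), duplicate edges collapse, self-loops are dropped.

    Parameters
    ----------
    path
        Edge-list (whitespace/TSV, '#' comments, optional header) or GraphML
        file.
    format
        ``"edgelist"`` or ``"graphml"``.
    attr_name
        Node-attribute name holding the survey variable (GraphML), or the
        column name in ``attr_path`` (edge list).
    dichotomize
        Optional recode rule applied to each raw attribute value; must return
        0 or 1.  The library never guesses a reference category.
    attr_path
        For edge lists: CSV with columns ``node,<attr_name>`` supplying the
        attribute (edge lists carry no node data themselves).
    """
    if format == "edgelist":
        g = _read_edgelist(path)
        if attr_path is None:
            raise ValueError("edgelist input requires attr_path with node attributes")
        import pandas as pd

        tab = pd.read_csv(attr_path, dtype={0: str})
        if attr_name not in tab.columns:
            raise ValueError(f"attribute column {attr_name!r} not in {attr_path}")
        raw = dict(zip(tab.iloc[:, 0].astype(str), tab[attr_name]))
        zcol = dict(zip(tab.iloc[:, 0].astype(str), tab["z"])) if "z" in tab.columns else None
        g.add_nodes_from(raw)  # the attribute file is the node roster: keep isolates
    elif format == "graphml":
        g0 = nx.read_graphml(path)
        g = nx.Graph()
        g.add_nodes_from(str(n) for n in g0.nodes)
        g.add_edges_from((str(u), str(v)) for u, v in g0.edges if str(u) != str(v))
        raw = {str(n): d.get(attr_name) for n, d in g0.nodes(data=True)}
        zcol = None
    else:
        raise ValueError(f"unknown format {format!r}")

    missing = sorted(n for n in g.nodes if raw.get(n) is None)
    if missing:
        raise ValueError(f"attribute {attr_name!r} missing for nodes: {missing[:20]}")
    recode = dichotomize if dichotomize is not None else lambda v: int(v)
    y = {n: recode(raw[n]) for n in g.nodes}
    z = {n: int(zcol[n]) for n in g.nodes} if zcol else None
    return Network(graph=g, y=y, z=z)


def _read_edgelist(path: str) -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: cannot parse edge {line!r}")
            u, v = parts[0], parts[1]
            if lineno == 1 and not any(c.isdigit() for c in u + v) and (u.lower(), v.lower()) in {
                ("source", "target"), ("from", "to"), ("ego", "alter")
            }:
                continue  # header row
            if u != v:
                g.add_edge(u, v)
    if g.number_of_nodes() == 0:
        raise ValueError(f"{path}: no edges found")
    return g


def write_network(net: Network, edge_path: str, attr_path: str) -> None:
    """Write edge list (TSV) plus node-attribute CSV (node, y[, z])."""
    with open(edge_path, "w") as fh:
        for u, v in sorted((tuple(sorted((u, v), key=str)) for u, v in net.graph.edges)):
            fh.write(f"{u}\t{v}\n")
    with open(attr_path, "w") as fh:
        cols = "node,y,z" if net.z is not None else "node,y"
        fh.write(cols + "\n")
        for n in net.nodes:
            if net.z is not None:
                fh.write(f"{n},{net.y[n]},{net.z[n]}\n")
            else:
                fh.write(f"{n},{net.y[n]}\n")


def largest_component(net: Network) -> Network:
    """Induced subgraph on the largest connected component.

    Ties in component size are broken by the smallest minimum node
    identifier, so the result is deterministic.
    """
    if net.n == 0:
        raise ValueError("empty network")
    comps = sorted(
        nx.connected_components(net.graph),
        key=lambda c: (-len(c), min(str(n) for n in c)),
    )
    keep = comps[0]
    sub = net.graph.subgraph(keep).copy()
    y = {n: net.y[n] for n in keep}
    z = {n: net.z[n] for n in keep} if net.z is not None else None
    return Network(graph=sub, y=y, z=z)


def realize_block_network(spec: BlockSpec, seed: int) -> Network:
    """Realize the block model at node level with exact cell-pair edge counts.

    Edges are placed uniformly at random without replacement within each cell
    pair, so the aggregate counts match the spec exactly in every draw.  The
    placement mechanism within cells is a modelling choice: the block model
    itself only pins down cell-level totals.

    Node ids are ``y<y>z<z>_<k>``; ``y`` and ``z`` attributes set per cell.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_per_cell
    if spec.d % 2 or spec.f % 2:
        raise ValueError("diagonal (within-cell) stub counts d and f must be even")
    within = {0: spec.d // 2, 1: spec.f // 2, 2: spec.f // 2, 3: spec.d // 2}
    between = {(0, 1): spec.e, (1, 2): spec.h, (2, 3): spec.e}
    max_within = n * (n - 1) // 2
    for ci, cnt in within.items():
        if cnt > max_within:
            raise ValueError(
                f"infeasible within-cell count for cell {CELLS[ci]}: "
                f"{cnt} > {max_within}"
            )
    for (ci, cj), cnt in between.items():
        if cnt > n * n:
            raise ValueError(
                f"infeasible cross-cell count for cells {CELLS[ci]}-{CELLS[cj]}: "
                f"{cnt} > {n * n}"
            )

    g = nx.Graph()
    names = {}
    y, z = {}, {}
    for ci, (yy, zz) in enumerate(CELLS):
        names[ci] = [f"y{yy}z{zz}_{k:03d}" for k in range(n)]
        for node in names[ci]:
            g.add_node(node)
            y[node] = int(yy)
            z[node] = int(zz)

    for ci, cnt in within.items():
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        chosen = rng.choice(len(pairs), size=cnt, replace=False)
        for idx in chosen:
            i, j = pairs[idx]
            g.add_edge(names[ci][i], names[ci][j])
    for (ci, cj), cnt in between.items():
        chosen = rng.choice(n * n, size=cnt, replace=False)
        for idx in chosen:
            g.add_edge(names[ci][idx // n], names[cj][idx % n])
    return Network(graph=g, y=y, z=z)


def assign_iid_attribute(net: Network, p: float, seed: int) -> Network:
    """Replace ``y`` with i.i.d. Bernoulli(p) draws (null-model fixture)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be a probability")
    rng = np.random.default_rng(seed)
    draws = rng.random(net.n) < p
    y = {node: int(b) for node, b in zip(net.nodes, draws)}
    return Network(graph=net.graph.copy(), y=y, z=net.z)
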