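"""Markov chains of random walks on networks and their exact sampling variance.

A simple random walk on an undirected connected graph visits nodes with
stationary probability pi_i = d_i / 2m.  The variance of the mean of a
binary attribute Y over an s-step stationary walk is governed by the
spectrum of the walk's transition matrix M (equivalently of its symmetrized
form M*_ij = G_ij / sqrt(d_i d_j), which shares M's eigenvalues):

    cov(t) = sum_{k>=2} alpha_k^2 lambda_k^t
    Var(ybar) = S^-2 [ S sigma^2 + 2 sum_{t=1}^{S-1} (S - t) cov(t) ]

where lambda_k are the eigenvalues, alpha_k the loadings of the
mean-centered, sqrt(pi)-weighted attribute on the orthonormal eigenvectors
of M*, and sigma^2 = sum_k>=2 alpha_k^2 is the stationary variance of Y.
The design effect divides Var(ybar) by the same-size simple-random-sampling
variance sigma^2 / S.

The module also builds the four-state cell-level chain of the hidden-variable
block model (:func:`block_chain`) together with its two-state dyadic
collapse (:func:`collapsed_chain`) — the pair whose spectral gap mismatch is
the source of downward bias in sample-based RDS variance estimators — and
the closed-form eigenvalues of the four-state chain
(:func:`block_eigenvalues`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graphs import BlockSpec, Network

__all__ = [
    "StateChain",
    "node_chain",
    "chain_from_matrix",
    "block_chain",
    "collapsed_chain",
    "block_eigenvalues",
    "propagate",
    "step_covariance",
    "exact_rw_variance",
    "RWVariance",
    "save_chain",
    "load_chain",
]

_ATOL = 1e-10


@dataclass(frozen=True)
class StateChain:
    """A finite Markov chain with a binary attribute on its states.

    Attributes
    ----------
    states : tuple of str
        Ordered state labels (nodes, y|z cells, or y categories).
    P : ndarray
        Row-stochastic transition matrix.
    y : ndarray
        Attribute value of each state, in {0, 1}.
    pi : ndarray
        Stationary distribution (pi @ P == pi).
    lambdas : ndarray
        Real eigenvalues sorted descending, lambdas[0] == 1.
    alphas : ndarray
        Loadings of sqrt(pi)-weighted, mean-centered y on the orthonormal
        eigenvectors of the symmetrized matrix; alphas[0] == 0 and
        sum(alphas[1:]**2) equals the stationary variance of y.
    irreducible : bool
        False when the chain has unreachable blocks (e.g. no cross-group
        mixing); spectral quantities are then computed but flagged.
    reversible : bool
        Detailed balance holds (pi_i P_ij == pi_j P_ji).  Chains built from
        undirected networks, block cells and 2-state chains are reversible;
        lifted history-state chains are not.  The eigen-sum covariance form
        requires reversibility; non-reversible chains fall back to exact
        matrix-power covariances and carry ``alphas=None``.
    """

    states: tuple[str, ...]
    P: np.ndarray
    y: np.ndarray
    pi: np.ndarray
    lambdas: np.ndarray
    alphas: np.ndarray | None
    irreducible: bool = True
    reversible: bool = True

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def stationary_mean(self) -> float:
        return float(self.pi @ self.y)

    @property
    def stationary_variance(self) -> float:
        """sum_i pi_i (y_i - mu)^2, identically sum_{k>=2} alpha_k^2."""
        mu = self.stationary_mean
        return float(self.pi @ (self.y - mu) ** 2)


def _is_irreducible(P: np.ndarray) -> bool:
    n = P.shape[0]
    reach = ((P > 0) | np.eye(n, dtype=bool)).astype(np.int64)
    # transitive closure by repeated squaring
    for _ in range(int(np.ceil(np.log2(max(n, 2))))):
        reach = np.minimum(reach @ reach, 1)
    return bool(reach.all())


def chain_from_matrix(
    P: np.ndarray,
    y: np.ndarray,
    states: tuple[str, ...] | None = None,
    pi: np.ndarray | None = None,
) -> StateChain:
    """Build a :class:`StateChain` from a row-stochastic matrix.

    ``pi`` is computed as the leading left eigenvector when not supplied.
    The eigensystem is taken from the pi-symmetrized matrix
    diag(pi)^1/2 P diag(pi)^-1/2, valid for reversible chains (every chain
    arising from an undirected network, and every 2-state chain).
    """
    P = np.asarray(P, dtype=float)
    y = np.asarray(y, dtype=float)
    n = P.shape[0]
    if P.shape != (n, n) or y.shape != (n,):
        raise ValueError("shape mismatch between P and y")
    if not np.allclose(P.sum(axis=1), 1.0, atol=_ATOL):
        raise ValueError("rows of P must sum to 1")
    if states is None:
        states = tuple(str(i) for i in range(n))

    irreducible = _is_irreducible(P)
    if pi is None:
        vals, vecs = np.linalg.eig(P.T)
        k = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, k])
        pi = pi / pi.sum()
    pi = np.asarray(pi, dtype=float)
    if np.any(pi < -_ATOL):
        raise ValueError("stationary distribution has negative entries")
    pi = np.clip(pi, 0.0, None)
    pi = pi / pi.sum()

    flows = pi[:, None] * P
    reversible = bool(np.allclose(flows, flows.T, atol=1e-9))
    if reversible:
        sq = np.sqrt(pi)
        with np.errstate(divide="ignore", invalid="ignore"):
            sym = (sq[:, None] / np.where(sq[None, :] > 0, sq[None, :], 1.0)) * P
        sym = (sym + sym.T) / 2.0
        lambdas, vecs = np.linalg.eigh(sym)
        order = np.argsort(lambdas)[::-1]
        lambdas = lambdas[order]
        vecs = vecs[:, order]
        mu = float(pi @ y)
        alphas = vecs.T @ (sq * (y - mu))
    else:
        ev = np.linalg.eigvals(P)
        lambdas = np.real(ev[np.argsort(-np.real(ev))])
        alphas = None
    return StateChain(
        states=states, P=P, y=y, pi=pi,
        lambdas=lambdas, alphas=alphas, irreducible=irreducible,
        reversible=reversible,
    )


def node_chain(net: Network) -> StateChain:
    """Node-level walk chain of a connected network: P_ij = G_ij / d_i."""
    net.require_connected()
    if net.n < 2:
        raise ValueError("need at least 2 nodes")
    import networkx as nx

    A = nx.to_numpy_array(net.graph, nodelist=list(net.nodes))
    d = A.sum(axis=1)
    P = A / d[:, None]
    pi = d / d.sum()
    return chain_from_matrix(P, net.y_vector().astype(float), states=net.nodes, pi=pi)


def block_chain(spec: BlockSpec) -> StateChain:
    """Four-state cell-level chain of the block model.

    States (y=0 z=0, y=0 z=1, y=1 z=1, y=1 z=0) with equal total degree per
    cell, hence uniform stationary distribution.  A chain with no cross-group
    mixing (b = 0) is reducible across y and flagged via ``irreducible``.
    """
    a, b = spec.a, spec.b
    P = np.array(
        [
            [1 - a, a, 0, 0],
            [a, 1 - a - b, b, 0],
            [0, b, 1 - a - b, a],
            [0, 0, a, 1 - a],
        ]
    )
    y = np.array([0.0, 0.0, 1.0, 1.0])
    states = ("y0z0", "y0z1", "y1z1", "y1z0")
    return chain_from_matrix(P, y, states=states, pi=np.full(4, 0.25))


def collapsed_chain(spec: BlockSpec) -> StateChain:
    """Two-state dyadic collapse of the block chain.

    Cross-group transition probability i = b/2: the fraction of all ties
    that cross y groups, which is what a first-order (dyadic) summary of the
    sample sees.
    """
    i = spec.b / 2.0
    P = np.array([[1 - i, i], [i, 1 - i]])
    return chain_from_matrix(P, np.array([0.0, 1.0]), states=("y0", "y1"),
                             pi=np.array([0.5, 0.5]))


def block_eigenvalues(spec: BlockSpec) -> np.ndarray:
    """Closed-form eigenvalues of the four-state block chain, sorted descending.

    [1, 1-b-a+sqrt(a^2+b^2), 1-2a, 1-b-a-sqrt(a^2+b^2)]; agrees with the
    numeric eigendecomposition of :func:`block_chain` to 1e-10.
    """
    a, b = spec.a, spec.b
    root = np.sqrt(a * a + b * b)
    vals = np.array([1.0, 1 - b - a + root, 1 - 2 * a, 1 - b - a - root])
    return np.sort(vals)[::-1]


def propagate(chain: StateChain, p0: np.ndarray, s: int) -> np.ndarray:
    """Distribution after s steps: p0 @ P^s."""
    p0 = np.asarray(p0, dtype=float)
    if not np.isclose(p0.sum(), 1.0, atol=1e-8):
        raise ValueError("p0 must sum to 1")
    if s < 0:
        raise ValueError("s must be nonnegative")
    out = p0.copy()
    for _ in range(s):
        out = out @ chain.P
    return out


def step_covariance(chain: StateChain, lag: int) -> float:
    """Covariance between two stationary-walk observations ``lag`` steps apart.

    cov(t) = sum_{k>=2} alpha_k^2 lambda_k^t; at lag 0 this is the
    stationary variance of y.  For non-reversible chains the equivalent
    matrix-power form pi . (y* o P^t y*) is used.
    """
    if lag < 0:
        raise ValueError("lag must be nonnegative")
    if chain.reversible:
        a2 = chain.alphas[1:] ** 2
        return float(np.sum(a2 * chain.lambdas[1:] ** lag))
    ystar = chain.y - chain.stationary_mean
    v = ystar.copy()
    for _ in range(lag):
        v = chain.P @ v
    return float(chain.pi @ (ystar * v))


@dataclass(frozen=True)
class RWVariance:
    variance: float
    sd: float = field(init=False)
    design_effect: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "sd", float(np.sqrt(self.variance)))


def exact_rw_variance(chain: StateChain, s: int) -> RWVariance:
    """Exact sampling variance of the mean of y over an s-step stationary walk.

    Var(ybar) = S^-2 [S sigma^2 + 2 sum_{t=1}^{S-1} (S-t) cov(t)], with the
    walk started from the stationary distribution.  The design effect divides
    by the SRS variance sigma^2 / S of the stationary law.  A constant-y
    chain returns variance 0 with design effect 1.
    """
    if s < 2:
        raise ValueError("s must be >= 2")
    sigma2 = chain.stationary_variance
    if sigma2 <= 0.0:
        return RWVariance(variance=0.0, design_effect=1.0)
    if chain.reversible:
        a2 = chain.alphas[1:] ** 2
        lam = chain.lambdas[1:]
        t = np.arange(1, s)
        # sum_t (S - t) * sum_k a2_k lam_k^t, via the (k, t) power table
        powers = lam[:, None] ** t[None, :]
        covsum = float(a2 @ (powers @ (s - t)))
    else:
        ystar = chain.y - chain.stationary_mean
        v = ystar.copy()
        covsum = 0.0
        for t in range(1, s):
            v = chain.P @ v
            covsum += (s - t) * float(chain.pi @ (ystar * v))
    variance = (s * sigma2 + 2.0 * covsum) / s**2
    return RWVariance(variance=variance, design_effect=variance / (sigma2 / s))


def save_chain(chain: StateChain, matrix_path: str, meta_path: str) -> None:
    """Serialize a chain as a transition-matrix CSV plus state metadata CSV."""
    np.savetxt(matrix_path, chain.P, delimiter=",")
    with open(meta_path, "w") as fh:
        fh.write("state,y,pi\n")
        for s, yy, pp in zip(chain.states, chain.y, chain.pi):
            fh.write(f"{s},{int(yy)},{float(pp):.17g}\n")


def load_chain(matrix_path: str, meta_path: str) -> StateChain:
    import pandas as pd

    P = np.loadtxt(matrix_path, delimiter=",", ndmin=2)
    meta = pd.read_csv(meta_path)
    return chain_from_matrix(
        P,
        meta["y"].to_numpy(dtype=float),
        states=tuple(meta["state"].astype(str)),
        pi=meta["pi"].to_numpy(dtype=float),
    )
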