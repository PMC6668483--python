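"""Markov Clustering with inflation, balance and penalty-proportion parameters.

Flow on the network is simulated on a column-stochastic matrix built from the
weighted adjacency matrix whose diagonal is each node's maximum incident
weight (a self-loop that keeps flow from oscillating).  One MCL iteration is

    penalty -> expansion (matrix power) -> inflation (entrywise power,
    column renormalization) -> pruning of near-zero entries,

repeated to (near-)idempotence.  Attractors are nodes that retain positive
self-flow at convergence; clusters are the connected components of the
attractor-support relation.  The penalty step down-weights columns of nodes
that have repeatedly served as attractors in earlier runs on the same
subnetwork (scale ``pp ** -(count ** b)``), nudging the search away from
always reusing the same high-propensity attractor nuclei; with a fresh
record it is the identity and the procedure is canonical MCL.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import PPINetwork

logger = logging.getLogger(__name__)


@dataclass
class MCLParams:
    """MCL tuning knobs: inflation ``ic``, balance ``b``, penalty proportion ``pp``.

    ``ic`` controls granularity (larger -> smaller clusters) and is searched
    in ``[lic, hic]`` = [1, 6]; ``b`` and ``pp`` shape the attractor penalty.
    Defaults for ``b`` and ``pp`` follow the standard parameterization of
    this method family (b = 0.5, pp = 1.25).
    """

    ic: float = 2.0
    b: float = 0.5
    pp: float = 1.25
    lic: float = 1.0
    hic: float = 6.0
    expansion: int = 2
    prune_eps: float = 1e-6
    tol: float = 1e-8
    max_iter: int = 100

    def __post_init__(self) -> None:
        if not (self.lic <= self.ic <= self.hic):
            raise ValueError(f"ic={self.ic} outside [{self.lic}, {self.hic}]")
        if not (0.0 <= self.b <= 1.0):
            raise ValueError("b must lie in [0, 1]")
        if self.pp < 1.0:
            raise ValueError("pp must be >= 1")
        if self.expansion < 2:
            raise ValueError("expansion must be >= 2")


@dataclass
class FlowMatrix:
    """Node order, adjacency matrix and the column-stochastic flow matrix."""

    order: list[str]
    adj: np.ndarray
    mat: np.ndarray | None = None


@dataclass
class AttractorRecord:
    """How often each node has served as an attractor across MCL runs.

    One record is shared by all MCL evaluations within a single optimization
    of one subnetwork; it feeds the penalty step.
    """

    counts: dict[str, int] = field(default_factory=dict)

    def increment(self, nodes) -> None:
        for n in nodes:
            self.counts[n] = self.counts.get(n, 0) + 1


def build_adjacency(net: PPINetwork) -> FlowMatrix:
    """Adjacency with self-loops: Adj(i,i) = max incident weight (1.0 if isolated)."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    order = sorted(net.nodes)
    idx = {n: i for i, n in enumerate(order)}
    n = len(order)
    adj = np.zeros((n, n))
    for u, v in net.graph.edges:
        w = net.weight(u, v)
        adj[idx[u], idx[v]] = w
        adj[idx[v], idx[u]] = w
    for i, node in enumerate(order):
        inc = adj[i, :]
        mx = inc.max()
        adj[i, i] = mx if mx > 0 else 1.0
    return FlowMatrix(order=order, adj=adj)


def normalize(fm: FlowMatrix) -> FlowMatrix:
    """Fill the column-stochastic flow matrix mat(i,j) = adj(i,j) / colsum_j."""
    colsums = fm.adj.sum(axis=0)
    assert (colsums > 0).all(), "zero column: adjacency diagonal must be positive"
    fm.mat = fm.adj / colsums
    return fm


def expand(mat: np.ndarray, power: int = 2) -> np.ndarray:
    """Matrix power: flow spreads along length-``power`` walks."""
    return np.linalg.matrix_power(mat, power)


def inflate(mat: np.ndarray, ic: float) -> np.ndarray:
    """Entrywise power ``ic`` followed by column renormalization."""
    out = np.power(mat, ic)
    return out / out.sum(axis=0)


def apply_penalty(
    mat: np.ndarray, params: MCLParams, rec: AttractorRecord, order: list[str]
) -> np.ndarray:
    """Scale column j by pp ** -(counts[j] ** b), then renormalize columns.

    With all counts zero this is exactly the identity.
    """
    counts = np.array([rec.counts.get(n, 0) for n in order], dtype=float)
    if not counts.any():
        return mat
    scale = np.power(params.pp, -np.power(counts, params.b))
    out = mat * scale
    colsums = out.sum(axis=0)
    colsums[colsums == 0] = 1.0
    return out / colsums


def prune(mat: np.ndarray, eps: float) -> np.ndarray:
    """Zero entries below eps and renormalize; a zeroed column regains unit diagonal mass."""
    out = np.where(mat < eps, 0.0, mat)
    colsums = out.sum(axis=0)
    dead = colsums == 0
    if dead.any():
        out[np.where(dead)[0], np.where(dead)[0]] = 1.0
        colsums = out.sum(axis=0)
    return out / colsums


def _components(pairs: dict[str, set[str]], order: list[str]) -> list[set[str]]:
    # union-find over the attractor-support relation
    parent = {n: n for n in order}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for attractor, supported in pairs.items():
        for node in supported:
            union(attractor, node)
    groups: dict[str, set[str]] = {}
    touched = set(pairs) | {n for s in pairs.values() for n in s}
    for n in touched:
        groups.setdefault(find(n), set()).add(n)
    return list(groups.values())


def run_mcl(
    net: PPINetwork,
    params: MCLParams,
    rec: AttractorRecord | None = None,
) -> list[frozenset[str]]:
    """Run MCL on a network and return clusters, largest first.

    The iteration is penalty -> expand -> inflate -> prune until the max-abs
    change between successive iterations falls below ``params.tol`` or
    ``params.max_iter`` is reached (then the current matrix is interpreted
    with a warning).  Unsupported nodes — possible only without full
    convergence — become singletons.  Deterministic: no randomness anywhere.
    """
    if net.n_nodes == 0:
        return []
    if rec is None:
        rec = AttractorRecord()
    fm = normalize(build_adjacency(net))
    order = fm.order
    mat = fm.mat
    converged = False
    for _ in range(params.max_iter):
        new = apply_penalty(mat, params, rec, order)
        new = expand(new, params.expansion)
        new = inflate(new, params.ic)
        new = prune(new, params.prune_eps)
        if np.abs(new - mat).max() < params.tol:
            mat = new
            converged = True
            break
        mat = new
    if not converged:
        warnings.warn("MCL did not converge within max_iter; clustering current matrix")
    attractor_rows = np.nonzero(np.diag(mat) > 0)[0]
    attractors = [order[i] for i in attractor_rows]
    support = {
        order[i]: {order[j] for j in np.nonzero(mat[i, :] > 0)[0]}
        for i in attractor_rows
    }
    comps = _components(support, order)
    clustered = set().union(*comps) if comps else set()
    comps.extend({n} for n in set(order) - clustered)  # safety net, empty at convergence
    rec.increment(attractors)
    comps.sort(key=lambda c: (-len(c), min(c)))
    return [frozenset(c) for c in comps]


def filter_min_size(
    clusters: list[frozenset[str]], k: int = 3
) -> tuple[list[frozenset[str]], set[str]]:
    """Drop clusters smaller than ``k`` members; return (kept, noise nodes).

    The minimum biologically meaningful complex size is three proteins;
    smaller MCL output is treated as noise.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    kept = [c for c in clusters if len(c) >= k]
    noise = set().union(*(c for c in clusters if len(c) < k)) if len(kept) < len(clusters) else set()
    return kept, noise


def dump_matrix(fm: FlowMatrix, path: str) -> None:
    """Write the flow matrix as dense tab-delimited text for inspection."""
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(fm.order) + "\n")
        m = fm.mat if fm.mat is not None else fm.adj
        for i, node in enumerate(fm.order):
            fh.write(node + "\t" + "\t".join(f"{x:.6g}" for x in m[i]) + "\n")
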