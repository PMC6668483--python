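"""Readers and writers for PPI edge lists, expression matrices and complex catalogs.

File formats are the flat tab-delimited conventions used by the yeast
protein-complex literature: a 2- or 3-column edge list, an expression table
with one gene per row and ``T * TR`` value columns (``T`` timestamps repeated
``TR`` times, timestamp-major), and one whitespace-separated complex per line
(the CYC2008/MIPS flat style).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when an input file violates its expected layout."""


class PPINetwork:
    """Undirected, optionally confidence-weighted protein interaction network.

    Nodes are opaque case-sensitive protein identifiers.  Self-loops are never
    stored; an edge ``(u, v)`` is identical to ``(v, u)``; weights are strictly
    positive (confidence scores in ``(0, 1]`` for real data, 1.0 by default).
    """

    def __init__(self, graph: nx.Graph | None = None):
        self._g = graph if graph is not None else nx.Graph()
        loops = list(nx.selfloop_edges(self._g))
        if loops:
            raise ValueError(f"self-loops are not allowed: {loops[:3]}")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str] | tuple[str, str, float]],
        nodes: Iterable[str] = (),
        default_weight: float = 1.0,
    ) -> "PPINetwork":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for e in edges:
            if len(e) == 2:
                u, v = e
                w = default_weight
            else:
                u, v, w = e
            if u == v:
                continue
            if w <= 0:
                raise ValueError(f"non-positive weight {w} on edge ({u}, {v})")
            # duplicate edges keep the maximum weight
            if g.has_edge(u, v):
                w = max(w, g[u][v]["weight"])
            g.add_edge(u, v, weight=float(w))
        return cls(g)

    # -- container surface ------------------------------------------------
    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((u, v)) for u, v in self._g.edges}

    def weight(self, u: str, v: str) -> float:
        return self._g[u][v]["weight"]

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def neighbors(self, u: str) -> set[str]:
        return set(self._g.neighbors(u))

    def subgraph(self, nodes: Iterable[str]) -> "PPINetwork":
        """Vertex-induced subgraph restricted to ``nodes`` present in the network."""
        keep = set(nodes) & set(self._g.nodes)
        return PPINetwork(nx.Graph(self._g.subgraph(keep)))

    def __contains__(self, node: str) -> bool:
        return node in self._g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PPINetwork):
            return NotImplemented
        if self.nodes != other.nodes or self.edges != other.edges:
            return False
        return all(
            np.isclose(self.weight(u, v), other.weight(u, v))
            for u, v in self._g.edges
        )

    def __repr__(self) -> str:
        return f"PPINetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass
class ExpressionMatrix:
    """Gene-expression table over ``T`` timestamps repeated ``TR`` times.

    ``values`` has one row per gene and ``T * TR`` columns; 0-based column
    ``j`` holds timestamp ``(j mod T) + 1`` of repetition ``j // T + 1``
    (timestamp-major layout, repetitions concatenated).
    """

    genes: list[str]
    values: np.ndarray
    T: int
    TR: int
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.T < 1 or self.TR < 1:
            raise ValueError("T and TR must be >= 1")
        if self.values.shape != (len(self.genes), self.T * self.TR):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.genes)}, {self.T * self.TR})"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene IDs must be unique")
        self._index = {g: i for i, g in enumerate(self.genes)}

    def row(self, gene: str) -> np.ndarray:
        return self.values[self._index[gene]]

    def __contains__(self, gene: str) -> bool:
        return gene in self._index


@dataclass
class ComplexCatalog:
    """An ordered family of protein complexes (member-ID sets)."""

    complexes: list[frozenset[str]]
    name: str = ""

    def __post_init__(self) -> None:
        if any(len(c) == 0 for c in self.complexes):
            raise ValueError("complexes must be non-empty")

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self):
        return iter(self.complexes)


def _tokens(line: str) -> list[str]:
    return line.split()


def read_ppi(path: str | Path, default_weight: float = 1.0) -> PPINetwork:
    """Read a 2- or 3-column tab/whitespace-delimited edge list.

    Lines starting with ``#`` are comments.  Self-loops are dropped with a
    warning (the flow matrix synthesizes its own diagonal); duplicate edges
    keep the maximum weight.
    """
    g = nx.Graph()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            toks = _tokens(line)
            if len(toks) not in (2, 3):
                raise FormatError(
                    f"{path}:{lineno}: expected 2 or 3 columns, found {len(toks)}"
                )
            u, v = toks[0], toks[1]
            if len(toks) == 3:
                try:
                    w = float(toks[2])
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: non-numeric weight {toks[2]!r}"
                    ) from None
            else:
                w = default_weight
            if w <= 0:
                raise FormatError(f"{path}:{lineno}: non-positive weight {w}")
            if u == v:
                logger.warning("%s:%d: dropping self-loop on %s", path, lineno, u)
                g.add_node(u)
                continue
            if g.has_edge(u, v) and g[u][v]["weight"] != w:
                logger.info(
                    "%s:%d: duplicate edge (%s, %s); keeping max weight", path, lineno, u, v
                )
                w = max(w, g[u][v]["weight"])
            g.add_edge(u, v, weight=w)
    return PPINetwork(g)


def read_expression(path: str | Path, T: int, TR: int) -> ExpressionMatrix:
    """Read a tab-delimited expression table (gene ID + ``T * TR`` numeric columns)."""
    genes: list[str] = []
    rows: list[list[float]] = []
    expected = T * TR
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            toks = _tokens(line)
            if len(toks) - 1 != expected:
                raise FormatError(
                    f"{path}:{lineno}: expected {expected} value columns "
                    f"(T={T} x TR={TR}), found {len(toks) - 1}"
                )
            try:
                vals = [float(t) for t in toks[1:]]
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric expression value") from None
            genes.append(toks[0])
            rows.append(vals)
    return ExpressionMatrix(genes=genes, values=np.array(rows, dtype=float), T=T, TR=TR)


def read_complexes(path: str | Path, name: str = "") -> ComplexCatalog:
    """Read a complex catalog: one complex per line, whitespace-separated members.

    Exact duplicate member sets are removed with a logged count.  Lines
    starting with ``#`` (e.g. the headers written by :func:`write_clusters`)
    are skipped.
    """
    seen: set[frozenset[str]] = set()
    complexes: list[frozenset[str]] = []
    dropped = 0
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            members = frozenset(_tokens(line))
            if members in seen:
                dropped += 1
                continue
            seen.add(members)
            complexes.append(members)
    if not complexes:
        raise FormatError(f"{path}: no complexes")
    if dropped:
        logger.warning("%s: removed %d duplicate complexes", path, dropped)
    return ComplexCatalog(complexes=complexes, name=name or str(path))


def write_clusters(
    clusters: Sequence[frozenset[str] | set[str]],
    path: str | Path,
    header: str | None = None,
) -> None:
    """Write complexes one per line, members sorted lexicographically.

    ``read_complexes(write_clusters(x))`` is the identity on deduplicated
    input.  An optional header comment (prefixed ``#``) records provenance.
    """
    with open(path, "w") as fh:
        if header:
            for h in header.splitlines():
                fh.write(f"# {h}\n")
        for c in clusters:
            fh.write(" ".join(sorted(c)) + "\n")
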