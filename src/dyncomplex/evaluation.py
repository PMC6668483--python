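"""CSS matching against gold-standard catalogs, accuracy measures, perturbation.

A predicted complex Pr and a benchmark complex Be match when their
complex similarity score (neighborhood affinity)

    CSS(Pr, Be) = |Pr ∩ Be|^2 / (|Pr| * |Be|)

strictly exceeds a threshold (0.2 by convention).  From the match counts the
standard measures follow: precision N_Pc/|predicted|, recall N_Bc/|known|,
their harmonic mean (F-measure) and geometric mean (accuracy), and the
coverage ratio — the fraction of benchmark protein mass captured by the
best-overlapping prediction of each benchmark complex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import sqrt
from typing import Sequence

import numpy as np

from .io import ComplexCatalog, PPINetwork

logger = logging.getLogger(__name__)

Sets = Sequence[frozenset[str]]


def css(pr: frozenset[str] | set[str], be: frozenset[str] | set[str]) -> float:
    """Complex similarity score |pr ∩ be|^2 / (|pr| * |be|); 1 iff equal sets."""
    if not pr or not be:
        raise ValueError("css is undefined for empty sets")
    inter = len(set(pr) & set(be))
    return inter * inter / (len(pr) * len(be))


def match(
    predicted: Sets, known: ComplexCatalog, threshold: float = 0.2
) -> tuple[int, int, np.ndarray]:
    """Count CSS matches (strict ``>`` at the threshold).

    Returns ``(n_pc, n_bc, matrix)`` where ``n_pc`` predicted complexes match
    at least one benchmark, ``n_bc`` benchmark complexes match at least one
    prediction, and ``matrix[i, j]`` says prediction i matches benchmark j.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    mat = np.zeros((len(predicted), len(known)), dtype=bool)
    for i, pr in enumerate(predicted):
        for j, be in enumerate(known.complexes):
            mat[i, j] = css(pr, be) > threshold
    n_pc = int(mat.any(axis=1).sum())
    n_bc = int(mat.any(axis=0).sum())
    return n_pc, n_bc, mat


def coverage_ratio(predicted: Sets, known: ComplexCatalog) -> float:
    """Fraction of benchmark protein mass covered by best-overlapping predictions."""
    num = 0
    den = 0
    for be in known.complexes:
        den += len(be)
        num += max((len(be & pr) for pr in predicted), default=0)
    return num / den if den else 0.0


@dataclass
class EvaluationReport:
    """CSS match counts and the derived accuracy measures."""

    n_pc: int
    n_bc: int
    n_predicted: int
    n_known: int
    precision: float
    recall: float
    f_measure: float
    accuracy: float
    coverage_ratio: float
    n_clusters: int
    css_threshold: float = 0.2

    def to_text(self) -> str:
        lines = [
            f"predicted complexes : {self.n_predicted}",
            f"known complexes     : {self.n_known}",
            f"matched predicted   : {self.n_pc}",
            f"matched known       : {self.n_bc}",
            f"precision           : {self.precision:.4f}",
            f"recall              : {self.recall:.4f}",
            f"f_measure           : {self.f_measure:.4f}",
            f"accuracy            : {self.accuracy:.4f}",
            f"coverage_ratio      : {self.coverage_ratio:.4f}",
            f"css_threshold       : {self.css_threshold}",
        ]
        return "\n".join(lines)

    def to_tsv(self) -> str:
        cols = [
            "n_predicted", "n_known", "n_pc", "n_bc", "precision", "recall",
            "f_measure", "accuracy", "coverage_ratio", "css_threshold",
        ]
        vals = [getattr(self, c) for c in cols]
        return (
            "\t".join(cols) + "\n"
            + "\t".join(f"{v:.6g}" if isinstance(v, float) else str(v) for v in vals)
        )


def evaluate(
    predicted: Sets, known: ComplexCatalog, threshold: float = 0.2
) -> EvaluationReport:
    """Score predictions against a gold standard at a CSS threshold.

    With zero predictions every measure is 0 by convention.  Order of either
    list never affects the result.
    """
    if len(known) == 0:
        raise ValueError("empty gold-standard catalog")
    if predicted:
        n_pc, n_bc, _ = match(predicted, known, threshold)
        precision = n_pc / len(predicted)
    else:
        n_pc = n_bc = 0
        precision = 0.0
    recall = n_bc / len(known)
    f = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    acc = sqrt(precision * recall)
    cr = coverage_ratio(predicted, known)
    return EvaluationReport(
        n_pc=n_pc,
        n_bc=n_bc,
        n_predicted=len(predicted),
        n_known=len(known),
        precision=precision,
        recall=recall,
        f_measure=f,
        accuracy=acc,
        coverage_ratio=cr,
        n_clusters=len(predicted),
        css_threshold=threshold,
    )


def perturb_network(
    net: PPINetwork,
    add_frac: float,
    del_frac: float,
    rng: np.random.Generator | int,
) -> PPINetwork:
    """Randomly delete then add edges; node set unchanged.

    Deletes ``round(del_frac * |E|)`` edges uniformly without replacement,
    then adds ``round(add_frac * |E|)`` uniformly chosen non-edges among the
    existing nodes with weight 1.0.  Deletion and addition use disjoint
    sub-streams of the seeded generator so either count can change without
    reshuffling the other.
    """
    if not (0.0 <= del_frac < 1.0):
        raise ValueError("del_frac must lie in [0, 1)")
    if add_frac < 0.0:
        raise ValueError("add_frac must be >= 0")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    del_rng, add_rng = rng.spawn(2)

    edges = sorted(tuple(sorted(e)) for e in net.edges)
    n_edges = len(edges)
    n_del = round(del_frac * n_edges)
    n_add = round(add_frac * n_edges)

    keep_idx = set(range(n_edges))
    if n_del:
        drop = del_rng.choice(n_edges, size=n_del, replace=False)
        keep_idx -= set(int(i) for i in drop)
    kept = [edges[i] for i in sorted(keep_idx)]

    nodes = sorted(net.nodes)
    present = set(kept)  # deletion happens first; a deleted pair is a valid addition
    non_edges = [
        (u, v)
        for i, u in enumerate(nodes)
        for v in nodes[i + 1:]
        if (u, v) not in present
    ]
    if n_add > len(non_edges):
        logger.warning(
            "requested %d additions but only %d non-edges available; capping",
            n_add, len(non_edges),
        )
        n_add = len(non_edges)
    added = []
    if n_add:
        pick = add_rng.choice(len(non_edges), size=n_add, replace=False)
        added = [non_edges[int(i)] for i in sorted(pick)]

    from .io import PPINetwork as _N

    return _N.from_edges(
        [(u, v, net.weight(u, v)) for u, v in kept] + [(u, v, 1.0) for u, v in added],
        nodes=nodes,
    )
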