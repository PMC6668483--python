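"""Three-sigma activity profiles and dynamic-network decomposition.

A gene's expression curve over T timestamps (averaged across TR repetitions)
defines an *active threshold*

    AT = UE + 3 * sigma * (1 - Fl),    Fl = 1 / (1 + sigma^2)

where UE is the grand mean and sigma^2 the population variance of the
per-timestamp means.  Fl damps the threshold for flat curves (a small
fluctuation above a flat baseline is meaningful) and pushes it toward the
full three-sigma bound UE + 3*sigma for volatile curves.  A gene is active at
timestamp i iff its mean expression there strictly exceeds AT; the static PPI
network is then split into one subnetwork per timestamp containing exactly
the co-active proteins and the edges between them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import networkx as nx
import numpy as np

from .io import ExpressionMatrix, PPINetwork

logger = logging.getLogger(__name__)

MissingPolicy = Literal["drop", "always_active"]


@dataclass
class ActivityProfile:
    """Per-gene three-sigma statistics and the derived active timestamps."""

    gene: str
    ev: np.ndarray          # mean expression per timestamp, length T
    ue: float               # grand mean over timestamps
    sigma2: float           # population variance of ev
    fl: float               # fluctuation weight 1/(1+sigma2), in (0, 1]
    s1: float               # normal mean bound (= ue)
    s2: float               # three-sigma bound ue + 3*sd
    at: float               # active threshold
    active: frozenset[int]  # 1-based timestamps with ev > at


def timestamp_means(expr: ExpressionMatrix, gene: str) -> np.ndarray:
    """Mean expression of ``gene`` at each timestamp, averaged over repetitions.

    Column ``i + T*(tr-1)`` (1-based) holds timestamp ``i`` of repetition
    ``tr``, so the row reshapes to ``(TR, T)`` and averages over axis 0.
    """
    row = expr.row(gene)  # KeyError for unknown gene
    return row.reshape(expr.TR, expr.T).mean(axis=0)


def activity_profile(expr: ExpressionMatrix, gene: str) -> ActivityProfile:
    """Compute the three-sigma profile of one gene.

    Variance is the population form (divide by T); activity uses the strict
    inequality ``ev[i] > at``, so a constant gene (sigma2 = 0, at = ue) is
    never active.
    """
    ev = timestamp_means(expr, gene)
    ue = float(ev.mean())
    sigma2 = float(ev.var())  # population variance
    sd = float(np.sqrt(sigma2))
    fl = 1.0 / (1.0 + sigma2)
    s1 = ue
    s2 = ue + 3.0 * sd
    at = ue + 3.0 * sd * (1.0 - fl)
    # strict exceedance, with a relative guard so rounding in the mean of a
    # constant row can never fabricate activity (sigma2 = 0 must give none)
    tiny = 1e-12 * max(1.0, abs(ue))
    active = frozenset(int(i) + 1 for i in np.nonzero(ev - at > tiny)[0])
    return ActivityProfile(
        gene=gene, ev=ev, ue=ue, sigma2=sigma2, fl=fl, s1=s1, s2=s2, at=at, active=active
    )


@dataclass
class DynamicNetwork:
    """A time-ordered sequence of vertex-induced subnetworks of one parent."""

    subnetworks: list[PPINetwork]
    provenance: PPINetwork

    @property
    def T(self) -> int:
        return len(self.subnetworks)

    def __getitem__(self, t: int) -> PPINetwork:
        """Subnetwork at 1-based timestamp ``t``."""
        if not 1 <= t <= self.T:
            raise IndexError(f"timestamp {t} outside 1..{self.T}")
        return self.subnetworks[t - 1]


def build_dynamic_network(
    net: PPINetwork,
    expr: ExpressionMatrix,
    missing_policy: MissingPolicy = "drop",
) -> DynamicNetwork:
    """Split a static PPI network into per-timestamp subnetworks.

    A protein is in the subnetwork at t iff it is active at t; an edge
    survives iff both endpoints are co-active.  Proteins with no expression
    row are dropped everywhere (``drop``, the default) or kept in every
    subnetwork (``always_active``).
    """
    if missing_policy not in ("drop", "always_active"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    T = expr.T
    active_at: list[set[str]] = [set() for _ in range(T)]
    n_missing = 0
    for node in net.nodes:
        if node in expr:
            prof = activity_profile(expr, node)
            for t in prof.active:
                active_at[t - 1].add(node)
        else:
            n_missing += 1
            if missing_policy == "always_active":
                for t in range(T):
                    active_at[t].add(node)
    if n_missing:
        logger.info(
            "%d of %d proteins have no expression row (policy=%s)",
            n_missing, net.n_nodes, missing_policy,
        )
    subnets = []
    for t in range(T):
        sub = net.subgraph(active_at[t])
        if sub.n_nodes == 0:
            logger.info("subnetwork at timestamp %d is empty", t + 1)
        subnets.append(sub)
    return DynamicNetwork(subnetworks=subnets, provenance=net)


def dump_profiles(
    expr: ExpressionMatrix, path: str | Path, genes: list[str] | None = None
) -> None:
    """Write per-gene activity diagnostics as tab-delimited text."""
    genes = genes if genes is not None else expr.genes
    with open(path, "w") as fh:
        fh.write("gene\tue\tsigma2\tfl\tat\tactive_timestamps\n")
        for g in genes:
            p = activity_profile(expr, g)
            ts = ",".join(str(t) for t in sorted(p.active))
            fh.write(f"{g}\t{p.ue:.6g}\t{p.sigma2:.6g}\t{p.fl:.6g}\t{p.at:.6g}\t{ts}\n")
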