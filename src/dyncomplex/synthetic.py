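"""Planted-complex networks and matched expression matrices for testing.

The generator plants disjoint dense complexes (within-complex edge
probability ``p_in``) inside a sparse background (``p_out``), then builds an
expression matrix in which each complex's genes spike at that complex's
active timestamps while everything else sits at a noisy baseline.  The
expression generator verifies its own output against the three-sigma
activity rule and refuses to emit a fixture the downstream decomposition
could not see.

Under the three-sigma threshold AT = UE + 3*sigma*(1 - 1/(1+sigma^2)), a
square activity bump of amplitude ``bump`` spanning a fraction f of the T
timestamps is strictly exceeded only when f is small (roughly f < 0.1 for
large bumps — the bump's own variance inflates AT past the peak otherwise).
The default windows are therefore a single timestamp per complex, assigned
round-robin over 1..T: the regime of sharply peaked, periodically expressed
genes that activity thresholding is designed to pick up.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .dynamics import activity_profile
from .io import ComplexCatalog, ExpressionMatrix, PPINetwork


@dataclass
class PlantedTruth:
    """Ground truth of a planted fixture: complexes, activity windows, parameters."""

    complexes: list[frozenset[str]]
    active_window: dict[int, frozenset[int]] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "complexes": [sorted(c) for c in self.complexes],
                "active_window": {str(k): sorted(v) for k, v in self.active_window.items()},
                "params": self.params,
            },
            indent=2,
        )


def make_planted_network(
    n_complexes: int = 10,
    size_range: tuple[int, int] = (5, 10),
    p_in: float = 0.9,
    p_out: float = 0.02,
    n_background: int = 20,
    seed: int = 0,
) -> tuple[PPINetwork, PlantedTruth]:
    """Plant disjoint complexes in a sparse background network.

    Within-complex pairs are connected with probability ``p_in``, every other
    pair with ``p_out``; ``n_background`` proteins carry no complex
    membership.  Each complex's induced subgraph is resampled (up to 100
    times) until connected, so a planted complex is always recoverable in
    principle.  Pure function of ``seed``.
    """
    if not (0.0 <= p_out < p_in <= 1.0):
        raise ValueError("need 0 <= p_out < p_in <= 1")
    rng = np.random.default_rng(seed)
    lo, hi = size_range
    sizes = rng.integers(lo, hi + 1, size=n_complexes)
    complexes: list[frozenset[str]] = []
    counter = 0
    members_all: list[str] = []
    for k, s in enumerate(sizes):
        names = [f"P{counter + i:04d}" for i in range(int(s))]
        counter += int(s)
        complexes.append(frozenset(names))
        members_all.extend(names)
    background = [f"B{counter + i:04d}" for i in range(n_background)]
    nodes = members_all + background

    g = nx.Graph()
    g.add_nodes_from(nodes)
    # dense within-complex structure, resampled until connected
    for comp in complexes:
        comp_sorted = sorted(comp)
        for attempt in range(100):
            edges = [
                (u, v)
                for i, u in enumerate(comp_sorted)
                for v in comp_sorted[i + 1:]
                if rng.random() < p_in
            ]
            h = nx.Graph(edges)
            h.add_nodes_from(comp_sorted)
            if nx.is_connected(h):
                g.add_edges_from(edges, weight=1.0)
                break
        else:
            raise RuntimeError(
                f"complex of size {len(comp)} not connected after 100 resamples; "
                "increase p_in"
            )
    # sparse background noise among all non-within-complex pairs
    comp_of = {m: i for i, c in enumerate(complexes) for m in c}
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            if comp_of.get(u, -1) == comp_of.get(v, -2):
                continue
            if rng.random() < p_out:
                g.add_edge(u, v, weight=1.0)

    truth = PlantedTruth(
        complexes=complexes,
        params=dict(
            n_complexes=n_complexes,
            size_range=list(size_range),
            p_in=p_in,
            p_out=p_out,
            n_background=n_background,
            seed=seed,
        ),
    )
    return PPINetwork(g), truth


def make_expression(
    truth: PlantedTruth,
    T: int = 12,
    TR: int = 3,
    baseline: float = 5.0,
    bump: float = 10.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> ExpressionMatrix:
    """Expression matrix with one activity spike per complex, plus noise.

    Each complex is assigned a single active timestamp (round-robin over
    1..T unless ``truth.active_window`` is already set); its genes read
    ``baseline + bump`` there and ``baseline`` elsewhere, with i.i.d.
    Gaussian noise per repetition.  Background proteins are pure noisy
    baseline.  The generator then re-derives the three-sigma activity calls
    from its own output and raises unless at least 95% of the intended
    (gene, timestamp) activations are recovered — a fixture the activity
    rule cannot see is a bug, not a fixture.
    """
    if bump <= 0:
        raise ValueError("bump must be > 0")
    rng = np.random.default_rng(seed)
    if not truth.active_window:
        truth.active_window = {
            k: frozenset({(k % T) + 1}) for k in range(len(truth.complexes))
        }
    truth.params.update(dict(T=T, TR=TR, baseline=baseline, bump=bump, noise_sd=noise_sd))

    genes: list[str] = []
    window_of: dict[str, frozenset[int]] = {}
    for k, comp in enumerate(truth.complexes):
        for m in sorted(comp):
            genes.append(m)
            window_of[m] = truth.active_window[k]
    values = []
    for g in genes:
        signal = np.array(
            [baseline + (bump if t in window_of[g] else 0.0) for t in range(1, T + 1)]
        )
        row = np.concatenate(
            [signal + rng.normal(0.0, noise_sd, size=T) for _ in range(TR)]
        )
        values.append(row)
    expr = ExpressionMatrix(genes=genes, values=np.array(values), T=T, TR=TR)

    # self-check: the three-sigma rule must recover the planted activations
    intended = [(g, t) for g in genes for t in window_of[g]]
    hit = sum(1 for g, t in intended if t in activity_profile(expr, g).active)
    rate = hit / len(intended) if intended else 1.0
    if rate < 0.95:
        raise RuntimeError(
            f"fixture self-check failed: only {rate:.0%} of planted activations "
            "recovered by the three-sigma rule; raise bump or lower noise_sd"
        )
    truth.params["selfcheck_recovery"] = rate
    return expr


def add_background_expression(
    expr: ExpressionMatrix,
    background: Sequence[str],
    baseline: float = 5.0,
    noise_sd: float = 0.5,
    seed: int = 1,
) -> ExpressionMatrix:
    """Append pure noisy-baseline rows for background proteins."""
    rng = np.random.default_rng(seed)
    rows = [
        baseline + rng.normal(0.0, noise_sd, size=expr.T * expr.TR)
        for _ in background
    ]
    return ExpressionMatrix(
        genes=list(expr.genes) + list(background),
        values=np.vstack([expr.values] + [np.array(rows)]) if background else expr.values,
        T=expr.T,
        TR=expr.TR,
    )


def make_planted_fixture(
    n_complexes: int = 10,
    size_range: tuple[int, int] = (5, 10),
    p_in: float = 0.9,
    p_out: float = 0.02,
    n_background: int = 20,
    T: int = 12,
    TR: int = 3,
    baseline: float = 5.0,
    bump: float = 10.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[PPINetwork, ExpressionMatrix, ComplexCatalog, PlantedTruth]:
    """One-call fixture: network + expression (complexes and background) + gold."""
    net, truth = make_planted_network(
        n_complexes, size_range, p_in, p_out, n_background, seed
    )
    expr = make_expression(truth, T, TR, baseline, bump, noise_sd, seed=seed + 1)
    background = sorted(net.nodes - set(expr.genes))
    expr = add_background_expression(expr, background, baseline, noise_sd, seed=seed + 2)
    gold = ComplexCatalog(complexes=list(truth.complexes), name="planted")
    return net, expr, gold, truth


def make_toy_fixture() -> tuple[PPINetwork, ExpressionMatrix, ComplexCatalog]:
    """A fixed 12-protein instance with two planted complexes; no randomness.

    Complex A (5 proteins, a clique) is active at timestamp 1 and complex B
    (4 proteins, a clique) at timestamp 2; three background proteins have
    constant expression and are therefore never active.  Expression uses a
    unit bump over baseline 1 at T=4, TR=1 — small enough that the
    three-sigma threshold sits below the peak.
    """
    a = [f"A{i}" for i in range(1, 6)]
    b = [f"B{i}" for i in range(1, 5)]
    bg = ["X1", "X2", "X3"]
    edges: list[tuple[str, str]] = []
    edges += [(u, v) for i, u in enumerate(a) for v in a[i + 1:]]
    edges += [(u, v) for i, u in enumerate(b) for v in b[i + 1:]]
    edges += [("A1", "B1"), ("A2", "X1"), ("X1", "X2")]
    net = PPINetwork.from_edges(edges, nodes=a + b + bg)

    T, TR = 4, 1
    rows = {}
    for g in a:
        rows[g] = [2.0, 1.0, 1.0, 1.0]
    for g in b:
        rows[g] = [1.0, 2.0, 1.0, 1.0]
    for g in bg:
        rows[g] = [1.0, 1.0, 1.0, 1.0]
    genes = a + b + bg
    expr = ExpressionMatrix(
        genes=genes, values=np.array([rows[g] for g in genes]), T=T, TR=TR
    )
    gold = ComplexCatalog(complexes=[frozenset(a), frozenset(b)], name="toy")
    return net, expr, gold
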