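"""Elephant-herd search over MCL parameters, per subnetwork, and the full pipeline.

Each elephant is a point in MCL parameter space (by default just the
inflation constant ic in [1, 6]; optionally also balance b and penalty
proportion pp).  Elephants live in clans; every generation each clan

  * moves its non-best members toward the clan best,
        p_new = p + alpha * (p_best - p) * rand        (clan updating),
  * moves the best member to a scaled clan center,
        p_best_new = beta * p_center,
  * and replaces its worst member with a fresh random position,
        p_worst = p_min + (p_max - p_min + 1) * rand   (clan separating),

with every position clamped into bounds afterwards.  Fitness of a position
is the quality of the clustering that MCL produces at those parameters —
either the CSS-based accuracy against a gold standard (the reference
protocol) or a gold-free internal density/coverage score.  A best-so-far
archive decouples reporting from population state, since the best-elephant
move can be detrimental.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from math import sqrt
from typing import Literal, Sequence

import numpy as np

from .dynamics import build_dynamic_network
from .evaluation import evaluate
from .io import ComplexCatalog, ExpressionMatrix, PPINetwork
from .mcl import AttractorRecord, MCLParams, filter_min_size, run_mcl
from .seeds import Cluster, SeedParams, attach_previous, refine, select_seeds

logger = logging.getLogger(__name__)

FitnessMode = Literal["benchmark_accuracy", "internal_quality"]


@dataclass
class EHOConfig:
    """Search-strategy knobs for the elephant-herd optimizer.

    The paper-scale profile is 20 clans of 10 elephants for up to 500
    generations with a 100-generation stagnation stop; the desk profile
    (5 clans of 5, 50 generations, stagnation 10) keeps full runs tractable
    on a single CPU and is the default for tests and examples.
    """

    n_clans: int = 20
    K: int = 10
    max_gen: int = 500
    stagnation: int = 100
    alpha: float = 0.5
    beta: float = 0.1
    dims: int = 1
    p_min: tuple[float, ...] = (1.0,)
    p_max: tuple[float, ...] = (6.0,)
    fitness_mode: FitnessMode = "benchmark_accuracy"
    css_threshold: float = 0.2
    min_size: int = 3
    mcl_b: float = 0.5    # balance used when not searched (dims == 1)
    mcl_pp: float = 1.25  # penalty proportion used when not searched

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0 and 0.0 < self.beta <= 1.0):
            raise ValueError("alpha and beta must lie in (0, 1]")
        if self.dims not in (1, 3):
            raise ValueError("dims must be 1 (ic) or 3 (ic, b, pp)")
        if self.dims == 3 and len(self.p_min) == 1:
            self.p_min = (self.p_min[0], 0.0, 1.0)
            self.p_max = (self.p_max[0], 1.0, 2.0)
        if len(self.p_min) != self.dims or len(self.p_max) != self.dims:
            raise ValueError("bounds must match dims")
        if not all(lo < hi for lo, hi in zip(self.p_min, self.p_max)):
            raise ValueError("p_min must be elementwise below p_max")
        if self.K < 2:
            raise ValueError("K must be >= 2")

    @classmethod
    def desk(cls, **overrides) -> "EHOConfig":
        base = dict(n_clans=5, K=5, max_gen=50, stagnation=10)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def paper(cls, **overrides) -> "EHOConfig":
        base = dict(n_clans=20, K=10, max_gen=500, stagnation=100)
        base.update(overrides)
        return cls(**base)


@dataclass
class Elephant:
    position: np.ndarray
    fitness: float | None = None


@dataclass
class Clan:
    elephants: list[Elephant]

    @property
    def best(self) -> int:
        fits = [e.fitness if e.fitness is not None else -np.inf for e in self.elephants]
        return int(np.argmax(fits))

    @property
    def worst(self) -> int:
        fits = [e.fitness if e.fitness is not None else np.inf for e in self.elephants]
        return int(np.argmin(fits))

    @property
    def center(self) -> np.ndarray:
        return np.mean([e.position for e in self.elephants], axis=0)


@dataclass
class BestArchive:
    """Best-so-far clustering; fitness is non-decreasing by construction."""

    clustering: list[frozenset[str]] = field(default_factory=list)
    fitness: float = -np.inf
    generation: int = 0

    def offer(self, clustering: list[frozenset[str]], fitness: float, generation: int) -> bool:
        if fitness > self.fitness:
            self.clustering = list(clustering)
            self.fitness = fitness
            self.generation = generation
            return True
        return False


def decode_position(position: np.ndarray, cfg: EHOConfig) -> MCLParams:
    """Map an elephant position to MCL parameters.

    Dimension 0 is ic (clamped into [lic, hic]); dimensions 1 and 2, when
    searched, are b in [0, 1] and pp in [1, 2]; otherwise b and pp take
    their standard defaults.
    """
    base = MCLParams()
    ic = float(np.clip(position[0], base.lic, base.hic))
    if cfg.dims == 3:
        b = float(np.clip(position[1], 0.0, 1.0))
        pp = float(np.clip(position[2], 1.0, 2.0))
        return replace(base, ic=ic, b=b, pp=pp)
    return replace(base, ic=ic, b=cfg.mcl_b, pp=cfg.mcl_pp)


def fitness(
    clusters: Sequence[frozenset[str]],
    subnet: PPINetwork,
    gold: ComplexCatalog | None,
    mode: FitnessMode,
    css_threshold: float = 0.2,
) -> float:
    """Score a clustering of one subnetwork.

    ``benchmark_accuracy`` is the geometric-mean accuracy against the gold
    standard at the CSS threshold; ``internal_quality`` is the size-weighted
    mean cluster density times the clustered fraction of subnetwork nodes —
    a gold-free proxy usable for de-novo discovery.
    """
    if not clusters:
        return 0.0
    if mode == "benchmark_accuracy":
        if gold is None:
            raise ValueError("benchmark_accuracy fitness requires a gold catalog")
        return evaluate(list(clusters), gold, css_threshold).accuracy
    if mode == "internal_quality":
        if subnet.n_nodes == 0:
            return 0.0
        tot = 0.0
        size = 0
        for c in clusters:
            cl = Cluster.from_members(c, subnet, 0)
            tot += cl.density * cl.n
            size += cl.n
        if size == 0:
            return 0.0
        clustered_frac = len(set().union(*clusters)) / subnet.n_nodes
        return (tot / size) * clustered_frac
    raise ValueError(f"unknown fitness mode {mode!r}")


def clan_update(clan: Clan, cfg: EHOConfig, rng: np.random.Generator) -> Clan:
    """Move non-best elephants toward the clan best; best toward beta * center.

    One uniform draw per elephant per dimension; the center is computed from
    pre-update positions; everything is clamped into bounds.
    """
    lo = np.asarray(cfg.p_min)
    hi = np.asarray(cfg.p_max)
    best = clan.best
    center = clan.center
    p_best = clan.elephants[best].position.copy()
    new = []
    for i, e in enumerate(clan.elephants):
        if i == best:
            pos = cfg.beta * center
        else:
            r = rng.uniform(0.0, 1.0, size=cfg.dims)
            pos = e.position + cfg.alpha * (p_best - e.position) * r
        new.append(Elephant(position=np.clip(pos, lo, hi), fitness=e.fitness))
    return Clan(elephants=new)


def clan_separate(clan: Clan, cfg: EHOConfig, rng: np.random.Generator) -> Clan:
    """Replace the worst elephant with p_min + (p_max - p_min + 1) * rand, clamped."""
    lo = np.asarray(cfg.p_min)
    hi = np.asarray(cfg.p_max)
    worst = clan.worst
    r = rng.uniform(0.0, 1.0, size=cfg.dims)
    pos = np.clip(lo + (hi - lo + 1.0) * r, lo, hi)
    new = [
        Elephant(position=pos.copy(), fitness=None) if i == worst
        else Elephant(position=e.position.copy(), fitness=e.fitness)
        for i, e in enumerate(clan.elephants)
    ]
    return Clan(elephants=new)


def _init_clans(cfg: EHOConfig, rng: np.random.Generator) -> list[Clan]:
    lo = np.asarray(cfg.p_min)
    hi = np.asarray(cfg.p_max)
    return [
        Clan(
            elephants=[
                Elephant(position=rng.uniform(lo, hi, size=cfg.dims))
                for _ in range(cfg.K)
            ]
        )
        for _ in range(cfg.n_clans)
    ]


def optimize_subnetwork(
    subnet: PPINetwork,
    warm_start: Sequence[Cluster],
    gold: ComplexCatalog | None,
    cfg: EHOConfig,
    rng: np.random.Generator,
) -> tuple[list[frozenset[str]], BestArchive]:
    """EHO search over MCL parameters for one subnetwork.

    Generation 1 scores the warm-start clustering and seeds the archive;
    every later generation evaluates each elephant (decode -> MCL ->
    minimum-size filter -> fitness), updates the archive on strict
    improvement, then applies clan updating and clan separating.  Stops at
    max_gen or after ``stagnation`` generations without archive improvement.
    """
    archive = BestArchive()
    if subnet.n_nodes == 0:
        archive.offer([], 0.0, 0)
        return [], archive

    warm = [c.members for c in warm_start if c.members]
    warm_kept, _ = filter_min_size(list(warm), cfg.min_size)
    archive.offer(warm_kept, fitness(warm_kept, subnet, gold, cfg.fitness_mode, cfg.css_threshold), 1)

    rec = AttractorRecord()
    clans = _init_clans(cfg, rng)
    since_improved = 0
    for gen in range(2, cfg.max_gen + 1):
        improved = False
        for clan in clans:
            for e in clan.elephants:
                if e.fitness is None:
                    params = decode_position(e.position, cfg)
                    clusters = run_mcl(subnet, params, rec)
                    kept, _ = filter_min_size(clusters, cfg.min_size)
                    e.fitness = fitness(kept, subnet, gold, cfg.fitness_mode, cfg.css_threshold)
                    if archive.offer(kept, e.fitness, gen):
                        improved = True
        clans = [clan_separate(clan_update(c, cfg, rng), cfg, rng) for c in clans]
        for clan in clans:  # moved elephants must be rescored next generation
            for e in clan.elephants:
                e.fitness = None
        since_improved = 0 if improved else since_improved + 1
        if since_improved >= cfg.stagnation:
            logger.info("stagnation stop at generation %d", gen)
            break
    return archive.clustering, archive


@dataclass
class DetectionResult:
    """Per-timestamp clusterings, archives and the merged prediction set."""

    per_timestamp: list[list[frozenset[str]]]
    archives: list[BestArchive]
    merged: list[frozenset[str]]
    subnet_sizes: list[tuple[int, int]]  # (n_nodes, n_edges) per timestamp


def detect_dynamic_complexes(
    net: PPINetwork,
    expr: ExpressionMatrix,
    gold: ComplexCatalog | None,
    cfg: EHOConfig,
    seed_params: SeedParams,
    seed: int = 0,
    missing_policy: str = "drop",
) -> DetectionResult:
    """Full pipeline: decompose, warm-start, optimize each timestamp, merge.

    Seeds and final clusters at timestamp t-1 warm-start timestamp t
    (persisting seeds inherit the surviving members of their previous
    cluster).  The merged prediction is the union over timestamps with
    exact-duplicate member sets removed.  Fully reproducible given ``seed``.
    """
    rng = np.random.default_rng(seed)
    dyn = build_dynamic_network(net, expr, missing_policy)
    prev_seed_clusters: dict[str, frozenset[str]] = {}
    per_timestamp: list[list[frozenset[str]]] = []
    archives: list[BestArchive] = []
    sizes: list[tuple[int, int]] = []
    for t in range(1, dyn.T + 1):
        subnet = dyn[t]
        sizes.append((subnet.n_nodes, subnet.n_edges))
        seeds_t = select_seeds(subnet, seed_params)
        initial = attach_previous(seeds_t, prev_seed_clusters, subnet)
        initial = [refine(c, subnet, seed_params) for c in initial]
        clusters, archive = optimize_subnetwork(subnet, initial, gold, cfg, rng)
        per_timestamp.append(clusters)
        archives.append(archive)
        prev_seed_clusters = {
            s: next((c for c in clusters if s in c), frozenset({s}))
            for s in seeds_t
        }
    merged: list[frozenset[str]] = []
    seen: set[frozenset[str]] = set()
    for clustering in per_timestamp:
        for c in clustering:
            if c not in seen:
                seen.add(c)
                merged.append(c)
    if not merged:
        logger.warning("empty prediction set (no active subnetwork content)")
    return DetectionResult(
        per_timestamp=per_timestamp, archives=archives, merged=merged, subnet_sizes=sizes
    )
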