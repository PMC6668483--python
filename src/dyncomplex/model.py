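"""Model/Results interface over the detection pipeline.

``DynamicComplexModel`` holds the data (static PPI network, expression
matrix, optional gold standard) and the configuration; ``fit`` runs the
decomposition + warm-start + EHO-tuned MCL pipeline and returns a
``ComplexDetectionResults`` carrying the per-timestamp clusterings, the
best-so-far archives, the merged prediction set and a ``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

from .dynamics import dump_profiles
from .eho import DetectionResult, EHOConfig, detect_dynamic_complexes
from .evaluation import EvaluationReport, evaluate
from .io import (
    ComplexCatalog,
    ExpressionMatrix,
    PPINetwork,
    read_complexes,
    read_expression,
    read_ppi,
    write_clusters,
)
from .seeds import SeedParams


class DynamicComplexModel:
    """Protein-complex detection model over a dynamic PPI network.

    Parameters
    ----------
    network
        Static PPI network.
    expression
        Expression matrix used to derive per-timestamp activity.
    gold
        Gold-standard catalog; required for the default benchmark-accuracy
        fitness, optional under internal-quality fitness.
    seed_params
        Thresholds for warm-start seed selection and refinement.
    config
        EHO search configuration; defaults to the desk profile.
    missing_policy
        How proteins absent from the expression matrix are handled
        ("drop" or "always_active").

    Examples
    --------
    >>> from dyncomplex import synthetic
    >>> net, expr, gold = synthetic.make_toy_fixture()
    >>> res = DynamicComplexModel(net, expr, gold).fit(seed=0)
    >>> sorted(len(c) for c in res.complexes)
    [4, 5]
    """

    def __init__(
        self,
        network: PPINetwork,
        expression: ExpressionMatrix,
        gold: ComplexCatalog | None = None,
        seed_params: SeedParams | None = None,
        config: EHOConfig | None = None,
        missing_policy: str = "drop",
    ):
        self.network = network
        self.expression = expression
        self.gold = gold
        self.seed_params = seed_params or SeedParams()
        self.config = config or EHOConfig.desk()
        self.missing_policy = missing_policy
        if self.config.fitness_mode == "benchmark_accuracy" and gold is None:
            raise ValueError(
                "benchmark_accuracy fitness requires a gold catalog; "
                "pass gold= or use fitness_mode='internal_quality'"
            )

    @classmethod
    def from_files(
        cls,
        ppi_path: str | Path,
        expr_path: str | Path,
        T: int,
        TR: int,
        gold_path: str | Path | None = None,
        **kwargs,
    ) -> "DynamicComplexModel":
        net = read_ppi(ppi_path)
        expr = read_expression(expr_path, T, TR)
        gold = read_complexes(gold_path) if gold_path else None
        return cls(net, expr, gold, **kwargs)

    def fit(self, seed: int = 0, profile: str | None = None) -> "ComplexDetectionResults":
        """Run the full detection pipeline; reproducible given ``seed``."""
        cfg = self.config
        if profile == "desk":
            cfg = EHOConfig.desk(fitness_mode=cfg.fitness_mode,
                                 css_threshold=cfg.css_threshold,
                                 min_size=cfg.min_size, dims=cfg.dims)
        elif profile == "paper":
            cfg = EHOConfig.paper(fitness_mode=cfg.fitness_mode,
                                  css_threshold=cfg.css_threshold,
                                  min_size=cfg.min_size, dims=cfg.dims)
        elif profile is not None:
            raise ValueError(f"unknown profile {profile!r}")
        result = detect_dynamic_complexes(
            self.network,
            self.expression,
            self.gold,
            cfg,
            self.seed_params,
            seed=seed,
            missing_policy=self.missing_policy,
        )
        return ComplexDetectionResults(self, result, cfg, seed)


class ComplexDetectionResults:
    """Fitted results: predicted complexes, archives, diagnostics."""

    def __init__(
        self,
        model: DynamicComplexModel,
        result: DetectionResult,
        config: EHOConfig,
        seed: int,
    ):
        self.model = model
        self._result = result
        self.config = config
        self.seed = seed

    @property
    def complexes(self) -> list[frozenset[str]]:
        """Merged prediction set (exact duplicates across timestamps removed)."""
        return self._result.merged

    @property
    def per_timestamp(self) -> list[list[frozenset[str]]]:
        return self._result.per_timestamp

    @property
    def archives(self):
        return self._result.archives

    @property
    def subnet_sizes(self) -> list[tuple[int, int]]:
        return self._result.subnet_sizes

    def evaluate(
        self, gold: ComplexCatalog | None = None, threshold: float | None = None
    ) -> EvaluationReport:
        gold = gold or self.model.gold
        if gold is None:
            raise ValueError("no gold catalog available for evaluation")
        thr = threshold if threshold is not None else self.config.css_threshold
        return evaluate(self.complexes, gold, thr)

    def summary(self) -> str:
        """Human-readable fit summary: per-timestamp table + merged metrics."""
        lines = [
            "Dynamic protein-complex detection results",
            "=" * 57,
            f"network: {self.model.network.n_nodes} proteins, "
            f"{self.model.network.n_edges} interactions",
            f"timestamps: {self.model.expression.T}  repetitions: {self.model.expression.TR}",
            f"fitness mode: {self.config.fitness_mode}   seed: {self.seed}",
            "-" * 57,
            f"{'t':>3} {'nodes':>6} {'edges':>6} {'clusters':>9} {'best fitness':>13}",
        ]
        for t, ((nn, ne), clustering, arch) in enumerate(
            zip(self.subnet_sizes, self.per_timestamp, self.archives), start=1
        ):
            fit = arch.fitness if arch.fitness != -float("inf") else 0.0
            lines.append(f"{t:>3} {nn:>6} {ne:>6} {len(clustering):>9} {fit:>13.4f}")
        lines.append("-" * 57)
        lines.append(f"merged predicted complexes: {len(self.complexes)}")
        if self.model.gold is not None:
            rep = self.evaluate()
            lines.append(
                f"precision {rep.precision:.4f}  recall {rep.recall:.4f}  "
                f"f_measure {rep.f_measure:.4f}"
            )
            lines.append(
                f"accuracy {rep.accuracy:.4f}  coverage_ratio {rep.coverage_ratio:.4f}"
            )
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> list[Path]:
        """Write per-timestamp and merged complex files, diagnostics, metadata."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for t, clustering in enumerate(self.per_timestamp, start=1):
            p = outdir / f"complexes_t{t:02d}.txt"
            write_clusters(clustering, p, header=f"timestamp {t} seed {self.seed}")
            written.append(p)
        merged_path = outdir / "complexes_merged.txt"
        write_clusters(self.complexes, merged_path, header=f"merged seed {self.seed}")
        written.append(merged_path)
        prof_path = outdir / "activity_profiles.tsv"
        dump_profiles(self.model.expression, prof_path)
        written.append(prof_path)
        from . import __version__ as pkg_version

        meta = {
            "package_version": pkg_version,
            "seed": self.seed,
            "config": asdict(self.config),
            "seed_params": asdict(self.model.seed_params),
            "missing_policy": self.model.missing_policy,
            "n_merged_complexes": len(self.complexes),
        }
        meta_path = outdir / "run_metadata.json"
        meta_path.write_text(json.dumps(meta, indent=2))
        written.append(meta_path)
        return written
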