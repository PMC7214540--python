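"""End-to-end orchestration: ingest → extract → normalize → prune → MRMD →
PCA → evaluate, with per-stage seeding, logging, and artifact output.

One master seed is expanded into independent per-stage seeds (subsampling,
synthetic generation, selection folds, evaluation folds) via
``numpy.random.SeedSequence.spawn``, so each stage is individually
reproducible and the whole run is deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import sequence_io
from .alphabet import builtin_scheme
from .evaluation import MODEL_NAMES, EvalReport, crossval
from .features import DEFAULT_FAMILIES, extract_features
from .matrix import FeatureMatrix
from .reduction import (
    PCAModel,
    PruneResult,
    SelectionResult,
    correlation_prune,
    mrmd_rank,
    mrmd_select,
    normalize,
    pca_fit,
    pca_transform,
)
from .synthetic import GeneratorSpec, generate

logger = logging.getLogger(__name__)

#: Stage names in execution order (used for error reporting and exit codes).
STAGES = ("ingest", "extract", "normalize", "prune", "mrmd", "pca", "evaluate")


class StageError(RuntimeError):
    """A pipeline stage failed; partial artifacts are preserved on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything needed to replay a run bit-identically.

    Input is either a synthetic :class:`GeneratorSpec` or FASTA paths (one
    file per class, or one FASTA plus a TSV label file).
    """

    generator: Optional[GeneratorSpec] = None
    positive_fasta: Optional[str] = None
    negative_fasta: Optional[str] = None
    fasta: Optional[str] = None
    labels: Optional[str] = None

    scheme: str = "susko19"
    max_gap: int = 2
    families: tuple[str, ...] = DEFAULT_FAMILIES
    original_dipeptides: bool = False

    corr_threshold: float = 0.85
    strict_prune: bool = False
    mrmd_patience: Optional[int] = 50  # None = full sweep over every k
    t_prime: float = 0.95
    k_override: Optional[int] = None

    models: tuple[str, ...] = ("svm",)
    folds: int = 10
    n_per_class: Optional[int] = None
    seed: int = 0
    save_feature_matrix: bool = True

    def __post_init__(self) -> None:
        if not self.families:
            raise ValueError("at least one feature family must be enabled")
        if not (0.0 < self.corr_threshold <= 1.0):
            raise ValueError("corr_threshold must be in (0, 1]")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        unknown = set(self.models) - set(MODEL_NAMES)
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.generator is not None:
            g = d["generator"]
            g["base_composition"] = list(map(float, g["base_composition"]))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("generator"):
            g = dict(d["generator"])
            if "base_composition" in g:
                g["base_composition"] = np.asarray(g["base_composition"], float)
            if "length_range" in g:
                g["length_range"] = tuple(g["length_range"])
            d["generator"] = GeneratorSpec(**g)
        for key in ("families", "models"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


@dataclass
class PipelineResult:
    """In-memory view of a completed run (everything is also on disk)."""

    config: PipelineConfig
    stage_dims: dict[str, int]
    prune: PruneResult
    ranking: list
    selection: SelectionResult
    pca: PCAModel
    reports: dict[str, EvalReport]
    run_dir: Path


def _stage_seeds(master: int) -> dict[str, int]:
    children = np.random.SeedSequence(master).spawn(4)
    names = ("subsample", "generate", "selection_folds", "eval_folds")
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, children)
    }


def _ingest(config: PipelineConfig, seeds: dict[str, int]) -> sequence_io.LabeledDataset:
    if config.generator is not None:
        spec = dataclasses.replace(config.generator, seed=seeds["generate"])
        dataset = generate(spec)
    elif config.positive_fasta and config.negative_fasta:
        records = sequence_io.read_fasta(config.positive_fasta, label=1)
        records += sequence_io.read_fasta(config.negative_fasta, label=0)
        dataset = sequence_io.LabeledDataset(records)
    elif config.fasta and config.labels:
        records = sequence_io.read_fasta(config.fasta)
        dataset = sequence_io.apply_labels(records, sequence_io.read_labels(config.labels))
    else:
        raise ValueError(
            "config must provide a generator spec, two per-class FASTA paths, "
            "or one FASTA plus a label TSV"
        )
    if config.n_per_class is not None:
        dataset = sequence_io.sample_balanced(
            dataset, config.n_per_class, seeds["subsample"]
        )
    return dataset


def run(config: PipelineConfig, out_dir: str | Path) -> PipelineResult:
    """Execute the full pipeline, writing all artifacts under ``out_dir``.

    Artifacts: ``manifest.json`` (config, per-stage dimensions, derived
    seeds — enough to replay the run), the assembled feature matrix
    (optional CSV), the prune report, the MRMD trace, the PCA model, and one
    evaluation report per model. Any stage failure raises
    :class:`StageError` naming the stage; artifacts from completed stages
    remain on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    dims: dict[str, int] = {}
    stage = "ingest"
    try:
        dataset = _ingest(config, seeds)
        logger.info(
            "ingest: %d records (%d positive / %d negative)",
            len(dataset), dataset.positive_count, dataset.negative_count,
        )

        stage = "extract"
        fm = extract_features(
            dataset,
            scheme=config.scheme,
            max_gap=config.max_gap,
            families=config.families,
            original_dipeptides=config.original_dipeptides,
        )
        dims["extract"] = fm.n_features
        logger.info("extract: %d x %d feature matrix", fm.n_samples, fm.n_features)
        if config.save_feature_matrix:
            fm.to_csv(out / "features.csv")

        stage = "normalize"
        fm = normalize(fm)
        dims["normalize"] = fm.n_features

        stage = "prune"
        prune = correlation_prune(fm, config.corr_threshold, config.strict_prune)
        fm = fm.drop_features(prune.removed)
        dims["prune"] = fm.n_features
        logger.info(
            "prune: removed %d, reserved %d, kept %d columns",
            len(prune.removed), len(prune.reserved), fm.n_features,
        )
        _write_prune_csv(prune, out / "prune.csv")

        stage = "mrmd"
        ranking = mrmd_rank(fm)
        selection = mrmd_select(
            ranking, fm,
            model=config.models[0],
            folds=config.folds,
            seed=seeds["selection_folds"],
            patience=config.mrmd_patience,
        )
        fm = fm.select_features(selection.feature_names)
        dims["mrmd"] = fm.n_features
        logger.info(
            "mrmd: selected top %d features (trace ACC max %.2f%%)",
            selection.k, max(acc for _, acc in selection.trace),
        )
        _write_mrmd_csv(ranking, selection, out / "mrmd.csv")

        stage = "pca"
        pca = pca_fit(fm, t_prime=config.t_prime, k_override=config.k_override)
        components = pca_transform(pca, fm)
        dims["pca"] = pca.k
        logger.info(
            "pca: %d components (cumulative contribution %.4f)",
            pca.k, pca.cumulative_contribution,
        )
        _write_pca_json(pca, out / "pca_model.json")

        stage = "evaluate"
        reports: dict[str, EvalReport] = {}
        for model in config.models:
            report = crossval(
                components, dataset.labels,
                model=model, folds=config.folds, seed=seeds["eval_folds"],
            )
            reports[model] = report
            report.to_json(out / f"eval_{model}.json")
            logger.info("evaluate: %s", report.summary())
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    manifest = {
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "stage_dims": dims,
        "n_samples": len(dataset),
        "selected_features": selection.feature_names,
        "metrics": {name: {"sn": r.sn, "sp": r.sp, "acc": r.acc, "auc": r.roc.area}
                    for name, r in reports.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return PipelineResult(config, dims, prune, ranking, selection, pca, reports, out)


def _write_prune_csv(prune: PruneResult, path: Path) -> None:
    lines = ["feature,status,partner,rho"]
    status = {n: "removed" for n in prune.removed}
    status.update({n: "reserved" for n in prune.reserved})
    first_partner: dict[str, tuple[str, float]] = {}
    for x, y, rho in prune.driving_pairs:
        first_partner.setdefault(x, (y, rho))
        first_partner.setdefault(y, (x, rho))
    for name in sorted(status):
        partner, rho = first_partner[name]
        lines.append(f"{name},{status[name]},{partner},{rho:.6f}")
    path.write_text("\n".join(lines) + "\n")


def _write_mrmd_csv(ranking, selection: SelectionResult, path: Path) -> None:
    lines = ["feature,relevance,distance,total,rank,selected"]
    chosen = set(selection.feature_names)
    for rank, score in enumerate(ranking, start=1):
        lines.append(
            f"{score.name},{score.relevance:.6f},{score.distance:.6f},"
            f"{score.total:.6f},{rank},{int(score.name in chosen)}"
        )
    lines.append("")
    lines.append("k,cv_accuracy")
    for k, acc in selection.trace:
        lines.append(f"{k},{acc:.4f}")
    path.write_text("\n".join(lines) + "\n")


def _write_pca_json(pca: PCAModel, path: Path) -> None:
    path.write_text(json.dumps({
        "k": pca.k,
        "t_prime": pca.t_prime,
        "cumulative_contribution": pca.cumulative_contribution,
        "mean": pca.mean.tolist(),
        "eigenvalues": pca.eigenvalues.tolist(),
        "components": pca.components.tolist(),
    }))


# ---------------------------------------------------------------------------
# Feature reporting


@dataclass
class FeatureReport:
    """Ranked retained features and a family/dipeptide view of removals."""

    top_features: list[dict]
    removed_by_family: dict[str, int]
    collapsed_dipeptides: dict[str, int]
    multiplicity: int

    def to_text(self) -> str:
        lines = ["Top retained features (by MRMD total):"]
        for row in self.top_features:
            lines.append(
                f"  {row['rank']:>3}  {row['feature']:<30} "
                f"MR={row['relevance']:.4f} MD={row['distance']:.4f}"
            )
        lines.append("Removed features by family:")
        for family, count in sorted(self.removed_by_family.items()):
            lines.append(f"  {family}: {count}")
        lines.append(
            f"Removed dipeptide pairs collapsed over gaps "
            f"(multiplicity >= {self.multiplicity}):"
        )
        for pair, count in sorted(self.collapsed_dipeptides.items()):
            lines.append(f"  {pair}: {count}")
        return "\n".join(lines)


def report_features(
    prune: PruneResult,
    ranking: Sequence,
    selection: SelectionResult,
    top_n: int = 10,
    multiplicity: int = 2,
) -> FeatureReport:
    """Summarize a completed run's retained and removed features.

    The top-n retained features are listed by MRMD total; removed features
    are grouped by family, and removed dipeptides are additionally collapsed
    over gaps (``RD|0|N|V``, ``RD|1|N|V`` and ``RD|2|N|V`` all count toward
    the pair NV), reporting pairs that appear at least ``multiplicity``
    times.
    """
    retained = [s for s in ranking if s.name in set(selection.feature_names)]
    if top_n > len(retained):
        logger.warning(
            "requested top %d but only %d retained features", top_n, len(retained)
        )
    top = [
        {
            "rank": i + 1,
            "feature": s.name,
            "relevance": s.relevance,
            "distance": s.distance,
            "total": s.total,
        }
        for i, s in enumerate(retained[:top_n])
    ]

    by_family: dict[str, int] = {}
    pair_counts: dict[str, int] = {}
    for name in prune.removed:
        if name.startswith("RD|"):
            family = "dipeptide"
            _, _lam, a, b = name.split("|")
            pair_counts[a + b] = pair_counts.get(a + b, 0) + 1
        elif name.startswith(("AC|", "CC|")):
            family = "acc"
        else:
            family = "physchem188"
        by_family[family] = by_family.get(family, 0) + 1

    collapsed = {p: c for p, c in pair_counts.items() if c >= multiplicity}
    return FeatureReport(top, by_family, collapsed, multiplicity)
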