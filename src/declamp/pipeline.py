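"""End-to-end pipeline: alignments + annotation → ranked DE gene scores.

Stage order: parse annotation → per-sample depth vectors and GC statistics →
per-transcript Poisson clamping → gene × sample count matrix from the clamped
totals → between-sample size-factor scaling → low-expression filter →
attribute extraction → naive Bayes scoring against a labeled training table →
ranked output.  Every stage writes its result as TSV/JSON so a run is
inspectable and restartable from intermediates; no stage uses randomness, so
reruns on identical inputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classifier, features, globalnorm, localnorm, readcount
from .annotation import GeneModel, parse_annotation
from .globalnorm import CountMatrix
from .readcount import GCStats

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one differential-expression run."""

    sam_by_condition: dict[str, list[str]]  # condition → SAM paths
    annotation: str
    outdir: str
    upper_p: float = 0.975
    lower_p: float = 0.025
    local_norm: bool = True
    global_norm: str = "deseq"              # or "tmm"
    min_mean: float = 5.0
    pseudocount: float = 1.0
    arpk_mode: str = "clamp"
    attributes: tuple[str, ...] = features.FEATURE_COLUMNS
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if len(self.sam_by_condition) != 2:
            raise ValueError("exactly two conditions required")
        for cond, paths in self.sam_by_condition.items():
            if not paths:
                raise ValueError(f"condition {cond} has no samples")

    def validate_paths(self) -> None:
        for paths in self.sam_by_condition.values():
            for p in paths:
                if not os.path.exists(p):
                    raise FileNotFoundError(p)
        if not os.path.exists(self.annotation):
            raise FileNotFoundError(self.annotation)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "attributes" in raw:
            raw["attributes"] = tuple(raw["attributes"])
        return cls(**raw)


@dataclass
class CountStage:
    """Output of SAM ingestion: depth vectors per sample plus GC stats."""

    models: dict[str, GeneModel]
    vectors: dict[str, dict[str, readcount.DepthVector]]  # sample → gene
    conditions: dict[str, str]
    gc: GCStats
    tallies: dict[str, readcount.ReadTally] = field(default_factory=dict)


def _stage(name: str):
    """Decorator naming the failing stage in pipeline errors."""
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") \
                    from exc
        wrapper.__name__ = fn.__name__
        wrapper.__doc__ = fn.__doc__
        return wrapper
    return deco


@_stage("count")
def count_stage(cfg: RunConfig) -> CountStage:
    """Parse the annotation and ingest every SAM into depth vectors."""
    models = parse_annotation(cfg.annotation)
    index = readcount.GeneIndex(models)
    vectors: dict[str, dict[str, readcount.DepthVector]] = {}
    conditions: dict[str, str] = {}
    gc = GCStats()
    tallies: dict[str, readcount.ReadTally] = {}
    for cond, paths in cfg.sam_by_condition.items():
        for p in paths:
            sample = os.path.splitext(os.path.basename(p))[0]
            if sample in vectors:
                sample = f"{cond}:{sample}"
            vecs, sample_gc, tally = readcount.build_depth_vectors(
                p, models, sample, index=index)
            vectors[sample] = vecs
            conditions[sample] = cond
            gc.merge(sample_gc)
            tallies[sample] = tally
    return CountStage(models=models, vectors=vectors, conditions=conditions,
                      gc=gc, tallies=tallies)


@_stage("localnorm")
def localnorm_stage(
    stage: CountStage,
    upper_p: float = 0.975,
    lower_p: float = 0.025,
    enabled: bool = True,
) -> tuple[CountMatrix, list[localnorm.LocalNormResult]]:
    """Clamp every gene in every sample; build the gene × sample matrix.

    With ``enabled=False`` the clamping is bypassed and raw read totals R are
    used, which reproduces the with/without comparisons.
    """
    results: list[localnorm.LocalNormResult] = []
    data: dict[str, dict[str, float]] = {}
    for sample, vecs in stage.vectors.items():
        col: dict[str, float] = {}
        for gid, dv in vecs.items():
            if enabled:
                res = localnorm.local_normalize(dv, upper_p, lower_p)
                results.append(res)
                col[gid] = res.R0
            else:
                col[gid] = dv.R
        data[sample] = col
    counts = pd.DataFrame(data, dtype=float)
    counts = counts.loc[list(stage.models.keys()),
                        list(stage.vectors.keys())]
    return CountMatrix(counts, dict(stage.conditions)), results


@_stage("globalnorm")
def globalnorm_stage(cm: CountMatrix, method: str = "deseq",
                     min_mean: float = 5.0
                     ) -> tuple[CountMatrix, pd.Series]:
    factors = globalnorm.size_factors(cm, method=method)
    normalized = globalnorm.normalize_counts(cm, factors)
    filtered = globalnorm.filter_low_expression(normalized, min_mean)
    return filtered, factors


def run_pipeline(cfg: RunConfig, training_table: pd.DataFrame) -> dict:
    """Execute the full pipeline and write every intermediate to ``outdir``.

    Returns a dict with the ranked score table (``ranked``), the feature
    table, size factors, clamping summaries and run report.  ``training_table``
    must carry the attribute columns and DE/NDE labels.
    """
    cfg.validate_paths()
    os.makedirs(cfg.outdir, exist_ok=True)
    out = os.path.join

    stage = count_stage(cfg)
    cm_raw, ln_results = localnorm_stage(
        stage, cfg.upper_p, cfg.lower_p, enabled=cfg.local_norm)
    globalnorm.counts_to_tsv(cm_raw, out(cfg.outdir, "counts.tsv"))
    if ln_results:
        localnorm.results_to_tsv(ln_results,
                                 out(cfg.outdir, "localnorm_summary.tsv"))

    cm_norm, factors = globalnorm_stage(cm_raw, cfg.global_norm, cfg.min_mean)
    factors.to_csv(out(cfg.outdir, "size_factors.tsv"), sep="\t",
                   index_label="sample")
    globalnorm.counts_to_tsv(cm_norm, out(cfg.outdir, "counts_normalized.tsv"))

    table = features.build_feature_table(
        cm_norm, stage.models, stage.gc,
        pseudocount=cfg.pseudocount, arpk_mode=cfg.arpk_mode)
    features.feature_table_to_tsv(table, out(cfg.outdir, "features.tsv"))

    labeled = training_table[
        training_table["label"].isin([features.LABEL_DE, features.LABEL_NDE])]
    model = classifier.nb_train(labeled, attributes=cfg.attributes)
    model.to_json(out(cfg.outdir, "nb_model.json"))
    scores = pd.Series(classifier.nb_score(model, table), index=table.index,
                       name="score")
    ranked = classifier.rank_genes(scores)
    ranked.to_csv(out(cfg.outdir, "scores.tsv"), sep="\t")

    report = {
        "config": {k: v for k, v in dataclasses.asdict(cfg).items()},
        "read_tallies": {s: t.as_dict() for s, t in stage.tallies.items()},
        "size_factors": {s: float(f) for s, f in factors.items()},
        "n_genes_annotated": len(stage.models),
        "n_genes_scored": len(ranked),
        "global_mean_gc": stage.gc.global_mean,
    }
    if ln_results:
        prof = localnorm.discarded_fraction_profile(ln_results)
        report["discarded_reads"] = {
            "mean_fraction": prof["mean_fraction"],
            "fraction_exceeding_10pct": prof["fraction_exceeding"],
        }
    with open(out(cfg.outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=str)

    return {"ranked": ranked, "features": table, "size_factors": factors,
            "localnorm_results": ln_results, "report": report,
            "count_stage": stage}


def report_with_without_localnorm(
    cfg: RunConfig, genes: list[str] | None = None
) -> pd.DataFrame:
    """Per-gene log2 fold change with and without the depth clamping.

    The SAMs are ingested once; the count matrix is then built twice —
    clamped and raw — and both are carried through the same global scaling.
    Columns ``log2FC_without`` and ``log2FC_with`` mirror the side-by-side
    comparison layout; for genes without localized peaks the two values
    coincide.
    """
    cfg.validate_paths()
    stage = count_stage(cfg)

    def log2fc_of(enabled: bool) -> pd.Series:
        cm, _ = localnorm_stage(stage, cfg.upper_p, cfg.lower_p,
                                enabled=enabled)
        factors = globalnorm.size_factors(cm, method=cfg.global_norm)
        normed = globalnorm.normalize_counts(cm, factors)
        means = normed.condition_means()
        c1, c2 = normed.condition_labels
        pc = cfg.pseudocount
        return np.log2((means[c1] + pc) / (means[c2] + pc))

    without = log2fc_of(False)
    with_ = log2fc_of(True)
    df = pd.DataFrame({"log2FC_without": without, "log2FC_with": with_})
    if genes is not None:
        df = df.loc[genes]
    return df
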