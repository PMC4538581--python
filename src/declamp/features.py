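"""The three bounded gene attributes: FC, ARPK, GCC.

Each attribute is a transform of a familiar quantity onto (0, 1]:

* ``FC   = 1 / (1 + |log2((M1+pc)/(M2+pc))|)`` — fold change; 1 means no
  change between conditions, values near 0 mean a large change in either
  direction.  The absolute value is required for the stated [0,1] range
  (without it any M1 < M2 would give FC > 1).
* ``ARPK = 1 / (1 + max(0, log2(1000·(M1+M2)/(2·TL))))`` — averaged reads
  per kilobase, a length-normalized expression level; low-expressed (or
  long) genes score 1, highly expressed short genes approach 0.  The log
  term is floored at 0 so genes below one read per kilobase do not push the
  attribute above 1; an ``abs`` mode is available instead.
* ``GCC  = 1 / (1 + c/C)`` — the gene's mean read GC fraction c relative to
  the global mean C; 0.5 means average GC content.

M1 and M2 are per-condition means of locally clamped, globally scaled
counts; c is computed from the raw assigned reads pooled over both
conditions (GC content is a property of the reads themselves, not of
corrected depths).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .annotation import GeneModel
from .globalnorm import CountMatrix
from .readcount import GCStats

logger = logging.getLogger(__name__)

LABEL_DE = "DE"
LABEL_NDE = "NDE"
LABEL_NOCALL = "NOCALL"

FEATURE_COLUMNS = ("FC", "ARPK", "GCC")


@dataclass
class GeneFeatures:
    gene_id: str
    M1: float
    M2: float
    TL: int
    c: float
    C: float
    FC: float
    ARPK: float
    GCC: float


def fold_change_attribute(M1: float, M2: float, pseudocount: float = 1.0) -> float:
    """Bounded fold-change score in (0, 1]; 1 ⇔ equal means."""
    if M1 < 0 or M2 < 0:
        raise ValueError("means must be nonnegative")
    return 1.0 / (1.0 + abs(math.log2((M1 + pseudocount) / (M2 + pseudocount))))


def arpk_attribute(M1: float, M2: float, TL: float, mode: str = "clamp") -> float:
    """Bounded averaged-reads-per-kilobase score in (0, 1]."""
    if TL <= 0:
        raise ValueError("transcript length must be positive")
    mean = (M1 + M2) / 2.0
    if mean <= 0:
        # genes with no reads are normally removed by the filter first
        return 1.0
    # log-domain form: the product 1000·mean/TL can underflow for tiny means
    term = math.log2(1000.0) + math.log2(mean) - math.log2(TL)
    if mode == "clamp":
        term = max(0.0, term)
    elif mode == "abs":
        term = abs(term)
    else:
        raise ValueError(f"unknown arpk mode {mode!r}")
    return 1.0 / (1.0 + term)


def gcc_attribute(c: float, C: float) -> float:
    """Bounded relative-GC score in (0, 1]; 0.5 ⇔ gene GC equals global GC."""
    if C <= 0:
        raise ValueError("global mean GC fraction must be positive "
                         "(no mapped reads?)")
    if c < 0:
        raise ValueError("gene GC fraction must be nonnegative")
    return 1.0 / (1.0 + c / C)


def label_from_log2fc(abs_log2fc: float, hi: float = 1.5, lo: float = 0.5) -> str:
    """Three-way label from a reference |log2 fold change|.

    > hi → DE, < lo → NDE, in between → no-call.
    """
    if not 0 <= lo <= hi:
        raise ValueError("thresholds must satisfy 0 <= lo <= hi")
    if abs_log2fc > hi:
        return LABEL_DE
    if abs_log2fc < lo:
        return LABEL_NDE
    return LABEL_NOCALL


def build_feature_table(
    cm_normalized: CountMatrix,
    models: dict[str, GeneModel],
    gc: GCStats,
    pseudocount: float = 1.0,
    arpk_mode: str = "clamp",
) -> pd.DataFrame:
    """Attribute table for every gene surviving filtering and normalization.

    Returns a DataFrame indexed by gene_id with columns
    ``M1, M2, TL, c, FC, ARPK, GCC``.  Genes absent from the annotation are
    skipped with a warning.  Condition order follows the count matrix.
    """
    c1, c2 = cm_normalized.condition_labels
    means = cm_normalized.condition_means()
    C = gc.global_mean
    rows = []
    for gid in cm_normalized.counts.index:
        model = models.get(gid)
        if model is None:
            logger.warning("gene %s missing from annotation; skipped", gid)
            continue
        M1 = float(means.at[gid, c1])
        M2 = float(means.at[gid, c2])
        c = gc.gene_mean(gid)
        if math.isnan(c):
            c = C  # no GC information: neutral relative GC
        rows.append({
            "gene_id": gid,
            "M1": M1,
            "M2": M2,
            "TL": model.TL,
            "c": c,
            "FC": fold_change_attribute(M1, M2, pseudocount),
            "ARPK": arpk_attribute(M1, M2, model.TL, arpk_mode),
            "GCC": gcc_attribute(c, C),
        })
    return pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame(
        columns=["M1", "M2", "TL", "c", "FC", "ARPK", "GCC"]
    )


def feature_table_to_tsv(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index_label="gene_id")


def feature_table_from_tsv(path: str) -> pd.DataFrame:
    """Read a feature (or labeled training) table.

    Requires the attribute columns FC, ARPK, GCC; a ``label`` column makes it
    a training table.
    """
    table = pd.read_csv(path, sep="\t", index_col="gene_id")
    missing = [col for col in FEATURE_COLUMNS if col not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing attribute columns {missing}")
    return table
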