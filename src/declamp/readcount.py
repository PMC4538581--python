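"""Read assignment and per-gene read-start depth vectors.

Reads are assigned to genes in "union" resolution mode: a primary, uniquely
mapped read counts for a gene only if its aligned blocks overlap the exon
union of exactly one gene; overlap with two or more genes makes it ambiguous
and it is discarded, overlap with none makes it no-feature.  For each assigned
read, the depth vector entry at the transcript position of its leftmost
aligned base is incremented (the read-*start* signal the per-transcript
clamping operates on), and the read's GC fraction is accumulated into per-gene
and global running means.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pysam
from intervaltree import IntervalTree

from .annotation import INTRONIC, GeneModel

logger = logging.getLogger(__name__)

AMBIGUOUS = "__ambiguous__"
NO_FEATURE = "__no_feature__"


@dataclass
class DepthVector:
    """Per-gene vector of read-start counts in transcript coordinates."""

    gene_id: str
    sample_id: str
    r: np.ndarray  # int counts, length TL

    @property
    def R(self) -> int:
        return int(self.r.sum())


@dataclass
class GCStats:
    """Running sums of per-read GC fractions, per gene and globally.

    The GC fraction of a read is (G+C) / (non-N length); reads that are all N
    contribute nothing.
    """

    gene_gc_sum: dict[str, float] = field(default_factory=lambda: defaultdict(float))
    gene_n_reads: dict[str, int] = field(default_factory=lambda: defaultdict(int))
    total_gc_sum: float = 0.0
    total_n_reads: int = 0

    def add(self, gene_id: str, gc_fraction: float) -> None:
        self.gene_gc_sum[gene_id] += gc_fraction
        self.gene_n_reads[gene_id] += 1
        self.total_gc_sum += gc_fraction
        self.total_n_reads += 1

    def merge(self, other: "GCStats") -> None:
        for gid, s in other.gene_gc_sum.items():
            self.gene_gc_sum[gid] += s
        for gid, n in other.gene_n_reads.items():
            self.gene_n_reads[gid] += n
        self.total_gc_sum += other.total_gc_sum
        self.total_n_reads += other.total_n_reads

    def gene_mean(self, gene_id: str) -> float:
        """Mean read GC fraction of a gene (c); NaN if no reads."""
        n = self.gene_n_reads.get(gene_id, 0)
        return self.gene_gc_sum[gene_id] / n if n else float("nan")

    @property
    def global_mean(self) -> float:
        """Mean GC fraction over all assigned reads (C)."""
        if self.total_n_reads == 0:
            return float("nan")
        return self.total_gc_sum / self.total_n_reads


def gc_fraction(sequence: str) -> float:
    """GC fraction of a read sequence over its non-N length."""
    seq = sequence.upper()
    denom = sum(1 for b in seq if b != "N")
    if denom == 0:
        return 0.0
    return sum(1 for b in seq if b in "GC") / denom


class GeneIndex:
    """Interval index over the union exons of a collection of gene models."""

    def __init__(self, models: dict[str, GeneModel]):
        self.models = models
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for gid, model in models.items():
            for exon in model.union_exons:
                self._trees[model.chrom][exon.start:exon.end] = gid

    def overlapping_genes(self, chrom: str, blocks: list[tuple[int, int]]) -> set[str]:
        tree = self._trees.get(chrom)
        if tree is None:
            return set()
        hits: set[str] = set()
        for start, end in blocks:
            for iv in tree.overlap(start, end):
                hits.add(iv.data)
        return hits


def is_multimapper(read: pysam.AlignedSegment) -> bool:
    # NH tag when the aligner sets it; otherwise MAPQ 0 is the usual signal
    if read.has_tag("NH"):
        return read.get_tag("NH") > 1
    return read.mapping_quality == 0


def assign_read(
    chrom: str, blocks: list[tuple[int, int]], index: GeneIndex
) -> str:
    """Union-mode gene assignment from a read's aligned blocks.

    Returns the gene_id when exactly one gene's exon union is hit, else the
    ``AMBIGUOUS`` or ``NO_FEATURE`` sentinel.
    """
    hits = index.overlapping_genes(chrom, blocks)
    if len(hits) == 1:
        return next(iter(hits))
    return AMBIGUOUS if hits else NO_FEATURE


@dataclass
class ReadTally:
    assigned: int = 0
    ambiguous: int = 0
    no_feature: int = 0
    discarded: int = 0  # unmapped / secondary / supplementary / multimapper

    def as_dict(self) -> dict[str, int]:
        return {
            "assigned": self.assigned,
            "ambiguous": self.ambiguous,
            "no_feature": self.no_feature,
            "discarded": self.discarded,
        }


def build_depth_vectors(
    sam_path: str, models: dict[str, GeneModel], sample_id: str,
    index: GeneIndex | None = None,
) -> tuple[dict[str, DepthVector], GCStats, ReadTally]:
    """Stream a SAM file into per-gene read-start depth vectors.

    For each assigned read the count at the transcript position of its
    leftmost aligned base is incremented; if that base falls in an intron of
    the assigned gene (a spliced alignment starting upstream of the union),
    the first exonic base of the read inside the gene is used instead.
    Unmapped, secondary, supplementary and multimapping reads are skipped and
    tallied.
    """
    if index is None:
        index = GeneIndex(models)
    vectors = {
        gid: DepthVector(gid, sample_id, np.zeros(m.TL, dtype=np.int64))
        for gid, m in models.items()
    }
    gc = GCStats()
    tally = ReadTally()

    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        n_records = 0
        for read in sam:
            n_records += 1
            if (read.is_unmapped or read.is_secondary or read.is_supplementary
                    or is_multimapper(read)):
                tally.discarded += 1
                continue
            blocks = read.get_blocks()
            if not blocks:
                tally.discarded += 1
                continue
            gid = assign_read(read.reference_name, blocks, index)
            if gid == AMBIGUOUS:
                tally.ambiguous += 1
                continue
            if gid == NO_FEATURE:
                tally.no_feature += 1
                continue
            model = models[gid]
            tpos = model.first_exonic_at_or_after(blocks[0][0])
            if tpos == INTRONIC:
                # overlap was via a later block only and past the last exon
                # start; treat as the first exonic base of any aligned block
                for bstart, bend in blocks:
                    tpos = model.first_exonic_at_or_after(bstart)
                    if tpos != INTRONIC:
                        break
            if tpos == INTRONIC:
                tally.no_feature += 1
                continue
            vectors[gid].r[tpos] += 1
            tally.assigned += 1
            if read.query_sequence:
                gc.add(gid, gc_fraction(read.query_sequence))
        if n_records == 0:
            logger.warning("SAM file %s contains no alignment records", sam_path)

    logger.info(
        "%s: %d assigned, %d ambiguous, %d no_feature, %d discarded",
        sample_id, tally.assigned, tally.ambiguous, tally.no_feature,
        tally.discarded,
    )
    return vectors, gc, tally


def dump_gc_tsv(gc: GCStats, path: str) -> None:
    """Write per-gene and global GC running sums; `*` row is the global."""
    with open(path, "w") as fh:
        fh.write("gene_id\tgc_sum\tn_reads\n")
        fh.write(f"*\t{gc.total_gc_sum!r}\t{gc.total_n_reads}\n")
        for gid in gc.gene_n_reads:
            fh.write(f"{gid}\t{gc.gene_gc_sum[gid]!r}\t{gc.gene_n_reads[gid]}\n")


def load_gc_tsv(path: str) -> GCStats:
    gc = GCStats()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["gene_id", "gc_sum", "n_reads"]:
            raise ValueError(f"unexpected GC TSV header in {path}: {header}")
        for line in fh:
            gid, s, n = line.rstrip("\n").split("\t")
            if gid == "*":
                gc.total_gc_sum = float(s)
                gc.total_n_reads = int(n)
            else:
                gc.gene_gc_sum[gid] = float(s)
                gc.gene_n_reads[gid] = int(n)
    return gc


def dump_depth_tsv(vectors: dict[str, DepthVector], path: str) -> None:
    """Write nonzero depth entries as ``gene_id, sample_id, position, count``."""
    with open(path, "w") as fh:
        fh.write("gene_id\tsample_id\tposition\tcount\n")
        for dv in vectors.values():
            for pos in np.nonzero(dv.r)[0]:
                fh.write(f"{dv.gene_id}\t{dv.sample_id}\t{pos}\t{dv.r[pos]}\n")


def load_depth_tsv(
    path: str, models: dict[str, GeneModel]
) -> dict[str, dict[str, DepthVector]]:
    """Reload a depth TSV into {sample_id: {gene_id: DepthVector}}."""
    out: dict[str, dict[str, DepthVector]] = defaultdict(dict)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["gene_id", "sample_id", "position", "count"]:
            raise ValueError(f"unexpected depth TSV header in {path}: {header}")
        for lineno, line in enumerate(fh, start=2):
            try:
                gid, sid, pos, count = line.rstrip("\n").split("\t")
                pos_i, count_i = int(pos), int(count)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row") from exc
            if gid not in models:
                logger.warning("%s:%d: unknown gene %s skipped", path, lineno, gid)
                continue
            dv = out[sid].get(gid)
            if dv is None:
                dv = DepthVector(gid, sid, np.zeros(models[gid].TL, dtype=np.int64))
                out[sid][gid] = dv
            dv.r[pos_i] += count_i
    return dict(out)
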