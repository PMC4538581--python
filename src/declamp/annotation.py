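"""Gene models from GTF/GFF3 annotation.

Each gene is represented by the union of all exons of all of its isoforms,
concatenated in ascending genomic order into a single "transcript" coordinate
system of length ``TL``.  All per-position depth accounting downstream happens
in this coordinate system.  Internally every interval is 0-based half-open;
GTF/GFF3 1-based inclusive coordinates are converted at the parsing boundary
and nowhere else.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field

import gffutils

logger = logging.getLogger(__name__)

INTRONIC = -1
"""Sentinel returned by :meth:`GeneModel.genomic_to_transcript` for
positions outside the exon union."""


@dataclass(frozen=True)
class ExonInterval:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(f"empty/inverted interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """Union-exon model of a gene with a concatenated transcript coordinate.

    ``union_exons`` are sorted, pairwise-disjoint intervals on one chromosome.
    Transcript position ``i`` in ``[0, TL)`` is the i-th exonic base in
    ascending genomic order, regardless of strand: the per-position clamping
    applied downstream is orientation-invariant, so strand flipping would add
    bookkeeping without changing any result.
    """

    gene_id: str
    chrom: str
    strand: str
    union_exons: list[ExonInterval]
    # cumulative transcript offset at the start of each union exon
    _offsets: list[int] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if not self.union_exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        starts = [e.start for e in self.union_exons]
        if starts != sorted(starts):
            raise ValueError(f"gene {self.gene_id}: exons not sorted")
        for a, b in zip(self.union_exons, self.union_exons[1:]):
            if a.end > b.start:
                raise ValueError(f"gene {self.gene_id}: overlapping union exons")
            if a.chrom != b.chrom:
                raise ValueError(f"gene {self.gene_id}: exons on multiple chroms")
        if not self._offsets:
            off = 0
            for e in self.union_exons:
                self._offsets.append(off)
                off += len(e)

    @property
    def TL(self) -> int:
        """Total exonic length in bases (the transcript length)."""
        last = self.union_exons[-1]
        return self._offsets[-1] + len(last)

    def genomic_to_transcript(self, gpos: int) -> int:
        """Map a genomic position to its transcript position.

        Returns ``INTRONIC`` (−1) when ``gpos`` is not in the exon union.
        """
        k = bisect.bisect_right([e.start for e in self.union_exons], gpos) - 1
        if k < 0:
            return INTRONIC
        exon = self.union_exons[k]
        if gpos >= exon.end:
            return INTRONIC
        return self._offsets[k] + (gpos - exon.start)

    def transcript_to_genomic(self, tpos: int) -> int:
        """Inverse of :meth:`genomic_to_transcript` on the exonic set."""
        if not 0 <= tpos < self.TL:
            raise IndexError(f"transcript position {tpos} outside [0, {self.TL})")
        k = bisect.bisect_right(self._offsets, tpos) - 1
        exon = self.union_exons[k]
        return exon.start + (tpos - self._offsets[k])

    def first_exonic_at_or_after(self, gpos: int) -> int:
        """Transcript position of the first exonic base at or after ``gpos``.

        Returns ``INTRONIC`` when no exonic base lies at or after ``gpos``
        (i.e. the position is past the gene's 3'-most union exon).
        """
        t = self.genomic_to_transcript(gpos)
        if t != INTRONIC:
            return t
        for exon, off in zip(self.union_exons, self._offsets):
            if exon.start > gpos:
                return off
        return INTRONIC


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of intervals; invariant to input order and duplication."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def build_gene_model(
    gene_id: str, chrom: str, strand: str, exons: list[tuple[int, int]]
) -> GeneModel:
    """Build a GeneModel from raw 0-based half-open exon intervals."""
    merged = _merge_intervals(exons)
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        union_exons=[ExonInterval(chrom, s, e, strand) for s, e in merged],
    )


def _gff3_gene_id(db: gffutils.FeatureDB, feature: gffutils.Feature) -> str | None:
    """Resolve a GFF3 exon to its gene by walking Parent links."""
    node = feature
    seen = set()
    while True:
        if node.featuretype == "gene":
            return node.id
        if "gene_id" in node.attributes:
            return node.attributes["gene_id"][0]
        parents = node.attributes.get("Parent", [])
        if not parents or parents[0] in seen:
            return None
        seen.add(parents[0])
        try:
            node = db[parents[0]]
        except gffutils.FeatureNotFoundError:
            return parents[0] if node is feature else node.id


def parse_annotation(
    path: str, feature_type: str = "exon", gene_key: str = "gene_id"
) -> dict[str, GeneModel]:
    """Parse a GTF or GFF3 file into per-gene union-exon models.

    Exons of all isoforms of a gene are merged into one union; genes sharing
    genomic intervals each keep their own copy (read ambiguity is resolved at
    assignment time, not here).  Coordinates are converted from the file's
    1-based inclusive convention to 0-based half-open.

    Parameters
    ----------
    path:
        GTF (Ensembl-style ``gene_id "X";`` attributes) or GFF3
        (``ID=``/``Parent=`` chains resolved up to the gene record).
    feature_type:
        Feature rows to collect (default ``"exon"``).
    gene_key:
        Attribute naming the gene in GTF dialect.

    Returns
    -------
    dict mapping gene_id to :class:`GeneModel`, insertion-ordered by first
    appearance in the file.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            if len(line.rstrip("\n").split("\t")) < 8:
                raise ValueError(
                    f"failed to parse annotation {path!r}: line {lineno} has "
                    f"fewer than 8 tab-separated fields"
                )
    try:
        db = gffutils.create_db(
            path,
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise ValueError(f"failed to parse annotation {path!r}: {exc}") from exc

    raw: dict[str, dict] = {}
    is_gff3 = db.dialect.get("fmt") == "gff3"
    for feat in db.features_of_type(feature_type, order_by=("seqid", "start")):
        if is_gff3 and gene_key not in feat.attributes:
            gid = _gff3_gene_id(db, feat)
        else:
            gid = feat.attributes.get(gene_key, [None])[0]
        if gid is None:
            logger.warning(
                "%s record at %s:%d-%d has no resolvable gene id; skipped",
                feature_type, feat.seqid, feat.start, feat.end,
            )
            continue
        entry = raw.setdefault(
            gid, {"chrom": feat.seqid, "strand": feat.strand or ".", "exons": []}
        )
        if entry["chrom"] != feat.seqid:
            logger.warning("gene %s spans multiple chromosomes; keeping %s only",
                           gid, entry["chrom"])
            continue
        # GTF/GFF3 are 1-based inclusive; gffutils preserves that convention
        entry["exons"].append((feat.start - 1, feat.end))

    models: dict[str, GeneModel] = {}
    for gid, entry in raw.items():
        if not entry["exons"]:
            logger.warning("gene %s has zero exons; excluded", gid)
            continue
        models[gid] = build_gene_model(gid, entry["chrom"], entry["strand"],
                                       entry["exons"])
    if not models:
        logger.warning("no gene models parsed from %s", path)
    return models
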