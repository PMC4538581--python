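"""Synthetic RNA-seq data with exact ground truth.

The generator embodies the null model the local normalization is calibrated
against — reads placed independently and uniformly along each transcript —
plus the two departures the method targets: localized depth spikes (a narrow
run of positions receiving a large extra read mass in one condition, the
signature of PCR/mapping artifacts) and true differential expression
(condition means differing by a configured log2 fold change).  Everything is
emitted in standard formats (GTF annotation, one SAM per sample) alongside a
ground-truth record of per-position read-start counts, so the SAM/annotation
ingestion path can be checked for exact agreement and downstream stages can
be validated against known truth.

All randomness flows from one integer seed; output is byte-identical across
reruns.  No sequencing-error model: reads are emitted pre-aligned with exact
positions (MAPQ 60, ``NH:i:1``) since alignment is upstream of this tool.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import features as feat

READ_QUAL_CHAR = "I"


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults encode the uniform-read null at realistic bulk depths: gene
    lengths uniform on [1000, 3000] bp, per-position read-start rate
    log-uniform on [0.5, 4], 35 bp reads, two replicates per condition.
    Spikes default to a 10 bp run carrying 50× the expected per-position
    depth, injected into condition 1 only.
    """

    seed: int = 0
    n_genes: int = 100
    length_range: tuple[int, int] = (1000, 3000)
    lambda_range: tuple[float, float] = (0.5, 4.0)
    lambda_law: str = "log-uniform"  # or "uniform", "constant" (lo value)
    replicates: int = 2              # per condition
    read_length: int = 35
    gc_range: tuple[float, float] = (0.35, 0.65)
    # spikes
    spike_fraction: float = 0.0
    spike_height: float = 50.0       # × expected per-position depth λ
    spike_width: int = 10            # bp
    spike_gc_shift: float = 0.0      # added to spiked reads' GC content
    spike_condition: int = 0         # 0-based condition index receiving spikes
    # differential expression
    de_fraction: float = 0.0
    de_log2fc_range: tuple[float, float] = (2.0, 4.0)
    # genome layout
    n_exons_range: tuple[int, int] = (1, 1)
    intron_length: int = 200
    intergenic_gap: int = 500
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        if self.read_length >= self.length_range[0]:
            raise ValueError("read_length must be shorter than the shortest "
                             "gene")
        for frac in (self.spike_fraction, self.de_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0,1]")
        if min(self.length_range) <= 0 or min(self.lambda_range) <= 0:
            raise ValueError("length and rate ranges must be positive")


@dataclass
class SimGene:
    gene_id: str
    TL: int
    gc: float                    # transcript base composition GC fraction
    lam: float                   # condition-1 per-position read-start rate
    log2fc: float                # true condition-2/condition-1 log2 ratio
    is_de: bool
    exon_starts: list[int]       # genomic, 0-based
    exon_lengths: list[int]
    spike_positions: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64))

    @property
    def lam2(self) -> float:
        return self.lam * 2.0 ** self.log2fc


@dataclass
class SimTruth:
    """Ground truth for one simulated data set."""

    config: SimConfig
    genes: list[SimGene]
    samples: list[str]                       # condition order: all of cond 1,
    conditions: dict[str, str]               # then all of cond 2
    # counts[sample][gene_id] = per-position read-start counts, length TL
    counts: dict[str, dict[str, np.ndarray]]
    # per-sample, per-gene number of spike reads (for diagnostics)
    spike_reads: dict[str, dict[str, int]]

    def total_reads(self, sample: str, gene_id: str) -> int:
        return int(self.counts[sample][gene_id].sum())


def _draw_lambda(rng: np.random.Generator, cfg: SimConfig, n: int) -> np.ndarray:
    lo, hi = cfg.lambda_range
    if cfg.lambda_law == "log-uniform":
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    if cfg.lambda_law == "uniform":
        return rng.uniform(lo, hi, size=n)
    if cfg.lambda_law == "constant":
        return np.full(n, lo)
    raise ValueError(f"unknown lambda law {cfg.lambda_law!r}")


def _layout_genes(rng: np.random.Generator, cfg: SimConfig) -> list[SimGene]:
    n = cfg.n_genes
    lengths = rng.integers(cfg.length_range[0], cfg.length_range[1] + 1,
                           size=n)
    gcs = rng.uniform(*cfg.gc_range, size=n)
    lams = _draw_lambda(rng, cfg, n)
    de_flags = rng.random(n) < cfg.de_fraction
    l2fc = np.zeros(n)
    de_mag = rng.uniform(*cfg.de_log2fc_range, size=n)
    de_sign = rng.choice([-1.0, 1.0], size=n)
    l2fc[de_flags] = (de_mag * de_sign)[de_flags]

    genes: list[SimGene] = []
    cursor = cfg.intergenic_gap
    width = len(str(n))
    for i in range(n):
        tl = int(lengths[i])
        n_exons = int(rng.integers(cfg.n_exons_range[0],
                                   cfg.n_exons_range[1] + 1))
        n_exons = min(n_exons, max(1, tl // (2 * cfg.read_length)))
        # split TL into n_exons parts, each ≥ read_length
        cuts = np.sort(rng.choice(
            np.arange(cfg.read_length, tl - cfg.read_length + 1),
            size=n_exons - 1, replace=False)) if n_exons > 1 else np.empty(0)
        bounds = np.concatenate(([0], cuts, [tl])).astype(int)
        exon_lengths = list(np.diff(bounds))
        exon_starts = []
        for el in exon_lengths:
            exon_starts.append(cursor)
            cursor += el + cfg.intron_length
        cursor += cfg.intergenic_gap - cfg.intron_length
        genes.append(SimGene(
            gene_id=f"G{i:0{width}d}",
            TL=tl,
            gc=float(gcs[i]),
            lam=float(lams[i]),
            log2fc=float(l2fc[i]),
            is_de=bool(de_flags[i]),
            exon_starts=exon_starts,
            exon_lengths=exon_lengths,
        ))
    return genes


def simulate_depths(cfg: SimConfig) -> SimTruth:
    """Simulate per-position read-start counts under uniform placement.

    For each gene and sample the read total is Poisson(rate × placeable
    positions) and start positions are i.i.d. uniform over
    [0, TL − read_length]; spikes configured in ``cfg`` are injected
    afterwards.  This is the ground-truth layer; :func:`simulate_uniform_reads`
    additionally materializes the reads into SAM files.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _layout_genes(rng, cfg)
    cond = {0: "cond1", 1: "cond2"}
    samples = [f"{cond[ci]}_rep{ri + 1}"
               for ci in (0, 1) for ri in range(cfg.replicates)]
    conditions = {s: s.rsplit("_", 1)[0] for s in samples}
    counts: dict[str, dict[str, np.ndarray]] = {s: {} for s in samples}
    spike_reads: dict[str, dict[str, int]] = {s: {} for s in samples}
    for g in genes:
        n_pos = g.TL - cfg.read_length + 1
        for ci in (0, 1):
            rate = g.lam if ci == 0 else g.lam2
            for ri in range(cfg.replicates):
                s = f"{cond[ci]}_rep{ri + 1}"
                total = int(rng.poisson(rate * n_pos))
                starts = rng.integers(0, n_pos, size=total)
                counts[s][g.gene_id] = np.bincount(
                    starts, minlength=g.TL).astype(np.int64)
                spike_reads[s][g.gene_id] = 0
    truth = SimTruth(config=cfg, genes=genes, samples=samples,
                     conditions=conditions, counts=counts,
                     spike_reads=spike_reads)
    if cfg.spike_fraction > 0:
        truth = inject_spikes(truth, rng=rng)
    return truth


def inject_spikes(truth: SimTruth,
                  rng: np.random.Generator | None = None) -> SimTruth:
    """Add localized depth spikes to a fraction of genes in one condition.

    Each spiked gene receives, in every replicate of the spike condition, an
    extra Poisson(height × λ) reads at each of ``spike_width`` consecutive
    positions.  The true (unspiked) expression and log2FC stay recorded in
    the gene entries; only the observed counts are biased.  A zero spike
    fraction returns the input unchanged.
    """
    cfg = truth.config
    if cfg.spike_fraction == 0:
        return truth
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    truth = copy.deepcopy(truth)
    n_spiked = int(round(cfg.spike_fraction * len(truth.genes)))
    spiked_idx = rng.choice(len(truth.genes), size=n_spiked, replace=False)
    cond_label = f"cond{cfg.spike_condition + 1}"
    target_samples = [s for s in truth.samples
                      if truth.conditions[s] == cond_label]
    for gi in np.sort(spiked_idx):
        g = truth.genes[gi]
        n_pos = g.TL - cfg.read_length + 1
        start = int(rng.integers(0, max(1, n_pos - cfg.spike_width)))
        g.spike_positions = np.arange(start, start + cfg.spike_width)
        rate = g.lam if cfg.spike_condition == 0 else g.lam2
        for s in target_samples:
            extra = rng.poisson(cfg.spike_height * rate,
                                size=cfg.spike_width)
            truth.counts[s][g.gene_id][g.spike_positions] += extra
            truth.spike_reads[s][g.gene_id] += int(extra.sum())
    return truth


def _base_probs(gc: float) -> np.ndarray:
    gc = min(max(gc, 0.02), 0.98)
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T


_BASES = np.array(list("ACGT"))


def _transcript_read_to_genomic(g: SimGene, tstart: int,
                                read_length: int) -> tuple[int, str]:
    """Genomic POS (0-based) and CIGAR of a read starting at ``tstart``."""
    offsets = np.cumsum([0] + g.exon_lengths[:-1])
    remaining = read_length
    tpos = tstart
    blocks: list[tuple[int, int]] = []
    for estart, elen, off in zip(g.exon_starts, g.exon_lengths, offsets):
        if tpos >= off + elen or remaining <= 0:
            continue
        if tpos < off:
            continue
        take = min(remaining, off + elen - tpos)
        blocks.append((estart + (tpos - off), take))
        remaining -= take
        tpos += take
    cigar_parts = []
    for bi, (bstart, blen) in enumerate(blocks):
        if bi > 0:
            gap = bstart - (blocks[bi - 1][0] + blocks[bi - 1][1])
            cigar_parts.append(f"{gap}N")
        cigar_parts.append(f"{blen}M")
    return blocks[0][0], "".join(cigar_parts)


def write_gtf(truth: SimTruth, path: str) -> None:
    """Emit the simulated annotation as Ensembl-dialect GTF."""
    cfg = truth.config
    with open(path, "w") as fh:
        for g in truth.genes:
            for estart, elen in zip(g.exon_starts, g.exon_lengths):
                attrs = (f'gene_id "{g.gene_id}"; '
                         f'transcript_id "{g.gene_id}.t1";')
                fh.write("\t".join([
                    cfg.chrom, "sim", "exon",
                    str(estart + 1), str(estart + elen),
                    ".", "+", ".", attrs,
                ]) + "\n")


def write_sam(truth: SimTruth, sample: str, path: str) -> None:
    """Emit one sample's reads as SAM, consistent with the truth counts.

    Read sequences are i.i.d. draws from the gene's base composition; reads
    at spike positions use the composition shifted by ``spike_gc_shift``.
    """
    cfg = truth.config
    # independent stream per sample so per-sample files are reproducible
    rng = np.random.default_rng(
        np.random.SeedSequence((cfg.seed, 7, truth.samples.index(sample))))
    last = truth.genes[-1]
    chrom_len = last.exon_starts[-1] + last.exon_lengths[-1] + cfg.intergenic_gap
    qual = READ_QUAL_CHAR * cfg.read_length
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{cfg.chrom}\tLN:{chrom_len}\n")
        fh.write(f"@RG\tID:{sample}\tSM:{sample}\n")
        serial = 0
        for g in truth.genes:
            r = truth.counts[sample][g.gene_id]
            spikes = set(g.spike_positions.tolist())
            spiked_here = (truth.spike_reads[sample][g.gene_id] > 0)
            for tstart in np.nonzero(r)[0]:
                pos0, cigar = _transcript_read_to_genomic(
                    g, int(tstart), cfg.read_length)
                gc = g.gc
                if spiked_here and int(tstart) in spikes:
                    gc = g.gc + cfg.spike_gc_shift
                probs = _base_probs(gc)
                for _ in range(int(r[tstart])):
                    seq = "".join(_BASES[rng.choice(4, size=cfg.read_length,
                                                    p=probs)])
                    fh.write("\t".join([
                        f"{sample}.{serial}", "0", cfg.chrom,
                        str(pos0 + 1), "60", cigar, "*", "0", "0",
                        seq, qual, "NH:i:1",
                    ]) + "\n")
                    serial += 1


def simulate_uniform_reads(cfg: SimConfig, outdir: str) -> dict:
    """Full synthetic data set: GTF + one SAM per sample + ground truth.

    Returns paths together with the :class:`SimTruth` record.  Deterministic
    given ``cfg.seed``: reruns produce byte-identical files.
    """
    import os

    truth = simulate_depths(cfg)
    os.makedirs(outdir, exist_ok=True)
    gtf_path = os.path.join(outdir, "annotation.gtf")
    write_gtf(truth, gtf_path)
    sam_paths = {}
    for s in truth.samples:
        p = os.path.join(outdir, f"{s}.sam")
        write_sam(truth, s, p)
        sam_paths[s] = p
    return {"truth": truth, "gtf": gtf_path, "sam": sam_paths,
            "conditions": truth.conditions}


def simulate_training_table(
    n_DE: int,
    n_NDE: int,
    seed: int = 0,
    de_log2fc_range: tuple[float, float] = (1.6, 4.0),
    nde_log2fc_range: tuple[float, float] = (0.0, 0.4),
    length_range: tuple[int, int] = (1000, 3000),
    lambda_range: tuple[float, float] = (0.5, 4.0),
    replicates: int = 2,
    global_gc: float = 0.5,
    gc_sd: float = 0.05,
) -> pd.DataFrame:
    """Labeled attribute table for classifier training and evaluation.

    Per gene: a transcript length and baseline per-position rate are drawn
    (uniform and log-uniform over the stated ranges), the condition-2 mean is
    the baseline times 2^log2FC with |log2FC| drawn from the class's range
    (DE above the calling threshold, NDE below), replicate counts are Poisson
    around the condition means, gene mean read GC is Normal(global_gc,
    gc_sd) truncated to (0, 1), and the three attributes are computed through
    the real feature formulas.  Labels come from the true |log2FC| via the
    standard thresholds, so every DE row is labeled DE by construction.
    """
    if n_DE < 2 or n_NDE < 2:
        raise ValueError("need at least 2 genes per class")
    rng = np.random.default_rng(seed)
    rows = []
    specs = [(feat.LABEL_DE, n_DE, de_log2fc_range),
             (feat.LABEL_NDE, n_NDE, nde_log2fc_range)]
    idx = 0
    for label, n, fc_range in specs:
        for _ in range(n):
            tl = int(rng.integers(length_range[0], length_range[1] + 1))
            lam = float(np.exp(rng.uniform(np.log(lambda_range[0]),
                                           np.log(lambda_range[1]))))
            l2fc = float(rng.uniform(*fc_range)) * float(rng.choice([-1, 1]))
            mu1 = lam * tl
            mu2 = mu1 * 2.0 ** l2fc
            M1 = float(np.mean(rng.poisson(mu1, size=replicates)))
            M2 = float(np.mean(rng.poisson(mu2, size=replicates)))
            c = float(np.clip(rng.normal(global_gc, gc_sd), 0.01, 0.99))
            rows.append({
                "gene_id": f"T{idx:05d}",
                "M1": M1, "M2": M2, "TL": tl, "c": c,
                "true_log2fc": l2fc,
                "FC": feat.fold_change_attribute(M1, M2),
                "ARPK": feat.arpk_attribute(M1, M2, tl),
                "GCC": feat.gcc_attribute(c, global_gc),
                "label": feat.label_from_log2fc(abs(l2fc)),
            })
            idx += 1
    return pd.DataFrame(rows).set_index("gene_id")
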