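import numpy as np
import pytest

from declamp import build_gene_model
from declamp.readcount import DepthVector

SAM_HEADER = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:chr1\tLN:100000\n"


def sam_line(qname, chrom, pos0, cigar, seq, mapq=60, flag=0, tags=("NH:i:1",)):
    """One SAM alignment line; pos0 is 0-based."""
    fields = [qname, str(flag), chrom, str(pos0 + 1), str(mapq), cigar,
              "*", "0", "0", seq, "I" * len(seq), *tags]
    return "\t".join(fields) + "\n"


@pytest.fixture
def write_sam(tmp_path):
    def _write(lines, name="reads.sam", header=SAM_HEADER):
        path = tmp_path / name
        path.write_text(header + "".join(lines))
        return str(path)

    return _write


@pytest.fixture
def toy_models():
    """Three genes on chr1: two-exon A, single-exon B, and C overlapping B."""
    return {
        "A": build_gene_model("A", "chr1", "+", [(100, 200), (300, 400)]),
        "B": build_gene_model("B", "chr1", "+", [(1000, 1500)]),
        "C": build_gene_model("C", "chr1", "-", [(1400, 1800)]),
    }


def depth_vector(r, gene_id="g", sample_id="s"):
    return DepthVector(gene_id, sample_id, np.asarray(r, dtype=np.int64))
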