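"""Between-sample scaling of gene counts and the low-expression filter.

Two size-factor methods are provided: the DESeq-style median-of-ratios
(default) and edgeR-style TMM (trimmed mean of M-values).  Normalized counts
are raw counts divided by their sample's factor.  Genes whose mean count is
below ``min_mean`` in *both* conditions are dropped before feature
extraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Genes × samples count matrix with a two-condition design.

    ``counts`` is a DataFrame indexed by gene_id with one column per sample;
    ``conditions`` maps every sample to one of exactly two condition labels.
    """

    counts: pd.DataFrame
    conditions: dict[str, str]

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        missing = set(self.counts.columns) - set(self.conditions)
        if missing:
            raise ValueError(f"samples without condition: {sorted(missing)}")
        if len(set(self.conditions[s] for s in self.counts.columns)) != 2:
            raise ValueError("exactly two conditions required")

    @property
    def condition_labels(self) -> tuple[str, str]:
        seen: list[str] = []
        for s in self.counts.columns:
            c = self.conditions[s]
            if c not in seen:
                seen.append(c)
        return tuple(seen)  # type: ignore[return-value]

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.conditions[s] == condition]

    def condition_means(self) -> pd.DataFrame:
        """Per-gene mean count within each condition (columns = conditions)."""
        c1, c2 = self.condition_labels
        return pd.DataFrame({
            c1: self.counts[self.samples_of(c1)].mean(axis=1),
            c2: self.counts[self.samples_of(c2)].mean(axis=1),
        })

    def with_counts(self, counts: pd.DataFrame) -> "CountMatrix":
        return CountMatrix(counts, dict(self.conditions))


def median_of_ratios_factors(cm: CountMatrix) -> pd.Series:
    """DESeq-style size factors.

    factor_j = median over genes positive in every sample of
    count_gj / geometric-mean_g(count).
    """
    counts = cm.counts
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; "
            "use TMM or add pseudocounts"
        )
    sub = counts.loc[positive]
    log_geomean = np.log(sub).mean(axis=1)
    factors = np.exp(np.log(sub).sub(log_geomean, axis=0)).median(axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _tmm_pair_factor(
    obs: np.ndarray, ref: np.ndarray, trim_M: float, trim_A: float
) -> float:
    """TMM scaling factor of one library against the reference library."""
    N_obs, N_ref = obs.sum(), ref.sum()
    ok = (obs > 0) & (ref > 0)
    if not ok.any():
        raise ValueError("no gene positive in both libraries")
    p_obs = obs[ok] / N_obs
    p_ref = ref[ok] / N_ref
    M = np.log2(p_obs / p_ref)
    A = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic delta-method inverse variances as weights
    w = 1.0 / ((N_obs - obs[ok]) / (N_obs * obs[ok])
               + (N_ref - ref[ok]) / (N_ref * ref[ok]))
    if np.abs(M).max() < 1e-6:  # libraries already proportional
        return 1.0
    # double trimming by rank: drop the extreme trim_M of M and trim_A of A
    n = M.size
    rM = stats.rankdata(M)
    rA = stats.rankdata(A)
    loM, hiM = np.floor(n * trim_M) + 1, n - np.floor(n * trim_M)
    loA, hiA = np.floor(n * trim_A) + 1, n - np.floor(n * trim_A)
    keep = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
    if not keep.any():
        keep[:] = True
    f = np.sum(w[keep] * M[keep]) / np.sum(w[keep])
    return float(2.0 ** f)


def tmm_factors(
    cm: CountMatrix,
    ref_sample: str | None = None,
    trim_M: float = 0.30,
    trim_A: float = 0.05,
) -> pd.Series:
    """edgeR-style TMM size factors, rescaled to geometric mean 1.

    The factor of a sample is its library size times the weighted trimmed
    mean of per-gene M-values against the reference sample, so that dividing
    counts by the factor aligns the bulk of the log-ratio distribution at 0.
    """
    counts = cm.counts
    lib = counts.sum(axis=0)
    if ref_sample is None:
        # edgeR's default: library whose 75th percentile of count/libsize is
        # closest to the mean of those quantiles
        q = counts.div(lib, axis=1).quantile(0.75)
        ref_sample = (q - q.mean()).abs().idxmin()
    ref = counts[ref_sample].to_numpy(dtype=float)
    tmm = {}
    for s in counts.columns:
        if s == ref_sample:
            tmm[s] = 1.0
        else:
            tmm[s] = _tmm_pair_factor(
                counts[s].to_numpy(dtype=float), ref, trim_M, trim_A
            )
    # size factor = relative library size × TMM correction
    raw = lib / lib[ref_sample] * pd.Series(tmm)
    factors = raw / np.exp(np.log(raw).mean())
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(cm: CountMatrix, factors: pd.Series) -> CountMatrix:
    """Divide each sample's counts by its size factor."""
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    return cm.with_counts(cm.counts.div(factors, axis=1))


def filter_low_expression(cm: CountMatrix, min_mean: float = 5) -> CountMatrix:
    """Drop genes whose mean count is below ``min_mean`` in both conditions.

    A gene is kept iff its mean is at least ``min_mean`` in at least one
    condition.  Idempotent.
    """
    means = cm.condition_means()
    keep = (means >= min_mean).any(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("low-expression filter removed %d of %d genes",
                    dropped, len(keep))
    return cm.with_counts(cm.counts.loc[keep])


def size_factors(cm: CountMatrix, method: str = "deseq", **kwargs) -> pd.Series:
    """Dispatch on the global-normalization method name."""
    if method == "deseq":
        return median_of_ratios_factors(cm)
    if method == "tmm":
        return tmm_factors(cm, **kwargs)
    raise ValueError(f"unknown global normalization method {method!r}")


def counts_to_tsv(cm: CountMatrix, path: str) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene_id")


def counts_from_tsv(path: str, conditions: dict[str, str]) -> CountMatrix:
    counts = pd.read_csv(path, sep="\t", index_col="gene_id")
    return CountMatrix(counts, conditions)
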