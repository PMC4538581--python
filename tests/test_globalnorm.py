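import numpy as np
import pandas as pd
import pytest

from declamp import (
    CountMatrix,
    filter_low_expression,
    median_of_ratios_factors,
    normalize_counts,
    tmm_factors,
)


def make_cm(values, samples=None, conditions=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    counts = pd.DataFrame(values, columns=samples,
                          index=[f"g{i}" for i in range(values.shape[0])])
    if conditions is None:
        half = len(samples) // 2 or 1
        conditions = {s: ("c1" if j < half else "c2")
                      for j, s in enumerate(samples)}
    return CountMatrix(counts, conditions)


class TestMedianOfRatios:
    def test_identical_samples_get_equal_factors(self):
        cm = make_cm(np.tile([[10], [20], [30]], (1, 2)))
        f = median_of_ratios_factors(cm)
        assert f.iloc[0] == pytest.approx(f.iloc[1])

    def test_proportional_samples_factor_ratio(self):
        base = np.array([[10.0], [25.0], [40.0], [100.0]])
        cm = make_cm(np.hstack([base, 2 * base]))
        f = median_of_ratios_factors(cm)
        assert f.iloc[1] / f.iloc[0] == pytest.approx(2.0)

    def test_three_gene_toy_matches_hand_oracle(self):
        counts = np.array([[4.0, 16.0], [9.0, 9.0], [25.0, 1.0]])
        cm = make_cm(counts)
        # hand oracle: geometric means per gene 8, 9, 5; ratios per sample:
        # s0: 4/8, 9/9, 25/5 -> median 1.0 ; s1: 16/8, 9/9, 1/5 -> median 1.0
        f = median_of_ratios_factors(cm)
        assert f.iloc[0] == pytest.approx(1.0)
        assert f.iloc[1] == pytest.approx(1.0)

    def test_matches_deseq_reference_on_fixed_matrix(self):
        # expected factors computed independently with DESeq's
        # estimateSizeFactorsForMatrix on this matrix
        counts = np.array([
            [100, 210, 95], [50, 95, 55], [400, 820, 390], [80, 150, 82],
            [250, 520, 240], [30, 65, 31], [600, 1150, 610], [120, 260, 118],
        ])
        cm = make_cm(counts, conditions={"s0": "a", "s1": "b", "s2": "b"})
        f = median_of_ratios_factors(cm)
        expected = [0.7939951171, 1.6396018543, 0.7819512943]
        assert np.allclose(f.to_numpy(), expected, rtol=1e-8)

    def test_no_all_positive_gene_raises(self):
        cm = make_cm([[0.0, 5.0], [5.0, 0.0]])
        with pytest.raises(ValueError, match="TMM|pseudocount"):
            median_of_ratios_factors(cm)


class TestTMM:
    def test_identical_samples_all_ones(self):
        cm = make_cm(np.tile([[10], [20], [30], [40], [50]], (1, 3)),
                     conditions={"s0": "a", "s1": "b", "s2": "b"})
        f = tmm_factors(cm)
        assert np.allclose(f.to_numpy(), 1.0)

    def test_proportional_samples_factor_ratio(self):
        base = np.array([[10.0], [25.0], [40.0], [100.0], [7.0]])
        cm = make_cm(np.hstack([base, 3 * base]))
        f = tmm_factors(cm)
        assert f.iloc[1] / f.iloc[0] == pytest.approx(3.0)

    def test_matches_edger_reference_on_fixed_matrix(self):
        # expected TMM corrections computed independently with edgeR's
        # calcNormFactors on this matrix (norm.factors column)
        counts = np.array([
            [100, 210, 95], [50, 95, 55], [400, 820, 390], [80, 150, 82],
            [250, 520, 240], [30, 65, 31], [600, 1150, 610], [120, 260, 118],
        ])
        cm = make_cm(counts, conditions={"s0": "a", "s1": "b", "s2": "b"})
        f = tmm_factors(cm)
        lib = cm.counts.sum()
        tmm_corr = f / (lib / np.exp(np.log(lib).mean()))
        tmm_corr /= np.exp(np.log(tmm_corr).mean())
        expected = [1.0002927888, 0.9923380119, 1.0074261843]
        assert np.allclose(tmm_corr.to_numpy(), expected, rtol=1e-6)


class TestScalingInvariance:
    # TMM is only approximately scale-equivariant: its delta-method weights
    # mix the scaled library's term with the (unscaled) reference library's
    @pytest.mark.parametrize("method,rel", [
        (median_of_ratios_factors, 1e-9), (tmm_factors, 5e-3)])
    def test_scaling_one_sample_scales_its_factor(self, method, rel):
        rng = np.random.default_rng(2)
        counts = rng.poisson(100, size=(50, 4)).astype(float) + 1
        cm = make_cm(counts)
        scaled = counts.copy()
        scaled[:, 2] *= 5.0
        cm2 = make_cm(scaled)
        f1, f2 = method(cm), method(cm2)
        ratio = (f2 / f1).to_numpy()
        assert ratio[2] / ratio[0] == pytest.approx(5.0, rel=rel)

    def test_normalized_identical_samples_are_identical(self):
        cm = make_cm(np.tile([[10.0], [20.0], [35.0]], (1, 2)))
        normed = normalize_counts(cm, median_of_ratios_factors(cm))
        assert np.allclose(normed.counts.iloc[:, 0], normed.counts.iloc[:, 1])


class TestLowExpressionFilter:
    def test_gene_low_in_both_conditions_removed(self):
        cm = make_cm([[4.0, 4.0], [6.0, 6.0]])
        kept = filter_low_expression(cm, min_mean=5)
        assert list(kept.counts.index) == ["g1"]

    def test_gene_low_in_only_one_condition_kept(self):
        cm = make_cm([[4.0, 6.0]])
        kept = filter_low_expression(cm, min_mean=5)
        assert list(kept.counts.index) == ["g0"]

    def test_zero_threshold_is_identity_and_filter_idempotent(self):
        rng = np.random.default_rng(0)
        cm = make_cm(rng.poisson(6, size=(30, 4)).astype(float))
        assert filter_low_expression(cm, 0).counts.equals(cm.counts)
        once = filter_low_expression(cm, 5)
        twice = filter_low_expression(once, 5)
        assert once.counts.equals(twice.counts)


class TestCountMatrixContracts:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            make_cm([[-1.0, 2.0]])

    def test_exactly_two_conditions_required(self):
        counts = pd.DataFrame([[1.0, 2.0, 3.0]], columns=["a", "b", "c"],
                              index=["g0"])
        with pytest.raises(ValueError):
            CountMatrix(counts, {"a": "x", "b": "y", "c": "z"})

    def test_condition_means(self):
        cm = make_cm([[2.0, 4.0, 10.0, 20.0]],
                     conditions={"s0": "c1", "s1": "c1",
                                 "s2": "c2", "s3": "c2"})
        means = cm.condition_means()
        assert means.loc["g0", "c1"] == 3.0
        assert means.loc["g0", "c2"] == 15.0
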