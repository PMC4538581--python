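import math

import numpy as np
import pandas as pd
import pytest

from declamp import (
    ablation_run,
    loocv_scores,
    nb_score,
    nb_train,
    rank_genes,
    roc_auc,
    simulate_training_table,
)
from declamp.classifier import NBModel


def make_table(de, nde, attrs=("FC", "ARPK", "GCC")):
    rows = []
    for i, x in enumerate(de):
        rows.append({"gene_id": f"d{i}", "label": "DE",
                     **dict(zip(attrs, np.atleast_1d(x)))})
    for i, x in enumerate(nde):
        rows.append({"gene_id": f"n{i}", "label": "NDE",
                     **dict(zip(attrs, np.atleast_1d(x)))})
    return pd.DataFrame(rows).set_index("gene_id")


def bayes_oracle(x, priors, means, variances):
    """Direct Bayes-rule evaluation with explicit Gaussian densities."""

    def lik(ci):
        out = 1.0
        for j, xv in enumerate(x):
            var = variances[ci][j]
            out *= math.exp(-((xv - means[ci][j]) ** 2) / (2 * var)) \
                / math.sqrt(2 * math.pi * var)
        return out

    num = priors[0] * lik(0)
    den = num + priors[1] * lik(1)
    return num / den


class TestNBTrain:
    def test_equal_class_sizes_give_half_priors(self):
        table = make_table(de=[[0.2, 0.5, 0.5]] * 4 + [[0.3, 0.4, 0.5]] * 2,
                           nde=[[0.9, 0.5, 0.5]] * 6)
        model = nb_train(table)
        assert model.priors.tolist() == [0.5, 0.5]

    def test_parameter_recovery_on_gaussian_classes(self):
        rng = np.random.default_rng(42)
        n = 500
        mu = {"DE": (0.3, 0.6, 0.5), "NDE": (0.8, 0.4, 0.5)}
        sigma = 0.05
        table = make_table(
            de=rng.normal(mu["DE"], sigma, size=(n, 3)),
            nde=rng.normal(mu["NDE"], sigma, size=(n, 3)),
        )
        model = nb_train(table)
        tol = 3 * sigma / math.sqrt(n)
        assert np.allclose(model.means[0], mu["DE"], atol=tol)
        assert np.allclose(model.means[1], mu["NDE"], atol=tol)
        assert np.allclose(np.sqrt(model.variances), sigma, rtol=0.2)

    def test_single_attribute_subset(self):
        table = make_table(de=[[0.2]] * 3, nde=[[0.9]] * 3, attrs=("FC",))
        model = nb_train(table, attributes=("FC",))
        assert model.attributes == ("FC",)
        assert model.means.shape == (2, 1)

    def test_missing_class_rejected(self):
        table = make_table(de=[[0.2, 0.5, 0.5]] * 3, nde=[])
        with pytest.raises(ValueError):
            nb_train(table)

    def test_zero_variance_column_floored(self):
        table = make_table(de=[[0.2, 0.5, 0.5]] * 5,
                           nde=[[0.9, 0.5, 0.5]] * 5)
        model = nb_train(table)
        assert (model.variances >= model.variance_floor).all()

    def test_empty_attribute_subset_rejected(self):
        table = make_table(de=[[0.2, 0.5, 0.5]] * 3,
                           nde=[[0.9, 0.5, 0.5]] * 3)
        with pytest.raises(ValueError):
            nb_train(table, attributes=())


class TestNBScore:
    def test_identical_class_distributions_score_half(self):
        model = NBModel(("FC",), ("DE", "NDE"), np.array([0.5, 0.5]),
                        means=np.array([[0.5], [0.5]]),
                        variances=np.array([[0.01], [0.01]]))
        x = pd.DataFrame({"FC": [0.1, 0.5, 0.9]})
        assert np.allclose(nb_score(model, x), 0.5)

    def test_symmetric_midpoint_scores_half(self):
        model = NBModel(("FC",), ("DE", "NDE"), np.array([0.5, 0.5]),
                        means=np.array([[1.0], [0.0]]),
                        variances=np.array([[1.0], [1.0]]))
        assert nb_score(model, pd.DataFrame({"FC": [0.5]}))[0] \
            == pytest.approx(0.5)

    def test_matches_bayes_rule_oracle_on_random_models(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            k = int(rng.integers(1, 4))
            attrs = tuple(f"f{j}" for j in range(k))
            p = float(rng.uniform(0.1, 0.9))
            priors = np.array([p, 1 - p])
            means = rng.uniform(0, 1, size=(2, k))
            variances = rng.uniform(1e-3, 0.2, size=(2, k))
            model = NBModel(attrs, ("DE", "NDE"), priors, means, variances)
            x = rng.uniform(0, 1, size=k)
            got = nb_score(model, pd.DataFrame([dict(zip(attrs, x))]))[0]
            want = bayes_oracle(x, priors, means, variances)
            assert got == pytest.approx(want, abs=1e-12)

    def test_posterior_normalization(self):
        rng = np.random.default_rng(9)
        model = NBModel(("a", "b"), ("DE", "NDE"), np.array([0.3, 0.7]),
                        means=rng.uniform(0, 1, (2, 2)),
                        variances=rng.uniform(0.01, 0.1, (2, 2)))
        swapped = NBModel(("a", "b"), ("DE", "NDE"),
                          model.priors[::-1].copy(),
                          model.means[::-1].copy(),
                          model.variances[::-1].copy())
        x = pd.DataFrame({"a": rng.uniform(0, 1, 20),
                          "b": rng.uniform(0, 1, 20)})
        assert np.allclose(nb_score(model, x) + nb_score(swapped, x), 1.0)

    def test_far_tail_inputs_stay_finite(self):
        # log-space evaluation: scores defined even 1000 sigmas out
        model = NBModel(("FC",), ("DE", "NDE"), np.array([0.5, 0.5]),
                        means=np.array([[0.4], [0.6]]),
                        variances=np.array([[1e-6], [1e-6]]))
        s = nb_score(model, pd.DataFrame({"FC": [100.0, -100.0]}))
        assert np.isfinite(s).all()
        assert 0 <= s.min() and s.max() <= 1


class TestLOOCV:
    def test_matches_explicit_retrains_on_toy_set(self):
        table = make_table(de=[[0.2, 0.5, 0.4], [0.3, 0.6, 0.5]],
                           nde=[[0.8, 0.5, 0.6], [0.9, 0.4, 0.5]])
        scores = loocv_scores(table)
        for gid in table.index:
            rest = table.drop(index=gid)
            model = nb_train(rest)
            expected = nb_score(model, table.loc[gid])[0]
            assert scores[gid] == pytest.approx(expected, abs=1e-12)

    def test_duplicated_rows_get_equal_scores(self):
        row_de = [0.25, 0.55, 0.45]
        table = make_table(de=[row_de, row_de, [0.3, 0.5, 0.5]],
                           nde=[[0.85, 0.5, 0.55]] * 3)
        scores = loocv_scores(table)
        assert scores["d0"] == pytest.approx(scores["d1"])

    def test_invariant_to_row_order(self):
        rng = np.random.default_rng(3)
        table = make_table(de=rng.uniform(0, 0.5, (10, 3)),
                           nde=rng.uniform(0.5, 1, (10, 3)))
        shuffled = table.sample(frac=1.0, random_state=0)
        s1 = loocv_scores(table)
        s2 = loocv_scores(shuffled)
        assert np.allclose(s1.sort_index(), s2.sort_index())

    def test_class_emptied_by_removal_rejected(self):
        table = make_table(de=[[0.2, 0.5, 0.5]],
                           nde=[[0.9, 0.5, 0.5]] * 4)
        with pytest.raises(ValueError):
            loocv_scores(table)


def auc_pair_counting(scores, labels):
    """(concordant + half-tied) / (n_pos * n_neg) over all pos-neg pairs."""
    pos = [s for s, l in zip(scores, labels) if l == "DE"]
    neg = [s for s, l in zip(scores, labels) if l == "NDE"]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation_gives_auc_one(self):
        scores = pd.Series([0.9, 0.8, 0.2, 0.1])
        labels = pd.Series(["DE", "DE", "NDE", "NDE"])
        res = roc_auc(scores, labels)
        assert res.auc == pytest.approx(1.0)
        assert res.fpr[0] == 0.0 and res.tpr[-1] == 1.0

    def test_matches_pair_counting_oracle_on_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            n = int(rng.integers(4, 51))
            labels = ["DE"] * (n // 2) + ["NDE"] * (n - n // 2)
            # coarse grid forces plenty of ties
            scores = rng.choice(np.linspace(0, 1, 5), size=n)
            got = roc_auc(np.asarray(scores), np.asarray(labels)).auc
            want = auc_pair_counting(scores, labels)
            assert got == pytest.approx(want, abs=1e-12)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(2024)
        n = 2000
        labels = np.array(["DE"] * (n // 2) + ["NDE"] * (n // 2))
        scores = rng.uniform(size=n)
        assert roc_auc(scores, labels).auc == pytest.approx(0.5, abs=0.04)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.9]), np.array(["DE", "DE"]))

    def test_roc_curve_monotone(self):
        rng = np.random.default_rng(5)
        scores = rng.uniform(size=100)
        labels = np.where(rng.uniform(size=100) < 0.4, "DE", "NDE")
        res = roc_auc(scores, labels)
        assert (np.diff(res.fpr) >= 0).all()
        assert (np.diff(res.tpr) >= 0).all()


class TestRanking:
    def test_stable_ordering_by_score_then_id(self):
        scores = pd.Series({"b": 0.5, "a": 0.5, "c": 0.9})
        ranked = rank_genes(scores)
        assert list(ranked.index) == ["c", "a", "b"]
        assert ranked["rank"].tolist() == [1, 2, 3]


class TestAblation:
    def make_fc_only_signal(self):
        rng = np.random.default_rng(21)
        n = 80
        de = np.column_stack([
            rng.normal(0.25, 0.03, n),   # FC separates classes
            rng.normal(0.5, 0.05, n),    # ARPK identical
            rng.normal(0.5, 0.05, n),    # GCC identical
        ])
        nde = np.column_stack([
            rng.normal(0.85, 0.03, n),
            rng.normal(0.5, 0.05, n),
            rng.normal(0.5, 0.05, n),
        ])
        return make_table(de=de, nde=nde)

    def test_removing_the_informative_attribute_destroys_auc(self):
        table = self.make_fc_only_signal()
        aucs = ablation_run(table)
        assert set(aucs) == {"all", "-FC", "-ARPK", "-GCC"}
        assert aucs["all"] > 0.95
        assert aucs["-FC"] == pytest.approx(0.5, abs=0.1)
        assert aucs["-ARPK"] > 0.95 and aucs["-GCC"] > 0.95

    def test_full_model_at_least_as_good_as_any_ablated(self):
        table = self.make_fc_only_signal()
        aucs = ablation_run(table)
        for key in ("-FC", "-ARPK", "-GCC"):
            assert aucs["all"] >= aucs[key] - 0.02

    def test_full_subset_equals_default_loocv(self):
        table = self.make_fc_only_signal()
        aucs = ablation_run(table)
        default = roc_auc(loocv_scores(table), table["label"]).auc
        assert aucs["all"] == pytest.approx(default)


class TestEndToEndTrainingTable:
    def test_strong_effect_table_loocv_auc_high(self):
        table = simulate_training_table(
            120, 120, seed=31,
            de_log2fc_range=(2.0, 4.0), nde_log2fc_range=(0.0, 0.0),
        )
        scores = loocv_scores(table)
        assert roc_auc(scores, table["label"]).auc > 0.9
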