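"""Gaussian naive Bayes scoring of genes for differential expression.

Given the three bounded attributes, a gene's posterior probability of being
differentially expressed is

    p(DE | f) = p(DE) Π_i φ(f_i; µ_DE,i, σ²_DE,i) / Σ_C p(C) Π_i φ(f_i; ...)

with one univariate Gaussian per class and attribute (the conditional
independence assumption) and class priors estimated as training frequencies.
Likelihoods are combined in log space; variances are floored to keep
degenerate training columns from producing infinities.  Sample variances use
the n−1 denominator.

Evaluation follows the ranking protocol: genes ordered by descending
posterior score, the DE call set grown one gene at a time, true/false
positive rates traced into a ROC curve whose area equals the tie-corrected
Mann–Whitney statistic.  Leave-one-out cross-validation scores each labeled
gene with a model trained on all the others.  Attribute ablation retrains on
each subset that omits one attribute.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .features import FEATURE_COLUMNS, LABEL_DE, LABEL_NDE

DEFAULT_VARIANCE_FLOOR = 1e-9  # on [0,1]-scaled attributes

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class NBModel:
    """Per-class priors and per-attribute Gaussian parameters."""

    attributes: tuple[str, ...]
    classes: tuple[str, ...]          # (DE, NDE)
    priors: np.ndarray                # shape (2,)
    means: np.ndarray                 # shape (2, n_attr)
    variances: np.ndarray             # shape (2, n_attr), floored
    variance_floor: float = DEFAULT_VARIANCE_FLOOR
    n_train: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({
                "attributes": list(self.attributes),
                "classes": list(self.classes),
                "priors": self.priors.tolist(),
                "means": self.means.tolist(),
                "variances": self.variances.tolist(),
                "variance_floor": self.variance_floor,
                "n_train": self.n_train,
            }, fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "NBModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            attributes=tuple(d["attributes"]),
            classes=tuple(d["classes"]),
            priors=np.array(d["priors"]),
            means=np.array(d["means"]),
            variances=np.array(d["variances"]),
            variance_floor=d["variance_floor"],
            n_train={k: int(v) for k, v in d.get("n_train", {}).items()},
        )


def nb_train(
    table: pd.DataFrame,
    attributes: tuple[str, ...] = FEATURE_COLUMNS,
    variance_floor: float = DEFAULT_VARIANCE_FLOOR,
) -> NBModel:
    """Fit the two-class Gaussian naive Bayes model by maximum likelihood.

    ``table`` needs the attribute columns plus a ``label`` column restricted
    to DE/NDE (no-call rows must be excluded by the caller).  Requires at
    least two examples per class so variances are defined.
    """
    if not attributes:
        raise ValueError("attribute subset must be nonempty")
    missing = [a for a in attributes if a not in table.columns]
    if missing:
        raise ValueError(f"table lacks attribute columns {missing}")
    classes = (LABEL_DE, LABEL_NDE)
    counts = {}
    means = np.empty((2, len(attributes)))
    variances = np.empty((2, len(attributes)))
    for ci, cls in enumerate(classes):
        sub = table.loc[table["label"] == cls, list(attributes)]
        if len(sub) < 1:
            raise ValueError(f"no training examples of class {cls}")
        counts[cls] = len(sub)
        means[ci] = sub.mean(axis=0).to_numpy()
        # a single-example class has no sample variance; it degrades to the
        # floor, same as a zero-variance column
        variances[ci] = np.nan_to_num(sub.var(axis=0, ddof=1).to_numpy())
    n_total = sum(counts.values())
    priors = np.array([counts[c] / n_total for c in classes])
    variances = np.maximum(variances, variance_floor)
    return NBModel(
        attributes=tuple(attributes),
        classes=classes,
        priors=priors,
        means=means,
        variances=variances,
        variance_floor=variance_floor,
        n_train=counts,
    )


def nb_score(model: NBModel, features: pd.DataFrame | pd.Series) -> np.ndarray:
    """Posterior p(DE | f) for one or many feature rows, computed in log space.

    Accepts a Series (one gene) or DataFrame; returns a 1-D array of scores
    in [0, 1].  p(DE|f) + p(NDE|f) = 1 by construction.
    """
    if isinstance(features, pd.Series):
        x = features[list(model.attributes)].to_numpy(dtype=float)[None, :]
    else:
        x = features[list(model.attributes)].to_numpy(dtype=float)
    # log N(x; µ, σ²) summed over attributes, per class
    log_lik = -0.5 * (
        _LOG_2PI + np.log(model.variances)[None, :, :]
        + (x[:, None, :] - model.means[None, :, :]) ** 2
        / model.variances[None, :, :]
    ).sum(axis=2)
    log_joint = np.log(model.priors)[None, :] + log_lik
    # normalize with the log-sum-exp trick
    m = log_joint.max(axis=1, keepdims=True)
    log_post = log_joint - (m + np.log(np.exp(log_joint - m).sum(axis=1,
                                                                 keepdims=True)))
    return np.exp(log_post[:, 0])


def loocv_scores(
    table: pd.DataFrame,
    attributes: tuple[str, ...] = FEATURE_COLUMNS,
    variance_floor: float = DEFAULT_VARIANCE_FLOOR,
) -> pd.Series:
    """Leave-one-out posterior score for every labeled gene.

    Each gene is scored by a model trained on all the other genes.  Class
    sufficient statistics (count, sum, sum of squares) are downdated per
    left-out row rather than refit from scratch, which is algebraically
    identical to a full retrain and keeps LOOCV linear in table size.
    Deterministic and invariant to row order.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 labeled examples for LOOCV")
    classes = (LABEL_DE, LABEL_NDE)
    X = table[list(attributes)].to_numpy(dtype=float)
    y = table["label"].to_numpy()
    stats = {}
    for cls in classes:
        sub = X[y == cls]
        if len(sub) < 2:
            raise ValueError(
                f"class {cls} needs ≥2 examples so it survives every "
                f"single removal"
            )
        stats[cls] = (len(sub), sub.sum(axis=0), (sub ** 2).sum(axis=0))
    n_total = len(X)

    scores = np.empty(n_total)
    for i in range(n_total):
        means = np.empty((2, len(attributes)))
        variances = np.empty((2, len(attributes)))
        priors = np.empty(2)
        for ci, cls in enumerate(classes):
            n, s, ss = stats[cls]
            if y[i] == cls:
                n, s, ss = n - 1, s - X[i], ss - X[i] ** 2
            means[ci] = s / n
            if n > 1:
                variances[ci] = np.maximum(
                    (ss - s ** 2 / n) / (n - 1), variance_floor
                )
            else:
                variances[ci] = variance_floor
            priors[ci] = n
        priors /= priors.sum()
        model = NBModel(tuple(attributes), classes, priors, means, variances,
                        variance_floor)
        scores[i] = nb_score(
            model, pd.DataFrame(X[i:i + 1], columns=list(attributes))
        )[0]
    return pd.Series(scores, index=table.index, name="score")


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_auc(scores: pd.Series | np.ndarray, labels: pd.Series | np.ndarray,
            positive_label: str = LABEL_DE) -> ROCResult:
    """ROC curve and AUC for gene scores against binary labels.

    The threshold is stepped through the distinct score values (equivalently,
    the predicted-DE set grows one gene at a time, jumping over ties) and the
    area is the trapezoidal integral, which equals the tie-corrected
    Mann–Whitney statistic (concordant + ½·tied pairs) / (n_pos · n_neg).
    """
    y = np.asarray(labels) == positive_label
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("both positive and negative labels required")
    fpr, tpr, thr = roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


def rank_genes(scores: pd.Series) -> pd.DataFrame:
    """Stable ranking by (score desc, gene_id asc); rank 1 = most likely DE."""
    df = scores.rename("score").rename_axis("gene_id").reset_index()
    df = df.sort_values(["score", "gene_id"],
                        ascending=[False, True], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.set_index("gene_id")


def ablation_run(
    table: pd.DataFrame,
    attributes: tuple[str, ...] = FEATURE_COLUMNS,
    variance_floor: float = DEFAULT_VARIANCE_FLOOR,
) -> dict[str, float]:
    """LOOCV AUC for the full attribute set and for each leave-one-out subset.

    Keys: ``"all"`` plus ``"-<attr>"`` per omitted attribute.
    """
    out: dict[str, float] = {}
    subsets: dict[str, tuple[str, ...]] = {"all": tuple(attributes)}
    for a in attributes:
        subsets[f"-{a}"] = tuple(b for b in attributes if b != a)
    for name, attrs in subsets.items():
        scores = loocv_scores(table, attributes=attrs,
                              variance_floor=variance_floor)
        out[name] = roc_auc(scores, table["label"]).auc
    return out
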