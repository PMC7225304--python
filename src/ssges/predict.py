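"""Multi-method class prediction with leave-one-out cross-validation.

Six classifiers, matching the standard microarray "multiple methods"
roster: compound covariate predictor (CCP), diagonal linear discriminant
analysis (DLDA), nearest centroid (NC), 1- and 3-nearest neighbours, and
a linear support vector machine.  CCP and DLDA are implemented here as
sklearn-style estimators; NC, kNN and SVM delegate to scikit-learn.

:func:`loocv_predict` runs honest leave-one-out cross-validation:
within every fold, genes are re-selected by a pooled t-test at the given
alpha on the training samples only, so the held-out sample never
influences feature selection.  A "fixed-list" mode skips re-selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.neighbors import KNeighborsClassifier, NearestCentroid
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from . import diffexp

__all__ = [
    "METHODS",
    "CompoundCovariateClassifier",
    "DiagonalLDA",
    "make_classifier",
    "classify",
    "loocv_predict",
    "PredictionReport",
]

METHODS = ("CCP", "DLDA", "NC", "1NN", "3NN", "SVM")


def _pooled_t_weights(X: np.ndarray, y01: np.ndarray):
    """Per-gene pooled t statistics (class 0 minus class 1) and validity mask."""
    X0, X1 = X[y01 == 0], X[y01 == 1]
    n0, n1 = len(X0), len(X1)
    m0, m1 = X0.mean(axis=0), X1.mean(axis=0)
    v0 = X0.var(axis=0, ddof=1) if n0 > 1 else np.zeros(X.shape[1])
    v1 = X1.var(axis=0, ddof=1) if n1 > 1 else np.zeros(X.shape[1])
    df = n0 + n1 - 2
    pooled = ((n0 - 1) * v0 + (n1 - 1) * v1) / max(df, 1)
    se = np.sqrt(pooled * (1 / n0 + 1 / n1))
    ok = se > 0
    t = np.zeros(X.shape[1])
    t[ok] = (m0[ok] - m1[ok]) / se[ok]
    return t, ok, pooled


class CompoundCovariateClassifier(BaseEstimator, ClassifierMixin):
    """Compound covariate predictor for two classes.

    A sample's score is the t-weighted sum of its gene expressions,
    Σ_g t_g · x_g, with t_g the pooled two-sample t statistic from the
    training data; the decision threshold is the midpoint of the two
    class-mean scores.  Zero-variance genes are dropped with a warning.
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.classes_, y01 = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise ValueError("CCP is a two-class method")
        t, ok, _ = _pooled_t_weights(X, y01)
        if not ok.all():
            warnings.warn("CCP: zero-variance genes dropped")
        self.weights_ = np.where(ok, t, 0.0)
        scores = X @ self.weights_
        self.threshold_ = 0.5 * (scores[y01 == 0].mean() + scores[y01 == 1].mean())
        # class 0 has the larger mean score iff its t-weighted mean is larger
        self.class0_high_ = scores[y01 == 0].mean() >= scores[y01 == 1].mean()
        return self

    def decision_function(self, X):
        check_is_fitted(self, "weights_")
        return np.asarray(X, dtype=float) @ self.weights_ - self.threshold_

    def predict(self, X):
        s = self.decision_function(X)
        if self.class0_high_:
            idx = np.where(s >= 0, 0, 1)
        else:
            idx = np.where(s >= 0, 1, 0)
        return self.classes_[idx]


class DiagonalLDA(BaseEstimator, ClassifierMixin):
    """Diagonal linear discriminant analysis.

    Gaussian classifier with per-gene pooled variances and no
    covariance: predict argmin_c Σ_g (x_g − x̄_cg)² / s_g².  Genes with
    zero pooled variance are dropped with a warning.
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.classes_, y01 = np.unique(y, return_inverse=True)
        t, ok, pooled = _pooled_t_weights(X, y01) if len(self.classes_) == 2 else (
            None,
            None,
            None,
        )
        if pooled is None:  # pooled variance across any number of classes
            resid = np.concatenate(
                [X[y01 == c] - X[y01 == c].mean(axis=0) for c in range(len(self.classes_))]
            )
            pooled = resid.var(axis=0, ddof=len(self.classes_))
            ok = pooled > 0
        if not ok.all():
            warnings.warn("DLDA: zero-variance genes dropped")
        self.ok_ = ok
        self.var_ = np.where(ok, pooled, 1.0)
        self.means_ = np.vstack(
            [X[y01 == c].mean(axis=0) for c in range(len(self.classes_))]
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "means_")
        X = np.asarray(X, dtype=float)
        dists = np.stack(
            [
                np.sum(
                    np.where(self.ok_, (X - mu) ** 2 / self.var_, 0.0), axis=1
                )
                for mu in self.means_
            ]
        )
        return self.classes_[np.argmin(dists, axis=0)]


def make_classifier(method: str) -> BaseEstimator:
    """Instantiate one of the roster's classifiers by name."""
    if method == "CCP":
        return CompoundCovariateClassifier()
    if method == "DLDA":
        return DiagonalLDA()
    if method == "NC":
        return NearestCentroid()
    if method == "1NN":
        return KNeighborsClassifier(n_neighbors=1)
    if method == "3NN":
        return KNeighborsClassifier(n_neighbors=3)
    if method == "SVM":
        return SVC(kernel="linear", C=1.0)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def classify(method: str, train_X, train_y, test_vector) -> object:
    """Train one method and classify a single test vector."""
    clf = make_classifier(method)
    clf.fit(np.asarray(train_X, dtype=float), np.asarray(train_y))
    test = np.asarray(test_vector, dtype=float).reshape(1, -1)
    return clf.predict(test)[0]


@dataclass
class PredictionReport:
    """LOOCV outcome: per-method rates, per-sample calls, mean rate."""

    rates: dict
    calls: pd.DataFrame  # index sample_id; columns: truth + one per method
    mean_rate: float
    flagged_folds: list = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        n = len(self.calls)
        rows = [
            {
                "method": mth,
                "n_correct": int(round(rate * n)),
                "n_total": n,
                "rate": rate,
            }
            for mth, rate in self.rates.items()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _impute_train_means(train: np.ndarray, test: np.ndarray):
    """Replace missing entries by training-fold per-gene means."""
    mu = np.nanmean(train, axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    tr = np.where(np.isnan(train), mu, train)
    te = np.where(np.isnan(test), mu, test)
    return tr, te


def loocv_predict(
    m: pd.DataFrame,
    groups: Sequence,
    gene_list: Sequence[str],
    alpha: float = 0.01,
    methods: Sequence[str] = METHODS,
    seed: int = 0,
    reselect: bool = True,
) -> PredictionReport:
    """Leave-one-out multi-method prediction over a gene list.

    ``m`` is genes × samples; ``groups`` a two-level label per sample.
    For each held-out sample the matrix is restricted to ``gene_list``,
    genes are re-selected at ``alpha`` by pooled t-test on the training
    fold only (unless ``reselect=False``), every method is trained, and
    the held-out sample is predicted.  Folds whose selected-gene set is
    empty fall back to the training majority class and are flagged.
    """
    gene_list = list(gene_list)
    present = [g for g in gene_list if g in m.index]
    if len(present) == 0:
        raise ValueError("gene_list is disjoint from the matrix genes")
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError("loocv_predict requires exactly two classes")
    for lv in levels:
        if (groups == lv).sum() < 2:
            raise ValueError(f"class {lv!r} has fewer than 2 samples")

    sub = m.loc[present]
    X = sub.to_numpy(dtype=float).T  # samples x genes
    n = X.shape[0]
    calls = {mth: [] for mth in methods}
    flagged = []
    for i in range(n):
        tr_idx = np.arange(n) != i
        train_m = sub.iloc[:, tr_idx]
        train_y = groups[tr_idx]
        if reselect:
            res = diffexp.ttest_per_gene(train_m, train_y, levels=list(levels))
            selected = diffexp.select_significant(res, alpha)
        else:
            selected = present
        if len(selected) == 0:
            maj = levels[np.argmax([(train_y == lv).sum() for lv in levels])]
            flagged.append(str(sub.columns[i]))
            for mth in methods:
                calls[mth].append(maj)
            continue
        rows = [present.index(g) for g in selected]
        tr = X[tr_idx][:, rows]
        te = X[i, rows]
        tr, te = _impute_train_means(tr, te)
        for mth in methods:
            calls[mth].append(classify(mth, tr, train_y, te))

    truth = pd.Series(groups, index=m.columns, name="truth")
    call_df = pd.DataFrame({"truth": truth})
    rates = {}
    for mth in methods:
        call_df[mth] = calls[mth]
        rates[mth] = float(np.mean(np.asarray(calls[mth]) == groups))
    mean_rate = float(np.mean(list(rates.values())))
    return PredictionReport(
        rates=rates,
        calls=call_df,
        mean_rate=mean_rate,
        flagged_folds=flagged,
        config={
            "gene_list_size": len(present),
            "alpha": alpha,
            "seed": seed,
            "reselect": reselect,
            "methods": list(methods),
        },
    )
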