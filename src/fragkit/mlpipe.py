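"""Interval-feature classification: ANOVA F selection + logistic regression
under repeated stratified k-fold cross-validation.

The pipeline mirrors the standard interval-MDS cancer-detection analysis:
per cross-validation fold, the top-k features by one-way ANOVA F statistic
are selected on the training portion only (no leakage into the held-out
fold), an L2-penalized logistic regression (C=1.0, tol=1e-4, lbfgs, up to
100 iterations, no class weighting) is fit on the training portion, and the
held-out samples are scored; the fold AUC is the rank-based ROC AUC. The
reported AUC is the mean over all folds and repeats. A fixed seed makes the
fold sequence reproducible and reusable across feature sets, enabling paired
comparison between genome-wide and interval-level features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import RepeatedStratifiedKFold

__all__ = ["FeatureMatrix", "CvResult", "anova_f_scores", "roc_auc", "cv_auc"]


@dataclass
class FeatureMatrix:
    """Samples x intervals feature values with binary labels.

    Features containing any missing value across samples are dropped on
    construction (``n_dropped`` reports how many). Both classes must be
    present and no label may be missing.
    """

    samples: list[str]
    features: list[str]
    values: np.ndarray
    labels: np.ndarray
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.shape != (len(self.samples), len(self.features)):
            raise ValueError("values shape does not match samples x features")
        if len(self.labels) != len(self.samples):
            raise ValueError("one label per sample required")
        if np.any(self.labels == None) or (  # noqa: E711
            self.labels.dtype.kind == "f" and np.isnan(self.labels.astype(float)).any()
        ):
            raise ValueError("missing labels are not allowed")
        if len(np.unique(self.labels)) != 2:
            raise ValueError("exactly two classes required")
        keep = ~np.isnan(self.values).any(axis=0)
        self.n_dropped = int((~keep).sum())
        if self.n_dropped:
            self.values = self.values[:, keep]
            self.features = [f for f, k in zip(self.features, keep) if k]

    @classmethod
    def from_dataframe(cls, df, label_col: str = "label") -> "FeatureMatrix":
        """Build from a samples x (features + label) DataFrame."""
        labels = df[label_col].to_numpy()
        feats = df.drop(columns=[label_col])
        return cls(
            samples=[str(s) for s in df.index],
            features=[str(c) for c in feats.columns],
            values=feats.to_numpy(dtype=float),
            labels=labels,
        )


@dataclass
class CvResult:
    """Per-fold AUCs across folds x repeats, and per-fold selected features."""

    fold_aucs: np.ndarray
    selected_features: list[list[str]] = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))


def anova_f_scores(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """One-way ANOVA F statistic per feature (two classes).

    F = (between-class SS / (g-1)) / (within-class SS / (n-g)). Zero
    within-class variance with nonzero between-class variance yields inf.
    """
    values = np.asarray(values, dtype=float)
    classes = np.unique(labels)
    if any((labels == c).sum() < 2 for c in classes):
        raise ValueError("need >= 2 samples per class")
    n, g = len(labels), len(classes)
    grand = values.mean(axis=0)
    ssb = np.zeros(values.shape[1])
    ssw = np.zeros(values.shape[1])
    for c in classes:
        grp = values[labels == c]
        ssb += len(grp) * (grp.mean(axis=0) - grand) ** 2
        ssw += ((grp - grp.mean(axis=0)) ** 2).sum(axis=0)
    msb = ssb / (g - 1)
    msw = ssw / (n - g)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = msb / msw
    # zero within-class variance: infinite when between-class variance exists,
    # 0 for a constant feature
    f[np.isnan(f)] = 0.0
    return f


def select_top_k(f_scores: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest F scores; ties broken by feature order,
    infinite scores ranked above all finite ones."""
    if k > len(f_scores):
        raise ValueError(f"k={k} exceeds {len(f_scores)} available features")
    order = np.argsort(-f_scores, kind="stable")  # stable -> feature-order ties
    return np.sort(order[:k])


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based ROC AUC: P(score_case > score_control) + 0.5 P(tie).

    Equivalent to trapezoidal integration of the ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == np.max(labels)
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required for ROC AUC")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def cv_splits(
    labels: np.ndarray, n_folds: int = 10, n_repeats: int = 10, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """The deterministic (train, test) index sequence cv_auc iterates over.

    Exposed so the identical split sequence can be reused across feature
    sets for paired comparisons.
    """
    cv = RepeatedStratifiedKFold(n_splits=n_folds, n_repeats=n_repeats, random_state=seed)
    X_dummy = np.zeros((len(labels), 1))
    return list(cv.split(X_dummy, labels))


def cv_auc(
    matrix: FeatureMatrix,
    k_features: int,
    n_folds: int = 10,
    n_repeats: int = 10,
    seed: int = 0,
    pooled: bool = False,
) -> CvResult:
    """Repeated stratified k-fold CV AUC with in-fold ANOVA F selection.

    Feature selection and model fitting see only the training portion of
    each fold. Identical seeds give identical folds and results. With
    ``pooled`` the held-out scores of each repeat are pooled into a single
    ROC instead of averaging per-fold AUCs.
    """
    y = matrix.labels
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError("each class needs at least n_folds samples")
    if k_features > len(matrix.features):
        raise ValueError(
            f"k_features={k_features} exceeds {len(matrix.features)} features"
        )
    X = matrix.values
    ybin = (y == classes[-1]).astype(int)
    cv = RepeatedStratifiedKFold(
        n_splits=n_folds, n_repeats=n_repeats, random_state=seed
    )
    fold_aucs: list[float] = []
    selected: list[list[str]] = []
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    for train, test in cv.split(X, ybin):
        f = anova_f_scores(X[train], ybin[train])
        idx = select_top_k(f, k_features)
        selected.append([matrix.features[i] for i in idx])
        clf = LogisticRegression(
            penalty="l2", C=1.0, tol=1e-4, fit_intercept=True,
            solver="lbfgs", max_iter=100, class_weight=None,
        )
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")  # lbfgs convergence at max_iter is acceptable
            clf.fit(X[train][:, idx], ybin[train])
        scores = clf.decision_function(X[test][:, idx])
        if pooled:
            pooled_scores.append(scores)
            pooled_labels.append(ybin[test])
        else:
            fold_aucs.append(roc_auc(scores, ybin[test]))
    if pooled:
        n_per_repeat = n_folds
        all_s = np.concatenate(pooled_scores)
        all_y = np.concatenate(pooled_labels)
        # one pooled AUC per repeat
        sizes = [len(s) for s in pooled_scores]
        bounds = np.cumsum([0] + sizes)
        for r in range(n_repeats):
            lo, hi = bounds[r * n_per_repeat], bounds[(r + 1) * n_per_repeat]
            fold_aucs.append(roc_auc(all_s[lo:hi], all_y[lo:hi]))
    return CvResult(fold_aucs=np.asarray(fold_aucs), selected_features=selected)
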