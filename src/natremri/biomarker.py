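"""Tumour vs non-tumour classification from imaging biomarkers.

Linear discriminant analysis (Gaussian classes with a shared covariance)
built from first principles, leave-one-out cross-validation, independent
test-set evaluation, ROC/AUC, and principal component analysis with loading
vectors — the workflow used to compare the maximum sodium signal, the ADC
and their combination as classifiers of malignant regions.

The tumour class is the positive class throughout: sensitivity = TP/(TP+FN)
on tumour rows, specificity = TN/(TN+FP) on non-tumour rows.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

POSITIVE = "tumour"
NEGATIVE = "non_tumour"


@dataclass
class LDAModel:
    """Gaussian discriminant with shared (pooled) within-class covariance."""

    features: list[str]
    classes: list[str]  # [negative, positive] order is fixed at fit time
    means: np.ndarray  # (2, p)
    pooled_cov: np.ndarray  # (p, p), denominator n - 2
    priors: np.ndarray  # (2,)

    def __post_init__(self) -> None:
        if not np.allclose(self.pooled_cov, self.pooled_cov.T):
            raise ValueError("pooled covariance must be symmetric")
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("priors must sum to 1")

    def discriminant_scores(self, x: np.ndarray) -> np.ndarray:
        """Linear discriminant functions delta_k(x), shape (n, 2).

        delta_k(x) = x' Sigma^-1 mu_k - mu_k' Sigma^-1 mu_k / 2 + log pi_k.
        """
        x = np.atleast_2d(np.asarray(x, float))
        inv = np.linalg.inv(self.pooled_cov)
        scores = np.empty((x.shape[0], len(self.classes)))
        for k, (mu, pi) in enumerate(zip(self.means, self.priors)):
            w = inv @ mu
            scores[:, k] = x @ w - 0.5 * mu @ w + np.log(pi)
        return scores

    def posterior(self, x: np.ndarray) -> np.ndarray:
        """Class posterior probabilities, rows summing to 1."""
        scores = self.discriminant_scores(x)
        scores -= scores.max(axis=1, keepdims=True)
        p = np.exp(scores)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Class labels by highest posterior; ties go to the larger prior,
        then to the positive (tumour) class."""
        post = self.posterior(x)
        tied = np.isclose(post[:, 0], post[:, 1])
        pick = np.argmax(post, axis=1)
        if tied.any():
            if not np.isclose(self.priors[0], self.priors[1]):
                pick[tied] = int(np.argmax(self.priors))
            else:
                pick[tied] = self.classes.index(POSITIVE)
        return np.asarray(self.classes)[pick]

    def positive_score(self, x: np.ndarray) -> np.ndarray:
        """Posterior probability of the positive (tumour) class — the ROC score."""
        return self.posterior(x)[:, self.classes.index(POSITIVE)]

    # serialisation -----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "features": self.features,
                    "classes": self.classes,
                    "means": self.means.tolist(),
                    "pooled_cov": self.pooled_cov.tolist(),
                    "priors": self.priors.tolist(),
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "LDAModel":
        d = json.loads(Path(path).read_text())
        return cls(
            features=d["features"],
            classes=d["classes"],
            means=np.asarray(d["means"]),
            pooled_cov=np.asarray(d["pooled_cov"]),
            priors=np.asarray(d["priors"]),
        )


@dataclass
class ClassifierReport:
    tp: int
    fp: int
    tn: int
    fn: int
    roc_points: np.ndarray | None = None  # (m, 2) of (FPR, TPR)
    auc: float | None = None
    skipped_folds: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def confusion_matrix(self) -> np.ndarray:
        """Rows = true (tumour, non_tumour); columns = predicted."""
        return np.array([[self.tp, self.fn], [self.fp, self.tn]])


@dataclass
class PCAResult:
    features: list[str]
    loadings: np.ndarray  # columns are components, orthonormal
    explained_variance_ratio: np.ndarray
    scores: np.ndarray  # per-sample component scores


def _design(table: pd.DataFrame, features: list[str]) -> tuple[np.ndarray, np.ndarray]:
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise ValueError(f"features absent from the table: {missing}")
    x = table[list(features)].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("missing values in feature columns")
    y = table["region"].to_numpy()
    bad = set(y) - {POSITIVE, NEGATIVE}
    if bad:
        raise ValueError(f"unknown region labels: {sorted(bad)}")
    return x, y


def fit_lda(
    table: pd.DataFrame, features: list[str], equal_priors: bool = False
) -> LDAModel:
    """Fit an LDA model: class means, pooled within-class covariance
    (denominator n - 2) and class-frequency priors (equal priors by flag)."""
    x, y = _design(table, features)
    classes = [NEGATIVE, POSITIVE]
    counts = np.array([(y == c).sum() for c in classes])
    # single-sample classes contribute no scatter but keep a mean and prior,
    # so LOOCV remains defined on very small cohorts
    if (counts < 1).any():
        raise ValueError("each class needs at least 1 sample")
    n, p = x.shape
    if n <= p + 1:
        raise ValueError("need more samples than features + 1")
    means = np.stack([x[y == c].mean(axis=0) for c in classes])
    pooled = np.zeros((p, p))
    for c, mu in zip(classes, means):
        d = x[y == c] - mu
        pooled += d.T @ d
    pooled /= n - 2
    if np.linalg.cond(pooled) > 1e12:
        raise np.linalg.LinAlgError(
            "pooled covariance is singular (collinear or constant features); "
            "drop or standardise redundant features"
        )
    priors = np.full(2, 0.5) if equal_priors else counts / n
    return LDAModel(list(features), classes, means, pooled, priors)


def _report_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, skipped: int = 0
) -> ClassifierReport:
    tp = int(np.sum((y_true == POSITIVE) & (y_pred == POSITIVE)))
    fn = int(np.sum((y_true == POSITIVE) & (y_pred == NEGATIVE)))
    fp = int(np.sum((y_true == NEGATIVE) & (y_pred == POSITIVE)))
    tn = int(np.sum((y_true == NEGATIVE) & (y_pred == NEGATIVE)))
    return ClassifierReport(tp=tp, fp=fp, tn=tn, fn=fn, skipped_folds=skipped)


def loocv(
    table: pd.DataFrame, features: list[str], equal_priors: bool = False
) -> ClassifierReport:
    """Leave-one-out cross-validation: n refits, each scored on its held-out row.

    Appropriate for the small cohorts this assay produces. Folds whose
    training split loses a class entirely are skipped with a warning.
    """
    x, y = _design(table, features)
    n = len(x)
    if n < 4:
        raise ValueError("LOOCV needs at least 4 samples")
    preds, truths, skipped = [], [], 0
    for i in range(n):
        keep = np.ones(n, bool)
        keep[i] = False
        sub = table.iloc[keep].reset_index(drop=True)
        try:
            model = fit_lda(sub, features, equal_priors=equal_priors)
        except ValueError:
            skipped += 1
            warnings.warn(f"LOOCV fold {i} skipped: training split lost a class")
            continue
        preds.append(model.predict(x[i : i + 1])[0])
        truths.append(y[i])
    if not preds:
        raise RuntimeError("every LOOCV fold was degenerate; nothing to score")
    report = _report_from_predictions(np.asarray(truths), np.asarray(preds), skipped)
    return report


def evaluate_on_test(
    model: LDAModel, test_table: pd.DataFrame, with_roc: bool = True
) -> ClassifierReport:
    """Score a fitted model on an untouched independent test table."""
    x, y = _design(test_table, model.features)
    report = _report_from_predictions(y, model.predict(x))
    if with_roc and len(set(y)) == 2:
        points, auc = roc_auc(model.positive_score(x), y == POSITIVE)
        report.roc_points, report.auc = points, auc
    return report


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC curve over all score thresholds and its trapezoidal area.

    The AUC equals the Mann-Whitney pair-win fraction: the probability that
    a random positive outscores a random negative, ties counted 1/2. It is
    invariant under strictly increasing transforms of the scores.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    s, l = scores[order], labels[order]
    fpr, tpr = [0.0], [0.0]
    tp = fp = 0
    for i in range(len(s)):
        tp += l[i]
        fp += ~l[i]
        if i + 1 == len(s) or s[i + 1] != s[i]:  # emit a point per threshold
            tpr.append(tp / n_pos)
            fpr.append(fp / n_neg)
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(points[:, 1], points[:, 0]))
    return points, auc


def pca(table: pd.DataFrame, features: list[str], scaling: str = "correlation") -> PCAResult:
    """Principal components of the selected features.

    ``scaling="correlation"`` (default, appropriate for incommensurate units
    such as phantom-normalised signal vs mm^2/s) standardises features
    before the eigen-decomposition; ``"covariance"`` uses centred features
    as-is. Loadings are signed so each component's first nonzero entry is
    positive.
    """
    x = table[list(features)].to_numpy(dtype=float)
    if x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("PCA needs at least 3 samples and 2 features")
    centred = x - x.mean(axis=0)
    if scaling == "correlation":
        sd = centred.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance feature under correlation scaling")
        centred = centred / sd
    elif scaling != "covariance":
        raise ValueError(f"unknown scaling {scaling!r}")
    cov = centred.T @ centred / (x.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    for j in range(eigvec.shape[1]):  # deterministic sign convention
        nz = np.flatnonzero(np.abs(eigvec[:, j]) > 1e-12)
        if nz.size and eigvec[nz[0], j] < 0:
            eigvec[:, j] *= -1
    total = eigval.sum()
    return PCAResult(
        features=list(features),
        loadings=eigvec,
        explained_variance_ratio=eigval / total if total > 0 else eigval,
        scores=centred @ eigvec,
    )


def concentration_ellipse(
    x: np.ndarray, level: float = 0.95
) -> tuple[np.ndarray, np.ndarray, float]:
    """Gaussian covariance ellipse of 2-D points at the given coverage level.

    Returns (centre, semi-axes lengths, rotation angle in radians). This is
    the Gaussian-model ellipse (chi-square quantile of the sample
    covariance), one of several possible "concentration ellipse" readings.
    """
    from scipy.stats import chi2

    x = np.asarray(x, float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("expected (n, 2) points")
    centre = x.mean(axis=0)
    cov = np.cov(x, rowvar=False)
    eigval, eigvec = np.linalg.eigh(cov)
    scale = chi2.ppf(level, df=2)
    semi = np.sqrt(eigval[::-1] * scale)
    angle = float(np.arctan2(eigvec[1, -1], eigvec[0, -1]))
    return centre, semi, angle
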