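"""Single-feature linear-SVM classification with cross-validated ROC and DeLong tests.

Each feature (a fitted model parameter or a behavioural error) is assessed
by a linear-kernel SVM under a repeated stratified 60/40 hold-out: per
repetition the SVM is trained on 60% of participants and scored on the held
out 40%, yielding a ROC/AUC; curves are averaged on a fixed
false-positive-rate grid and AUCs are averaged across repetitions.
Correlated AUCs are compared with DeLong's covariance-based z-test, either
per repetition (fraction of significant repetitions) or once on posterior
scores averaged over repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "RocResult",
    "DelongResult",
    "svm_roc",
    "delong_test",
    "per_repetition_delong",
    "averaged_posterior_delong",
]


@dataclass
class RocResult:
    feature: str
    aucs: np.ndarray  # one AUC per repetition
    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    mean_posterior: np.ndarray  # held-out posterior per subject, averaged over reps
    labels: np.ndarray
    test_indices: list = field(repr=False, default_factory=list)
    test_scores: list = field(repr=False, default_factory=list)

    @property
    def mean_auc(self) -> float:
        return float(self.aucs.mean())


def _roc_points(labels, scores):
    """ROC curve and AUC by threshold sweep (rank statistic)."""
    labels = np.asarray(labels, dtype=bool)
    order = np.argsort(-np.asarray(scores, dtype=float), kind="mergesort")
    y = labels[order]
    tps = np.cumsum(y)
    fps = np.cumsum(~y)
    tpr = np.concatenate([[0.0], tps / max(tps[-1], 1)])
    fpr = np.concatenate([[0.0], fps / max(fps[-1], 1)])
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def svm_roc(
    feature,
    labels,
    reps: int = 1000,
    holdout: float = 0.40,
    seed: int = 0,
    C: float = 1.0,
    feature_name: str = "feature",
    n_grid: int = 101,
) -> RocResult:
    """Repeated stratified hold-out linear-SVM ROC for a single feature.

    Stratified 60/40 splits keep both classes in every test set (a
    repetition whose test split would lack a class is redrawn).  Posterior
    probabilities come from the SVM's sigmoid calibration on the training
    fold; for a single-feature linear SVM the per-repetition ROC is
    invariant to that calibration.
    """
    x = np.asarray(feature, dtype=float).reshape(-1, 1)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) != 2:
        raise ValueError("need exactly two classes")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature values must be finite")
    splitter = StratifiedShuffleSplit(n_splits=reps, test_size=holdout, random_state=seed)
    fpr_grid = np.linspace(0.0, 1.0, n_grid)
    aucs = []
    tpr_sum = np.zeros(n_grid)
    post_sum = np.zeros(len(y))
    post_count = np.zeros(len(y))
    test_indices, test_scores = [], []
    for rep, (train, test) in enumerate(splitter.split(x, y)):
        if len(np.unique(y[test])) < 2:  # stratification guard; split is skipped
            continue
        # the feature is standardized inside the training fold: an unscaled
        # narrow-range feature gives the SVC a near-degenerate margin and an
        # unstable sigmoid-calibration slope
        base = make_pipeline(StandardScaler(), SVC(kernel="linear", C=C))
        clf = CalibratedClassifierCV(
            base, method="sigmoid", cv=min(5, np.bincount(y[train]).min()), ensemble=False
        )
        clf.fit(x[train], y[train])
        post = clf.predict_proba(x[test])[:, 1]
        fpr, tpr, auc = _roc_points(y[test], post)
        aucs.append(auc)
        tpr_sum += np.interp(fpr_grid, fpr, tpr)
        post_sum[test] += post
        post_count[test] += 1
        test_indices.append(test)
        test_scores.append(post)
    if not aucs:
        raise ValueError("no repetition had both classes in the test split")
    mean_posterior = np.divide(post_sum, post_count, out=np.full(len(y), np.nan), where=post_count > 0)
    return RocResult(
        feature=feature_name,
        aucs=np.asarray(aucs),
        fpr_grid=fpr_grid,
        mean_tpr=tpr_sum / len(aucs),
        mean_posterior=mean_posterior,
        labels=y,
        test_indices=test_indices,
        test_scores=test_scores,
    )


@dataclass
class DelongResult:
    auc_a: float
    auc_b: float
    z: float
    p: float
    var_a: float
    var_b: float
    cov: float


def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    ranks = np.empty(n, dtype=float)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n, dtype=float)
    out[order] = ranks
    return out


def _delong_components(labels: np.ndarray, scores: np.ndarray):
    """AUC and the DeLong structural components (V10, V01) of one classifier."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return auc, v10, v01


def delong_test(scores_a, scores_b, labels) -> DelongResult:
    """DeLong z-test for the difference of two correlated AUCs.

    Both score vectors must be paired on the same subjects.  Identical score
    vectors give z = 0, p = 1; degenerate (constant) scores with differing
    AUCs raise a ``ValueError`` (undefined variance).
    """
    labels = np.asarray(labels).astype(bool)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if not (len(a) == len(b) == len(labels)):
        raise ValueError("scores and labels must be paired")
    auc_a, v10_a, v01_a = _delong_components(labels, a)
    auc_b, v10_b, v01_b = _delong_components(labels, b)
    m, n = len(v10_a), len(v01_a)
    var_a = np.var(v10_a, ddof=1) / m + np.var(v01_a, ddof=1) / n
    var_b = np.var(v10_b, ddof=1) / m + np.var(v01_b, ddof=1) / n
    cov = (
        np.cov(np.vstack([v10_a, v10_b]))[0, 1] / m
        + np.cov(np.vstack([v01_a, v01_b]))[0, 1] / n
    )
    diff = auc_a - auc_b
    denom = var_a + var_b - 2.0 * cov
    if denom <= 0:
        if diff == 0:
            return DelongResult(auc_a, auc_b, 0.0, 1.0, var_a, var_b, cov)
        raise ValueError("degenerate scores: AUC-difference variance is not positive")
    z = diff / np.sqrt(denom)
    p = 2.0 * norm.sf(abs(z))
    return DelongResult(float(auc_a), float(auc_b), float(z), float(p), float(var_a), float(var_b), float(cov))


def per_repetition_delong(roc_a: RocResult, roc_b: RocResult, alpha: float = 0.05) -> float:
    """Fraction of repetitions with a significant DeLong AUC difference.

    The two ROC results must come from :func:`svm_roc` runs with the same
    labels and seed, so that repetition k used the same held-out subjects.
    """
    if len(roc_a.test_indices) != len(roc_b.test_indices):
        raise ValueError("mismatched repetition counts")
    n_sig = 0
    n_done = 0
    for idx_a, sa, idx_b, sb in zip(roc_a.test_indices, roc_a.test_scores, roc_b.test_indices, roc_b.test_scores):
        if not np.array_equal(idx_a, idx_b):
            raise ValueError("repetitions used different splits; rerun with a shared seed")
        try:
            res = delong_test(sa, sb, roc_a.labels[idx_a])
        except ValueError:
            continue
        n_done += 1
        n_sig += res.p < alpha
    if n_done == 0:
        raise ValueError("no comparable repetitions")
    return n_sig / n_done


def averaged_posterior_delong(roc_a: RocResult, roc_b: RocResult) -> DelongResult:
    """DeLong's test on held-out posteriors averaged over all repetitions."""
    keep = np.isfinite(roc_a.mean_posterior) & np.isfinite(roc_b.mean_posterior)
    return delong_test(roc_a.mean_posterior[keep], roc_b.mean_posterior[keep], roc_a.labels[keep])
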