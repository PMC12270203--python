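"""Statistical toolkit: Fisher Z comparison of correlations, sample
correlation matrices, heatmap leaf ordering, silhouette and spectral
entropy diagnostics, rank tests with multiplicity correction, and the
classification-metric / cross-validation harness.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "ConfusionCounts",
    "fisher_z_test",
    "sample_correlation_matrix",
    "ward_cluster_order",
    "silhouette_scores",
    "correlation_entropy",
    "mann_whitney",
    "adjust_pvalues",
    "classification_metrics",
    "stratified_kfold",
    "cross_validated_metrics",
]


@dataclasses.dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    adjusted_p: float | None = None


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn == 0:
            raise ValueError("confusion counts are all zero")


def fisher_z_test(r1: float, n1: int, r2: float, n2: int) -> TestResult:
    """Two-sample comparison of Pearson correlations via Fisher's Z.

    ``Z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3))`` with a
    two-sided p-value from the standard normal.
    """
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n1 <= 3 or n2 <= 3:
        raise ValueError("sample sizes must exceed 3")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(statistic=z, p_value=float(p), method="fisher_z")


def fisher_z_statistic(r1: np.ndarray, n1: int, r2: np.ndarray, n2: int) -> np.ndarray:
    """Vectorized Fisher Z statistic (used for calibration studies)."""
    denom = math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return (np.arctanh(r1) - np.arctanh(r2)) / denom


def sample_correlation_matrix(features: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Pearson correlation between sample (row) feature vectors.

    Rows with zero variance get correlation 0 with everything (and 1 on
    the diagonal) by convention.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D array with at least 2 samples")
    sd = x.std(axis=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def ward_cluster_order(
    corr: np.ndarray, groups: Sequence[str] | None = None
) -> np.ndarray:
    """Leaf permutation for correlation heatmaps.

    Within each group (e.g. strong/weak binding), samples are ordered by
    Ward-D2 agglomeration on the distance ``d = 1 - r``; groups appear
    in sorted order.  Deterministic for a given input.
    """
    corr = np.asarray(corr, dtype=float)
    n = corr.shape[0]
    if groups is None:
        groups = ["all"] * n
    order: list[int] = []
    for g in sorted(set(groups)):
        idx = np.array([i for i, gi in enumerate(groups) if gi == g])
        if len(idx) == 1:
            order.extend(idx.tolist())
            continue
        sub = 1.0 - corr[np.ix_(idx, idx)]
        np.fill_diagonal(sub, 0.0)
        z = linkage(squareform(sub, checks=False), method="ward")
        order.extend(idx[leaves_list(z)].tolist())
    return np.array(order)


def silhouette_scores(dist: np.ndarray, labels: Sequence) -> tuple[np.ndarray, float]:
    """Per-sample silhouette ``s(i) = (b - a) / max(a, b)`` and the median.

    ``a`` is the mean distance to the own cluster (excluding self), ``b``
    the smallest mean distance to any other cluster.  Members of
    singleton clusters score 0 by convention, as do samples where
    ``a = b = 0``.
    """
    d = np.asarray(dist, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    n = d.shape[0]
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            continue
        a = d[i, own].sum() / (n_own - 1)
        b = min(d[i, labels == g].mean() for g in uniq if g != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s, float(np.median(s))


def correlation_entropy(corr: np.ndarray, tol: float = 1e-8) -> float:
    """Von Neumann spectral entropy of a correlation matrix, in bits.

    The eigenvalues of ``corr / n`` sum to 1 (trace of a correlation
    matrix is ``n``); ``H = -sum(lam * log2(lam))``.  An identity matrix
    of size n gives ``log2(n)`` bits; a rank-1 all-ones matrix gives 0.
    Lower entropy means the correlation structure is concentrated in few
    modes — i.e. the feature space carries shared structure.
    """
    c = np.asarray(corr, dtype=float)
    n = c.shape[0]
    lam = np.linalg.eigvalsh(c / n)
    if lam.min() < -tol * max(1.0, abs(lam.max())):
        raise ValueError(f"matrix is not positive semidefinite (min eigenvalue {lam.min():g})")
    lam = np.clip(lam, 0.0, None)
    lam = lam / lam.sum()
    nz = lam[lam > 0]
    return float(-(nz * np.log2(nz)).sum())


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney-Wilcoxon rank-sum test.

    Exact enumeration when both samples have n <= 8 and no ties;
    otherwise the tie-corrected normal approximation with continuity
    correction.  The reported U counts pairs ``(x_i, y_j)`` with
    ``x_i > y_j`` (plus half-ties), i.e. U of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(
        statistic=float(res.statistic), p_value=float(res.pvalue), method=f"mann_whitney_{method}"
    )


def adjust_pvalues(
    pvalues: Sequence[float], method: Literal["bonferroni", "bh"] = "bh"
) -> np.ndarray:
    """Multiple-testing adjustment: Bonferroni (p*m capped at 1) or
    Benjamini-Hochberg step-up FDR."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    sm_method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[method]
    return multipletests(p, method=sm_method)[1]


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


def classification_metrics(c: ConfusionCounts) -> dict[str, float]:
    """MCC, F1, balanced accuracy, specificity, precision, recall.

    Undefined ratios (zero denominators) return 0.
    """
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    specificity = _safe_div(tn, tn + fp)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = _safe_div(tp * tn - fp * fn, mcc_den)
    balanced = (recall + specificity) / 2.0
    return {
        "mcc": mcc,
        "f1": f1,
        "balanced_accuracy": balanced,
        "specificity": specificity,
        "precision": precision,
        "recall": recall,
    }


def stratified_kfold(labels: Sequence, k: int = 10, seed: int = 0) -> np.ndarray:
    """Fold assignment (0..k-1) per sample, stratified by label."""
    labels = np.asarray(labels)
    counts = pd.Series(labels).value_counts()
    if (counts < k).any():
        small = counts[counts < k].index.tolist()
        raise ValueError(f"class(es) {small} have fewer than k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(labels), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        folds[test_idx] = f
    return folds


def cross_validated_metrics(
    scorer,
    features: np.ndarray,
    labels: Sequence,
    k: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Stratified k-fold metric harness for any probability scorer.

    ``scorer`` must implement ``fit(X, y)`` and ``predict_proba(X)``
    (sklearn convention).  Returns one metric row per fold.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    folds = stratified_kfold(y, k=k, seed=seed)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("binary labels required")
    pos = classes[-1]
    rows = []
    for f in range(k):
        test = folds == f
        scorer.fit(x[~test], y[~test])
        proba = scorer.predict_proba(x[test])
        pos_col = list(scorer.classes_).index(pos)
        pred = proba[:, pos_col] >= threshold
        truth = y[test] == pos
        counts = ConfusionCounts(
            tp=int(np.sum(pred & truth)),
            fp=int(np.sum(pred & ~truth)),
            tn=int(np.sum(~pred & ~truth)),
            fn=int(np.sum(~pred & truth)),
        )
        rows.append({"fold": f, **classification_metrics(counts)})
    return pd.DataFrame(rows)
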