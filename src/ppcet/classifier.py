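"""Gene-panel SVM classification under leave-one-out cross-validation.

Panels of differential promoters feed a linear SVM; every sample's
decision score comes from a model fit on the remaining n − 1 samples with
per-fold feature standardization, so no information leaks from the held
out sample. ROC/AUC uses the Mann-Whitney convention (ties count 1/2);
AUC confidence intervals and paired AUC comparisons use DeLong's
nonparametric variance of the structural components. The operating
threshold maximizes Youden's J on training scores and is frozen for every
other cohort.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

POSITIVE_LABEL = "pCR"
NEGATIVE_LABEL = "non-pCR"


@dataclass
class CohortSplit:
    training: list[str]
    validation: list[str]


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


@dataclass
class PanelEvaluation:
    panel: tuple[str, ...]
    scores: pd.Series  # per-sample decision scores
    labels: pd.Series
    roc: RocCurve
    auc: float
    auc_ci: tuple[float, float]
    threshold: float
    sensitivity: float
    specificity: float
    accuracy: float
    cohort: str = "training"
    ci_degenerate: bool = False

    def metrics(self) -> dict:
        y = _binary(self.labels)
        return {
            "cohort": self.cohort,
            "panel": list(self.panel),
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "n_pos": int(y.sum()),
            "n_neg": int((1 - y).sum()),
        }


def _binary(labels) -> np.ndarray:
    labels = np.asarray(pd.Series(labels))
    known = np.isin(labels, [POSITIVE_LABEL, NEGATIVE_LABEL])
    if not known.all():
        raise ValueError("labels must be pCR / non-pCR")
    return (labels == POSITIVE_LABEL).astype(int)


# ---------------------------------------------------------------------------
# cohort split
# ---------------------------------------------------------------------------

def chronological_split(samples: Sequence, training_fraction: float = 0.7) -> CohortSplit:
    """Split labeled samples by collection date (ties by sample_id).

    The earliest ``training_fraction`` of samples form the training
    cohort. Each resulting cohort must contain at least two samples of
    each label.
    """
    if not 0 < training_fraction < 1:
        raise ValueError("training_fraction must be in (0, 1)")
    recs = sorted(samples, key=lambda r: (r.collection_date, r.sample_id))
    n_train = int(len(recs) * training_fraction)
    train, valid = recs[:n_train], recs[n_train:]
    for name, part in (("training", train), ("validation", valid)):
        labs = [r.label for r in part]
        for lab in (POSITIVE_LABEL, NEGATIVE_LABEL):
            if labs.count(lab) < 2:
                raise ValueError(f"{name} cohort has < 2 {lab} samples")
    return CohortSplit([r.sample_id for r in train], [r.sample_id for r in valid])


# ---------------------------------------------------------------------------
# SVM fitting
# ---------------------------------------------------------------------------

def _standardize(train: np.ndarray, other: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    constant = sd == 0
    sd = np.where(constant, 1.0, sd)
    a = (train - mu) / sd
    b = (other - mu) / sd
    if constant.any():
        a[:, constant] = 0.0
        b[:, constant] = 0.0
    return a, b


def _fit_svm(x: np.ndarray, y: np.ndarray, kernel: str, c: float) -> SVC:
    clf = SVC(kernel=kernel, C=c)
    clf.fit(x, y)
    return clf


def loocv_scores(
    features: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    kernel: str = "linear",
    c: float = 1.0,
) -> pd.Series:
    """Leave-one-out decision scores (samples × genes feature table).

    Each fold standardizes features on its n − 1 training samples only;
    a feature constant within a fold contributes standardized zeros there.
    """
    labels = pd.Series(labels)[features.index]
    y = _binary(labels)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need >= 2 samples per label for LOOCV")
    x = features.to_numpy(dtype=np.float64)
    if not np.isfinite(x).all():
        raise ValueError("features contain missing values")
    n = x.shape[0]
    scores = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        xtr, xte = _standardize(x[mask], x[~mask])
        scores[i] = _fit_svm(xtr, y[mask], kernel, c).decision_function(xte)[0]
        mask[i] = True
    return pd.Series(scores, index=features.index, name="score")


def train_and_score(
    train_features: pd.DataFrame,
    train_labels,
    eval_features: pd.DataFrame,
    kernel: str = "linear",
    c: float = 1.0,
) -> pd.Series:
    """Fit once on the full training cohort, score another cohort."""
    y = _binary(pd.Series(train_labels)[train_features.index])
    xtr, xev = _standardize(
        train_features.to_numpy(dtype=np.float64), eval_features.to_numpy(dtype=np.float64)
    )
    clf = _fit_svm(xtr, y, kernel, c)
    return pd.Series(clf.decision_function(xev), index=eval_features.index, name="score")


# ---------------------------------------------------------------------------
# ROC / AUC / DeLong
# ---------------------------------------------------------------------------

def roc_auc(scores, labels) -> tuple[RocCurve, float]:
    """ROC points at every distinct threshold plus the Mann-Whitney AUC."""
    y = _binary(labels)
    s = np.asarray(pd.Series(scores), dtype=np.float64)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both labels must be present")
    fpr, tpr, thr = roc_curve(y, s)
    return RocCurve(fpr, tpr, thr), float(roc_auc_score(y, s))


def _delong_components(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Structural components V10 (per positive) and V01 (per negative)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    # psi(x, y) = 1[x > y] + 0.5 * 1[x == y], vectorized over the grid
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return v10, v01, float(psi.mean())


def delong_variance(scores, labels) -> tuple[float, float]:
    """DeLong estimate of (AUC, var(AUC))."""
    y = _binary(labels)
    s = np.asarray(pd.Series(scores), dtype=np.float64)
    v10, v01, auc = _delong_components(s, y)
    m, n = len(v10), len(v01)
    if m < 2 or n < 2:
        raise ValueError("need >= 2 samples per label")
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
    return auc, float(var)


def auc_ci(scores, labels, level: float = 0.95) -> tuple[tuple[float, float], bool]:
    """DeLong Wald interval clipped to [0, 1]; degenerate at var 0."""
    auc, var = delong_variance(scores, labels)
    if var <= 0:
        logger.debug("auc_ci: degenerate DeLong variance; interval collapses to the point")
        return (auc, auc), True
    z = _stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return (max(0.0, auc - half), min(1.0, auc + half)), False


def compare_auc(scores_a, scores_b, labels) -> float:
    """Paired DeLong test (two-sided) for correlated ROC curves."""
    sa = np.asarray(pd.Series(scores_a), dtype=np.float64)
    sb = np.asarray(pd.Series(scores_b), dtype=np.float64)
    if sa.shape != sb.shape:
        raise ValueError("score vectors must have the same length")
    y = _binary(labels)
    v10a, v01a, auc_a = _delong_components(sa, y)
    v10b, v01b, auc_b = _delong_components(sb, y)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 1e-16:
        return 1.0 if abs(auc_a - auc_b) < 1e-12 else 0.0
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    return float(min(1.0, 2.0 * _stats.norm.sf(abs(z))))


def operating_point(roc: RocCurve) -> tuple[float, float, float]:
    """Threshold maximizing Youden's J, ties broken toward specificity.

    Returns (threshold, sensitivity, specificity) at the chosen point.
    Scores >= threshold predict the positive class.
    """
    j = roc.tpr - roc.fpr
    best = np.flatnonzero(j == j.max())
    # ties toward higher specificity = lower fpr; roc_curve sorts fpr ascending
    i = best[0]
    return float(roc.thresholds[i]), float(roc.tpr[i]), float(1.0 - roc.fpr[i])


def confusion_metrics(scores, labels, threshold: float) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) at a fixed score threshold."""
    y = _binary(labels)
    s = np.asarray(pd.Series(scores), dtype=np.float64)
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    npos, nneg = int(y.sum()), int((1 - y).sum())
    sens = tp / npos if npos else float("nan")
    spec = tn / nneg if nneg else float("nan")
    return sens, spec, (tp + tn) / len(y)


def evaluate_scores(
    scores: pd.Series,
    labels,
    cohort: str,
    panel: Sequence[str],
    threshold: float | None = None,
) -> PanelEvaluation:
    """Bundle ROC, AUC + CI and operating-point metrics for a score vector."""
    labels = pd.Series(labels)[scores.index]
    roc, auc = roc_auc(scores, labels)
    ci, degenerate = auc_ci(scores, labels)
    if threshold is None:
        threshold, _, _ = operating_point(roc)
    sens, spec, acc = confusion_metrics(scores, labels, threshold)
    return PanelEvaluation(
        panel=tuple(panel),
        scores=scores,
        labels=labels,
        roc=roc,
        auc=auc,
        auc_ci=ci,
        threshold=threshold,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        cohort=cohort,
        ci_degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# panel search
# ---------------------------------------------------------------------------

def rank_candidates(screen: pd.DataFrame, passing_only: bool = True) -> list[str]:
    """Order genes by FDR, then |log2 FC| (descending), then gene_id."""
    df = screen[screen["passes"]] if passing_only and screen["passes"].any() else screen
    df = df.assign(_abs_lfc=df["log2_fold_change"].abs())
    df = df.sort_values(["fdr", "_abs_lfc", "gene_id"], ascending=[True, False, True],
                        key=None, kind="mergesort")
    return list(df.index)


@dataclass
class PanelSearchResult:
    best: PanelEvaluation
    ranked: list[tuple[tuple[str, ...], float]]  # (panel, LOOCV AUC), best first
    n_evaluated: int
    exhaustive: bool


def panel_search(
    candidates: Sequence[str],
    features: pd.DataFrame,
    labels,
    max_panel_size: int = 9,
    pool_size: int = 20,
    enumeration_budget: int = 1_000_000,
    kernel: str = "linear",
    c: float = 1.0,
    seed: int = 0,
) -> PanelSearchResult:
    """Search gene panels by training LOOCV AUC.

    The search restricts to the top ``pool_size`` ranked candidates and
    enumerates every combination of size 1..``max_panel_size`` when that
    count fits the ``enumeration_budget``; otherwise it falls back to
    greedy forward selection with the same objective (logged loudly).
    Ties prefer smaller panels, then lexicographic gene order, so the
    result is deterministic.
    """
    if not candidates:
        raise ValueError("no candidate genes to search")
    pool = list(candidates)[:pool_size]
    if max_panel_size > len(pool):
        max_panel_size = len(pool)
    labels = pd.Series(labels)[features.index]

    def objective(panel: tuple[str, ...]) -> float:
        scores = loocv_scores(features[list(panel)], labels, kernel=kernel, c=c)
        _, auc = roc_auc(scores, labels)
        return auc

    n_panels = sum(_ncomb(len(pool), k) for k in range(1, max_panel_size + 1))
    evaluated: list[tuple[tuple[str, ...], float]] = []
    if n_panels <= enumeration_budget:
        exhaustive = True
        for k in range(1, max_panel_size + 1):
            for panel in itertools.combinations(pool, k):
                evaluated.append((panel, objective(panel)))
    else:
        exhaustive = False
        logger.warning(
            "panel_search: %d panels exceed the enumeration budget (%d); "
            "falling back to greedy forward selection over the top-%d pool",
            n_panels, enumeration_budget, len(pool),
        )
        current: tuple[str, ...] = ()
        best_auc = -np.inf
        while len(current) < max_panel_size:
            step = [
                (current + (g,), objective(current + (g,)))
                for g in pool if g not in current
            ]
            step.sort(key=lambda t: (-t[1], len(t[0]), t[0]))
            evaluated.extend(step)
            if step[0][1] <= best_auc:
                break
            current, best_auc = step[0]

    evaluated.sort(key=lambda t: (-t[1], len(t[0]), t[0]))
    best_panel, best_auc = evaluated[0]
    best_scores = loocv_scores(features[list(best_panel)], labels, kernel=kernel, c=c)
    best_eval = evaluate_scores(best_scores, labels, "training", best_panel)
    return PanelSearchResult(best=best_eval, ranked=evaluated, n_evaluated=len(evaluated), exhaustive=exhaustive)


def _ncomb(n: int, k: int) -> int:
    import math

    return math.comb(n, k)
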