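"""Classifier training and evaluation for the residual-disease model.

Two random-forest classifiers are compared: one on every
repeatability-surviving feature (the plain "RF" arm) and one restricted
to the Boruta-confirmed subset, alongside the clinical positive-margin
flag used as a two-valued score. AUCs are compared with the paired
DeLong test. Thresholded metrics use the Youden-optimal threshold on the
training scores, frozen and carried to the test cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import train_test_split

__all__ = [
    "SplitPlan", "PerformanceReport", "make_split", "train_model",
    "youden_threshold", "evaluate", "margin_baseline", "delong_test",
]


@dataclass
class SplitPlan:
    assignment: pd.Series  # case_id -> "training" | "test"
    ratio: float
    seed: int
    stratified: bool = True

    @property
    def training_ids(self) -> list[str]:
        return list(self.assignment.index[self.assignment == "training"])

    @property
    def test_ids(self) -> list[str]:
        return list(self.assignment.index[self.assignment == "test"])


def make_split(case_ids, labels, seed: int, ratio: float = 0.5, stratified: bool = True) -> SplitPlan:
    """Deterministic 1:1 (by default) training/test partition, stratified by label."""
    case_ids = list(case_ids)
    labels = np.asarray(labels)
    train_ids, test_ids = train_test_split(
        case_ids,
        test_size=ratio,
        random_state=seed,
        stratify=labels if stratified else None,
        shuffle=True,
    )
    assignment = pd.Series("test", index=case_ids, dtype=object)
    assignment.loc[train_ids] = "training"
    return SplitPlan(assignment, ratio, seed, stratified)


def train_model(
    X_train: pd.DataFrame,
    y_train,
    feature_subset: list[str] | None = None,
    n_estimators: int = 500,
    seed: int = 0,
    max_depth: int | None = None,
):
    """Fit a seeded random forest (500 trees, sqrt(p) features per split)
    on the given feature subset; returns (classifier, subset)."""
    subset = list(feature_subset) if feature_subset is not None else list(X_train.columns)
    if not subset:
        raise ValueError("empty feature subset")
    clf = RandomForestClassifier(
        n_estimators=n_estimators,
        max_features="sqrt",
        max_depth=max_depth,
        random_state=seed,
        n_jobs=1,
    )
    clf.fit(X_train[subset].to_numpy(), np.asarray(y_train))
    return clf, subset


def predict_scores(model, X: pd.DataFrame) -> np.ndarray:
    clf, subset = model
    return clf.predict_proba(X[subset].to_numpy())[:, 1]


def youden_threshold(scores, labels) -> float:
    """Threshold maximizing sensitivity + specificity - 1 on these scores."""
    fpr, tpr, thr = roc_curve(np.asarray(labels).astype(int), np.asarray(scores))
    j = tpr - fpr
    return float(thr[int(np.argmax(j))])


@dataclass
class PerformanceReport:
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    threshold: float
    cohort: str = ""
    confusion: dict = field(default_factory=dict)  # tp, fp, tn, fn counts

    def as_dict(self) -> dict:
        return {
            "auc": self.auc, "accuracy": self.accuracy,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "npv": self.npv, "threshold": self.threshold,
            "cohort": self.cohort, **{f"n_{k}": v for k, v in self.confusion.items()},
        }


def evaluate(scores, labels, threshold: float, cohort: str = "") -> PerformanceReport:
    """AUC (Mann–Whitney/trapezoidal) plus confusion metrics at a frozen
    threshold (score >= threshold predicts positive).

    Empty ratio denominators (e.g. PPV with no positive calls) yield 0.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("labels must contain both classes")
    auc = float(roc_auc_score(y, scores))
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))

    def ratio(a, b):
        return a / b if b else 0.0

    return PerformanceReport(
        auc=auc,
        accuracy=ratio(tp + tn, len(y)),
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
        threshold=float(threshold),
        cohort=cohort,
        confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
    )


def margin_baseline(margin_positive, labels, cohort: str = "") -> PerformanceReport:
    """The binary positive-margin flag treated as a score; its AUC equals
    the flag's balanced accuracy."""
    flags = np.asarray(margin_positive).astype(int)
    return evaluate(flags.astype(float), labels, threshold=0.5, cohort=cohort)


# --------------------------------------------------------------------------
# DeLong paired AUC comparison

def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Mann–Whitney placement values (structural components) with ties at 1/2."""
    m, n = len(pos), len(neg)
    cmp = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)  # per positive case
    v01 = cmp.mean(axis=0)  # per negative case
    return v10, v01, float(cmp.mean())


def auc_variance(scores, labels) -> tuple[float, float]:
    """Single-classifier AUC and its DeLong variance estimate."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    v10, v01, auc = _placements(scores[y == 1], scores[y == 0])
    var = np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01)
    return auc, float(var)


def delong_test(scores_a, scores_b, labels) -> dict:
    """Paired DeLong test for the difference of two correlated AUCs.

    Returns auc_a, auc_b, z and the two-sided normal p-value. When the
    variance of the difference is 0 (e.g. identical score vectors) the
    difference is deterministic: p = 1 if the AUCs agree, else 0.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels).astype(int)
    if a.shape != b.shape or a.shape[0] != y.shape[0]:
        raise ValueError("score vectors must cover the same cases")
    if np.unique(y).size < 2:
        raise ValueError("labels must contain both classes")
    pos, neg = y == 1, y == 0
    v10a, v01a, auc_a = _placements(a[pos], a[neg])
    v10b, v01b, auc_b = _placements(b[pos], b[neg])
    m, n = int(pos.sum()), int(neg.sum())
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1)
    s = s10 / m + s01 / n
    var_diff = float(s[0, 0] + s[1, 1] - 2 * s[0, 1])
    delta = auc_a - auc_b
    if var_diff <= 0:
        z = 0.0
        p = 1.0 if np.isclose(delta, 0.0) else 0.0
    else:
        z = delta / np.sqrt(var_diff)
        p = 2.0 * stats.norm.sf(abs(z))
    return {"auc_a": float(auc_a), "auc_b": float(auc_b), "z": float(z), "p": float(p)}
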