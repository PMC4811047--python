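"""Classifier evaluation: confusion-count metric panel, ROC/AUC, and
stratified k-fold cross validation.

The scalar panel is accuracy, precision, sensitivity and specificity (all
in percent), the F1 score (percent, the harmonic mean of precision and
sensitivity) and Matthews' correlation coefficient (in [-1, 1]). Any
metric with a zero denominator is reported as undefined (None), never
silently zeroed. AUC is computed twice — trapezoidal integration of the
ROC curve and the equivalent mid-rank statistic — and the two must agree
to 1e-12.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from . import model as model_mod
from .features import FeatureSchema


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EvalReport:
    """Confusion counts plus the seven-metric panel (and ROC when scored)."""

    counts: ConfusionCounts
    accuracy: float | None
    precision: float | None
    sensitivity: float | None
    specificity: float | None
    f1: float | None
    mcc: float | None
    auc: float | None = None
    roc: list[tuple[float, float]] | None = field(default=None, repr=False)
    undefined: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = {
            "counts": {"tp": self.counts.tp, "fp": self.counts.fp,
                       "tn": self.counts.tn, "fn": self.counts.fn},
            "accuracy": self.accuracy,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1": self.f1,
            "mcc": self.mcc,
            "auc": self.auc,
            "undefined": list(self.undefined),
        }
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def confusion(y_true: Sequence[int], calls: Sequence[bool]) -> ConfusionCounts:
    y = np.asarray(y_true, dtype=int)
    c = np.asarray(calls, dtype=bool)
    return ConfusionCounts(
        tp=int((c & (y == 1)).sum()),
        fp=int((c & (y == 0)).sum()),
        tn=int((~c & (y == 0)).sum()),
        fn=int((~c & (y == 1)).sum()),
    )


def metrics_from_counts(counts: ConfusionCounts) -> EvalReport:
    """The six scalar metrics from confusion counts (AUC needs scores)."""
    if counts.total == 0:
        raise ValueError("empty confusion matrix")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    undefined: list[str] = []

    def ratio(num: float, den: float, name: str) -> float | None:
        if den == 0:
            undefined.append(name)
            return None
        return num / den

    accuracy = 100.0 * (tp + tn) / counts.total
    precision = ratio(tp, tp + fp, "precision")
    precision = None if precision is None else 100.0 * precision
    sensitivity = ratio(tp, tp + fn, "sensitivity")
    sensitivity = None if sensitivity is None else 100.0 * sensitivity
    specificity = ratio(tn, tn + fp, "specificity")
    specificity = None if specificity is None else 100.0 * specificity
    if precision is None or sensitivity is None or (precision + sensitivity) == 0:
        undefined.append("f1")
        f1 = None
    else:
        f1 = 2.0 * precision * sensitivity / (precision + sensitivity)
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        undefined.append("mcc")
        mcc = None
    else:
        mcc = (tp * tn - fp * fn) / mcc_den
    return EvalReport(
        counts=counts,
        accuracy=accuracy,
        precision=precision,
        sensitivity=sensitivity,
        specificity=specificity,
        f1=f1,
        mcc=mcc,
        undefined=tuple(undefined),
    )


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the mid-rank Mann-Whitney statistic (ties by mid-rank)."""
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    ranks = rankdata(scores)
    r_pos = ranks[labels == 1].sum()
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def roc_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, list[tuple[float, float]]]:
    """AUC and the ROC points (FPR, TPR) over all score thresholds.

    Computed by trapezoidal integration and cross-checked against the
    rank-statistic formulation; the two must agree to 1e-12.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(labels, scores)
    auc_trap = float(np.trapezoid(tpr, fpr))
    auc_rank = _rank_auc(scores, labels)
    if abs(auc_trap - auc_rank) > 1e-12:
        raise AssertionError(
            f"trapezoidal AUC {auc_trap!r} != rank AUC {auc_rank!r}"
        )
    return auc_trap, list(zip(fpr.tolist(), tpr.tolist()))


def evaluate_predictions(
    y_true: Sequence[int], scores: Sequence[float], threshold: float = 0.5
) -> EvalReport:
    """Full panel (including AUC/ROC) from scores and true labels."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y_true, dtype=int)
    report = metrics_from_counts(confusion(y, scores >= threshold))
    if len(np.unique(y)) == 2:
        report.auc, report.roc = roc_auc(scores, y)
    return report


@dataclass
class CrossValidationResult:
    fold_reports: list[EvalReport]
    pooled: EvalReport
    oof_scores: np.ndarray = field(repr=False)
    fold_assignment: np.ndarray = field(repr=False)

    def fold_mean_sd(self, metric: str) -> tuple[float, float]:
        vals = [getattr(r, metric) for r in self.fold_reports]
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)), float(np.std(vals))


def cross_validate(
    X: np.ndarray,
    y: Sequence[int],
    residue: str = "S",
    k_folds: int = 10,
    n_trees: int = model_mod.DEFAULT_N_TREES,
    seed: int = 0,
    threshold: float = 0.5,
    schema: FeatureSchema | None = None,
    feature_subset: Sequence[int] | None = None,
) -> CrossValidationResult:
    """Stratified k-fold cross validation of the forest.

    Folds are a seeded stratified random partition; each fold's model is
    trained on the other k-1 folds. Per-fold reports are returned together
    with the pooled report over the concatenated out-of-fold predictions
    (the headline numbers). Features are window-local, so extraction can
    precede the split without leakage.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if schema is None:
        from .features import FeatureSchema as FS, family_lengths

        # infer w from the column count
        for w in range(3, 200, 2):
            if sum(family_lengths(w).values()) == X.shape[1]:
                schema = FS.for_window(w)
                break
        if schema is None:
            raise ValueError("cannot infer a window size from the column count")
    if min(np.bincount(y, minlength=2)) < k_folds:
        raise ValueError(
            f"too few windows for residue {residue}: need >= {k_folds} per class"
        )
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    oof = np.full(len(y), np.nan)
    assignment = np.full(len(y), -1, dtype=int)
    fold_reports = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        bundle = model_mod.train(
            X[tr], y[tr], residue, schema, n_trees=n_trees, seed=seed,
            feature_subset=feature_subset,
        )
        proba, _ = model_mod.predict(bundle, X[te], threshold=threshold)
        oof[te] = proba
        assignment[te] = fold
        fold_reports.append(evaluate_predictions(y[te], proba, threshold))
    pooled = evaluate_predictions(y, oof, threshold)
    return CrossValidationResult(fold_reports, pooled, oof, assignment)


def cross_validate_windows(
    windows,
    asa_profiles=None,
    k_folds: int = 10,
    n_trees: int = model_mod.DEFAULT_N_TREES,
    seed: int = 0,
    threshold: float = 0.5,
) -> CrossValidationResult:
    """Cross-validate directly from windows (encodes once, then folds)."""
    from .features import encode_windows

    windows = list(windows)
    residues = {w.center_residue for w in windows}
    residue = residues.pop() if len(residues) == 1 else "/".join(sorted(residues))
    X, y, schema, _ = encode_windows(windows, asa_profiles)
    return cross_validate(
        X, y, residue=residue, k_folds=k_folds, n_trees=n_trees,
        seed=seed, threshold=threshold, schema=schema,
    )


def write_roc(points: Sequence[tuple[float, float]], path) -> None:
    with open(path, "w") as fh:
        fh.write("fpr\ttpr\n")
        for fpr, tpr in points:
            fh.write(f"{fpr:.6f}\t{tpr:.6f}\n")
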