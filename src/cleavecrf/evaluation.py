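"""Metrics, repeated cross-validation, grid search and significance tests.

Classification quality is summarized by sensitivity, specificity,
precision, accuracy, Matthews correlation coefficient and ROC AUC (the
primary measure).  Models are compared by repeated stratified k-fold
cross-validation (default 10 repeats of 5 folds) with all preprocessing
state (smoothing, bin edges, attribute vocabulary) fitted inside each
training fold, and by paired t-tests over the per-repeat mean AUCs.
The smoothing range and bin number of each structural descriptor are
optimized by CV AUC over the 5 × 10 grid (range 1–5, bins 1–10).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from . import crf
from .encoding import (
    STRUCTURAL_FEATURES,
    CleavageDataset,
    FeatureSetConfig,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "EvaluationReport",
    "confusion_metrics",
    "roc_auc",
    "cross_validate",
    "grid_search_smoothing",
    "paired_t_test",
    "threshold_at_specificity",
]


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Sn, Sp, precision, Acc and MCC from a confusion table.

    A zero denominator yields NaN (undefined), except the MCC
    denominator, which yields MCC = 0 by convention.
    """
    if c.total == 0:
        raise ValueError("at least one evaluated sample required")

    def _ratio(num, den):
        return num / den if den > 0 else float("nan")

    sn = _ratio(c.tp, c.tp + c.fn)
    sp = _ratio(c.tn, c.tn + c.fp)
    precision = _ratio(c.tp, c.tp + c.fp)
    acc = (c.tp + c.tn) / c.total
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = (
        (c.tp * c.tn - c.fp * c.fn) / np.sqrt(float(denom)) if denom > 0 else 0.0
    )
    return {"sn": sn, "sp": sp, "precision": precision, "acc": acc, "mcc": mcc}


def roc_auc(scores, labels) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC (tie-aware trapezoid over all thresholds) with the ROC points."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present to compute ROC/AUC")
    fpr, tpr, _ = roc_curve(labels, scores)
    return float(_trapezoid_auc(fpr, tpr)), fpr, tpr


@dataclass
class EvaluationReport:
    config_name: str
    fold_aucs: np.ndarray          # (repeats, folds)
    repeat_mean_aucs: np.ndarray   # (repeats,)
    metrics: dict[str, float]      # aggregate at the 0.5 operating point
    roc_points: tuple[np.ndarray, np.ndarray]
    folds: int = 5
    repeats: int = 10
    seed: int = 0
    extra: dict = field(default_factory=dict)

    @property
    def mean_auc(self) -> float:
        return float(self.repeat_mean_aucs.mean())

    def summary_table(self) -> str:
        m = self.metrics
        lines = [
            f"config     : {self.config_name}",
            f"CV         : {self.repeats} x {self.folds}-fold (seed {self.seed})",
            f"AUC        : {self.mean_auc:.4f}",
            f"Sn         : {m['sn']:.4f}",
            f"Sp         : {m['sp']:.4f}",
            f"Precision  : {m['precision']:.4f}",
            f"Acc        : {m['acc']:.4f}",
            f"MCC        : {m['mcc']:.4f}",
        ]
        return "\n".join(lines)


def _fold_scores(
    dataset: CleavageDataset,
    config: FeatureSetConfig,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    l2_sigma: float,
    max_iter: int,
) -> np.ndarray:
    """Train on one fold and score the held-out windows.

    All preprocessing (bin edges) is fitted on the training fold only.
    """
    train = dataset.subset(train_idx)
    test = dataset.subset(test_idx)
    fitted = train.fit_preprocessing(config)
    model = crf.train(
        train.encode(config, fitted),
        list(train.labels),
        l2_sigma=l2_sigma,
        max_iter=max_iter,
    )
    return crf.predict_sites(model, test.encode(config, fitted))


def cross_validate(
    dataset: CleavageDataset,
    config: FeatureSetConfig,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
    l2_sigma: float = 1.0,
    max_iter: int = 150,
    config_name: str = "",
) -> EvaluationReport:
    """Repeated stratified k-fold cross-validation of a feature combination.

    Fold assignment is re-randomized per repeat from the seed, so the
    whole report is reproducible.  The aggregate confusion metrics pool
    held-out scores over all repeats at a 0.5 probability cutoff.
    """
    labels = dataset.labels
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if len(set(labels.tolist())) < 2:
        raise ValueError("dataset must contain both classes")
    fold_aucs = np.zeros((repeats, folds))
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + r)
        for f, (tr, te) in enumerate(skf.split(np.zeros(len(labels)), labels)):
            y_te = labels[te]
            if len(set(y_te.tolist())) < 2:
                raise ValueError(
                    f"repeat {r} fold {f}: a class is absent from the test fold"
                )
            scores = _fold_scores(dataset, config, tr, te, l2_sigma, max_iter)
            fold_aucs[r, f], _, _ = roc_auc(scores, y_te)
            pooled_scores.append(scores)
            pooled_labels.append(y_te)
    all_scores = np.concatenate(pooled_scores)
    all_labels = np.concatenate(pooled_labels)
    pred = all_scores >= 0.5
    counts = ConfusionCounts(
        tp=int(np.sum(pred & (all_labels == 1))),
        tn=int(np.sum(~pred & (all_labels == 0))),
        fp=int(np.sum(pred & (all_labels == 0))),
        fn=int(np.sum(~pred & (all_labels == 1))),
    )
    auc_value, fpr, tpr = roc_auc(all_scores, all_labels)
    metrics = confusion_metrics(counts)
    metrics["auc"] = auc_value
    return EvaluationReport(
        config_name=config_name,
        fold_aucs=fold_aucs,
        repeat_mean_aucs=fold_aucs.mean(axis=1),
        metrics=metrics,
        roc_points=(fpr, tpr),
        folds=folds,
        repeats=repeats,
        seed=seed,
    )


def grid_search_smoothing(
    dataset: CleavageDataset,
    feature_names: tuple[str, ...] = STRUCTURAL_FEATURES,
    ranges: tuple[int, ...] = (1, 2, 3, 4, 5),
    bins: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10),
    seed: int = 0,
    folds: int = 5,
    default: tuple[int, int] = (2, 5),
    l2_sigma: float = 1.0,
    max_iter: int = 80,
) -> dict[str, tuple[int, int]]:
    """Per-feature (smoothing range, bins) chosen by cross-validated AUC.

    Sequential coordinate-wise search in the order of `feature_names`:
    each feature's grid is evaluated with every other feature held at
    `default`, on the same seeded fold split for every candidate.  Ties
    are broken toward fewer bins, then a smaller range.
    """
    chosen: dict[str, tuple[int, int]] = {}
    for name in feature_names:
        best: tuple[int, int] | None = None
        best_auc = -np.inf
        for b in sorted(bins):
            for r in sorted(ranges):
                structural = {f: default for f in feature_names}
                structural[name] = (r, b)
                config = FeatureSetConfig(True, True, structural)
                report = cross_validate(
                    dataset, config, folds=folds, repeats=1, seed=seed,
                    l2_sigma=l2_sigma, max_iter=max_iter,
                    config_name=f"grid:{name}",
                )
                auc_value = report.mean_auc
                if auc_value > best_auc + 1e-12:
                    best_auc = auc_value
                    best = (r, b)
        assert best is not None
        chosen[name] = best
        logger.info("grid search %s -> range=%d bins=%d (AUC %.4f)",
                    name, best[0], best[1], best_auc)
    return chosen


def paired_t_test(auc_a, auc_b) -> tuple[float, float]:
    """Paired two-sided t-test over per-repeat AUCs; returns (t, p).

    Degenerate cases: identical vectors give (0, 1); a constant nonzero
    shift (zero-variance differences) gives (±inf, 0).
    """
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired test requires equal-length AUC vectors")
    d = a - b
    if np.allclose(d.std(ddof=1) if len(d) > 1 else 0.0, 0.0):
        if np.allclose(d, 0.0):
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    t, p = scipy.stats.ttest_rel(a, b)
    return float(t), float(p)


def threshold_at_specificity(scores, labels, target_sp: float = 0.99) -> float:
    """Smallest score threshold achieving Sp ≥ target on the given set.

    Prediction rule: positive when score ≥ threshold.  When no finite
    threshold reaches the target, the value just above the maximum score
    is returned (zero sensitivity).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    neg = scores[labels == 0]
    if len(neg) == 0:
        raise ValueError("negative samples required to compute specificity")
    candidates = np.unique(scores)
    for t in candidates:
        sp = float(np.mean(neg < t))
        if sp >= target_sp:
            return float(t)
    return float(np.nextafter(scores.max(), np.inf))
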