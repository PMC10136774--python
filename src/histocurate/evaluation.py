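"""Monte Carlo cross-validation, the seven-metric suite, and bootstrap CIs.

Folds are drawn by repeated random subject-level splits (sampled with
replacement across folds, so at least 20 folds are recommended to touch
most of the data). Splits are always by subject, never by patch, so a
subject's patches cannot leak between a fold's train and validation sides.

Metrics: accuracy, sensitivity (recall), specificity, precision, negative
predictive value, F1 and AUC. AUC is computed as the Mann-Whitney
statistic — the probability a random positive outscores a random negative,
ties counted half — via average ranks. Ratios with a zero denominator are
reported as None (absent), never silently as 0.

Fold aggregation pools predictions across folds and computes each metric
once on the pooled set (the merge-then-compute recommendation of Forman &
Scholz for F1/AUC under cross-validation); per-fold values are kept for
diagnostics. Confidence intervals are percentile bootstrap over
subject-level resampling, which respects within-subject correlation of
patches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "METRIC_NAMES",
    "FoldPlan",
    "FoldPredictions",
    "MetricsReport",
    "make_folds",
    "auc_mann_whitney",
    "compute_metrics",
    "aggregate_folds",
    "bootstrap_ci",
    "run_mccv",
]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision", "npv", "f1", "auc")


@dataclass
class FoldPlan:
    """Subject-level Monte Carlo CV splits: one (train, validation) pair per fold."""

    folds: list[tuple[tuple, tuple]]
    seed: int | None = None

    @property
    def n_folds(self) -> int:
        return len(self.folds)


@dataclass
class FoldPredictions:
    """One fold's validation-set outcomes."""

    y_true: np.ndarray
    y_pred: np.ndarray
    y_score: np.ndarray
    subjects: np.ndarray


@dataclass
class MetricsReport:
    """Point estimates with 95% bootstrap CIs for the seven-metric suite."""

    estimates: dict[str, float | None]
    ci_low: dict[str, float | None] = field(default_factory=dict)
    ci_high: dict[str, float | None] = field(default_factory=dict)
    n_skipped_replicates: int = 0

    def as_dict(self) -> dict:
        return {
            m: {
                "estimate": self.estimates.get(m),
                "ci_low": self.ci_low.get(m),
                "ci_high": self.ci_high.get(m),
            }
            for m in METRIC_NAMES
        }


def make_folds(
    subject_ids: Sequence,
    n_folds: int = 20,
    val_fraction: float = 0.1,
    rng: np.random.Generator | int | None = None,
) -> FoldPlan:
    """Draw ``n_folds`` independent random subject-level splits.

    Each fold holds out ``round(val_fraction * n_subjects)`` subjects
    (at least 1) uniformly at random; the rest train. Folds are sampled
    independently, so subjects recur across validation sets.
    """
    if not (0.0 < val_fraction < 1.0):
        raise ValueError("val_fraction must lie in (0, 1)")
    rng = np.random.default_rng(rng)
    subjects = list(dict.fromkeys(subject_ids))  # unique, order-preserving
    n_val = max(1, round(val_fraction * len(subjects)))
    if n_val >= len(subjects):
        raise ValueError("validation fraction leaves no training subjects")
    folds = []
    for _ in range(n_folds):
        val = rng.choice(len(subjects), size=n_val, replace=False)
        val_set = {subjects[i] for i in val}
        folds.append(
            (tuple(s for s in subjects if s not in val_set), tuple(sorted(val_set, key=str)))
        )
    return FoldPlan(folds=folds)


def auc_mann_whitney(y_true: np.ndarray, y_score: np.ndarray) -> float | None:
    """AUC as P(score_pos > score_neg) + 0.5 P(tie), via average ranks."""
    y_true = np.asarray(y_true).astype(int)
    y_score = np.asarray(y_score, dtype=float)
    n_pos = int(y_true.sum())
    n_neg = y_true.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(y_score)
    return float((ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _safe_ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def compute_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, y_score: np.ndarray | None = None
) -> dict[str, float | None]:
    """Binary-classification metric suite from labels, predictions and scores."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred shape mismatch")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    sens = _safe_ratio(tp, tp + fn)
    prec = _safe_ratio(tp, tp + fp)
    f1 = None
    if prec is not None and sens is not None and (prec + sens) > 0:
        f1 = 2.0 * prec * sens / (prec + sens)
    elif tp + fp + fn > 0:
        f1 = 2.0 * tp / (2.0 * tp + fp + fn) if tp else 0.0
    return {
        "accuracy": _safe_ratio(tp + tn, y_true.size),
        "sensitivity": sens,
        "specificity": _safe_ratio(tn, tn + fp),
        "precision": prec,
        "npv": _safe_ratio(tn, tn + fn),
        "f1": f1,
        "auc": auc_mann_whitney(y_true, y_score) if y_score is not None else None,
    }


def aggregate_folds(
    fold_predictions: Sequence[FoldPredictions],
) -> tuple[dict[str, float | None], list[dict[str, float | None]], FoldPredictions]:
    """Pool validation predictions across folds, then compute metrics once.

    Returns (pooled metrics, per-fold metrics, pooled predictions).
    """
    if not fold_predictions:
        raise ValueError("no folds to aggregate")
    pooled = FoldPredictions(
        y_true=np.concatenate([f.y_true for f in fold_predictions]),
        y_pred=np.concatenate([f.y_pred for f in fold_predictions]),
        y_score=np.concatenate([f.y_score for f in fold_predictions]),
        subjects=np.concatenate([np.asarray(f.subjects) for f in fold_predictions]),
    )
    per_fold = [compute_metrics(f.y_true, f.y_pred, f.y_score) for f in fold_predictions]
    return compute_metrics(pooled.y_true, pooled.y_pred, pooled.y_score), per_fold, pooled


def bootstrap_ci(
    pooled: FoldPredictions,
    B: int = 1000,
    level: float = 0.95,
    rng: np.random.Generator | int | None = None,
) -> tuple[dict[str, tuple[float, float] | None], int]:
    """Percentile bootstrap CIs over subject-level resampling.

    Draws B resamples of subjects with replacement, recomputes every metric
    on each, and takes the (2.5, 97.5) percentiles at level 0.95.
    Replicates whose resample contains a single class are skipped and
    counted. Returns (per-metric CI or None, skipped count).
    """
    if B < 200:
        raise ValueError("B must be at least 200")
    rng = np.random.default_rng(rng)
    subjects = np.asarray(pooled.subjects)
    unique = np.unique(subjects)
    groups = [np.flatnonzero(subjects == s) for s in unique]
    singletons = all(g.size == 1 for g in groups)
    flat = np.concatenate(groups) if singletons else None
    samples: dict[str, list[float]] = {m: [] for m in METRIC_NAMES}
    skipped = 0
    for _ in range(B):
        draw = rng.integers(0, unique.size, size=unique.size)
        idx = flat[draw] if singletons else np.concatenate([groups[i] for i in draw])
        yt = pooled.y_true[idx]
        if yt.min() == yt.max():
            skipped += 1
            continue
        rep = compute_metrics(yt, pooled.y_pred[idx], pooled.y_score[idx])
        for m, v in rep.items():
            if v is not None:
                samples[m].append(v)
    alpha = (1.0 - level) / 2.0
    cis: dict[str, tuple[float, float] | None] = {}
    for m in METRIC_NAMES:
        vals = np.asarray(samples[m])
        if vals.size == 0:
            cis[m] = None
        else:
            cis[m] = (float(np.percentile(vals, 100 * alpha)), float(np.percentile(vals, 100 * (1 - alpha))))
    return cis, skipped


def run_mccv(
    model_factory: Callable[[], "object"],
    X: np.ndarray,
    y: np.ndarray,
    subjects: Sequence,
    n_folds: int = 20,
    val_fraction: float = 0.1,
    rng: np.random.Generator | int | None = None,
    bootstrap: int = 0,
    positive_class: int = 1,
) -> tuple[MetricsReport, FoldPredictions]:
    """Full MCCV evaluation of a pluggable classifier.

    Per fold: fit a fresh model on the training subjects' samples, score
    the validation subjects' samples, and record label/prediction/score
    triples. Predictions are pooled across folds for the headline metrics;
    when ``bootstrap`` > 0, subject-level percentile CIs are attached.
    """
    rng = np.random.default_rng(rng)
    subjects = np.asarray(subjects)
    y = np.asarray(y)
    plan = make_folds(list(subjects), n_folds=n_folds, val_fraction=val_fraction, rng=rng)
    fold_preds = []
    for train_subj, val_subj in plan.folds:
        train_idx = np.flatnonzero(np.isin(subjects, train_subj))
        val_idx = np.flatnonzero(np.isin(subjects, val_subj))
        model = model_factory()
        model.fit(X[train_idx], y[train_idx])
        scores = model.predict_scores(X[val_idx])
        pos = scores[:, positive_class] if scores.ndim == 2 else scores
        fold_preds.append(
            FoldPredictions(
                y_true=(y[val_idx] == positive_class).astype(int),
                y_pred=(np.asarray(pos) >= 0.5).astype(int)
                if scores.ndim == 1
                else (scores.argmax(axis=1) == positive_class).astype(int),
                y_score=np.asarray(pos, dtype=float),
                subjects=subjects[val_idx],
            )
        )
    pooled_metrics, _, pooled = aggregate_folds(fold_preds)
    report = MetricsReport(estimates=pooled_metrics)
    if bootstrap:
        cis, skipped = bootstrap_ci(pooled, B=bootstrap, rng=rng)
        report.ci_low = {m: (ci[0] if ci else None) for m, ci in cis.items()}
        report.ci_high = {m: (ci[1] if ci else None) for m, ci in cis.items()}
        report.n_skipped_replicates = skipped
    return report, pooled
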