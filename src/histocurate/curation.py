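"""Training-set curation: consensus-based outlier removal and class balancing.

Outlier removal follows a RANSAC-style consensus vote: a committee of
models (naturally, the models of a cross-validation run) each predicts
every training sample, and samples that almost never classify correctly —
0 or 1 correct out of, say, 20 models — are treated as likely label noise
and dropped from future training sets. Validation data are never altered;
the consensus table is built over training samples only, so removal cannot
touch a held-out sample by construction.

Class balancing uses bootstrap resampling per batch: every batch draws an
equal number of samples per class, with replacement, so a 2:1 majority
class never dominates a gradient update.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np

__all__ = [
    "ConsensusTable",
    "OutlierPolicy",
    "RansacReport",
    "consensus_scores",
    "remove_outliers",
    "consensus_histogram",
    "ransac_iterations",
    "balanced_batches",
]


@dataclass
class ConsensusTable:
    """Per-sample count of committee models that classified it correctly."""

    sample_ids: list
    n_correct: np.ndarray
    n_models: int

    def __post_init__(self) -> None:
        self.n_correct = np.asarray(self.n_correct, dtype=int)
        if len(self.sample_ids) != len(self.n_correct):
            raise ValueError("sample_ids and n_correct length mismatch")
        if self.n_correct.size and not (
            (self.n_correct >= 0).all() and (self.n_correct <= self.n_models).all()
        ):
            raise ValueError("n_correct must lie in 0..n_models")


@dataclass(frozen=True)
class OutlierPolicy:
    """Remove samples with at most ``max_correct_to_remove`` correct votes."""

    max_correct_to_remove: int = 1
    max_iterations: int = 3
    protect_validation: bool = True


@dataclass
class RansacReport:
    """Per-iteration consensus histograms and removals."""

    iterations: list[dict] = field(default_factory=list)
    removed_ids: list = field(default_factory=list)

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)


def consensus_scores(predictions: np.ndarray, truth: Sequence, sample_ids: Sequence | None = None) -> ConsensusTable:
    """Tally committee agreement: predictions is (n_models, n_samples).

    ``n_correct[j]`` counts the models whose prediction of sample j equals
    its (possibly noisy) training label.
    """
    predictions = np.asarray(predictions)
    if predictions.ndim != 2:
        raise ValueError("predictions must be a 2-D (n_models, n_samples) array")
    truth = np.asarray(truth)
    if predictions.shape[1] != truth.shape[0]:
        raise ValueError(
            f"predictions cover {predictions.shape[1]} samples but truth has {truth.shape[0]}"
        )
    n_models = predictions.shape[0]
    n_correct = (predictions == truth[None, :]).sum(axis=0)
    if sample_ids is None:
        sample_ids = list(range(truth.shape[0]))
    return ConsensusTable(sample_ids=list(sample_ids), n_correct=n_correct, n_models=n_models)


def remove_outliers(table: ConsensusTable, policy: OutlierPolicy = OutlierPolicy()) -> tuple[list, list]:
    """Split sample ids into (retained, removed) under the consensus threshold.

    Raises if the policy would empty the training set entirely.
    """
    if not table.sample_ids:
        raise ValueError("empty consensus table")
    if policy.max_correct_to_remove >= table.n_models:
        raise ValueError("threshold must be below the committee size")
    low = table.n_correct <= policy.max_correct_to_remove
    if low.all():
        raise ValueError("outlier policy would remove every training sample")
    removed = [sid for sid, bad in zip(table.sample_ids, low) if bad]
    retained = [sid for sid, bad in zip(table.sample_ids, low) if not bad]
    return retained, removed


def consensus_histogram(table: ConsensusTable) -> np.ndarray:
    """Counts over consensus scores 0..n_models; bins sum to the table size."""
    if not table.sample_ids:
        raise ValueError("empty consensus table")
    return np.bincount(table.n_correct, minlength=table.n_models + 1)


def ransac_iterations(
    X: np.ndarray,
    y: np.ndarray,
    committee_fn: Callable[[np.ndarray, np.ndarray, np.ndarray, np.random.Generator], np.ndarray],
    policy: OutlierPolicy = OutlierPolicy(),
    n_models: int = 20,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, RansacReport]:
    """Iterate committee training + consensus removal to a fixed point.

    ``committee_fn(X, y, train_idx, rng)`` must train one model on the
    indexed subset and return its predicted labels for every row of X. A
    fresh committee is retrained each iteration on the surviving samples;
    iteration stops at ``policy.max_iterations`` or when nothing is
    removed. Returns the surviving index array and a report with one
    consensus histogram per iteration.
    """
    rng = np.random.default_rng(rng)
    alive = np.arange(len(y))
    report = RansacReport()
    for _ in range(policy.max_iterations):
        preds = np.stack([committee_fn(X, y, alive, rng) for _ in range(n_models)])
        table = consensus_scores(preds[:, alive], y[alive], sample_ids=list(alive))
        retained, removed = remove_outliers(table, policy)
        report.iterations.append(
            {"histogram": consensus_histogram(table), "removed": list(removed), "n_alive": len(alive)}
        )
        report.removed_ids.extend(removed)
        if not removed:
            break
        alive = np.asarray(retained)
    return alive, report


def balanced_batches(
    labels: Sequence, batch_size: int, rng: np.random.Generator | int | None = None
) -> Iterator[np.ndarray]:
    """Infinite stream of class-balanced index batches (bootstrap per class).

    Every batch holds exactly ``batch_size / n_classes`` samples per class,
    drawn with replacement from that class's pool; deterministic under a
    fixed seed.
    """
    rng = np.random.default_rng(rng)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if batch_size % len(classes):
        raise ValueError(f"batch_size {batch_size} not divisible by {len(classes)} classes")
    pools = [np.flatnonzero(labels == c) for c in classes]
    for pool, c in zip(pools, classes):
        if pool.size == 0:
            raise ValueError(f"class {c!r} has no samples")
    per_class = batch_size // len(classes)
    while True:
        batch = np.concatenate([rng.choice(pool, size=per_class, replace=True) for pool in pools])
        yield batch
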