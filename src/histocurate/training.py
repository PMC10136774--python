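"""Training support: cosine-annealed learning rate, staged fine-tuning plans,
the combined source-by-grade label space, and a pluggable classifier contract
with a lightweight reference implementation.

The learning rate follows the warm-restart cosine schedule: within a cycle
of ``cycle_epochs`` (29 by default) times ``batches_per_epoch`` batch
updates, the rate anneals from ``eta_max`` down to ``eta_min`` along a half
cosine, then restarts ("shocks") back to ``eta_max`` at the cycle boundary.

Transfer learning proceeds in up to four stages: coarse-tune the classifier
head on the pretraining cohort, fine-tune all layers on it, then repeat
both steps on the target cohort. Plans with no pretraining cohort run the
last two stages only.

To generalize across staining sources, a model can be trained on the
product label space source x grade (e.g. cohortA-GS3, cohortB-GS4); at
inference the per-class scores are reduced back to grades by summing over
sources, which preserves total probability.

Heavyweight CNNs are deliberately not part of this package: any model
implementing :class:`ClassifierContract` (two named parameter groups, a
32-unit aggregation layer feeding the output units) can be plugged in.
:class:`ReferenceClassifier` is a small numpy MLP over simple image summary
features that trains in seconds and serves as the committee/evaluation
vehicle for desk-scale experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np

__all__ = [
    "LRScheduleParams",
    "cosine_lr",
    "Stage",
    "make_stage_plan",
    "CombinedLabelSpace",
    "ClassifierContract",
    "extract_patch_features",
    "ReferenceClassifier",
    "run_stage_plan",
]

PARAMETER_GROUPS = ("feature_extractor", "classifier_head")


@dataclass(frozen=True)
class LRScheduleParams:
    """Cosine-annealing schedule parameters.

    ``eta_min`` defaults to ``eta_max / 100`` (one to two orders of
    magnitude below the peak); the cycle length in batch updates is
    ``cycle_epochs * batches_per_epoch``.
    """

    eta_max: float = 0.1
    eta_min: float | None = None
    cycle_epochs: int = 29
    batches_per_epoch: int = 25

    def __post_init__(self) -> None:
        if self.eta_max <= 0:
            raise ValueError("eta_max must be positive")
        if self.eta_min is not None and not (0 < self.eta_min <= self.eta_max):
            raise ValueError("need 0 < eta_min <= eta_max")
        if self.cycle_epochs < 1 or self.batches_per_epoch < 1:
            raise ValueError("cycle_epochs and batches_per_epoch must be >= 1")

    @property
    def floor(self) -> float:
        return self.eta_min if self.eta_min is not None else self.eta_max / 100.0

    @property
    def cycle_batches(self) -> int:
        return self.cycle_epochs * self.batches_per_epoch


def cosine_lr(global_batch: int, params: LRScheduleParams) -> float:
    """Learning rate at a batch counter under cosine annealing with restarts."""
    if global_batch < 0:
        raise ValueError("global_batch must be >= 0")
    T = params.cycle_batches
    t = global_batch % T
    lo = params.floor
    return lo + 0.5 * (params.eta_max - lo) * (1.0 + math.cos(math.pi * t / T))


@dataclass(frozen=True)
class Stage:
    """One fine-tuning stage: which cohort and which parameter groups train."""

    dataset_role: str  # "pretrain" or "target"
    trainable_groups: frozenset[str]

    def __post_init__(self) -> None:
        if self.dataset_role not in ("pretrain", "target"):
            raise ValueError(f"unknown dataset role {self.dataset_role!r}")
        if not self.trainable_groups <= set(PARAMETER_GROUPS):
            raise ValueError(f"unknown parameter group in {self.trainable_groups}")


_HEAD_ONLY = frozenset({"classifier_head"})
_ALL_GROUPS = frozenset(PARAMETER_GROUPS)


def make_stage_plan(two_stage_pretraining: bool = True) -> list[Stage]:
    """Build the staged fine-tuning plan.

    With pretraining: coarse (head-only) then fine (all groups) on the
    pretraining cohort, then the same pair on the target cohort — four
    stages. Without: the target pair only.
    """
    target = [Stage("target", _HEAD_ONLY), Stage("target", _ALL_GROUPS)]
    if not two_stage_pretraining:
        return target
    return [Stage("pretrain", _HEAD_ONLY), Stage("pretrain", _ALL_GROUPS)] + target


class CombinedLabelSpace:
    """Bijection between (source, grade) pairs and class indices.

    Index layout is source-major: ``index = i_source * n_grades + i_grade``,
    so the grade is recoverable as ``index % n_grades`` and reduction to
    grades sums score columns over sources.
    """

    def __init__(self, sources: Sequence[str], grades: Sequence[str]):
        self.sources = list(sources)
        self.grades = list(grades)

    @property
    def n_classes(self) -> int:
        return len(self.sources) * len(self.grades)

    def encode(self, source: str, grade: str) -> int:
        if source not in self.sources:
            raise ValueError(f"unknown source {source!r}")
        if grade not in self.grades:
            raise ValueError(f"unknown grade {grade!r}")
        return self.sources.index(source) * len(self.grades) + self.grades.index(grade)

    def decode(self, index: int) -> tuple[str, str]:
        if not 0 <= index < self.n_classes:
            raise ValueError(f"class index {index} out of range")
        return self.sources[index // len(self.grades)], self.grades[index % len(self.grades)]

    def reduce_to_grade(self, scores: np.ndarray) -> np.ndarray:
        """Collapse (n, sources*grades) scores to (n, grades) by summing sources."""
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        if scores.shape[1] != self.n_classes:
            raise ValueError(f"expected {self.n_classes} score columns, got {scores.shape[1]}")
        return scores.reshape(scores.shape[0], len(self.sources), len(self.grades)).sum(axis=1)


class ClassifierContract(Protocol):
    """Minimal interface a pluggable patch classifier must satisfy."""

    def fit(
        self,
        inputs: np.ndarray,
        class_indices: np.ndarray,
        trainable_groups: frozenset[str] = _ALL_GROUPS,
        lr_schedule: LRScheduleParams | None = None,
    ) -> "ClassifierContract": ...

    def predict_scores(self, inputs: np.ndarray) -> np.ndarray: ...


def extract_patch_features(images: np.ndarray | Sequence[np.ndarray]) -> np.ndarray:
    """Summary features per RGB patch: channel means/sds, gradient energy,
    lumen fraction (bright-pixel share) and gray-level spread.

    Accepts a 4-D array or a list of H x W x 3 arrays (sizes may differ).
    """
    feats = []
    for img in images:
        arr = np.asarray(img, dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[:, :, None].repeat(3, axis=2)
        chans = arr.reshape(-1, arr.shape[2])
        gray = arr.mean(axis=2)
        gy, gx = np.gradient(gray)
        grad_energy = np.sqrt(gx**2 + gy**2).mean()
        lumen_frac = (gray > 0.85 * 255).mean() if gray.max() > 1.5 else (gray > 0.85).mean()
        feats.append(
            np.concatenate(
                [chans.mean(axis=0), chans.std(axis=0), [grad_energy, lumen_frac, gray.std()]]
            )
        )
    return np.asarray(feats)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class ReferenceClassifier:
    """Desk-scale trainable classifier over simple image features.

    Architecture: summary features -> linear+ReLU hidden layer (the
    ``feature_extractor`` group) -> 32-unit aggregation layer + softmax
    output (the ``classifier_head`` group). Trained by minibatch SGD under
    the cosine schedule. Inputs to :meth:`fit`/:meth:`predict_scores` may
    be feature matrices (2-D) or raw patch images (list / 4-D array).
    """

    def __init__(self, n_classes: int = 2, hidden: int = 16, agg: int = 32, seed: int | None = 0):
        self.n_classes = n_classes
        self.hidden = hidden
        self.agg = agg
        self._rng = np.random.default_rng(seed)
        self.params: dict[str, dict[str, np.ndarray]] | None = None
        self._norm: tuple[np.ndarray, np.ndarray] | None = None

    # -- plumbing -------------------------------------------------------------

    def _features(self, inputs) -> np.ndarray:
        arr = np.asarray(inputs, dtype=object) if isinstance(inputs, list) else np.asarray(inputs)
        if isinstance(inputs, list) or arr.ndim > 2:
            return extract_patch_features(inputs)
        return np.asarray(inputs, dtype=np.float64)

    def _init_params(self, n_features: int) -> None:
        r = self._rng
        def glorot(n_in, n_out):
            return r.normal(0.0, math.sqrt(2.0 / (n_in + n_out)), size=(n_in, n_out))

        self.params = {
            "feature_extractor": {"W1": glorot(n_features, self.hidden), "b1": np.zeros(self.hidden)},
            "classifier_head": {
                "W2": glorot(self.hidden, self.agg),
                "b2": np.zeros(self.agg),
                "W3": glorot(self.agg, self.n_classes),
                "b3": np.zeros(self.n_classes),
            },
        }

    def parameter_snapshot(self) -> dict[str, dict[str, np.ndarray]]:
        if self.params is None:
            raise RuntimeError("classifier has not been fit")
        return {g: {k: v.copy() for k, v in grp.items()} for g, grp in self.params.items()}

    # -- forward / backward ---------------------------------------------------

    def _forward(self, X: np.ndarray):
        fe, ch = self.params["feature_extractor"], self.params["classifier_head"]
        h1 = np.maximum(X @ fe["W1"] + fe["b1"], 0.0)
        h2 = np.maximum(h1 @ ch["W2"] + ch["b2"], 0.0)
        probs = _softmax(h2 @ ch["W3"] + ch["b3"])
        return h1, h2, probs

    def fit(
        self,
        inputs,
        class_indices,
        trainable_groups: frozenset[str] = _ALL_GROUPS,
        lr_schedule: LRScheduleParams | None = None,
        epochs: int = 30,
        batch_size: int = 32,
    ) -> "ReferenceClassifier":
        X = self._features(inputs)
        y = np.asarray(class_indices, dtype=int)
        if X.shape[0] == 0:
            raise ValueError("cannot fit on an empty dataset")
        if self._norm is None:
            sd = X.std(axis=0)
            self._norm = (X.mean(axis=0), np.where(sd > 0, sd, 1.0))
        X = (X - self._norm[0]) / self._norm[1]
        if self.params is None:
            self._init_params(X.shape[1])

        n = X.shape[0]
        batches_per_epoch = max(1, n // batch_size)
        if lr_schedule is None:
            lr_schedule = LRScheduleParams(
                eta_max=0.1, cycle_epochs=epochs, batches_per_epoch=batches_per_epoch
            )
        onehot = np.eye(self.n_classes)[y]
        global_batch = 0
        for _ in range(epochs):
            order = self._rng.permutation(n)
            for b in range(batches_per_epoch):
                idx = order[b * batch_size : (b + 1) * batch_size]
                if idx.size == 0:
                    continue
                lr = cosine_lr(global_batch, lr_schedule)
                global_batch += 1
                self._sgd_step(X[idx], onehot[idx], lr, trainable_groups)
        return self

    def _sgd_step(self, Xb, Yb, lr, trainable_groups) -> None:
        fe, ch = self.params["feature_extractor"], self.params["classifier_head"]
        h1, h2, probs = self._forward(Xb)
        m = Xb.shape[0]
        d3 = (probs - Yb) / m
        gW3, gb3 = h2.T @ d3, d3.sum(axis=0)
        d2 = (d3 @ ch["W3"].T) * (h2 > 0)
        gW2, gb2 = h1.T @ d2, d2.sum(axis=0)
        d1 = (d2 @ ch["W2"].T) * (h1 > 0)
        gW1, gb1 = Xb.T @ d1, d1.sum(axis=0)
        if "classifier_head" in trainable_groups:
            ch["W3"] -= lr * gW3
            ch["b3"] -= lr * gb3
            ch["W2"] -= lr * gW2
            ch["b2"] -= lr * gb2
        if "feature_extractor" in trainable_groups:
            fe["W1"] -= lr * gW1
            fe["b1"] -= lr * gb1

    def predict_scores(self, inputs) -> np.ndarray:
        """Per-class probabilities; rows sum to 1."""
        if self.params is None:
            raise RuntimeError("fit must be called before predict_scores")
        X = (self._features(inputs) - self._norm[0]) / self._norm[1]
        return self._forward(X)[2]

    def predict(self, inputs) -> np.ndarray:
        return self.predict_scores(inputs).argmax(axis=1)


def run_stage_plan(
    classifier: ReferenceClassifier,
    plan: Sequence[Stage],
    data_by_role: dict[str, tuple[np.ndarray, np.ndarray]],
    lr_schedule: LRScheduleParams | None = None,
    epochs_per_stage: int = 10,
) -> list[dict]:
    """Execute a stage plan in order, fitting with each stage's group mask.

    ``data_by_role`` maps "pretrain"/"target" to (inputs, class_indices).
    Returns a per-stage log of the groups whose parameters actually changed.
    """
    log = []
    for i, stage in enumerate(plan):
        if stage.dataset_role not in data_by_role:
            raise ValueError(f"stage {i + 1} needs {stage.dataset_role!r} data")
        X, y = data_by_role[stage.dataset_role]
        before = classifier.parameter_snapshot() if classifier.params is not None else None
        classifier.fit(
            X, y, trainable_groups=stage.trainable_groups, lr_schedule=lr_schedule,
            epochs=epochs_per_stage,
        )
        changed = set()
        if before is not None:
            for group, tensors in classifier.params.items():
                if any(not np.array_equal(tensors[k], before[group][k]) for k in tensors):
                    changed.add(group)
        log.append(
            {"stage": i + 1, "dataset_role": stage.dataset_role,
             "trainable_groups": set(stage.trainable_groups), "changed_groups": changed}
        )
    return log
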