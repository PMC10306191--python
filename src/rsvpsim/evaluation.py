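"""Task-performance metrics: per-step top-k accuracy and the sequential
recognition protocol (random multi-category sequences scored at several
presentation durations, in sequential and single-image mode)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, ShapeError
from .network import OutputTrace, RecurrentRateNetwork, make_sequence

__all__ = [
    "SequenceLabels",
    "TopkResult",
    "topk_accuracy",
    "sequential_recognition_protocol",
]


@dataclass
class SequenceLabels:
    """True category index per model step, aligned with an OutputTrace."""

    true_category_per_step: np.ndarray

    def __post_init__(self):
        self.true_category_per_step = np.asarray(
            self.true_category_per_step, dtype=int
        )

    @classmethod
    def from_image_labels(cls, image_labels, steps_per_image: int):
        return cls(np.repeat(np.asarray(image_labels, int), steps_per_image))

    def __len__(self):
        return len(self.true_category_per_step)


@dataclass
class TopkResult:
    per_step: np.ndarray  # bool, length T
    per_image: np.ndarray  # float, one entry per image
    accuracy: float  # mean of per_step


def _topk_sets(values: np.ndarray, k: int) -> np.ndarray:
    # stable argsort of the negated row: ties broken by smallest category index
    order = np.argsort(-values, axis=1, kind="stable")
    return order[:, :k]


def topk_accuracy(trace: OutputTrace, labels, k: int = 5,
                  per_image: str = "mean") -> TopkResult:
    """Score a trace: step t is correct iff its true label is among the k
    largest readout entries (ties to the smallest category index).

    ``per_image`` aggregates step-wise correctness within each image's
    presentation window: "mean" (default) averages over the window,
    "final" keeps only the window's last step.
    """
    if isinstance(labels, SequenceLabels):
        labels = labels.true_category_per_step
    labels = np.asarray(labels, dtype=int)
    T, C = trace.values.shape
    if len(labels) != T:
        raise ShapeError(f"{len(labels)} labels for {T} steps")
    if not 1 <= k <= C:
        raise ConfigError(f"k={k} outside [1, {C}]")
    if labels.min() < 0 or labels.max() >= C:
        raise ShapeError("label out of category range")
    top = _topk_sets(trace.values, k)
    correct = (top == labels[:, None]).any(axis=1)
    images = np.unique(trace.step_to_image)
    if per_image == "mean":
        img_acc = np.array(
            [correct[trace.step_to_image == i].mean() for i in images]
        )
    elif per_image == "final":
        img_acc = np.array(
            [correct[np.flatnonzero(trace.step_to_image == i)[-1]] for i in images],
            dtype=float,
        )
    else:
        raise ConfigError(f"unknown per_image aggregation {per_image!r}")
    return TopkResult(per_step=correct, per_image=img_acc,
                      accuracy=float(correct.mean()))


def sequential_recognition_protocol(
    network: RecurrentRateNetwork,
    image_bank,
    n_sequences: int = 500,
    images_per_sequence: int = 6,
    steps_grid=(1, 2, 4, 8),
    seed: int = 0,
    k: int = 5,
    modes=("sequential", "single_image"),
    per_image: str = "mean",
) -> pd.DataFrame:
    """Accuracy over random image sequences, per mode and duration.

    Each sequence draws ``images_per_sequence`` images from *different*
    categories of the bank; every sequence is scored at every
    steps-per-image value in both sequential mode (state carried across
    images) and single-image mode (state reset per image).  Deterministic
    given ``seed``.  Returns tidy rows (mode, steps_per_image,
    adaptation_kind, accuracy, n).
    """
    n_cat = image_bank.n_categories
    if n_cat < images_per_sequence:
        raise ConfigError(
            f"bank has {n_cat} categories < {images_per_sequence} per sequence"
        )
    rng = np.random.default_rng(seed)
    draws = []  # all sequences drawn up-front, shared across modes and grid
    for _ in range(n_sequences):
        cats = rng.choice(n_cat, size=images_per_sequence, replace=False)
        exemplars = rng.integers(0, image_bank.n_exemplars, images_per_sequence)
        draws.append((cats, exemplars))

    rows = []
    for n_steps in steps_grid:
        acc = {m: [] for m in modes}
        for cats, exemplars in draws:
            images = [image_bank.images[c, e] for c, e in zip(cats, exemplars)]
            if "sequential" in acc:
                trace = network.run_sequential(make_sequence(images, n_steps))
                lab = SequenceLabels.from_image_labels(cats, n_steps)
                acc["sequential"].append(
                    topk_accuracy(trace, lab, k=k, per_image=per_image)
                    .per_image.mean()
                )
            if "single_image" in acc:
                per_img = []
                for c, im in zip(cats, images):
                    tr = network.run_single_image(im, n_steps)
                    lab = SequenceLabels.from_image_labels([c], n_steps)
                    per_img.append(
                        topk_accuracy(tr, lab, k=k, per_image=per_image)
                        .per_image.mean()
                    )
                acc["single_image"].append(np.mean(per_img))
        for mode in modes:
            rows.append(
                {
                    "mode": mode,
                    "steps_per_image": n_steps,
                    "adaptation_kind": network.config.adaptation.kind,
                    "accuracy": float(np.mean(acc[mode])),
                    "n": n_sequences,
                }
            )
    return pd.DataFrame(rows)
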