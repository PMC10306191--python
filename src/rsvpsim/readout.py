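"""Prototype readout: categorical prototypes and representational strength.

A category's prototype is the geometric centre (arithmetic mean) of readout
states evoked by its most semantically relevant exemplars.  Relevance is
judged against a reference vector — the mean of the readout states of the
trial's target and foil image — and exemplars are ranked by similarity to
that reference.  Representational strength p_t is the Pearson correlation
between the network's linear output state y_t and a target vector (a
prototype, a categorical one-hot, or the output state of a single image run
in isolation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DegenerateInputError, ShapeError
from .network import OutputTrace

__all__ = [
    "ExemplarSet",
    "Prototype",
    "RepresentationalTrace",
    "rank_exemplars",
    "compute_prototype",
    "strength_trace",
    "pearson_rows",
]

logger = logging.getLogger(__name__)

TARGET_KINDS = ("prototype", "onehot", "image_state")


@dataclass
class ExemplarSet:
    """Readout states of a category's exemplars plus the relevance reference.

    ``reference`` is the mean of the target-image and foil-image readout
    states, the marker for semantic relevance.
    """

    activations: np.ndarray  # (E, C)
    reference: np.ndarray  # (C,)
    category_label: object = None

    def __post_init__(self):
        self.activations = np.atleast_2d(np.asarray(self.activations, float))
        self.reference = np.asarray(self.reference, float)
        if self.activations.shape[0] < 1:
            raise ShapeError("need at least one exemplar")
        if self.reference.shape != (self.activations.shape[1],):
            raise ShapeError("reference length must match activation columns")

    @property
    def n_exemplars(self) -> int:
        return self.activations.shape[0]


@dataclass
class Prototype:
    """Geometric centre phi of the k most relevant exemplar states."""

    phi: np.ndarray
    k: int
    category_label: object = None

    def __post_init__(self):
        self.phi = np.asarray(self.phi, float)


def pearson_rows(rows: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Pearson r of each row of ``rows`` with vector ``v``; NaN where a row
    (or v) has zero variance."""
    rows = np.atleast_2d(np.asarray(rows, float))
    v = np.asarray(v, float)
    rc = rows - rows.mean(axis=1, keepdims=True)
    vc = v - v.mean()
    denom = np.linalg.norm(rc, axis=1) * np.linalg.norm(vc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, rc @ vc / np.where(denom > 0, denom, 1.0), np.nan)
    return np.clip(r, -1.0, 1.0)


def rank_exemplars(exemplars: ExemplarSet, metric: str = "correlation") -> np.ndarray:
    """Exemplar indices ordered by decreasing semantic relevance.

    Relevance is Pearson correlation with the reference vector by default;
    ``metric="euclidean"`` ranks by increasing distance instead.  Ties keep
    the original order (stable sort).
    """
    if metric == "correlation":
        ref = exemplars.reference
        if np.std(ref) == 0:
            raise DegenerateInputError("zero-variance reference vector")
        score = pearson_rows(exemplars.activations, ref)
        score = np.where(np.isnan(score), -np.inf, score)
        return np.argsort(-score, kind="stable")
    if metric == "euclidean":
        d = np.linalg.norm(exemplars.activations - exemplars.reference, axis=1)
        return np.argsort(d, kind="stable")
    raise ConfigError(f"unknown ranking metric {metric!r}")


def compute_prototype(exemplars: ExemplarSet, k: int,
                      metric: str = "correlation") -> Prototype:
    """Mean of the top-k most relevant exemplar states."""
    if not 1 <= k <= exemplars.n_exemplars:
        raise ConfigError(
            f"k={k} outside [1, {exemplars.n_exemplars}] exemplars"
        )
    order = rank_exemplars(exemplars, metric=metric)
    phi = exemplars.activations[order[:k]].mean(axis=0)
    return Prototype(phi=phi, k=k, category_label=exemplars.category_label)


@dataclass
class RepresentationalTrace:
    """Per-step correlation p_t between output states and a target vector.

    Undefined correlations (zero-variance output rows) are NaN sentinels:
    they mean "no evidence" and are ignored by peak-taking downstream.
    """

    p: np.ndarray
    target_kind: str = "prototype"

    def __post_init__(self):
        self.p = np.asarray(self.p, float)
        if self.target_kind not in TARGET_KINDS:
            raise ConfigError(f"unknown target_kind {self.target_kind!r}")
        finite = self.p[np.isfinite(self.p)]
        if finite.size and (finite.min() < -1 or finite.max() > 1):
            raise ShapeError("correlations outside [-1, 1]")


def strength_trace(trace, target, target_kind: str = "prototype"
                   ) -> RepresentationalTrace:
    """Representational-strength trace p_t = r(target, y_t).

    ``trace`` may be an OutputTrace or a bare (T, C) array; ``target`` a
    Prototype or a C-vector.  Zero-variance rows yield NaN and are counted
    in a log message rather than raising mid-trial.
    """
    values = trace.values if isinstance(trace, OutputTrace) else \
        np.atleast_2d(np.asarray(trace, float))
    phi = target.phi if isinstance(target, Prototype) else np.asarray(target, float)
    if phi.shape != (values.shape[1],):
        raise ShapeError(
            f"target length {phi.shape} != readout dim {values.shape[1]}"
        )
    if np.std(phi) == 0:
        raise DegenerateInputError("zero-variance target vector")
    p = pearson_rows(values, phi)
    n_bad = int(np.isnan(p).sum())
    if n_bad:
        logger.warning("strength_trace: %d/%d undefined (zero-variance) steps",
                       n_bad, p.size)
    return RepresentationalTrace(p=p, target_kind=target_kind)
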