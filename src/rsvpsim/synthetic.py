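"""Synthetic worlds: toy image categories, RSVP trial sets and simulated
observer panels.

The generators emulate the structure of an RSVP detection experiment: six
images per trial drawn from distinct categories, a quarter of trials with
no target, targets never in the first or last position, presentation
duration emulated as model steps per image, and a panel of observers whose
yes-probability is a logistic function of per-trial latent evidence with
per-subject bias and noise.  Everything is deterministic given a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .comparison import ObserverReports
from .errors import ConfigError

__all__ = [
    "SynthConfig",
    "ImageBank",
    "TrialRecord",
    "generate_image_bank",
    "generate_rsvp_trials",
    "generate_observer_panel",
    "nearest_template_labels",
    "trials_to_frame",
    "trials_from_frame",
]

logger = logging.getLogger(__name__)


@dataclass
class SynthConfig:
    """The stated synthetic world.

    Defaults mirror the human experiment being emulated: 176 trials (8
    blocks of 22), 36 subjects, 6 images per trial, 25% target-absent,
    presentation durations 13/40/80 ms mapped to 2/4/8 model steps per
    image.  Image geometry and observer parameters are desk-scale choices
    documented in the methods note.
    """

    n_categories: int = 180
    n_exemplars: int = 12
    image_shape: tuple[int, ...] = (1, 8, 8)
    category_signal: float = 1.0
    noise_sd: float = 0.25
    n_trials: int = 176
    p_target_absent: float = 0.25
    images_per_trial: int = 6
    steps_grid: tuple[int, ...] = (1, 2, 4, 8)
    durations_ms: tuple[int, ...] = (13, 40, 80)
    duration_steps_map: dict = field(
        default_factory=lambda: {13: 2, 40: 4, 80: 8}
    )
    n_subjects: int = 36
    subject_noise_sd: float = 0.5
    observer_gain: float = 6.0
    prototype_k: int = 10
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p_target_absent <= 1.0:
            raise ConfigError("p_target_absent must be in [0, 1]")
        if self.images_per_trial < 3:
            raise ConfigError(
                "images_per_trial must be >= 3 (target needs an interior slot)"
            )
        if self.n_categories < 2:
            raise ConfigError("need at least 2 categories")


@dataclass
class ImageBank:
    """Per-category template images plus noisy exemplars."""

    templates: np.ndarray  # (n_cat, *shape)
    images: np.ndarray  # (n_cat, n_ex, *shape)

    @property
    def n_categories(self) -> int:
        return self.templates.shape[0]

    @property
    def n_exemplars(self) -> int:
        return self.images.shape[1]

    @property
    def image_shape(self) -> tuple[int, ...]:
        return self.templates.shape[1:]

    def flat_images(self) -> np.ndarray:
        """(n_cat * n_ex, D) flattened exemplars with matching labels."""
        n_cat, n_ex = self.images.shape[:2]
        return self.images.reshape(n_cat * n_ex, -1)

    def flat_labels(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_categories), self.n_exemplars)


def generate_image_bank(config: SynthConfig, seed: int | None = None) -> ImageBank:
    """Per category: a fixed uniform-random template plus i.i.d. Gaussian
    pixel noise per exemplar, clipped to [0, 1].

    Random templates are pairwise distinguishable by a linear readout with
    probability one; at ``noise_sd=0`` all exemplars of a category are the
    template itself.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    shape = tuple(config.image_shape)
    base = rng.uniform(0.1, 0.9, (config.n_categories, *shape))
    mid = 0.5
    templates = np.clip(mid + config.category_signal * (base - mid), 0.0, 1.0)
    noise = rng.normal(
        0.0, 1.0, (config.n_categories, config.n_exemplars, *shape)
    )
    images = np.clip(templates[:, None] + config.noise_sd * noise, 0.0, 1.0)
    if config.noise_sd == 0:
        images = np.broadcast_to(templates[:, None], images.shape).copy()
    return ImageBank(templates=templates, images=images)


def nearest_template_labels(images, bank: ImageBank) -> np.ndarray:
    """Nearest-template (Euclidean) category assignment for flat images."""
    flat = np.atleast_2d(np.asarray(images, float).reshape(len(images), -1))
    t = bank.templates.reshape(bank.n_categories, -1)
    d = ((flat[:, None, :] - t[None]) ** 2).sum(axis=2)
    return d.argmin(axis=1)


@dataclass
class TrialRecord:
    """One RSVP trial: ordered stimuli, cue category and target placement.

    ``categories``/``exemplars`` index the image bank per position.  The
    cue's target and foil exemplars (used for the prototype relevance
    reference) are stored explicitly; on target-present trials the target
    exemplar is the one actually shown at ``target_position``.
    """

    trial_id: int
    categories: tuple[int, ...]
    exemplars: tuple[int, ...]
    target_present: bool
    target_position: int | None
    cue_category: int
    cue_target_exemplar: int
    cue_foil_exemplar: int
    duration_ms: int = 0

    def __post_init__(self):
        n = len(self.categories)
        if len(self.exemplars) != n:
            raise ConfigError("categories and exemplars must align")
        if self.target_present:
            if self.target_position is None or not (
                1 <= self.target_position <= n - 2
            ):
                raise ConfigError(
                    "target position must be interior (never first or last)"
                )
            if self.categories[self.target_position] != self.cue_category:
                raise ConfigError("target position must show the cue category")
        elif self.cue_category in self.categories:
            raise ConfigError("target-absent trial shows the cue category")

    def images(self, bank: ImageBank) -> list[np.ndarray]:
        return [bank.images[c, e] for c, e in zip(self.categories, self.exemplars)]


def generate_rsvp_trials(
    config: SynthConfig, bank: ImageBank, seed: int | None = None
) -> list[TrialRecord]:
    """RSVP trial set with the experiment's structural constraints.

    Exactly ``round(n_trials * p_target_absent)`` trials are target-absent
    (stratified, then shuffled); each trial shows ``images_per_trial``
    images from distinct categories; targets sit uniformly on interior
    positions; cue categories are unique across trials when the bank is
    large enough (otherwise reused with a warning).  Presentation-duration
    labels cycle through ``durations_ms`` and are shuffled.
    """
    ipt = config.images_per_trial
    if bank.n_categories < ipt + 1:
        raise ConfigError(
            f"bank needs > {ipt} categories for {ipt}-image trials with an "
            "absent cue"
        )
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    n = config.n_trials
    n_absent = int(round(n * config.p_target_absent))
    present = np.ones(n, bool)
    present[:n_absent] = False
    rng.shuffle(present)

    if bank.n_categories >= n:
        cues = rng.permutation(bank.n_categories)[:n]
    else:
        logger.warning(
            "bank has %d categories for %d trials: cue uniqueness relaxed",
            bank.n_categories, n,
        )
        cues = np.resize(rng.permutation(bank.n_categories), n)
        rng.shuffle(cues)

    durations = np.resize(np.asarray(config.durations_ms), n)
    rng.shuffle(durations)

    trials = []
    for i in range(n):
        cue = int(cues[i])
        others = np.setdiff1d(np.arange(bank.n_categories), [cue])
        cue_tgt, cue_foil = rng.choice(bank.n_exemplars, 2, replace=False)
        if present[i]:
            cats = list(rng.choice(others, ipt - 1, replace=False))
            pos = int(rng.integers(1, ipt - 1))
            cats.insert(pos, cue)
        else:
            cats = list(rng.choice(others, ipt, replace=False))
            pos = None
        exemplars = [int(rng.integers(bank.n_exemplars)) for _ in cats]
        if pos is not None:
            exemplars[pos] = int(cue_tgt)
        trials.append(
            TrialRecord(
                trial_id=i,
                categories=tuple(int(c) for c in cats),
                exemplars=tuple(exemplars),
                target_present=bool(present[i]),
                target_position=pos,
                cue_category=cue,
                cue_target_exemplar=int(cue_tgt),
                cue_foil_exemplar=int(cue_foil),
                duration_ms=int(durations[i]),
            )
        )
    return trials


def generate_observer_panel(
    trial_evidence,
    config: SynthConfig,
    durations=None,
    seed: int | None = None,
    deterministic: bool = False,
) -> ObserverReports:
    """Simulate a panel of observers from per-trial latent evidence.

    Subject s answers yes with probability
    ``logistic(gain * (evidence - median) + bias_s + noise_st)`` where bias
    and noise are N(0, subject_noise_sd) draws.  With zero noise all
    subjects share one probability; with ``deterministic=True`` responses
    threshold that probability at 0.5, making zero-noise subjects
    bitwise identical.
    """
    e = np.asarray(trial_evidence, float)
    if not np.isfinite(e).all():
        raise ConfigError("evidence must be finite")
    n = len(e)
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    z = config.observer_gain * (e - np.median(e))
    bias = rng.normal(0.0, config.subject_noise_sd, config.n_subjects)
    eps = rng.normal(0.0, config.subject_noise_sd, (config.n_subjects, n))
    prob = 1.0 / (1.0 + np.exp(-(z[None, :] + bias[:, None] + eps)))
    if deterministic:
        reports = (prob > 0.5).astype(int)
    else:
        reports = (rng.random((config.n_subjects, n)) < prob).astype(int)
    if durations is None:
        durations = np.resize(np.asarray(config.durations_ms), n)
    return ObserverReports(reports=reports, durations=np.asarray(durations))


def trials_to_frame(trials) -> pd.DataFrame:
    """Tidy trial table: one row per trial, stimuli as dash-joined indices."""
    return pd.DataFrame(
        {
            "trial_id": [t.trial_id for t in trials],
            "categories": ["-".join(map(str, t.categories)) for t in trials],
            "exemplars": ["-".join(map(str, t.exemplars)) for t in trials],
            "target_present": [int(t.target_present) for t in trials],
            "target_position": [
                -1 if t.target_position is None else t.target_position
                for t in trials
            ],
            "cue_category": [t.cue_category for t in trials],
            "cue_target_exemplar": [t.cue_target_exemplar for t in trials],
            "cue_foil_exemplar": [t.cue_foil_exemplar for t in trials],
            "duration_ms": [t.duration_ms for t in trials],
        }
    )


def trials_from_frame(df: pd.DataFrame) -> list[TrialRecord]:
    trials = []
    for row in df.itertuples(index=False):
        pos = None if row.target_position < 0 else int(row.target_position)
        trials.append(
            TrialRecord(
                trial_id=int(row.trial_id),
                categories=tuple(int(c) for c in str(row.categories).split("-")),
                exemplars=tuple(int(e) for e in str(row.exemplars).split("-")),
                target_present=bool(row.target_present),
                target_position=pos,
                cue_category=int(row.cue_category),
                cue_target_exemplar=int(row.cue_target_exemplar),
                cue_foil_exemplar=int(row.cue_foil_exemplar),
                duration_ms=int(row.duration_ms),
            )
        )
    return trials
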