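"""End-to-end glue: build a decodable toy network on a synthetic bank,
derive trial prototypes, simulate PPC tables over a steps grid, and run
the full self-consistency experiment (model -> observers -> comparison).

These functions are what the CLI wraps; they are also the reference
recipes for composing the library by hand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adaptation import AdaptationParams
from .comparison import (
    ObserverReports,
    PredictivityProfile,
    bootstrap_noise_ceilings,
    bootstrap_profile,
    noise_ceilings,
)
from .errors import ConfigError
from .network import (
    LayerSpec,
    NetworkConfig,
    RecurrentRateNetwork,
    build_network,
    make_sequence,
)
from .psychophysics import dprime_table, peak_prototype_correlation
from .readout import ExemplarSet, compute_prototype, strength_trace
from .synthetic import (
    ImageBank,
    SynthConfig,
    TrialRecord,
    generate_image_bank,
    generate_observer_panel,
    generate_rsvp_trials,
)

__all__ = [
    "build_toy_classifier",
    "exemplar_activations",
    "trial_prototype",
    "simulate_ppc",
    "run_self_consistency",
    "SelfConsistencyResult",
]

logger = logging.getLogger(__name__)


def build_toy_classifier(
    bank: ImageBank,
    adaptation: AdaptationParams | None = None,
    hidden_units: int = 32,
    lateral: bool = True,
    seed: int = 0,
    ridge: float = 1e-2,
    calibration_size: int = 64,
) -> RecurrentRateNetwork:
    """A small dense recurrent network whose linear readout decodes the bank.

    Hidden weights are seeded random draws (never trained); normalization
    is frozen from a calibration subset of the bank; the readout is then
    solved in closed form (ridge regression from single-step feedforward
    hidden states to one-hot category labels).  Identically-seeded builds
    on the same bank are identical.
    """
    config = NetworkConfig(
        input_shape=bank.image_shape,
        layer_specs=[LayerSpec(kind="dense", units=hidden_units, lateral=lateral)],
        readout_dim=bank.n_categories,
        adaptation=adaptation or AdaptationParams(),
        seed=seed,
    )
    net = build_network(config)
    flat = bank.flat_images()
    labels = bank.flat_labels()
    rng = np.random.default_rng(seed)
    calib = flat[rng.permutation(len(flat))[: min(calibration_size, len(flat))]]
    net.freeze_normalization(
        [im.reshape(bank.image_shape) for im in calib], at_step=1
    )
    # single-step feedforward hidden states (suppression state is zero at t=0)
    H = np.stack(
        [
            net.hidden_trace(make_sequence([im.reshape(bank.image_shape)], 1))[0]
            for im in flat
        ]
    )
    Y = np.eye(bank.n_categories)[labels]
    Hc = np.column_stack([H, np.ones(len(H))])  # intercept column
    G = Hc.T @ Hc + ridge * np.eye(Hc.shape[1])
    W = np.linalg.solve(G, Hc.T @ Y)  # (hidden+1, C)
    net.readout_W = W[:-1].T
    net.readout_b = W[-1]
    return net


def exemplar_activations(
    network: RecurrentRateNetwork, bank: ImageBank, n_steps: int = 1
) -> np.ndarray:
    """(n_cat, n_ex, C) final-step single-image readout states."""
    out = np.empty((bank.n_categories, bank.n_exemplars, network.config.readout_dim))
    for c in range(bank.n_categories):
        for e in range(bank.n_exemplars):
            out[c, e] = network.run_single_image(bank.images[c, e], n_steps).values[-1]
    return out


def trial_prototype(
    exemplar_acts: np.ndarray, trial: TrialRecord, k: int = 10
):
    """Prototype for a trial's cue category.

    The relevance reference is the mean of the cue's target- and
    foil-exemplar readout states; the prototype is the geometric centre of
    the k most relevant exemplars.
    """
    acts = exemplar_acts[trial.cue_category]
    reference = 0.5 * (
        acts[trial.cue_target_exemplar] + acts[trial.cue_foil_exemplar]
    )
    exemplars = ExemplarSet(
        activations=acts, reference=reference, category_label=trial.cue_category
    )
    return compute_prototype(exemplars, k=min(k, exemplars.n_exemplars))


def simulate_ppc(
    network: RecurrentRateNetwork,
    bank: ImageBank,
    trials,
    steps_grid=(1, 2, 4, 8),
    k: int = 10,
    exemplar_steps: int = 1,
    mode: str = "sequential",
) -> pd.DataFrame:
    """PPC per (trial, steps_per_image): tidy table with columns
    trial_id, steps_per_image, ppc, target_present.

    Sequential mode runs the whole stream with carried state and takes the
    peak over model steps; single-image mode runs every image in isolation
    and takes the peak over images (final-step states).
    """
    if mode not in ("sequential", "single_image"):
        raise ConfigError(f"unknown mode {mode!r}")
    acts = exemplar_activations(network, bank, n_steps=exemplar_steps)
    rows = []
    for trial in trials:
        phi = trial_prototype(acts, trial, k=k)
        images = trial.images(bank)
        for n_steps in steps_grid:
            if mode == "sequential":
                trace = network.run_sequential(make_sequence(images, n_steps))
                p = strength_trace(trace, phi).p
                ppc = peak_prototype_correlation(p, mode="sequential")
            else:
                finals = np.stack(
                    [
                        network.run_single_image(im, n_steps).values[-1]
                        for im in images
                    ]
                )
                p = strength_trace(finals, phi).p
                ppc = peak_prototype_correlation(p, mode="single_image")
            rows.append(
                {
                    "trial_id": trial.trial_id,
                    "steps_per_image": n_steps,
                    "ppc": ppc,
                    "target_present": int(trial.target_present),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class SelfConsistencyResult:
    """Everything the end-to-end synthetic experiment produces."""

    config: SynthConfig
    bank: ImageBank = field(repr=False)
    trials: list = field(repr=False)
    network: RecurrentRateNetwork = field(repr=False)
    ppc: pd.DataFrame = field(repr=False)
    reports: ObserverReports = field(repr=False)
    dprime: pd.DataFrame
    profile: PredictivityProfile
    ceilings: dict
    ceiling_boot: dict = field(repr=False)


def run_self_consistency(
    config: SynthConfig,
    adaptation: AdaptationParams | None = None,
    n_boot: int = 200,
    seed: int | None = None,
    mode: str = "sequential",
) -> SelfConsistencyResult:
    """Full synthetic experiment with observers driven by the model's own PPC.

    Latent evidence for each trial is the model's PPC at the model duration
    mapped from the trial's presentation-duration label, so the generating
    model should track the observer panel up to inter-subject noise.
    """
    seed = config.seed if seed is None else seed
    bank = generate_image_bank(config, seed=seed)
    trials = generate_rsvp_trials(config, bank, seed=seed + 1)
    net = build_toy_classifier(bank, adaptation=adaptation, seed=seed + 2)
    ppc = simulate_ppc(
        net, bank, trials, steps_grid=config.steps_grid,
        k=config.prototype_k, mode=mode,
    )
    ppc_wide = ppc.pivot(index="trial_id", columns="steps_per_image", values="ppc")
    evidence = np.array(
        [
            ppc_wide.loc[t.trial_id, config.duration_steps_map[t.duration_ms]]
            for t in trials
        ]
    )
    durations = np.array([t.duration_ms for t in trials])
    reports = generate_observer_panel(
        evidence, config, durations=durations, seed=seed + 3
    )
    dp = dprime_table(ppc)
    profile = bootstrap_profile(ppc, reports, n_boot=n_boot, seed=seed + 4)
    ceilings = {
        d: noise_ceilings(reports, d) for d in np.unique(durations)
    }
    ceiling_boot = {
        d: bootstrap_noise_ceilings(reports, d, n_boot=n_boot, seed=seed + 5)
        for d in np.unique(durations)
    }
    return SelfConsistencyResult(
        config=config, bank=bank, trials=trials, network=net, ppc=ppc,
        reports=reports, dprime=dp, profile=profile, ceilings=ceilings,
        ceiling_boot=ceiling_boot,
    )
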