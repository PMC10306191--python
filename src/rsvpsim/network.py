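"""Recurrent rate-network simulator for sequential image recognition.

A network is a stack of rectified layers (dense or small same-padded
convolutions), each optionally carrying lateral recurrence (the layer's own
activation at t-1 feeds back into its drive at t) and intrinsic suppression
on its rectifier, followed by a *linear* category readout — no softmax, so
output traces are smooth and unbounded.

Presentation duration is emulated by repeating each image for n model
steps.  In sequential mode recurrent and adaptation state carries across
image boundaries; in single-image mode state is reset before every image.
Normalization is a fixed per-channel affine (frozen batch statistics), so
the network behaves identically at every time step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .adaptation import AdaptationParams, apply_suppression, init_state, step_state
from .errors import ConfigError, ShapeError

__all__ = [
    "LayerSpec",
    "NetworkConfig",
    "StimulusSequence",
    "OutputTrace",
    "RecurrentRateNetwork",
    "build_network",
    "make_sequence",
    "run_sequential",
    "run_single_image",
]


@dataclass(frozen=True)
class LayerSpec:
    """One hidden layer: dense units or conv channels, optional lateral loop."""

    kind: str = "dense"  # "dense" | "conv"
    units: int = 16  # channel count for conv layers
    kernel_size: int = 3  # conv only; odd, same-padded
    lateral: bool = False

    def __post_init__(self):
        if self.kind not in ("dense", "conv"):
            raise ConfigError(f"unknown layer kind {self.kind!r}")
        if self.units < 1:
            raise ConfigError("layer must have >= 1 unit/channel")
        if self.kind == "conv" and self.kernel_size % 2 != 1:
            raise ConfigError("conv kernel_size must be odd (same padding)")


@dataclass
class NetworkConfig:
    """Declarative description of a network.

    ``input_shape`` is ``(channels, height, width)`` for image input or a
    1-tuple for flat input.  Weights are drawn deterministically from
    ``seed``; two identically-seeded builds are bitwise identical.
    """

    input_shape: tuple[int, ...]
    layer_specs: Sequence[LayerSpec]
    readout_dim: int
    adaptation: AdaptationParams = field(default_factory=AdaptationParams)
    seed: int = 0
    weight_scale: float = 1.0
    lateral_scale: float = 0.5

    def __post_init__(self):
        self.input_shape = tuple(int(d) for d in self.input_shape)
        self.layer_specs = list(self.layer_specs)
        if not self.layer_specs:
            raise ConfigError("layer_specs must contain at least one layer")
        if self.readout_dim < 2:
            raise ConfigError("readout_dim must be >= 2")
        for spec in self.layer_specs:
            if spec.kind == "conv" and len(self.input_shape) != 3:
                raise ConfigError("conv layers require (C, H, W) input_shape")


@dataclass
class StimulusSequence:
    """Ordered images, each repeated for ``steps_per_image`` model steps."""

    frames: np.ndarray  # (n_images, *frame_shape)
    steps_per_image: int

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim < 2:
            raise ShapeError("frames must be (n_images, *frame_shape)")
        if self.steps_per_image < 1:
            raise ConfigError("steps_per_image must be >= 1")

    @property
    def n_images(self) -> int:
        return self.frames.shape[0]

    @property
    def n_steps(self) -> int:
        return self.n_images * self.steps_per_image

    @property
    def step_to_image(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_images), self.steps_per_image)

    @property
    def boundaries(self) -> list[tuple[int, int, int]]:
        """(image_index, first_step, last_step) with half-open windows."""
        n = self.steps_per_image
        return [(i, i * n, (i + 1) * n) for i in range(self.n_images)]


def make_sequence(images, steps_per_image: int) -> StimulusSequence:
    """Build a stimulus sequence from a list of same-shaped images."""
    images = list(images)
    if not images:
        raise ShapeError("need at least one image")
    shapes = {np.asarray(im).shape for im in images}
    if len(shapes) != 1:
        raise ShapeError(f"heterogeneous image shapes: {sorted(shapes)}")
    return StimulusSequence(np.stack([np.asarray(im, float) for im in images]),
                            int(steps_per_image))


@dataclass
class OutputTrace:
    """T x C linear readout trace plus the step -> image map."""

    values: np.ndarray
    step_to_image: np.ndarray
    steps_per_image: int = 1

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.step_to_image = np.asarray(self.step_to_image, dtype=int)
        if self.values.ndim != 2:
            raise ShapeError("values must be a T x C matrix")
        if len(self.step_to_image) != self.values.shape[0]:
            raise ShapeError("step_to_image length must equal trace rows")

    @property
    def n_steps(self) -> int:
        return self.values.shape[0]

    @property
    def n_categories(self) -> int:
        return self.values.shape[1]

    def to_frame(self):
        """Tidy long-format view: (step, image_index, category, activation)."""
        import pandas as pd

        T, C = self.values.shape
        return pd.DataFrame(
            {
                "step": np.repeat(np.arange(T), C),
                "image_index": np.repeat(self.step_to_image, C),
                "category": np.tile(np.arange(C), T),
                "activation": self.values.ravel(),
            }
        )


def _conv2d(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    # x: (C_in, H, W); w: (C_out, C_in, k, k); stride 1, same zero padding
    k = w.shape[-1]
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (C_in, H, W, k, k)
    return np.einsum("oikl,ihwkl->ohw", w, win, optimize=True)


class _Layer:
    """Internal per-layer weights and frozen normalization statistics."""

    def __init__(self, spec: LayerSpec, in_shape, rng, weight_scale, lateral_scale):
        self.spec = spec
        if spec.kind == "dense":
            fan_in = int(np.prod(in_shape))
            self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in) * weight_scale,
                                (spec.units, fan_in))
            self.b = np.zeros(spec.units)
            self.out_shape = (spec.units,)
            self.W_lat = (
                rng.normal(0.0, np.sqrt(1.0 / spec.units) * lateral_scale,
                           (spec.units, spec.units))
                if spec.lateral else None
            )
            self.scale = np.ones(spec.units)
            self.shift = np.zeros(spec.units)
        else:
            c_in = in_shape[0]
            k = spec.kernel_size
            fan_in = c_in * k * k
            self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in) * weight_scale,
                                (spec.units, c_in, k, k))
            self.b = np.zeros(spec.units)
            self.out_shape = (spec.units, in_shape[1], in_shape[2])
            self.W_lat = (
                rng.normal(0.0, np.sqrt(1.0 / (spec.units * k * k)) * lateral_scale,
                           (spec.units, spec.units, k, k))
                if spec.lateral else None
            )
            self.scale = np.ones((spec.units, 1, 1))
            self.shift = np.zeros((spec.units, 1, 1))

    def drive(self, x: np.ndarray, h_prev: np.ndarray) -> np.ndarray:
        """Pooled pre-activation: feedforward + bias + lateral, normalized."""
        if self.spec.kind == "dense":
            pre = self.W @ np.ravel(x) + self.b
            if self.W_lat is not None:
                pre = pre + self.W_lat @ h_prev
        else:
            pre = _conv2d(x, self.W) + self.b[:, None, None]
            if self.W_lat is not None:
                pre = pre + _conv2d(h_prev, self.W_lat)
        return pre * self.scale + self.shift


class RecurrentRateNetwork:
    """Sequential recurrent network with a linear readout.

    Not trained here: weights are seeded random draws (or set directly by
    the caller, e.g. a closed-form readout fit).  The linear readout carries
    no rectifier and hence no adaptation.
    """

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.layers: list[_Layer] = []
        shape = config.input_shape
        for spec in config.layer_specs:
            layer = _Layer(spec, shape, rng, config.weight_scale,
                           config.lateral_scale)
            self.layers.append(layer)
            shape = layer.out_shape
        flat = int(np.prod(shape))
        self.readout_W = rng.normal(0.0, np.sqrt(1.0 / flat),
                                    (config.readout_dim, flat))
        self.readout_b = np.zeros(config.readout_dim)

    # -- state -------------------------------------------------------------
    def init_state(self):
        """Zeroed recurrent activations and suppression channels per layer."""
        ad = self.config.adaptation
        return [
            {"h": np.zeros(layer.out_shape), "s": init_state(ad, layer.out_shape)}
            for layer in self.layers
        ]

    # -- single model step -------------------------------------------------
    def step(self, frame: np.ndarray, state, collect: str = "readout"):
        frame = np.asarray(frame, dtype=float)
        if frame.shape != self.config.input_shape:
            raise ShapeError(
                f"frame shape {frame.shape} != input shape {self.config.input_shape}"
            )
        ad = self.config.adaptation
        x = frame
        new_state = []
        collected = []
        for layer, st in zip(self.layers, state):
            pre = layer.drive(x, st["h"])
            a = apply_suppression(pre, st["s"], ad)
            new_state.append({"h": a, "s": step_state(st["s"], a, ad)})
            collected.append(pre if collect == "pre" else a)
            x = a
        y = self.readout(x)
        return y, new_state, collected

    def readout(self, hidden) -> np.ndarray:
        """Linear readout of a (possibly multi-dim) last hidden state."""
        return self.readout_W @ np.ravel(np.asarray(hidden, float)) + self.readout_b

    # -- runs ---------------------------------------------------------------
    def run_sequential(self, sequence: StimulusSequence) -> OutputTrace:
        """Run with state carried across image boundaries.

        The first step is a pure feedforward pass (zero recurrent state).
        """
        state = self.init_state()
        ys = np.empty((sequence.n_steps, self.config.readout_dim))
        t = 0
        for frame in sequence.frames:
            for _ in range(sequence.steps_per_image):
                ys[t], state, _ = self.step(frame, state)
                t += 1
        return OutputTrace(ys, sequence.step_to_image, sequence.steps_per_image)

    def run_single_image(self, image, n_steps: int) -> OutputTrace:
        """Run one image from a fresh (zeroed) state for n_steps."""
        return self.run_sequential(make_sequence([image], n_steps))

    def hidden_trace(self, sequence: StimulusSequence) -> np.ndarray:
        """(T, flat_hidden) final-layer activations of a sequential run."""
        state = self.init_state()
        out = np.empty((sequence.n_steps,
                        int(np.prod(self.layers[-1].out_shape))))
        t = 0
        for frame in sequence.frames:
            for _ in range(sequence.steps_per_image):
                _, state, acts = self.step(frame, state)
                out[t] = np.ravel(acts[-1])
                t += 1
        return out

    # -- normalization ------------------------------------------------------
    def freeze_normalization(self, images, at_step: int = 4, eps: float = 1e-6):
        """Freeze per-channel affine normalization from a calibration batch.

        Each image is run (fresh state) for ``at_step`` steps with the
        current normalization; pre-activation statistics at the final step
        set scale = 1/std and shift = -mean/std per channel/unit, after
        which they never change (time-invariant statistics).
        """
        per_layer = [[] for _ in self.layers]
        for im in images:
            state = self.init_state()
            for _ in range(at_step):
                _, state, pres = self.step(np.asarray(im, float), state,
                                           collect="pre")
            for i, pre in enumerate(pres):
                per_layer[i].append(pre)
        for layer, pres in zip(self.layers, per_layer):
            batch = np.stack(pres)  # (B, units) or (B, C, H, W)
            if layer.spec.kind == "dense":
                mu = batch.mean(axis=0)
                sd = batch.std(axis=0) + eps
            else:
                mu = batch.mean(axis=(0, 2, 3))[:, None, None]
                sd = batch.std(axis=(0, 2, 3))[:, None, None] + eps
            layer.scale = layer.scale / sd
            layer.shift = layer.shift / sd - mu / sd


def build_network(config: NetworkConfig) -> RecurrentRateNetwork:
    """Construct a network with deterministic, seed-derived weights."""
    return RecurrentRateNetwork(config)


def run_sequential(network: RecurrentRateNetwork,
                   sequence: StimulusSequence) -> OutputTrace:
    return network.run_sequential(sequence)


def run_single_image(network: RecurrentRateNetwork, image,
                     n_steps: int) -> OutputTrace:
    return network.run_single_image(image, n_steps)
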