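"""Activation-based intrinsic suppression (rapid neural adaptation).

Each rectified unit carries a suppression state ``s`` that integrates its
own recent activation and is subtracted, scaled by a gain ``beta``, from the
incoming drive before rectification:

    a_t = relu(drive_t - beta * sum_k s_t^(k))
    s_{t+1}^(k) = alpha_k * s_t^(k) + (1 - alpha_k) * a_t

A single decay factor ``alpha`` gives exponential adaptation.  Power-law
adaptation is approximated by a sum of exponentials: one independent state
channel per decay factor, with the effective suppression being the sum over
channels (hence the much smaller ``beta`` of the power-law preset).

Two named presets are provided:

``exponential-vinken``
    alpha = 0.96, beta = 0.7 — the single-exponential mechanism of
    Vinken-style intrinsic suppression.
``powerlaw-paper``
    alphas = (0.96, 0.75), beta = 0.15 — a two-exponential power-law
    approximation whose short-timescale behaviour matches the exponential
    preset but which suppresses far less over long horizons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, ShapeError

__all__ = [
    "AdaptationParams",
    "UnitTrace",
    "PRESETS",
    "get_preset",
    "init_state",
    "step_state",
    "step_exponential",
    "step_powerlaw",
    "apply_suppression",
    "simulate_unit",
]

_KINDS = ("none", "exponential", "powerlaw")


def relu(x):
    """Rectified linear nonlinearity, the sigma of every hidden layer."""
    return np.maximum(x, 0.0)


@dataclass(frozen=True)
class AdaptationParams:
    """Parameters of an intrinsic-suppression mechanism.

    Parameters
    ----------
    kind : {"none", "exponential", "powerlaw"}
        ``none`` disables adaptation entirely (no state, beta ignored).
    alphas : tuple of float
        Per-channel decay factors, each in [0, 1).  Exactly one for
        ``exponential``; one or more for ``powerlaw`` (a single alpha makes
        power-law degenerate to the exponential mechanism).
    beta : float
        Non-negative suppression gain applied to the summed state at
        subtraction time.  States are stored pre-beta so beta can be swept
        without re-simulating.
    """

    kind: str = "none"
    alphas: tuple[float, ...] = field(default=())
    beta: float = 0.0

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ConfigError(f"unknown adaptation kind {self.kind!r}")
        object.__setattr__(self, "alphas", tuple(float(a) for a in self.alphas))
        if self.kind == "none":
            if self.alphas:
                raise ConfigError("kind='none' takes no alphas")
            return
        if not self.alphas:
            raise ConfigError(f"kind={self.kind!r} requires at least one alpha")
        if self.kind == "exponential" and len(self.alphas) != 1:
            raise ConfigError("exponential adaptation takes exactly one alpha")
        for a in self.alphas:
            if not (0.0 <= a < 1.0):
                raise ConfigError(f"alpha {a} outside [0, 1)")
        if self.beta < 0:
            raise ConfigError("beta must be >= 0")

    @property
    def n_channels(self) -> int:
        """Number of suppression state channels (0 when disabled)."""
        return len(self.alphas) if self.kind != "none" else 0

    @property
    def active(self) -> bool:
        return self.kind != "none" and self.beta > 0


#: Named presets addressable from config files.
PRESETS: dict[str, AdaptationParams] = {
    "none": AdaptationParams("none"),
    "exponential-vinken": AdaptationParams("exponential", (0.96,), 0.7),
    "powerlaw-paper": AdaptationParams("powerlaw", (0.96, 0.75), 0.15),
}


def get_preset(name: str) -> AdaptationParams:
    try:
        return PRESETS[name]
    except KeyError:
        raise ConfigError(
            f"unknown adaptation preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def init_state(params: AdaptationParams, unit_shape: tuple[int, ...]) -> np.ndarray:
    """Fresh all-zero suppression state, one channel per alpha.

    Shape is ``(n_channels, *unit_shape)``; an empty array when adaptation
    is disabled.
    """
    return np.zeros((params.n_channels, *unit_shape), dtype=float)


def _check_state(state: np.ndarray, activation: np.ndarray, params: AdaptationParams):
    expected = (params.n_channels, *activation.shape)
    if state.shape != expected:
        raise ShapeError(
            f"state shape {state.shape} does not match "
            f"{params.n_channels} channel(s) over activations {activation.shape}"
        )


def step_state(
    state: np.ndarray, prev_activation, params: AdaptationParams
) -> np.ndarray:
    """One update of every suppression channel (pure; input untouched).

    s_t^(k) = alpha_k * s_{t-1}^(k) + (1 - alpha_k) * a_{t-1}
    """
    a = np.asarray(prev_activation, dtype=float)
    if params.kind == "none":
        return state
    _check_state(state, a, params)
    al = np.asarray(params.alphas).reshape((-1,) + (1,) * a.ndim)
    return al * state + (1.0 - al) * a


def step_exponential(state, prev_activation, params: AdaptationParams) -> np.ndarray:
    """Exponential-adaptation update; requires a single-alpha parameter set."""
    if params.kind != "exponential":
        raise ConfigError("step_exponential requires kind='exponential'")
    return step_state(np.asarray(state, dtype=float), prev_activation, params)


def step_powerlaw(state, prev_activation, params: AdaptationParams) -> np.ndarray:
    """Power-law (sum-of-exponentials) update, one channel per alpha."""
    if params.kind != "powerlaw":
        raise ConfigError("step_powerlaw requires kind='powerlaw'")
    return step_state(np.asarray(state, dtype=float), prev_activation, params)


def suppression_of(state: np.ndarray, params: AdaptationParams):
    """Effective (pre-beta) suppression: the sum over state channels."""
    if params.n_channels == 0:
        return 0.0
    return state.sum(axis=0)


def apply_suppression(drive, state, params: AdaptationParams, nonlinearity=relu):
    """a_t = sigma(drive - beta * sum_k s^(k)).

    With ``beta == 0`` or ``kind='none'`` this returns ``sigma(drive)``
    exactly (same arithmetic, no subtraction performed).
    """
    drive = np.asarray(drive, dtype=float)
    if not np.all(np.isfinite(drive)):
        raise ShapeError("drive contains non-finite values")
    if not params.active:
        return nonlinearity(drive)
    return nonlinearity(drive - params.beta * suppression_of(np.asarray(state), params))


@dataclass
class UnitTrace:
    """Closed-loop time course of a single adapting unit.

    ``suppression`` holds the raw (pre-beta) summed state at each step, so
    the suppressive drive actually subtracted is ``beta * suppression``.
    """

    drive: np.ndarray
    suppression: np.ndarray
    activation: np.ndarray

    def __post_init__(self):
        if not (len(self.drive) == len(self.suppression) == len(self.activation)):
            raise ShapeError("drive/suppression/activation lengths differ")


def simulate_unit(drive_series, params: AdaptationParams) -> UnitTrace:
    """Simulate one rectified unit under a given drive time series.

    Starts from zero state.  Within each step the activation is computed
    from the *current* state, then the state is updated from that
    activation, so suppression at step t reflects activity strictly before
    t.  For constant positive drive x under exponential adaptation the
    trace converges to the fixed point a* = s* = x / (1 + beta).
    """
    drive = np.atleast_1d(np.asarray(drive_series, dtype=float))
    if drive.ndim != 1 or drive.size < 1:
        raise ShapeError("drive_series must be a non-empty 1-d series")
    s = init_state(params, ())
    supp = np.empty_like(drive)
    act = np.empty_like(drive)
    for t, x in enumerate(drive):
        supp[t] = suppression_of(s, params)
        act[t] = apply_suppression(x, s, params)
        s = step_state(s, act[t], params)
    return UnitTrace(drive=drive, suppression=supp, activation=act)
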