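"""Trial-by-trial model-human comparison.

The per-trial human summary is the report rate RR = P/N — the fraction of
subjects reporting "target present", taken over all trials (including
target-absent ones).  A model's predictivity at a given number of model
steps per image and human presentation duration is the Spearman correlation
rho between its PPC values and RR over the trials shown at that duration.
Confidence intervals come from resampling subjects with replacement;
attainable correlation is bounded by noise ceilings (group-average vs
leave-one-out group-average correlations with individual subjects).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ConfigError, DegenerateInputError, ShapeError

__all__ = [
    "ObserverReports",
    "PredictivityProfile",
    "NoiseCeiling",
    "report_rate",
    "spearman",
    "trial_predictivity",
    "bootstrap_profile",
    "noise_ceilings",
    "bootstrap_noise_ceilings",
    "temporal_correspondence",
    "explanatory_power",
]

logger = logging.getLogger(__name__)


@dataclass
class ObserverReports:
    """Binary target-present reports: subjects x trials.

    Every trial carries exactly one presentation-duration label (e.g. 13,
    40 or 80 ms/image); subjects are rows.
    """

    reports: np.ndarray  # (S, N) in {0, 1}
    durations: np.ndarray  # (N,)
    subject_ids: np.ndarray | None = None
    trial_ids: np.ndarray | None = None

    def __post_init__(self):
        self.reports = np.asarray(self.reports, dtype=int)
        self.durations = np.asarray(self.durations)
        if self.reports.ndim != 2:
            raise ShapeError("reports must be subjects x trials")
        if not np.isin(self.reports, (0, 1)).all():
            raise ShapeError("reports must be binary")
        if len(self.durations) != self.reports.shape[1]:
            raise ShapeError("one duration label per trial required")
        if self.subject_ids is None:
            self.subject_ids = np.arange(self.reports.shape[0])
        if self.trial_ids is None:
            self.trial_ids = np.arange(self.reports.shape[1])
        self.subject_ids = np.asarray(self.subject_ids)
        self.trial_ids = np.asarray(self.trial_ids)

    @property
    def n_subjects(self) -> int:
        return self.reports.shape[0]

    @property
    def n_trials(self) -> int:
        return self.reports.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format: (subject, trial, duration_ms, response)."""
        S, N = self.reports.shape
        return pd.DataFrame(
            {
                "subject": np.repeat(self.subject_ids, N),
                "trial": np.tile(self.trial_ids, S),
                "duration_ms": np.tile(self.durations, S),
                "response": self.reports.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ObserverReports":
        wide = df.pivot(index="subject", columns="trial", values="response")
        if wide.isna().any().any():
            raise ShapeError("every subject must have a response on every trial")
        dur = df.drop_duplicates("trial").set_index("trial")["duration_ms"]
        dur = dur.loc[wide.columns]
        return cls(
            reports=wide.to_numpy(int),
            durations=dur.to_numpy(),
            subject_ids=wide.index.to_numpy(),
            trial_ids=wide.columns.to_numpy(),
        )


def report_rate(reports: ObserverReports, duration=None) -> pd.Series:
    """Per-trial report rate RR = (# yes) / (# subjects).

    Includes target-absent trials by construction; restricted to one
    presentation duration when ``duration`` is given.
    """
    mask = (
        np.ones(reports.n_trials, bool)
        if duration is None
        else reports.durations == duration
    )
    rr = reports.reports[:, mask].mean(axis=0)
    return pd.Series(rr, index=reports.trial_ids[mask], name="rr")


def spearman(x, y) -> float:
    """Midrank Spearman rho; NaN sentinel if either input is constant."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ShapeError("spearman needs two equal-length vectors")
    rx, ry = rankdata(x), rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def trial_predictivity(ppc_values, rr_values) -> float:
    """Spearman rho between model PPC and human RR across trials."""
    ppc_values = np.asarray(ppc_values, float)
    if len(ppc_values) < 3:
        raise ConfigError("need >= 3 trials for a rank correlation")
    return spearman(ppc_values, np.asarray(rr_values, float))


def _spearman_matrix(ppc_ranks: np.ndarray, rr: np.ndarray) -> np.ndarray:
    """Spearman of each row of pre-ranked PPC matrix against one RR vector."""
    ry = rankdata(rr)
    ry = ry - ry.mean()
    ny = np.linalg.norm(ry)
    xc = ppc_ranks - ppc_ranks.mean(axis=1, keepdims=True)
    nx = np.linalg.norm(xc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = xc @ ry / (nx * ny)
    rho[(nx == 0)] = np.nan
    if ny == 0:
        rho[:] = np.nan
    return rho


@dataclass
class PredictivityProfile:
    """Spearman rho over (model steps x presentation duration) cells with
    95% bootstrap percentile bounds and, optionally, the full bootstrap
    sample for downstream argmax statistics."""

    steps: np.ndarray  # (S,)
    durations: np.ndarray  # (D,)
    rho: np.ndarray  # (S, D)
    ci_low: np.ndarray
    ci_high: np.ndarray
    boot: np.ndarray | None = field(default=None, repr=False)  # (B, S, D)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.steps):
            for j, d in enumerate(self.durations):
                rows.append(
                    {
                        "steps_per_image": s,
                        "duration": d,
                        "rho": self.rho[i, j],
                        "ci_low": self.ci_low[i, j],
                        "ci_high": self.ci_high[i, j],
                    }
                )
        return pd.DataFrame(rows)


def _cells(ppc_table: pd.DataFrame, reports: ObserverReports):
    """Align PPC values per (steps, duration) cell to the report trials."""
    steps = np.sort(ppc_table["steps_per_image"].unique())
    durations = np.sort(np.unique(reports.durations))
    ppc_wide = ppc_table.pivot(
        index="trial_id", columns="steps_per_image", values="ppc"
    )
    missing = ~np.isin(reports.trial_ids, ppc_wide.index)
    if missing.any():
        logger.warning("excluding %d trial(s) without PPC", int(missing.sum()))
    cells = {}
    for d in durations:
        tmask = (reports.durations == d) & ~missing
        tid = reports.trial_ids[tmask]
        ranks = np.vstack(
            [rankdata(ppc_wide.loc[tid, s].to_numpy(float)) for s in steps]
        )
        cells[d] = (tmask, ranks)
    return steps, durations, cells


def bootstrap_profile(
    ppc_table: pd.DataFrame,
    reports: ObserverReports,
    n_boot: int = 1000,
    seed: int = 0,
    trial_bootstrap: bool = False,
) -> PredictivityProfile:
    """Predictivity profile with subject-bootstrap confidence intervals.

    Subjects are resampled with replacement (``n_boot`` draws, deterministic
    given ``seed``); RR and rho are recomputed per resample and the 95%
    percentile interval is reported per cell.  Trial resampling is
    available behind ``trial_bootstrap`` but off by default.
    """
    if n_boot < 1:
        raise ConfigError("n_boot must be >= 1")
    steps, durations, cells = _cells(ppc_table, reports)
    S = reports.n_subjects
    if S == 1:
        warnings.warn("single subject: bootstrap CIs are degenerate")
    R = reports.reports

    rho = np.full((len(steps), len(durations)), np.nan)
    for j, d in enumerate(durations):
        tmask, ranks = cells[d]
        rho[:, j] = _spearman_matrix(ranks, R[:, tmask].mean(axis=0))

    rng = np.random.default_rng(seed)
    boot = np.full((n_boot, len(steps), len(durations)), np.nan)
    for b in range(n_boot):
        subj = rng.integers(0, S, S)
        for j, d in enumerate(durations):
            tmask, ranks = cells[d]
            rr_b = R[np.ix_(subj, np.flatnonzero(tmask))].mean(axis=0)
            if trial_bootstrap:
                tsel = rng.integers(0, ranks.shape[1], ranks.shape[1])
                boot[b, :, j] = _spearman_matrix(
                    np.vstack([rankdata(r[tsel]) for r in ranks]), rr_b[tsel]
                )
            else:
                boot[b, :, j] = _spearman_matrix(ranks, rr_b)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
        ci_low = np.nanpercentile(boot, 2.5, axis=0)
        ci_high = np.nanpercentile(boot, 97.5, axis=0)
    return PredictivityProfile(steps, durations, rho, ci_low, ci_high, boot)


@dataclass
class NoiseCeiling:
    """Bounds on attainable model-human correlation at one duration."""

    lower: float  # mean leave-one-out Spearman
    upper: float  # mean all-subject Spearman


def noise_ceilings(reports: ObserverReports, duration=None) -> NoiseCeiling:
    """Upper/lower noise ceilings from inter-subject agreement.

    Upper: mean over subjects of Spearman(subject's reports, N-subject mean
    RR).  Lower: the same with the focal subject excluded from the group
    average (N-1 subjects).
    """
    if reports.n_subjects < 2:
        raise ConfigError("noise ceilings require >= 2 subjects")
    mask = (
        np.ones(reports.n_trials, bool)
        if duration is None
        else reports.durations == duration
    )
    R = reports.reports[:, mask].astype(float)
    S = R.shape[0]
    g = R.mean(axis=0)
    upper = np.array([spearman(R[s], g) for s in range(S)])
    loo = (g * S - R) / (S - 1)
    lower = np.array([spearman(R[s], loo[s]) for s in range(S)])
    if np.isnan(upper).all() or np.isnan(lower).all():
        return NoiseCeiling(lower=float("nan"), upper=float("nan"))
    return NoiseCeiling(
        lower=float(np.nanmean(lower)), upper=float(np.nanmean(upper))
    )


def bootstrap_noise_ceilings(
    reports: ObserverReports, duration=None, n_boot: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Subject-bootstrap distribution of the ceilings: rows (boot, lower,
    upper)."""
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(n_boot):
        subj = rng.integers(0, reports.n_subjects, reports.n_subjects)
        rep_b = ObserverReports(
            reports.reports[subj],
            reports.durations,
            subject_ids=np.arange(reports.n_subjects),
            trial_ids=reports.trial_ids,
        )
        nc = noise_ceilings(rep_b, duration)
        rows.append({"boot": b, "lower": nc.lower, "upper": nc.upper})
    return pd.DataFrame(rows)


def temporal_correspondence(profile: PredictivityProfile) -> pd.DataFrame:
    """Most predictive model step per presentation duration.

    Ties resolve to the smallest step (the more parsimonious temporal
    mapping).  When the profile carries a bootstrap sample, the per-boot
    argmax distribution gives 95% bounds on the best step.  All-undefined
    durations are excluded.
    """
    rows = []
    for j, d in enumerate(profile.durations):
        col = profile.rho[:, j]
        if np.isnan(col).all():
            logger.warning("duration %s: all-undefined rho column excluded", d)
            continue
        best = profile.steps[int(np.flatnonzero(col == np.nanmax(col))[0])]
        row = {"duration": d, "best_step": best}
        if profile.boot is not None:
            bb = profile.boot[:, :, j]
            ok = ~np.isnan(bb).all(axis=1)
            idx = [int(np.flatnonzero(r == np.nanmax(r))[0]) for r in bb[ok]]
            best_b = profile.steps[idx]
            row["best_step_ci_low"] = float(np.percentile(best_b, 2.5))
            row["best_step_ci_high"] = float(np.percentile(best_b, 97.5))
        rows.append(row)
    return pd.DataFrame(rows)


def explanatory_power(profile: PredictivityProfile, ceilings) -> float:
    """Best predictivity per duration as a proportion of the lower noise
    ceiling, averaged over durations.

    ``ceilings`` maps each duration to its NoiseCeiling.  Values above 1
    are legal (the model exceeds the ceiling); durations with a
    non-positive or undefined lower ceiling are excluded with a warning.
    """
    ratios = []
    for j, d in enumerate(profile.durations):
        col = profile.rho[:, j]
        if np.isnan(col).all():
            logger.warning("explanatory_power: duration %s has no rho", d)
            continue
        lc = ceilings[d].lower
        if not np.isfinite(lc) or lc <= 0:
            logger.warning(
                "explanatory_power: duration %s excluded (lower ceiling %s)", d, lc
            )
            continue
        ratios.append(np.nanmax(col) / lc)
    if not ratios:
        raise DegenerateInputError("no duration with a usable lower ceiling")
    return float(np.mean(ratios))
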