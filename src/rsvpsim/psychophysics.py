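"""Signal-detection analysis of RSVP trials.

A trial's sensory evidence is its peak prototype correlation (PPC): the
maximum of the representational-strength trace over the trial.  Model
sensitivity is obtained by comparing the PPC distributions of
target-present and target-absent trials through the ROC:

    d'_model = sqrt(2) * z(AUC)

where AUC is estimated by the midrank Mann-Whitney statistic (exactly the
criterion-sweep ROC integral, with ties handled by midranks).  Human
sensitivity uses the log-linear correction: 0.5 added to every trial type
so that d' = z(TPR) - z(FPR) stays finite at 0% and 100% rates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from .errors import ConfigError, DegenerateInputError
from .readout import RepresentationalTrace

__all__ = [
    "SDTCounts",
    "peak_prototype_correlation",
    "roc_auc",
    "model_dprime",
    "dprime_table",
    "human_dprime_loglinear",
]

logger = logging.getLogger(__name__)


def peak_prototype_correlation(trace, mode: str = "sequential") -> float:
    """PPC = max(p) over a trial.

    ``mode="sequential"`` takes the maximum over model steps of the trial's
    trace; ``mode="single_image"`` expects per-image correlation values
    (one per presented image, each from an isolated run) and takes their
    maximum.  NaN entries are "no evidence" sentinels and are skipped; an
    all-undefined trace raises.
    """
    if mode not in ("sequential", "single_image"):
        raise ConfigError(f"unknown PPC mode {mode!r}")
    p = trace.p if isinstance(trace, RepresentationalTrace) else \
        np.asarray(trace, float)
    if p.size == 0:
        raise DegenerateInputError("empty trace")
    finite = p[np.isfinite(p)]
    if finite.size == 0:
        raise DegenerateInputError("all-undefined representational trace")
    return float(finite.max())


def roc_auc(positives, negatives) -> float:
    """Midrank Mann-Whitney AUC: P(pos > neg) + 0.5 P(pos == neg)."""
    pos = np.asarray(positives, float)
    neg = np.asarray(negatives, float)
    n_pos, n_neg = len(pos), len(neg)
    if n_pos == 0 or n_neg == 0:
        raise ConfigError("both classes need at least one value")
    ranks = rankdata(np.concatenate([pos, neg]))
    return float((ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _split_ppc(ppc):
    """Accept a PPC table (DataFrame with ppc/target_present columns) or an
    explicit (present, absent) pair; drop NaN sentinels with a log entry."""
    if isinstance(ppc, pd.DataFrame):
        present = ppc.loc[ppc["target_present"].astype(bool), "ppc"].to_numpy(float)
        absent = ppc.loc[~ppc["target_present"].astype(bool), "ppc"].to_numpy(float)
    else:
        present, absent = (np.asarray(v, float) for v in ppc)
    n_bad = int(np.isnan(present).sum() + np.isnan(absent).sum())
    if n_bad:
        logger.warning("model_dprime: excluding %d undefined PPC value(s)", n_bad)
    return present[~np.isnan(present)], absent[~np.isnan(absent)]


def model_dprime(ppc, absent=None, auc_clamp: float | None = None) -> float:
    """d' = sqrt(2) * z(AUC) over target-present vs target-absent PPCs.

    ``ppc`` is either a PPC table DataFrame or the present-class values with
    ``absent`` the absent-class values.  AUC is clipped to
    [clamp, 1 - clamp] before the probit, default clamp 1/(2n + 2) with n
    the total trial count, so perfect separation maps to a finite d'.
    """
    present, neg = _split_ppc(ppc if absent is None else (ppc, absent))
    if len(present) == 0 or len(neg) == 0:
        raise ConfigError("need >=1 target-present and >=1 target-absent trial")
    auc = roc_auc(present, neg)
    n = len(present) + len(neg)
    clamp = 1.0 / (2 * n + 2) if auc_clamp is None else float(auc_clamp)
    return float(np.sqrt(2.0) * ndtri(np.clip(auc, clamp, 1.0 - clamp)))


def dprime_table(ppc_table: pd.DataFrame, by=("steps_per_image",)) -> pd.DataFrame:
    """One d' row per group of a tidy PPC table (default: per duration)."""
    rows = []
    for keys, grp in ppc_table.groupby(list(by)):
        keys = keys if isinstance(keys, tuple) else (keys,)
        rows.append(
            dict(zip(by, keys))
            | {"dprime": model_dprime(grp), "n": len(grp)}
        )
    return pd.DataFrame(rows)


@dataclass
class SDTCounts:
    """Signal-detection trial counts for one observer and condition."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")

    @classmethod
    def from_reports(cls, responses, target_present) -> "SDTCounts":
        """Tally binary yes/no responses against ground truth."""
        r = np.asarray(responses, int)
        t = np.asarray(target_present, bool)
        if r.shape != t.shape:
            raise ConfigError("responses and truth must align")
        return cls(
            tp=int((r[t] == 1).sum()),
            fn=int((r[t] == 0).sum()),
            fp=int((r[~t] == 1).sum()),
            tn=int((r[~t] == 0).sum()),
        )


def human_dprime_loglinear(counts: SDTCounts) -> float:
    """Log-linear d': 0.5 added to every cell, finite for all count tables.

    TPR = (TP + 0.5) / (TP + FN + 1), FPR = (FP + 0.5) / (FP + TN + 1),
    d' = z(TPR) - z(FPR).
    """
    tpr = (counts.tp + 0.5) / (counts.tp + counts.fn + 1.0)
    fpr = (counts.fp + 0.5) / (counts.fp + counts.tn + 1.0)
    return float(ndtri(tpr) - ndtri(fpr))
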