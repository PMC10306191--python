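"""Minimal plotting helpers for predictivity profiles and ceilings."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .comparison import PredictivityProfile


def plot_predictivity(profile: PredictivityProfile, ceilings=None, path=None):
    """One panel per presentation duration: rho over model steps with 95%
    bootstrap band and, if given, the noise-ceiling range."""
    D = len(profile.durations)
    fig, axes = plt.subplots(1, D, figsize=(3.2 * D, 3.0), sharey=True,
                             squeeze=False)
    for j, d in enumerate(profile.durations):
        ax = axes[0, j]
        ax.plot(profile.steps, profile.rho[:, j], "o-", color="tab:blue")
        ax.fill_between(profile.steps, profile.ci_low[:, j],
                        profile.ci_high[:, j], alpha=0.25, color="tab:blue")
        if ceilings is not None and d in ceilings:
            nc = ceilings[d]
            ax.axhspan(nc.lower, nc.upper, color="grey", alpha=0.3,
                       label="noise ceiling")
        ax.set_title(f"{d} ms/image")
        ax.set_xlabel("model steps per image")
        if j == 0:
            ax.set_ylabel(r"Spearman $\rho$ (PPC vs RR)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
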