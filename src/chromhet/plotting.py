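"""Basic plots mirroring the field's conventions (log-scaled separation axis)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .metrics import HeterogeneityProfile, RsProfile  # noqa: E402

__all__ = ["plot_heterogeneity"]


def plot_heterogeneity(
    profiles: list[RsProfile],
    het: HeterogeneityProfile,
    path: str,
) -> str:
    """Three-panel figure: per-cell Rs, relative Rs, and relative C.H. vs s."""
    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    s_bp = het.grid.separations_bp
    for p in profiles:
        axes[0].plot(s_bp, p.values, lw=0.6, alpha=0.6)
    axes[0].set_ylabel("Rs")
    if het.relative_rs is not None:
        for row in het.relative_rs:
            axes[1].plot(s_bp, row, lw=0.6, alpha=0.6)
    axes[1].set_ylabel("relative Rs")
    if het.resample_sd is not None:
        axes[2].errorbar(s_bp, het.relative_ch, yerr=het.resample_sd,
                         lw=1.0, elinewidth=0.5)
    else:
        axes[2].plot(s_bp, het.relative_ch, lw=1.0)
    axes[2].set_ylabel("relative C.H.")
    for ax in axes:
        ax.set_xscale("log")
        ax.set_xlabel("genomic separation s (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
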