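"""Optional plotting of diagnostic data (requires matplotlib).

These render the data products produced elsewhere: the funnel of per-SNP
estimates against precision, and the SNP-outcome vs SNP-exposure scatter
with fitted IVW and MR-Egger lines.
"""

from __future__ import annotations

import numpy as np


def _pyplot():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def funnel_plot(funnel_table, pooled: float | None = None, path=None):
    """Precision vs per-SNP causal estimate, with the pooled estimate marked."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(funnel_table["theta"], funnel_table["precision"], s=18, alpha=0.8)
    if pooled is not None:
        ax.axvline(pooled, color="crimson", lw=1, label=f"pooled = {pooled:.3g}")
        ax.legend(frameon=False)
    ax.set_xlabel("per-SNP causal estimate")
    ax.set_ylabel("precision (1/SE)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def effect_scatter(instruments, fits: dict[str, tuple[float, float]] | None = None, path=None):
    """SNP-outcome vs SNP-exposure effects with (intercept, slope) fit lines."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(
        instruments.gamma_hat, instruments.Gamma_hat,
        xerr=instruments.sigma_x, yerr=instruments.sigma_y,
        fmt="o", ms=4, lw=0.8, alpha=0.8,
    )
    if fits:
        xs = np.linspace(0, float(np.max(instruments.gamma_hat)) * 1.05, 50)
        for label, (intercept, slope) in fits.items():
            ax.plot(xs, intercept + slope * xs, lw=1.2, label=label)
        ax.legend(frameon=False)
    ax.set_xlabel("SNP-exposure effect")
    ax.set_ylabel("SNP-outcome effect")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
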