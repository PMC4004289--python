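"""Rendering helpers: context-matrix heatmaps and drift curves.

Matplotlib is imported lazily so the core pipeline stays import-light.
"""

from __future__ import annotations

import numpy as np

from codoncontext.codon_stats import CodonContextMatrix
from codoncontext.drift_analysis import DriftCurve

__all__ = ["plot_matrix_heatmap", "plot_drift_curve"]


def plot_matrix_heatmap(m: CodonContextMatrix, out_path=None, ax=None):
    """Heatmap of the 61x61 context matrix, probability 0..1.

    Rows are the first codon of the pair, columns the second; the
    single-codon amino-acid columns (ATG, TGG) render as solid stripes.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 9))
    im = ax.imshow(m.P, cmap="RdBu", vmin=0.0, vmax=1.0, interpolation="nearest")
    ticks = np.arange(len(m.labels))
    ax.set_xticks(ticks, m.labels, rotation=90, fontsize=4)
    ax.set_yticks(ticks, m.labels, fontsize=4)
    ax.set_xlabel("second codon")
    ax.set_ylabel("first codon")
    if m.source_label:
        ax.set_title(m.source_label)
    ax.figure.colorbar(im, ax=ax, label="P(second codon | first codon, second aa)")
    if out_path is not None:
        ax.figure.savefig(out_path, dpi=200, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_drift_curve(curve: DriftCurve, out_path=None, ax=None, label="random subsets"):
    """Mean +/- sd drift versus subsample size with the fitted power law."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.errorbar(
        curve.sizes,
        curve.mean_norm,
        yerr=curve.sd_norm,
        fmt="s",
        capsize=3,
        label=label,
    )
    if curve.fit_A is not None:
        xs = np.linspace(min(curve.sizes), max(curve.sizes), 200)
        ax.plot(
            xs,
            curve.fit_A * xs**curve.fit_b,
            "--",
            label=f"fit: y = {curve.fit_A:.3g} x^{curve.fit_b:.3g}",
        )
    ax.set_xlabel("genes per subsample")
    ax.set_ylabel("Frobenius drift from reference")
    ax.legend()
    if out_path is not None:
        ax.figure.savefig(out_path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
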