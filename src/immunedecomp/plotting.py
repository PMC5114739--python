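"""Plots for the mixture-recovery sweep."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["plot_recovery"]


def plot_recovery(results: pd.DataFrame, axes=None):
    """Recovery rho (top) and bootstrap p (bottom) against the noise level.

    ``results`` is the tidy frame from
    :func:`immunedecomp.validation.run_snr_sweep`; the clean dataset
    (snr = inf) is drawn leftmost.  Returns the two matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(2, 1, sharex=True, figsize=(6, 6))
    ax_rho, ax_p = axes

    levels = sorted(results["snr"].unique(), reverse=True)
    xticks = np.arange(len(levels))
    pos = {s: i for i, s in enumerate(levels)}
    for cell_type, chunk in results.groupby("cell_type"):
        chunk = chunk.sort_values("snr", ascending=False)
        x = [pos[s] for s in chunk["snr"]]
        ax_rho.plot(x, chunk["rho"], marker="o", label=cell_type)
        ax_p.plot(x, chunk["p"], marker="o", label=cell_type)
    ax_rho.axhline(0.6, color="gray", ls="--", lw=0.8)
    ax_p.axhline(0.05, color="gray", ls="--", lw=0.8)
    ax_rho.set_ylabel("Spearman rho (true vs inferred)")
    ax_p.set_ylabel("bootstrap p")
    ax_p.set_xlabel("noise level (S of S:1)")
    ax_p.set_xticks(xticks)
    ax_p.set_xticklabels(
        ["clean" if np.isinf(s) else f"{s:g}:1" for s in levels]
    )
    ax_rho.legend(fontsize=8)
    return axes
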