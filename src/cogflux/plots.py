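"""Diagnostic plots (PNG); reporting only, never load-bearing."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_learning_curves(
    sessions: pd.DataFrame, curves: pd.DataFrame, path: str | Path,
    max_panels: int = 12,
) -> None:
    """Per-participant baseline-adjusted series with fitted inverse curves."""
    curves = curves.set_index("participant_id")
    pids = list(curves.index[:max_panels])
    ncol = 4
    nrow = int(np.ceil(len(pids) / ncol))
    fig, axes = plt.subplots(
        nrow, ncol, figsize=(3.2 * ncol, 2.6 * nrow), squeeze=False
    )
    for ax, pid in zip(axes.ravel(), pids):
        grp = sessions[sessions["participant_id"] == pid].sort_values(
            "assessment_index"
        )
        row = curves.loc[pid]
        y = grp["d_prime"].to_numpy() - row["starting_point"]
        x = grp["assessment_index"].to_numpy(dtype=float)
        ax.plot(x, y, color="0.6", lw=0.8)
        if row["fit_adequate"]:
            xx = np.linspace(1, x.max(), 200)
            ax.plot(xx, row["asymptote_a"] - row["slope_b"] / xx, color="tab:orange")
            ax.axhline(row["asymptote_a"], ls="--", color="k", lw=0.8)
            if pd.notna(row.get("learning_rate_90")):
                ax.axvline(row["learning_rate_90"], color="0.8")
        ax.set_title(pid, fontsize=8)
    for ax in axes.ravel()[len(pids):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def plot_residual_diagnostics(fit, path: str | Path) -> None:
    """Residual histogram and residual-vs-fitted scatter for one model."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3))
    resid = np.asarray(fit.lmm.resid)
    ax1.hist(resid, bins=40, color="0.7")
    ax1.set_xlabel("conditional residual")
    ax2.plot(fit.lmm.fitted, resid, ".", ms=2, alpha=0.5)
    ax2.axhline(0, color="k", lw=0.8)
    ax2.set_xlabel("fitted")
    ax2.set_ylabel("residual")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
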