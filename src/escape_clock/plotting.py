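"""Minimal plot helpers driven by the pipeline's output TSVs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_timeline", "plot_timing_distributions"]

_LABEL_COLORS = {"early": "#2ca02c", "late": "#7b3294", "undetermined": "#bbbbbb", "": "#eeeeee"}


def plot_timeline(timeline: pd.DataFrame, out_path) -> Path:
    """Dot plot of cancer-type-level event labels with the smoothed
    late/early ratio on the x axis (log scale)."""
    df = timeline.copy()
    df["label"] = df["label"].fillna("")
    ctypes = sorted(df["cancer_type"].unique())
    events = sorted(df["event"].unique())
    fig, axes = plt.subplots(
        1, len(ctypes), figsize=(3.2 * len(ctypes), 0.5 * len(events) + 1.5),
        sharey=True, squeeze=False,
    )
    for ax, ct in zip(axes[0], ctypes):
        sub = df[df["cancer_type"] == ct].set_index("event").reindex(events)
        y = np.arange(len(events))
        colors = [_LABEL_COLORS.get(str(l), "#bbbbbb") for l in sub["label"]]
        ax.scatter(sub["ratio"], y, c=colors, s=60, edgecolors="black", linewidths=0.5)
        ax.axvline(0.5, ls="--", lw=0.8, color="#2ca02c")
        ax.axvline(2.0, ls="--", lw=0.8, color="#7b3294")
        ax.set_xscale("log")
        ax.set_yticks(y, events)
        ax.set_xlabel("(late + 1) / (early + 1)")
        ax.set_title(ct)
    fig.tight_layout()
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def plot_timing_distributions(timing: pd.DataFrame, out_path, by: str = "gene") -> Path:
    """Histogram grid of per-SNV mean mutation times grouped by a column."""
    df = timing[timing["timed"].fillna(False).astype(bool)]
    groups = sorted(df[by].dropna().unique())
    n = max(len(groups), 1)
    ncols = min(n, 4)
    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 2.2 * nrows), squeeze=False)
    for ax, g in zip(axes.ravel(), groups):
        vals = df.loc[df[by] == g, "mean_time"].dropna()
        ax.hist(vals, bins=np.linspace(0, 1.05, 22), color="#4477aa")
        ax.set_title(str(g), fontsize=9)
        ax.set_xlim(0, 1.05)
    for ax in axes.ravel()[len(groups):]:
        ax.axis("off")
    fig.tight_layout()
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
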