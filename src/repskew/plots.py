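"""Figure writers for region maps, information sweeps and info-value curves.

All functions take tidy tables produced by the solver modules and write a
vector-graphics file; styling is deliberately minimal.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = [
    "region_heatmap",
    "sweep_figure",
    "optimal_information_figure",
    "relatedness_value_figure",
]

_REGION_COLORS = {
    "both_prefer_group": "#2ca02c",
    "dominant_only": "#ffdd44",
    "subordinate_only": "#17becf",
    "neither": "#1f77b4",
}


def region_heatmap(table: pd.DataFrame, path: str, title: str = "") -> None:
    """Region map over (perceived z, true x) with the offer curve overlaid."""
    xs = np.sort(table["x"].unique())
    zs = np.sort(table["z"].unique())
    codes = {label: i for i, label in enumerate(_REGION_COLORS)}
    grid = (
        table.pivot_table(index="x", columns="z", values="region",
                          aggfunc="first")
        .reindex(index=xs, columns=zs)
        .replace(codes)
        .to_numpy(dtype=float)
    )
    cmap = matplotlib.colors.ListedColormap(list(_REGION_COLORS.values()))
    fig, ax = plt.subplots(figsize=(4.2, 3.6))
    ax.pcolormesh(zs, xs, grid, cmap=cmap, vmin=-0.5,
                  vmax=len(codes) - 0.5, shading="nearest")
    offer = table.groupby("z", sort=True)["share"].first()
    ax.plot(offer.index, offer.to_numpy(), color="black", lw=1.5,
            label="offered share y*")
    ax.set_xlabel("perceived quality z")
    ax.set_ylabel("true quality x / share y")
    if title:
        ax.set_title(title, fontsize=9)
    ax.legend(loc="upper left", fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def sweep_figure(frame: pd.DataFrame, path: str, title: str = "") -> None:
    """Mean share and mean fitness of both parties against omega."""
    finite = frame[np.isfinite(frame["omega"])]
    fig, axes = plt.subplots(3, 1, figsize=(4.2, 7.0), sharex=True)
    panels = (
        ("mean_share", "mean concession y"),
        ("dominant_mean", "dominant mean inclusive fitness"),
        ("subordinate_mean", "subordinate mean inclusive fitness"),
    )
    for ax, (col, label) in zip(axes, panels):
        ax.plot(finite["omega"], finite[col], "-o", ms=3, color="black")
        inf_rows = frame[~np.isfinite(frame["omega"])]
        if not inf_rows.empty:
            ax.axhline(inf_rows[col].iloc[0], ls="--", color="gray",
                       label="perfect information")
        if col != "mean_share":
            ax.axhline(frame["alone_baseline"].iloc[0], ls="-.",
                       color="firebrick", label="alone")
        ax.set_ylabel(label, fontsize=8)
        ax.legend(fontsize=6)
    axes[-1].set_xscale("symlog", linthresh=1.0)
    axes[-1].set_xlabel("information about quality, omega")
    if title:
        axes[0].set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def optimal_information_figure(frame: pd.DataFrame, path: str,
                               title: str = "") -> None:
    """Optimal omega against relatedness, one line per party/quality."""
    fig, ax = plt.subplots(figsize=(4.2, 3.4))
    for label, sub in frame.groupby("party"):
        ax.plot(sub["r"], sub["omega_star"].replace(np.inf, np.nan), "-o",
                ms=3, label=label)
    ax.set_xlabel("relatedness r")
    ax.set_ylabel("preferred information omega*")
    ax.set_yscale("symlog", linthresh=1.0)
    ax.legend(fontsize=6)
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def relatedness_value_figure(frame: pd.DataFrame, path: str,
                             title: str = "") -> None:
    """Value of relatedness information against quality, per QPC value."""
    fig, axes = plt.subplots(1, 3, figsize=(8.4, 2.9), sharex=True)
    panels = (
        ("delta_dominant", "dominant"),
        ("delta_unrelated", "unrelated subordinate"),
        ("delta_related", "related subordinate"),
    )
    for ax, (col, label) in zip(axes, panels):
        for a, sub in frame.groupby("a"):
            ax.plot(sub["x"], sub[col], label=f"a = {a:g}")
        ax.axhline(0.0, color="gray", lw=0.5)
        ax.set_xlabel("subordinate quality x")
        ax.set_title(label, fontsize=8)
    axes[0].set_ylabel("fitness gain from knowing r")
    axes[0].legend(fontsize=6)
    if title:
        fig.suptitle(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
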