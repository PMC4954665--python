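"""Static figures for study reports: presence/absence plot, spatial
chronograms, PT box plots, overlap heat map, typology/environment overlay
and the PCoA scatter."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

ZONE_COLORS = {"NT": "#d62728", "PR": "#1f77b4", "NR": "#2ca02c", "": "white"}


def presence_plot(presence: pd.DataFrame, ax=None):
    """Daily presence grid: one row per fish, coloured by zone."""
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 0.25 * max(len(presence.columns), 4) + 1))
    dates = list(presence.index)
    for i, tag in enumerate(presence.columns):
        zs = presence[tag]
        for j, z in enumerate(zs):
            if z:
                ax.plot([j, j + 1], [i, i], color=ZONE_COLORS.get(z, "gray"), lw=4)
    ax.set_yticks(range(len(presence.columns)))
    ax.set_yticklabels(presence.columns)
    step = max(len(dates) // 8, 1)
    ax.set_xticks(range(0, len(dates), step))
    ax.set_xticklabels([str(dates[k]) for k in range(0, len(dates), step)], rotation=45)
    ax.set_xlabel("date")
    ax.set_ylabel("fish")
    return ax


def chronogram_plot(grid: pd.DataFrame, ax=None):
    """Day x 30-min-bin grid coloured by modal receiver; empty bins white."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 6))
    stations = sorted({s for s in grid.to_numpy().ravel() if s})
    code = {s: i + 1 for i, s in enumerate(stations)}
    z = grid.map(lambda s: code.get(s, 0)).to_numpy(dtype=float)
    z[z == 0] = np.nan  # white
    ax.imshow(z, aspect="auto", interpolation="nearest", cmap="tab20")
    ax.set_xlabel("30-min interval of day")
    ax.set_ylabel("day of tracking period")
    return ax


def pt_boxplot(series_by_fish: dict, variable: str = "mean depth", ax=None):
    """Distribution of PT_DN values per fish."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    tags = list(series_by_fish)
    ax.boxplot([series_by_fish[t] for t in tags], labels=tags, showfliers=False)
    ax.axhline(0.0, color="gray", lw=0.8)
    ax.set_ylabel(f"PT D-N ({variable})")
    ax.set_xlabel("fish")
    return ax


def overlap_heatmap(overlap: pd.DataFrame, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(overlap.to_numpy(), cmap="viridis")
    ax.set_xticks(range(len(overlap.columns)))
    ax.set_xticklabels(overlap.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(overlap.index)))
    ax.set_yticklabels(overlap.index, fontsize=6)
    plt.colorbar(im, ax=ax, label="UDOI")
    return ax


def typology_overlay_plot(env_overlay: pd.DataFrame, ax=None):
    """Wave height / SST series with extraordinary days marked."""
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    x = pd.to_datetime(env_overlay["date"])
    extra = env_overlay["label"] == "extraordinary"
    for d in x[extra]:
        ax.axvline(d, color="red", alpha=0.4, lw=1)
    if "wave_m" in env_overlay:
        ax.plot(x, env_overlay["wave_m"], color="steelblue", label="wave height (m)")
    if "sst_c" in env_overlay:
        ax2 = ax.twinx()
        ax2.plot(x, env_overlay["sst_c"], color="darkorange", label="SST (°C)")
        ax2.set_ylabel("SST (°C)")
    ax.set_ylabel("wave height (m)")
    ax.legend(loc="upper left")
    return ax


def pcoa_plot(typology, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    c = typology.coordinates
    lab = typology.labels
    for name, color in (("ordinary", "steelblue"), ("extraordinary", "red")):
        m = lab == name
        if c.shape[1] >= 2:
            ax.scatter(c.loc[m.to_numpy(), "PCo1"], c.loc[m.to_numpy(), "PCo2"],
                       s=12, label=name, color=color, alpha=0.7)
    ax.set_xlabel("PCo1")
    ax.set_ylabel("PCo2")
    ax.legend()
    return ax


def save_report_figures(report, out_dir) -> None:
    """Write the standard figure set for a finished study run."""
    from pathlib import Path

    out = Path(out_dir)
    if report.presence is not None and len(report.presence):
        presence_plot(report.presence)
        plt.savefig(out / "presence.png", dpi=120, bbox_inches="tight")
        plt.close("all")
    if report.overlap is not None and len(report.overlap):
        overlap_heatmap(report.overlap)
        plt.savefig(out / "overlap.png", dpi=120, bbox_inches="tight")
        plt.close("all")
    if report.env_overlay is not None and len(report.env_overlay):
        typology_overlay_plot(report.env_overlay)
        plt.savefig(out / "typology_env.png", dpi=120, bbox_inches="tight")
        plt.close("all")
    if report.typology is not None:
        pcoa_plot(report.typology)
        plt.savefig(out / "pcoa.png", dpi=120, bbox_inches="tight")
        plt.close("all")
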