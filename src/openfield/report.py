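"""Figure rendering from pipeline CSV outputs.

Kept separate from the numeric stages so the pipeline itself has no hard
plotting dependency: time-course curves (mean +/- SEM per dose), p-value
heatmaps, zone occupancy heatmaps and individual track plots.
"""

from __future__ import annotations

import glob
import os

import numpy as np
import pandas as pd


def _require_matplotlib():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_timecourses(bins: pd.DataFrame, out_dir: str) -> None:
    plt = _require_matplotlib()
    for (drug, metric), sub in bins.groupby(["drug", "metric"]):
        pooled = pd.concat(
            [sub, bins[(bins["drug"] == "saline") & (bins["metric"] == metric)]]
        )
        if drug == "saline":
            continue
        fig, ax = plt.subplots(figsize=(6, 4))
        for dose, grp in pooled.groupby("dose"):
            agg = grp.groupby("bin_end_min")["value"].agg(["mean", "sem"])
            label = "saline" if dose == 0 else f"{dose:g} mg/kg"
            ax.errorbar(agg.index, agg["mean"], yerr=agg["sem"], label=label)
        ax.set_xlabel("time (min)")
        ax.set_ylabel(metric)
        ax.set_title(f"{metric} over time, {drug}")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(os.path.join(out_dir, f"timecourse_{drug}_{metric}.png"), dpi=120)
        plt.close(fig)


def plot_heatmap_tables(stats_dir: str, out_dir: str) -> None:
    plt = _require_matplotlib()
    for path in sorted(glob.glob(os.path.join(stats_dir, "heatmap_*.csv"))):
        name = os.path.splitext(os.path.basename(path))[0]
        table = pd.read_csv(path, index_col=0)
        clipped = table.clip(lower=1e-4, upper=0.9999)
        fig, ax = plt.subplots(figsize=(8, 2 + 0.3 * len(table)))
        im = ax.imshow(
            -np.log10(clipped.to_numpy(dtype=float)),
            aspect="auto",
            cmap="viridis",
            vmin=0,
            vmax=4,
        )
        ax.set_xticks(range(len(table.columns)), table.columns, fontsize=6)
        ax.set_yticks(range(len(table.index)), table.index, fontsize=7)
        ax.set_title(name)
        fig.colorbar(im, ax=ax, label="-log10 adjusted p")
        fig.tight_layout()
        fig.savefig(os.path.join(out_dir, f"{name}.png"), dpi=120)
        plt.close(fig)


def plot_track_examples(traj_dir: str, out_dir: str, n: int = 6) -> None:
    from .core import iter_sessions, read_manifest

    plt = _require_matplotlib()
    manifest = read_manifest(os.path.join(traj_dir, "manifest.csv"))
    picks = manifest.sort_values("dose").groupby("drug").head(1).head(n)
    fig, axes = plt.subplots(1, max(len(picks), 1), figsize=(3 * len(picks), 3))
    axes = np.atleast_1d(axes)
    for ax, (meta, traj) in zip(axes, iter_sessions(picks, traj_dir)):
        ax.plot(traj.center[:, 0], traj.center[:, 1], lw=0.3)
        ax.set_xlim(0, traj.arena.side_length)
        ax.set_ylim(0, traj.arena.side_length)
        ax.set_aspect("equal")
        ax.set_title(f"{meta.drug} {meta.dose:g}", fontsize=8)
    fig.tight_layout()
    fig.savefig(os.path.join(out_dir, "tracks.png"), dpi=120)
    plt.close(fig)


def render_report(run_dir: str, out_dir: str) -> None:
    """Render all figures for a completed `run` output directory."""
    os.makedirs(out_dir, exist_ok=True)
    bins_path = os.path.join(run_dir, "bins.csv")
    if os.path.exists(bins_path):
        plot_timecourses(pd.read_csv(bins_path), out_dir)
    stats_dir = os.path.join(run_dir, "stats")
    if os.path.isdir(stats_dir):
        plot_heatmap_tables(stats_dir, out_dir)
    traj_dir = os.path.join(run_dir, "trajectories")
    if os.path.isdir(traj_dir):
        plot_track_examples(traj_dir, out_dir)
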