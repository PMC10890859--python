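"""Figure panels for the evaluation benchmarks."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from ossim.evaluate import SweepResult


def plot_sweep(result: SweepResult, path: str | Path) -> Path:
    """SSIM versus Poisson factor eta, one line per method, +-1 sd band."""
    fig, ax = plt.subplots(figsize=(5.2, 3.6))
    summary = result.summary()
    for method, grp in summary.groupby("method"):
        grp = grp.sort_values("eta")
        ax.plot(grp["eta"], grp["mean"], marker="o", ms=3, label=method)
        ax.fill_between(
            grp["eta"],
            grp["mean"] - grp["std"].fillna(0),
            grp["mean"] + grp["std"].fillna(0),
            alpha=0.2,
        )
    ax.set_xscale("log")
    ax.set_xlabel(r"Poisson factor $\eta$")
    ax.set_ylabel("SSIM vs noise-free sectioned GT")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_motion(table: pd.DataFrame, path: str | Path) -> Path:
    """Bar chart of per-method SSIM on the moving-sample benchmark."""
    stats = table.groupby("method")["ssim"].agg(["mean", "std"])
    fig, ax = plt.subplots(figsize=(4.2, 3.2))
    ax.bar(stats.index, stats["mean"], yerr=stats["std"], capsize=3)
    ax.set_ylabel("SSIM vs mid-frame sectioned GT")
    ax.tick_params(axis="x", rotation=20)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
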