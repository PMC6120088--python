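"""Rendering of benchmark tables to SVG/PNG via matplotlib."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .biasmetrics import FoldDeviationTable
from .crosskit import KitComparison
from .detection import DetectionSummary


def fold_deviation_histogram(
    fdt: FoldDeviationTable, path: str | Path, bins: int = 60
) -> None:
    """Histogram of per-reference log2 fold-deviations with the accuracy
    window marked at +/- tau."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.hist(fdt.data["log2_fd"], bins=bins, color="#4878a8")
    for x in (-fdt.tau, fdt.tau):
        ax.axvline(x, color="black", linestyle="--", linewidth=0.8)
    ax.set_xlabel("log2(observed / expected)")
    ax.set_ylabel("references")
    ax.set_title(
        f"{fdt.library_id}: {fdt.percent_accurate:.1f}% within ±{fdt.tau} log2"
    )
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def detection_curve_plot(
    summaries: Sequence[DetectionSummary], path: str | Path
) -> None:
    """Mean detected references versus subsampling depth."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    depths = [s.depth for s in summaries]
    means = [s.n_detected for s in summaries]
    sds = [s.sd for s in summaries]
    ax.errorbar(depths, means, yerr=sds, marker="o")
    ax.set_xscale("log")
    ax.set_xlabel("subsampled depth (reads)")
    ax.set_ylabel(f"references detected (≥{summaries[0].min_reads} reads)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def kit_comparison_scatter(comp: KitComparison, path: str | Path) -> None:
    """Differential quantification versus the focal kit's pool accuracy."""
    fig, ax = plt.subplots(figsize=(4.2, 4.2))
    colors = {
        "concordant": "#999999",
        "FN_x": "#c23b22",
        "FP_x": "#e08214",
        "FN_ref": "#2166ac",
        "FP_ref": "#67a9cf",
        "unattributed": "#444444",
    }
    for call, grp in comp.data.groupby("call"):
        ax.scatter(
            grp["pool_fd_x"],
            grp["diff_log2"],
            s=8,
            label=call,
            color=colors.get(call, "black"),
        )
    ax.axhline(0, color="black", linewidth=0.5)
    ax.set_xlabel(f"{comp.kit_x} pool log2 fold-deviation")
    ax.set_ylabel(f"log2({comp.kit_x} / {comp.kit_ref})")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
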