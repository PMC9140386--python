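"""Mapping plots: per-chromosome delta(SNP index) with the confidence band."""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_mapping"]

logger = logging.getLogger(__name__)


def plot_mapping(window_table: pd.DataFrame, out_dir: str | Path) -> list[Path]:
    """One panel per chromosome: window mean delta, null band, exceedances.

    ``window_table`` is the per-window TSV produced by mapping (columns
    chrom, start, end, n_snps, mean_delta, lower, upper, exceeds).  Empty
    input is a no-op with a warning.
    """
    if len(window_table) == 0:
        logger.warning("empty window table; nothing to plot")
        return []
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    for chrom, grp in window_table.groupby("chrom", sort=False):
        mid = (grp["start"] + grp["end"]) / 2 / 1e6
        fig, ax = plt.subplots(figsize=(8, 3))
        ax.axhline(0.0, color="0.7", lw=0.8)
        ax.plot(mid, grp["mean_delta"], color="C0", lw=1.2,
                label="window mean Δ(SNP index)")
        ax.plot(mid, grp["upper"], color="green", lw=1.0, label="95% band")
        ax.plot(mid, grp["lower"], color="green", lw=1.0)
        hits = grp[grp["exceeds"].astype(bool)]
        if len(hits):
            ax.scatter((hits["start"] + hits["end"]) / 2 / 1e6,
                       hits["mean_delta"], color="C3", s=12, zorder=3,
                       label="above threshold")
        ax.set_xlabel(f"{chrom} position (Mb)")
        ax.set_ylabel("Δ(SNP index)")
        ax.set_ylim(-1, 1)
        ax.legend(loc="upper left", fontsize=8, frameon=False)
        fig.tight_layout()
        path = out / f"delta_snp_index_{chrom}.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        files.append(path)
    return files
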