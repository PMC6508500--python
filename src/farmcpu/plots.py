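"""Manhattan and QQ plots, decoupled from the scan itself.

Both functions take the results table (a DataFrame with at least chrom,
pos, p) and never mutate it.  Output format follows the file extension
(png/pdf/svg).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
matplotlib.rcParams["svg.hashsalt"] = "farmcpu"  # deterministic SVG element ids
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["PlotSpec", "manhattan_plot", "qq_plot"]


@dataclass
class PlotSpec:
    """Styling and output options shared by both plot types.

    ``threshold`` defaults to Bonferroni 0.05 / m when left as None.
    """

    threshold: float | None = None
    point_size: float = 6.0
    colors: tuple[str, str] = ("#4C72B0", "#55A868")
    figsize: tuple[float, float] = (10.0, 4.0)
    dpi: int = 150

    def resolved_threshold(self, m: int) -> float:
        thr = self.threshold if self.threshold is not None else 0.05 / m
        if not 0.0 < thr < 1.0:
            raise ValueError(f"significance threshold must be in (0, 1), got {thr}")
        return thr


def _save(fig, path: Path, spec: PlotSpec) -> None:
    kwargs = {"dpi": spec.dpi}
    if path.suffix.lower() == ".svg":
        kwargs["metadata"] = {"Date": None}  # keep output byte-deterministic
    fig.savefig(path, **kwargs)
    plt.close(fig)


def manhattan_plot(
    results: pd.DataFrame, path: str | Path, spec: PlotSpec | None = None
):
    """-log10(p) against cumulative genomic position, chromosomes alternately
    colored, with a horizontal genome-wide significance line."""
    spec = spec or PlotSpec()
    path = Path(path)
    if results.empty:
        raise ValueError("results table is empty")
    df = results[["chrom", "pos", "p"]].copy()
    df = df[np.isfinite(df["p"].to_numpy(dtype=float))]
    if df.empty:
        raise ValueError("no finite p-values to plot")
    m_total = len(results)
    threshold = spec.resolved_threshold(m_total)

    fig, ax = plt.subplots(figsize=spec.figsize)
    offset = 0
    ticks, tick_labels = [], []
    for i, (chrom, grp) in enumerate(df.groupby("chrom", sort=False)):
        x = offset + grp["pos"].to_numpy(dtype=float)
        y = -np.log10(grp["p"].to_numpy(dtype=float))
        ax.scatter(x, y, s=spec.point_size, color=spec.colors[i % 2], linewidths=0)
        ticks.append(x.mean())
        tick_labels.append(str(chrom))
        offset = x.max()
    ax.axhline(-np.log10(threshold), color="red", linestyle="--", linewidth=1)
    ax.set_xticks(ticks)
    ax.set_xticklabels(tick_labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10}(p)$")
    fig.tight_layout()
    _save(fig, path, spec)
    return path


def qq_plot(results: pd.DataFrame, path: str | Path, spec: PlotSpec | None = None):
    """Observed vs expected -log10(p) with the identity line.

    Expected quantiles are (i - 0.5) / m for the i-th smallest p-value.
    """
    spec = spec or PlotSpec()
    path = Path(path)
    if results.empty:
        raise ValueError("results table is empty")
    p = results["p"].to_numpy(dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no finite p-values to plot")
    p = np.sort(p)
    # p = 1 maps to 0 on the -log10 scale; no infinities for p in (0, 1]
    observed = -np.log10(p)
    expected = -np.log10((np.arange(1, p.size + 1) - 0.5) / p.size)

    fig, ax = plt.subplots(figsize=(5.0, 5.0))
    ax.scatter(expected, observed, s=spec.point_size, color=spec.colors[0], linewidths=0)
    lim = max(expected.max(), observed.max()) * 1.05
    ax.plot([0, lim], [0, lim], color="red", linestyle="--", linewidth=1)
    ax.set_xlabel(r"expected $-\log_{10}(p)$")
    ax.set_ylabel(r"observed $-\log_{10}(p)$")
    fig.tight_layout()
    _save(fig, path, spec)
    return path
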