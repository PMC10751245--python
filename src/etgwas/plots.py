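"""Manhattan and Q-Q rendering for association results."""

from __future__ import annotations

import logging
import os

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def render_manhattan(
    results: pd.DataFrame,
    path: str | os.PathLike,
    thresholds: tuple[float, float] = (1e-4, 1e-6),
    p_column: str = "p_adj",
) -> None:
    """Manhattan plot with the two genome-wide threshold lines drawn.

    ``thresholds`` defaults to the pipeline's primary (1e-4) and stringent
    (1e-6) cutoffs.  Empty results are a warned no-op.
    """
    if results is None or len(results) == 0:
        logger.warning("render_manhattan: empty result set; nothing drawn")
        return
    fig, ax = plt.subplots(figsize=(9, 3.2))
    offset = 0
    ticks, labels = [], []
    for i, (chrom, sub) in enumerate(results.groupby("chrom", sort=True)):
        x = sub["pos"].to_numpy() + offset
        ax.scatter(x, -np.log10(sub[p_column].to_numpy()), s=4, color=f"C{i % 10}")
        ticks.append(offset + sub["pos"].max() / 2)
        labels.append(str(chrom))
        offset += sub["pos"].max() + 1
    for thr, color in zip(thresholds, ("red", "black")):
        ax.axhline(-np.log10(thr), color=color, linestyle="--", linewidth=0.8)
    ax.set_xticks(ticks)
    ax.set_xticklabels(labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10}(p)$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def render_qq(results: pd.DataFrame, path: str | os.PathLike, p_column: str = "p_raw") -> None:
    """Q-Q plot of -log10 expected vs observed p-values."""
    if results is None or len(results) == 0:
        logger.warning("render_qq: empty result set; nothing drawn")
        return
    p = np.sort(results[p_column].to_numpy())
    n = len(p)
    expected = -np.log10((np.arange(n) + 0.5) / n)
    observed = -np.log10(np.clip(p, 1e-300, 1.0))
    fig, ax = plt.subplots(figsize=(3.6, 3.6))
    ax.scatter(expected, observed, s=4, color="C0")
    lim = max(expected.max(), observed.max()) * 1.05
    ax.plot([0, lim], [0, lim], color="grey", linewidth=0.8)
    ax.set_xlabel(r"expected $-\log_{10}(p)$")
    ax.set_ylabel(r"observed $-\log_{10}(p)$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
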