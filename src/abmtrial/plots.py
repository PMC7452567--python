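"""Plot helpers for reliable-change and classification results."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .change import JT_LABELS


def reliable_change_plot(table: pd.DataFrame, s_diff: float, multiplier: float = 1.96,
                         ax=None, assessment: int | None = None):
    """Pre-vs-post scatter with the +-1.96 S_diff no-change band.

    Points outside the band changed reliably; `table` is the per-participant
    classification table from classify_cohort.
    """
    if assessment is not None:
        table = table[table["assessment"] == assessment]
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    lo = min(table["pre"].min(), table["post"].min())
    hi = max(table["pre"].max(), table["post"].max())
    grid = np.linspace(lo, hi, 50)
    band = multiplier * s_diff
    ax.fill_between(grid, grid - band, grid + band, alpha=0.2, label="no reliable change")
    ax.plot(grid, grid, lw=0.8, color="k")
    for rel, marker in (("improved", "v"), ("unchanged", "o"), ("deteriorated", "^")):
        sub = table[table["reliable"] == rel]
        ax.scatter(sub["pre"], sub["post"], marker=marker, s=18, label=rel)
    ax.set_xlabel("baseline score")
    ax.set_ylabel("follow-up score")
    ax.legend(fontsize=8)
    return ax


def jt_distribution_plot(counts: pd.DataFrame, ax=None):
    """Stacked bars of the five Jacobson-Truax categories per timepoint."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    bottom = np.zeros(len(counts))
    for label in JT_LABELS:
        vals = counts[label].to_numpy()
        ax.bar(counts.index.astype(str), vals, bottom=bottom, label=label)
        bottom += vals
    ax.set_xlabel("assessment")
    ax.set_ylabel("participants")
    ax.legend(fontsize=8)
    return ax
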