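"""Optional figures: presence/absence heat grid and allele-balance histogram.

Matplotlib is imported lazily so the rest of the package works without it.
"""

from __future__ import annotations

from typing import Optional

from .losses import PresenceMatrix
from .ploidy import PloidyReport

_STATE_VALUE = {"present": 2, "present_genome_only": 1, "absent": 0}


def plot_presence_matrix(matrix: PresenceMatrix, ax=None):
    """Heat grid of the presence matrix: dark = proteome evidence, mid =
    genome-only rescue, light = absent."""
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    if ax is None:
        _, ax = plt.subplots(
            figsize=(1 + 0.4 * len(matrix.taxa), 1 + 0.3 * len(matrix.families))
        )
    grid = matrix.states.map(_STATE_VALUE.get).astype(int)
    cmap = ListedColormap(["#f2f2f2", "#8fb8de", "#2c5f8a"])
    ax.imshow(grid.to_numpy(), cmap=cmap, vmin=0, vmax=2, aspect="auto")
    ax.set_xticks(range(len(matrix.taxa)), matrix.taxa, rotation=90, fontsize=7)
    ax.set_yticks(range(len(matrix.families)), matrix.families, fontsize=7)
    ax.set_xlabel("taxon")
    ax.set_ylabel("family")
    return ax


def plot_balance_histogram(report: PloidyReport, ax=None):
    """Minor-allele-fraction histogram of heterozygous sites, with the
    decision floor and balance window marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    widths = report.bin_edges[1:] - report.bin_edges[:-1]
    ax.bar(report.bin_edges[:-1], report.histogram, width=widths, align="edge",
           color="#2c5f8a")
    ax.axvline(report.thresholds["balance_floor"], ls="--", color="gray")
    ax.axvspan(report.thresholds["balance_window_low"],
               report.thresholds["balance_window_high"], alpha=0.15, color="green")
    ax.set_xlabel("minor-allele fraction")
    ax.set_ylabel("heterozygous sites")
    ax.set_title(f"verdict: {report.verdict}")
    return ax
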