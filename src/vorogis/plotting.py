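"""Figure-style visualizations: AD/RFH scatter, hexbin class maps, L(d) plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Polygon as MplPolygon

from .globalstats import RipleyResult
from .hexgrid import HexGrid
from .localstats import LocalStatResult

LISA_COLORS = {"HH": "#e75480", "LL": "#87cefa", "HL": "#d62728", "LH": "#1f4fd6", "NS": "#dddddd"}
GI_COLORS = {
    "hot99": "#8b0000",
    "hot95": "#e03020",
    "hot90": "#f59060",
    "cold90": "#9ecae1",
    "cold95": "#4292c6",
    "cold99": "#084594",
    "NS": "#dddddd",
}


def plot_ad_rfh(indices_by_group: dict[str, list], ax=None):
    """AD (x) vs RFH (y) scatter; ordered populations sit low-AD/high-RFH."""
    if ax is None:
        _, ax = plt.subplots()
    for group, indices in indices_by_group.items():
        ax.scatter(
            [i.area_disorder for i in indices],
            [i.rf_homogeneity for i in indices],
            label=group,
            alpha=0.8,
        )
    ax.set_xlabel("Area disorder (AD)")
    ax.set_ylabel("Roundness-factor homogeneity (RFH)")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend()
    return ax


def plot_hex_classes(grid: HexGrid, result: LocalStatResult, ax=None):
    """Hexagon map colored by cluster/outlier (or hot/cold) class."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    colors = LISA_COLORS if result.name == "local_morans_i" else GI_COLORS
    for i in range(grid.n_cells):
        ax.add_patch(
            MplPolygon(grid.vertices(i), closed=True, facecolor=colors[str(result.classes[i])],
                       edgecolor="white", linewidth=0.3)
        )
    ax.set_xlim(grid.frame.x0, grid.frame.x0 + grid.frame.width)
    ax.set_ylim(grid.frame.y0 + grid.frame.height, grid.frame.y0)  # image convention
    ax.set_aspect("equal")
    return ax


def plot_l_function(result: RipleyResult, ax=None):
    """L(d) − d with its CSR permutation envelope."""
    if ax is None:
        _, ax = plt.subplots()
    d = result.distances
    ax.plot(d, result.l - d, "k-", label="observed")
    if result.envelope_lo is not None:
        ax.fill_between(
            d, result.envelope_lo - d, result.envelope_hi - d, alpha=0.3, label="CSR envelope"
        )
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("distance d (μm)")
    ax.set_ylabel("L(d) − d")
    ax.legend()
    return ax
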