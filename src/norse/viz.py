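"""Heatmap rendering of distribution and prevalence maps.

d-maps use a white-to-blue-to-purple ramp (white = empty cell); p-maps a
grey-green-yellow-red ramp (green = low prevalence, red = high).  Suppressed
cells are drawn blank.  For 2D prevalence maps the per-row NORSE scores are
annotated in blue at the right edge and the per-column scores in brown
below, with |N| < 2 hidden to keep the annotation readable.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import LinearSegmentedColormap

from .engine import DISPLAY_THRESHOLD, Norse2DResult, norse_2d
from .maps import DMap, PMap

__all__ = ["render_dmap", "render_pmap", "DMAP_CMAP", "PMAP_CMAP"]

DMAP_CMAP = LinearSegmentedColormap.from_list(
    "dmap", ["#ffffff", "#7a9bdc", "#5b2a86"]
)
PMAP_CMAP = LinearSegmentedColormap.from_list(
    "pmap", ["#b9bdb6", "#3a8f4d", "#e8d44d", "#c23b22"]
)

ROW_NORSE_COLOR = "#1f4fd8"  # along-x scores, printed at row ends
COL_NORSE_COLOR = "#8a5a2b"  # along-y scores, printed at column ends


def _as_2d(arr: np.ndarray) -> np.ndarray:
    """Map arrays to (ny, nx) display orientation, y increasing upward."""
    a = np.asarray(arr, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    return a.T  # (nx, ny) -> (ny, nx)


def _edge_labels(edges: np.ndarray) -> list[str]:
    return [f"{e:g}" for e in edges]


def _setup_axes(ax, grid):
    ax.set_xticks(np.arange(len(grid.edges[0])) - 0.5)
    ax.set_xticklabels(_edge_labels(grid.edges[0]), rotation=90, fontsize=7)
    ax.set_xlabel(grid.axes[0])
    if grid.ndim == 2:
        ax.set_yticks(np.arange(len(grid.edges[1])) - 0.5)
        ax.set_yticklabels(_edge_labels(grid.edges[1]), fontsize=7)
        ax.set_ylabel(grid.axes[1])
    else:
        ax.set_yticks([])


def render_dmap(dmap: DMap, ax=None, annotate: bool = True, suppress: bool = True):
    """Heatmap of population fractions; returns the matplotlib Figure."""
    frac = _as_2d(dmap.fraction)
    ncell = _as_2d(dmap.n_cell)
    if suppress:
        blank = _as_2d(dmap.suppressed())
        frac = np.where(blank, np.nan, frac)
    if not np.isfinite(frac).any():
        raise ValueError("d-map has no displayable cell")
    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, frac.shape[1] * 0.7), max(2, frac.shape[0] * 0.55)))
    cmap = DMAP_CMAP.copy()
    cmap.set_bad("#ffffff")
    ax.imshow(frac, cmap=cmap, vmin=0, origin="lower", aspect="auto")
    if annotate:
        for (iy, ix), v in np.ndenumerate(frac):
            if np.isfinite(v):
                ax.text(
                    ix, iy, f"{int(ncell[iy, ix])}\n{100 * v:.1f}%",
                    ha="center", va="center", fontsize=6,
                    color="black" if v < 0.6 * np.nanmax(frac) else "white",
                )
    _setup_axes(ax, dmap.grid)
    ax.set_title(f"population distribution (n = {dmap.n_tot})", fontsize=9)
    return ax.figure


def render_pmap(
    pmap: PMap,
    ax=None,
    annotate: bool = True,
    show_norse: bool = True,
    norse_result: Norse2DResult | None = None,
    threshold: float = DISPLAY_THRESHOLD,
):
    """Heatmap of per-cell prevalence with NORSE annotations.

    For 2D maps the row/column NORSE scores are computed (or taken from
    ``norse_result``) and printed at the ends of each row and column;
    scores with absolute value below ``threshold`` are hidden.
    """
    prev = _as_2d(pmap.prevalence)
    prev = np.where(_as_2d(pmap.suppressed), np.nan, prev)
    if not np.isfinite(prev).any():
        raise ValueError("p-map is fully suppressed; nothing to render")
    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, prev.shape[1] * 0.7), max(2, prev.shape[0] * 0.55)))
    cmap = PMAP_CMAP.copy()
    cmap.set_bad("#ffffff")
    ax.imshow(prev, cmap=cmap, vmin=0, origin="lower", aspect="auto")
    if annotate:
        for (iy, ix), v in np.ndenumerate(prev):
            if np.isfinite(v):
                ax.text(ix, iy, f"{v:.1f}%", ha="center", va="center", fontsize=6)
    if show_norse and pmap.grid.ndim == 2:
        if norse_result is None:
            norse_result = norse_2d(pmap)
        nx, ny = pmap.grid.shape
        for j, val in enumerate(norse_result.displayed("row", threshold)):
            if np.isfinite(val):
                ax.text(nx - 0.35, j, f"{val:+.1f}", ha="left", va="center",
                        fontsize=7, color=ROW_NORSE_COLOR, fontweight="bold")
        for i, val in enumerate(norse_result.displayed("col", threshold)):
            if np.isfinite(val):
                ax.text(i, ny - 0.25, f"{val:+.1f}", ha="center", va="bottom",
                        fontsize=7, color=COL_NORSE_COLOR, fontweight="bold")
    _setup_axes(ax, pmap.grid)
    ax.set_title(f"{pmap.condition} prevalence (n = {pmap.n_tot})", fontsize=9)
    return ax.figure
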