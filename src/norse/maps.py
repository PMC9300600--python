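"""Distribution (d-map) and prevalence (p-map) construction on sigma/2 grids.

Both map types bin participants over one or two biomarkers on a uniform grid
whose cell side is half the biomarker's population standard deviation, with
edges anchored at the mean: edge_k = mu + k * sigma/2, k integer.  Bins are
half-open [left, right) with the topmost edge closed, so every finite value
is assigned to exactly one cell.

A d-map holds per-cell participant counts and population fractions; a p-map
holds, for one binary condition, the per-cell count of positives and the
prevalence n_cond / n_cell in percent.  Cells with n_cell < 40 or holding
less than 0.2% of the mapped population are flagged suppressed: prevalence
estimates from so few people are noise, and tiny cells are a disclosure
concern in survey data.  Suppression is a mask — counts are never deleted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .registry import BiomarkerVector

__all__ = [
    "BinGrid",
    "DMap",
    "PMap",
    "make_grid",
    "build_dmap",
    "build_pmap",
    "DEFAULT_MIN_CELL",
    "DEFAULT_MIN_FRACTION",
]

#: Suppression thresholds: minimum participants per cell, minimum cell share
#: of the mapped population.
DEFAULT_MIN_CELL = 40
DEFAULT_MIN_FRACTION = 0.002


class DegenerateGridError(ValueError):
    """Grid cannot be built (sigma = 0 on an axis)."""


class InsufficientSupportError(ValueError):
    """Too few usable cells (or participants) for the requested estimate."""


@dataclass(frozen=True)
class BinGrid:
    """Uniform bin edges over 1 or 2 biomarker axes, cell side sigma/2."""

    axes: tuple[str, ...]
    mus: tuple[float, ...]
    sigmas: tuple[float, ...]
    edges: tuple[np.ndarray, ...]

    @property
    def ndim(self) -> int:
        return len(self.axes)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(e) - 1 for e in self.edges)

    def centers(self, axis: int = 0) -> np.ndarray:
        e = self.edges[axis]
        return 0.5 * (e[:-1] + e[1:])

    def assign(self, axis: int, values: np.ndarray) -> np.ndarray:
        """Bin index per value; -1 for values outside the grid or missing.

        Half-open [left, right) bins; a value exactly on the topmost edge is
        placed in the last bin.
        """
        mu = self.mus[axis]
        half = self.sigmas[axis] / 2.0
        e = self.edges[axis]
        k0 = np.rint((e[0] - mu) / half)
        x = np.asarray(values, dtype=float)
        with np.errstate(invalid="ignore"):
            idx = np.floor((x - mu) / half - k0)
        nbins = len(e) - 1
        out = np.full(x.shape, -1, dtype=np.int64)
        ok = np.isfinite(x)
        # top edge closed
        at_top = ok & (x == e[-1])
        inside = ok & (idx >= 0) & (idx < nbins)
        out[inside] = idx[inside].astype(np.int64)
        out[at_top] = nbins - 1
        return out


def _axis_edges(vector: BiomarkerVector) -> tuple[float, float, np.ndarray]:
    if vector.sigma is None or vector.mu is None:
        raise ValueError(
            f"biomarker {vector.name!r} has no mu/sigma; call zscore() first"
        )
    if vector.sigma <= 0 or not np.isfinite(vector.sigma):
        raise DegenerateGridError(f"sigma must be positive for {vector.name!r}")
    vals = vector.values.dropna().to_numpy(dtype=float)
    if vals.size == 0:
        raise DegenerateGridError(f"no finite values for {vector.name!r}")
    mu, half = float(vector.mu), vector.sigma / 2.0
    kmin = int(np.floor((vals.min() - mu) / half))
    kmax = int(np.floor((vals.max() - mu) / half)) + 1
    edges = mu + np.arange(kmin, kmax + 1, dtype=float) * half
    return mu, float(vector.sigma), edges


def make_grid(*vectors: BiomarkerVector) -> BinGrid:
    """Deterministic sigma/2 grid anchored at the mean, covering the data.

    Edge k sits at mu + k*sigma/2; the same population always yields the
    same grid, and an affine change of units moves the edges by the same
    affine map (cell memberships are preserved).
    """
    if not 1 <= len(vectors) <= 2:
        raise ValueError("maps support 1 or 2 biomarker axes")
    mus, sigmas, edges = [], [], []
    for v in vectors:
        mu, sigma, e = _axis_edges(v)
        mus.append(mu)
        sigmas.append(sigma)
        edges.append(e)
    return BinGrid(
        axes=tuple(v.name for v in vectors),
        mus=tuple(mus),
        sigmas=tuple(sigmas),
        edges=tuple(edges),
    )


@dataclass(frozen=True)
class DMap:
    """Population distribution over the grid.  Axis 0 of ``n_cell`` is the
    first (x) biomarker; axis 1, if present, the second (y)."""

    grid: BinGrid
    n_cell: np.ndarray
    n_tot: int

    @property
    def fraction(self) -> np.ndarray:
        return self.n_cell / self.n_tot

    def suppressed(
        self,
        min_cell: int = DEFAULT_MIN_CELL,
        min_fraction: float = DEFAULT_MIN_FRACTION,
    ) -> np.ndarray:
        return (self.n_cell < min_cell) | (self.fraction < min_fraction)

    def to_frame(self) -> pd.DataFrame:
        return _map_frame(self.grid, n_cell=self.n_cell, fraction=self.fraction)


@dataclass(frozen=True)
class PMap:
    """Per-cell prevalence (percent) of one condition over the grid.

    ``axis_sums`` (when built from participant data) holds, per axis, the
    per-cell sum of that axis's biomarker values, so estimators can use the
    per-cell mean coordinate instead of the geometric cell center.
    """

    grid: BinGrid
    condition: str
    n_cell: np.ndarray
    n_cond: np.ndarray
    n_tot: int
    min_cell: int = DEFAULT_MIN_CELL
    min_fraction: float = DEFAULT_MIN_FRACTION
    axis_sums: tuple[np.ndarray, ...] | None = None

    def mean_coords(self, axis: int) -> np.ndarray | None:
        """Per-cell mean biomarker value on ``axis``; NaN for empty cells."""
        if self.axis_sums is None:
            return None
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n_cell > 0, self.axis_sums[axis] / self.n_cell, np.nan)

    @property
    def prevalence(self) -> np.ndarray:
        """n_cond / n_cell in percent; NaN for empty cells."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n_cell > 0, 100.0 * self.n_cond / self.n_cell, np.nan)

    @property
    def suppressed(self) -> np.ndarray:
        return (self.n_cell < self.min_cell) | (
            self.n_cell / self.n_tot < self.min_fraction
        )

    def to_frame(self) -> pd.DataFrame:
        return _map_frame(
            self.grid,
            n_cell=self.n_cell,
            n_cond=self.n_cond,
            prevalence=self.prevalence,
            suppressed=self.suppressed,
        )


def _map_frame(grid: BinGrid, **arrays: np.ndarray) -> pd.DataFrame:
    """One row per cell: bin bounds per axis plus the given per-cell arrays."""
    idx = np.indices(grid.shape).reshape(grid.ndim, -1)
    cols: dict[str, np.ndarray] = {}
    for a, name in enumerate(grid.axes):
        e = grid.edges[a]
        cols[f"{name}_left"] = e[idx[a]]
        cols[f"{name}_right"] = e[idx[a] + 1]
    for key, arr in arrays.items():
        cols[key] = np.asarray(arr).reshape(-1)
    return pd.DataFrame(cols)


def _as_vectors(vectors) -> tuple[BiomarkerVector, ...]:
    if isinstance(vectors, BiomarkerVector):
        return (vectors,)
    return tuple(vectors)


def _joint_indices(
    vectors: Sequence[BiomarkerVector], grid: BinGrid, extra_mask: pd.Series | None
) -> tuple[np.ndarray, ...]:
    """Per-axis bin indices for rows complete on every axis (and mask)."""
    mask = vectors[0].values.notna()
    for v in vectors[1:]:
        mask &= v.values.notna()
    if extra_mask is not None:
        mask &= extra_mask
    per_axis = []
    for a, v in enumerate(vectors):
        idx = grid.assign(a, v.values[mask].to_numpy(dtype=float))
        per_axis.append(idx)
    keep = np.ones(len(per_axis[0]), dtype=bool)
    for idx in per_axis:
        keep &= idx >= 0
    return tuple(idx[keep] for idx in per_axis)


def _count(indices: tuple[np.ndarray, ...], shape: tuple[int, ...]) -> np.ndarray:
    flat = np.ravel_multi_index(indices, shape)
    return np.bincount(flat, minlength=int(np.prod(shape))).reshape(shape)


def build_dmap(vectors, grid: BinGrid | None = None) -> DMap:
    """Bin the population; complete cases on all map axes only."""
    vecs = _as_vectors(vectors)
    if grid is None:
        grid = make_grid(*vecs)
    indices = _joint_indices(vecs, grid, None)
    n_tot = len(indices[0])
    if n_tot == 0:
        raise InsufficientSupportError("empty population: no complete cases on map axes")
    n_cell = _count(indices, grid.shape)
    return DMap(grid=grid, n_cell=n_cell, n_tot=n_tot)


def build_pmap(
    vectors,
    condition_flags: pd.Series,
    grid: BinGrid | None = None,
    condition: str = "",
    min_cell: int = DEFAULT_MIN_CELL,
    min_fraction: float = DEFAULT_MIN_FRACTION,
) -> PMap:
    """Bin condition prevalence; rows missing the flag are excluded.

    ``n_tot`` (the suppression denominator) counts participants complete on
    every axis and the condition, so the p-map is consistent with a d-map
    built over the same complete-case population.
    """
    vecs = _as_vectors(vectors)
    flags = pd.to_numeric(condition_flags, errors="coerce")
    if not flags.index.equals(vecs[0].values.index):
        raise ValueError("condition flags must share the participant index")
    if grid is None:
        grid = make_grid(*vecs)
    mask = flags.notna()
    for v in vecs:
        mask &= v.values.notna()
    raw = [grid.assign(a, v.values[mask].to_numpy(dtype=float)) for a, v in enumerate(vecs)]
    keep = np.ones(int(mask.sum()), dtype=bool)
    for idx in raw:
        keep &= idx >= 0
    indices = tuple(idx[keep] for idx in raw)
    n_tot = len(indices[0])
    if n_tot == 0:
        raise InsufficientSupportError(
            "empty population: no complete cases on axes and condition"
        )
    n_cell = _count(indices, grid.shape)
    pos = (flags[mask] == 1.0).to_numpy()[keep]
    n_cond = _count(tuple(idx[pos] for idx in indices), grid.shape)
    flat = np.ravel_multi_index(indices, grid.shape)
    size = int(np.prod(grid.shape))
    axis_sums = tuple(
        np.bincount(
            flat,
            weights=v.values[mask].to_numpy(dtype=float)[keep],
            minlength=size,
        ).reshape(grid.shape)
        for v in vecs
    )
    return PMap(
        grid=grid,
        condition=condition or str(condition_flags.name or ""),
        n_cell=n_cell,
        n_cond=n_cond,
        n_tot=n_tot,
        min_cell=min_cell,
        min_fraction=min_fraction,
        axis_sums=axis_sums,
    )
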