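"""NORSE scoring: sensitivity of condition prevalence to biomarker change.

The sensitivity of a condition C to a biomarker B is the slope
S_CB = dP_C/dB of prevalence (in percentage points) with respect to the
biomarker, estimated here by count-weighted least squares of per-cell
prevalence on cell centers over the non-suppressed cells of a p-map.  The
normalized sensitivity score is

    N_CB = sigma_B * S_CB

i.e. the percentage-point change in prevalence per one population standard
deviation of B — a unit-less quantity comparable across biomarkers.  In a
2D map, the same slope is taken along each row (x direction, holding the y
biomarker fixed) and column (y direction); row/column scores aggregate into
a single x-NORSE and y-NORSE by a count-weighted mean, and their difference
y - x is the NORSE separation of the pair.

Ranking tables average NORSE over the six conditions within each sex, and
average the two per-sex means into the cross-gender key used to sort the
table.  All averaging is done at full precision; rounding (half away from
zero, one decimal) is applied only for display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import maps as _maps
from .maps import BinGrid, InsufficientSupportError, PMap, build_pmap, make_grid
from .registry import (
    CONDITIONS,
    BiomarkerRegistry,
    BiomarkerVector,
    DegenerateDistributionError,
    default_registry,
    derive_biomarker,
    list_pairs,
    zscore,
)

__all__ = [
    "SensitivityFit",
    "NorseResult",
    "Norse2DResult",
    "RankingTable",
    "estimate_sensitivity",
    "norse_score",
    "norse_2d",
    "rank_1d",
    "rank_2d",
    "age_stratified_norse",
    "summarize_1d",
    "summarize_2d",
    "round_half_away",
    "DISPLAY_THRESHOLD",
    "DEFAULT_AGE_BRACKETS",
]

#: |N_CB| below this is hidden in visualizations (display only — aggregation
#: always uses every usable row/column).
DISPLAY_THRESHOLD = 2.0

#: Decade brackets over the adult range; the last bracket is open-ended to
#: the adult upper bound.
DEFAULT_AGE_BRACKETS = (
    (20, 30), (30, 40), (40, 50), (50, 60), (60, 70), (70, 80), (80, 110),
)

SEXES = ("male", "female")


def round_half_away(x, decimals: int = 1):
    """Round half away from zero (7.65 -> 7.7, -7.65 -> -7.7).

    Values are pre-rounded at 9 decimals so that sums like 45.9/6, whose
    float representation sits a hair below the exact half, still round the
    way the printed arithmetic does.
    """
    x = np.asarray(x, dtype=float)
    snapped = np.round(x, 9)
    factor = 10.0 ** decimals
    out = np.sign(snapped) * np.floor(np.abs(snapped) * factor + 0.5) / factor
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Slope estimation


def _weighted_slope(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted least-squares slope and intercept of y on x.

    Closed form; exact when the points lie on a line.
    """
    w = w / w.sum()
    xbar = float(np.dot(w, x))
    ybar = float(np.dot(w, y))
    dx = x - xbar
    denom = float(np.dot(w, dx * dx))
    if denom <= 0.0:
        raise InsufficientSupportError("all usable cells share one center; slope undefined")
    slope = float(np.dot(w, dx * (y - ybar)) / denom)
    return slope, ybar - slope * xbar


@dataclass(frozen=True)
class SensitivityFit:
    """Slope of prevalence vs. biomarker with per-cell diagnostics."""

    sensitivity: float  # percentage points per biomarker unit
    intercept: float
    n_cells_used: int
    n_participants: int
    cells: pd.DataFrame  # center, prevalence, n_cell, used


def estimate_sensitivity(pmap: PMap, axis: int = 0) -> SensitivityFit:
    """Count-weighted LS slope of prevalence on cell centers (1D p-map).

    Only non-suppressed cells enter the fit; at least two are required.
    """
    if pmap.grid.ndim != 1:
        raise ValueError("estimate_sensitivity takes a 1D p-map; use norse_2d for 2D")
    centers = pmap.grid.centers(axis)
    prev = pmap.prevalence
    usable = (~pmap.suppressed) & (pmap.n_cell > 0)
    if int(usable.sum()) < 2:
        raise InsufficientSupportError(
            f"{int(usable.sum())} non-suppressed cells; need >= 2 for a slope"
        )
    slope, intercept = _weighted_slope(
        centers[usable], prev[usable], pmap.n_cell[usable].astype(float)
    )
    cells = pd.DataFrame(
        {
            "center": centers,
            "prevalence": prev,
            "n_cell": pmap.n_cell,
            "used": usable,
        }
    )
    return SensitivityFit(
        sensitivity=slope,
        intercept=intercept,
        n_cells_used=int(usable.sum()),
        n_participants=int(pmap.n_cell[usable].sum()),
        cells=cells,
    )


@dataclass(frozen=True)
class NorseResult:
    """Normalized sensitivity of one condition to one biomarker."""

    biomarker: str
    condition: str
    stratum: Mapping[str, object]
    sensitivity: float  # %-points per biomarker unit
    norse: float  # %-points per SD; == sigma * sensitivity
    n_used: int
    fit: SensitivityFit | None = None

    @property
    def available(self) -> bool:
        return np.isfinite(self.norse)


def norse_score(
    pmap: PMap,
    biomarker_sigma: float | None = None,
    stratum: Mapping[str, object] | None = None,
) -> NorseResult:
    """NORSE of a 1D p-map: sigma_B times the prevalence slope."""
    sigma = float(pmap.grid.sigmas[0] if biomarker_sigma is None else biomarker_sigma)
    fit = estimate_sensitivity(pmap)
    return NorseResult(
        biomarker=pmap.grid.axes[0],
        condition=pmap.condition,
        stratum=dict(stratum or {}),
        sensitivity=fit.sensitivity,
        norse=sigma * fit.sensitivity,
        n_used=fit.n_participants,
        fit=fit,
    )


# ---------------------------------------------------------------------------
# 2D


@dataclass(frozen=True)
class Norse2DResult:
    """Row/column NORSE of a 2D p-map and their aggregates.

    ``row_norse[j]`` is the NORSE along x within y-bin j (the blue numbers
    at row ends); ``col_norse[i]`` the NORSE along y within x-bin i (brown,
    at column ends).  NaN marks rows/columns without enough usable cells.
    ``x_norse``/``y_norse`` are count-weighted means of the finite entries;
    ``separation = y_norse - x_norse``.
    """

    x_biomarker: str
    y_biomarker: str
    condition: str
    stratum: Mapping[str, object]
    row_norse: np.ndarray
    col_norse: np.ndarray
    row_weights: np.ndarray
    col_weights: np.ndarray
    x_norse: float
    y_norse: float
    n_used: int

    @property
    def separation(self) -> float:
        return self.y_norse - self.x_norse

    def displayed(self, which: str = "row", threshold: float = DISPLAY_THRESHOLD) -> np.ndarray:
        """Scores for annotation: |N| < threshold masked to NaN (hidden,
        never deleted)."""
        arr = self.row_norse if which == "row" else self.col_norse
        out = arr.copy()
        out[np.abs(out) < threshold] = np.nan
        return out


def _line_norse(
    centers: np.ndarray,
    prev_line: np.ndarray,
    n_line: np.ndarray,
    supp_line: np.ndarray,
    sigma: float,
) -> tuple[float, float]:
    """(NORSE, weight) for one row or column; (nan, 0) if under-supported."""
    usable = (~supp_line) & (n_line > 0) & np.isfinite(prev_line)
    if int(usable.sum()) < 2:
        return np.nan, 0.0
    try:
        slope, _ = _weighted_slope(
            centers[usable], prev_line[usable], n_line[usable].astype(float)
        )
    except InsufficientSupportError:
        return np.nan, 0.0
    return sigma * slope, float(n_line[usable].sum())


def _gradient_norse(
    pmap: PMap, sx: float, sy: float
) -> tuple[float, float] | None:
    """Count-weighted plane fit of prevalence over non-suppressed cells.

    The abscissae are per-cell mean coordinates where the map carries them
    (prevalence in a cell is exactly linear in the cell's mean z-scores
    under a linear risk model, so this estimates the gradient without the
    attenuation a center-based fit suffers on correlated axes); geometric
    centers are the fallback.  Returns None when the fit is impossible.
    """
    ok = (~pmap.suppressed) & (pmap.n_cell > 0)
    if int(ok.sum()) < 3:
        return None
    mx, my = pmap.mean_coords(0), pmap.mean_coords(1)
    if mx is None:
        cx, cy = np.meshgrid(pmap.grid.centers(0), pmap.grid.centers(1), indexing="ij")
        mx, my = cx, cy
    w = np.sqrt(pmap.n_cell[ok].astype(float))
    X = np.column_stack([np.ones(int(ok.sum())), mx[ok], my[ok]])
    y = pmap.prevalence[ok]
    try:
        beta, _, rank, _ = np.linalg.lstsq(X * w[:, None], y * w, rcond=None)
    except np.linalg.LinAlgError:
        return None
    if rank < 3:
        return None
    return float(sx * beta[1]), float(sy * beta[2])


def norse_2d(
    pmap: PMap,
    sigmas: tuple[float, float] | None = None,
    stratum: Mapping[str, object] | None = None,
    weighted: bool = True,
    aggregate: str = "gradient",
) -> Norse2DResult:
    """Row-wise and column-wise NORSE of a 2D p-map.

    The per-row (along x) and per-column (along y) scores are always the
    weighted-LS slopes of the corresponding 1D slices — the numbers printed
    at row and column ends of a p-map.  The aggregated ``x_norse``/
    ``y_norse`` scalars use one of two strategies:

    * ``aggregate="gradient"`` (default): a count-weighted plane fit of
      per-cell prevalence on per-cell mean coordinates, estimating the
      prevalence gradient directly.  On correlated axes the within-row
      variation of the other biomarker contaminates row-slice slopes, so
      their mean is attenuated; the joint fit is consistent.
    * ``aggregate="rowmean"``: count-weighted (or plain, with
      ``weighted=False``) mean of the per-row / per-column scores.
    """
    if pmap.grid.ndim != 2:
        raise ValueError("norse_2d requires a 2D p-map")
    if aggregate not in ("gradient", "rowmean"):
        raise ValueError(f"unknown aggregate strategy {aggregate!r}")
    sx, sy = sigmas if sigmas is not None else pmap.grid.sigmas
    cx, cy = pmap.grid.centers(0), pmap.grid.centers(1)
    prev, n_cell, supp = pmap.prevalence, pmap.n_cell, pmap.suppressed
    nx, ny = pmap.grid.shape

    row_norse = np.full(ny, np.nan)
    row_w = np.zeros(ny)
    for j in range(ny):
        row_norse[j], row_w[j] = _line_norse(cx, prev[:, j], n_cell[:, j], supp[:, j], sx)
    col_norse = np.full(nx, np.nan)
    col_w = np.zeros(nx)
    for i in range(nx):
        col_norse[i], col_w[i] = _line_norse(cy, prev[i, :], n_cell[i, :], supp[i, :], sy)

    def _aggregate(scores: np.ndarray, w: np.ndarray) -> float:
        ok = np.isfinite(scores)
        if not ok.any():
            return np.nan
        if weighted:
            return float(np.dot(scores[ok], w[ok]) / w[ok].sum())
        return float(scores[ok].mean())

    x_norse = _aggregate(row_norse, row_w)
    y_norse = _aggregate(col_norse, col_w)
    if not (np.isfinite(x_norse) or np.isfinite(y_norse)):
        raise InsufficientSupportError(
            "no row or column has >= 2 non-suppressed cells"
        )
    if aggregate == "gradient":
        grad = _gradient_norse(pmap, sx, sy)
        if grad is not None:
            x_norse, y_norse = grad
    return Norse2DResult(
        x_biomarker=pmap.grid.axes[0],
        y_biomarker=pmap.grid.axes[1],
        condition=pmap.condition,
        stratum=dict(stratum or {}),
        row_norse=row_norse,
        col_norse=col_norse,
        row_weights=row_w,
        col_weights=col_w,
        x_norse=x_norse,
        y_norse=y_norse,
        n_used=int(pmap.n_cell[~supp].sum()),
    )


# ---------------------------------------------------------------------------
# Ranking tables


@dataclass
class RankingTable:
    """Ranking-table container shared by the 1D and 2D pipelines.

    ``scores`` is the long-format per-(sex, row, condition) table;
    ``per_sex_average`` and ``key`` hold full-precision aggregates, with the
    rows of every attribute sorted descending by the cross-gender key.
    ``to_frame`` renders the display table rounded half-away-from-zero to
    one decimal.
    """

    kind: str  # "1d" | "2d"
    scores: pd.DataFrame
    per_condition: pd.DataFrame  # index rows, columns (sex, condition)
    per_sex_average: pd.DataFrame  # index rows, columns sexes
    key: pd.Series  # cross-gender ranking key, sorted descending
    column_average: pd.DataFrame | None = None  # 1D: (sex x condition) means

    def to_frame(self, rounded: bool = True) -> pd.DataFrame:
        out = self.per_condition.copy()
        for sex in self.per_sex_average.columns:
            out[(sex, "average")] = self.per_sex_average[sex]
        out[("both", "ranking_key")] = self.key
        out = out.loc[self.key.index]
        if rounded:
            out = out.apply(lambda c: round_half_away(c.to_numpy()), axis=0)
        return out

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    def to_json(self, path) -> None:
        frame = self.to_frame()
        frame.columns = ["/".join(map(str, c)) for c in frame.columns]
        frame.to_json(path, orient="index", indent=2)


def summarize_1d(
    scores: pd.DataFrame,
    conditions: Sequence[str] = CONDITIONS,
    sexes: Sequence[str] = SEXES,
) -> RankingTable:
    """Aggregate long-format 1D NORSE scores into a ranking table.

    ``scores`` needs columns sex, biomarker, condition, norse.  Per-sex
    average = mean of the per-condition scores; ranking key = mean of the
    two per-sex averages; the bottom-row column averages are the per-
    condition means over all biomarkers within a sex.
    """
    wide = scores.pivot_table(
        index="biomarker", columns=["sex", "condition"], values="norse", sort=False
    )
    cols = [(s, c) for s in sexes for c in conditions if (s, c) in wide.columns]
    wide = wide.reindex(columns=pd.MultiIndex.from_tuples(cols))
    per_sex = pd.DataFrame(
        {s: wide[s].mean(axis=1) for s in sexes if s in wide.columns.get_level_values(0)}
    )
    key = per_sex.mean(axis=1).sort_values(ascending=False, kind="stable")
    col_avg = wide.mean(axis=0).unstack(level=0).T  # sex x condition
    order = key.index
    return RankingTable(
        kind="1d",
        scores=scores,
        per_condition=wide.loc[order],
        per_sex_average=per_sex.loc[order],
        key=key,
        column_average=col_avg,
    )


def summarize_2d(
    scores: pd.DataFrame,
    conditions: Sequence[str] = CONDITIONS,
    sexes: Sequence[str] = SEXES,
) -> RankingTable:
    """Aggregate long-format 2D scores (x_norse, y_norse, separation).

    ``scores`` needs columns sex, pair, x_biomarker, y_biomarker, condition,
    x_norse, y_norse, separation.  Rows of the output are (pair, measure)
    with measure in {x_norse, y_norse, separation}; the ranking key is the
    cross-gender average separation.
    """
    long = scores.melt(
        id_vars=["sex", "pair", "condition"],
        value_vars=["x_norse", "y_norse", "separation"],
        var_name="measure",
        value_name="value",
    )
    wide = long.pivot_table(
        index=["pair", "measure"], columns=["sex", "condition"], values="value", sort=False
    )
    cols = [(s, c) for s in sexes for c in conditions if (s, c) in wide.columns]
    wide = wide.reindex(columns=pd.MultiIndex.from_tuples(cols))
    per_sex = pd.DataFrame({s: wide[s].mean(axis=1) for s in sexes})
    sep_key = (
        per_sex.xs("separation", level="measure").mean(axis=1)
        .sort_values(ascending=False, kind="stable")
    )
    order = pd.MultiIndex.from_tuples(
        [(p, m) for p in sep_key.index for m in ("x_norse", "y_norse", "separation")],
        names=["pair", "measure"],
    )
    key = pd.Series(
        {(p, m): sep_key[p] for p, m in order}, index=order, name="ranking_key"
    )
    return RankingTable(
        kind="2d",
        scores=scores,
        per_condition=wide.loc[order],
        per_sex_average=per_sex.loc[order],
        key=key,
    )


# ---------------------------------------------------------------------------
# Full pipelines


def _sex_subset(table: pd.DataFrame, sex: str, age_range=(20.0, 110.0)) -> pd.DataFrame:
    lo, hi = age_range
    return table[(table["sex"] == sex) & (table["age"] >= lo) & (table["age"] <= hi)]


def _standardized(table, name, registry) -> BiomarkerVector | None:
    try:
        return zscore(derive_biomarker(table, name, registry))
    except (ValueError, DegenerateDistributionError):
        return None


def rank_1d(
    table: pd.DataFrame,
    biomarkers: Sequence[str] | None = None,
    conditions: Sequence[str] = CONDITIONS,
    sexes: Sequence[str] = SEXES,
    registry: BiomarkerRegistry | None = None,
    age_range: tuple[float, float] = (20.0, 110.0),
    min_cell: int = _maps.DEFAULT_MIN_CELL,
    min_fraction: float = _maps.DEFAULT_MIN_FRACTION,
) -> RankingTable:
    """1D ranking: NORSE per (biomarker, condition, sex) plus averages.

    Biomarker moments, grids and p-maps are computed per sex on the adult
    population; a biomarker underivable for every sex is dropped with a
    warning, and an individual (biomarker, condition) cell without enough
    map support is left missing.
    """
    registry = registry if registry is not None else default_registry()
    biomarkers = list(biomarkers) if biomarkers is not None else registry.names()
    rows = []
    seen: dict[str, bool] = {b: False for b in biomarkers}
    for sex in sexes:
        sub = _sex_subset(table, sex, age_range)
        for name in biomarkers:
            vec = _standardized(sub, name, registry)
            if vec is None:
                continue
            seen[name] = True
            try:
                grid = make_grid(vec)
            except _maps.DegenerateGridError:
                continue
            for cond in conditions:
                if cond not in sub.columns:
                    raise KeyError(f"condition {cond!r} not in table")
                try:
                    pmap = build_pmap(
                        vec, sub[cond], grid, condition=cond,
                        min_cell=min_cell, min_fraction=min_fraction,
                    )
                    res = norse_score(pmap, vec.sigma, stratum={"sex": sex})
                    rows.append(
                        {
                            "sex": sex, "biomarker": name, "condition": cond,
                            "norse": res.norse, "sensitivity": res.sensitivity,
                            "n_used": res.n_used,
                        }
                    )
                except InsufficientSupportError:
                    rows.append(
                        {
                            "sex": sex, "biomarker": name, "condition": cond,
                            "norse": np.nan, "sensitivity": np.nan, "n_used": 0,
                        }
                    )
    for name, ok in seen.items():
        if not ok:
            warnings.warn(f"biomarker {name!r} underivable for every sex; excluded")
    scores = pd.DataFrame(rows)
    if scores.empty:
        raise InsufficientSupportError("no biomarker/condition produced a score")
    return summarize_1d(scores, conditions=conditions, sexes=sexes)


def rank_2d(
    table: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] | None = None,
    conditions: Sequence[str] = CONDITIONS,
    sexes: Sequence[str] = SEXES,
    registry: BiomarkerRegistry | None = None,
    age_range: tuple[float, float] = (20.0, 110.0),
    min_cell: int = _maps.DEFAULT_MIN_CELL,
    min_fraction: float = _maps.DEFAULT_MIN_FRACTION,
    weighted: bool = True,
    aggregate: str = "gradient",
) -> RankingTable:
    """2D ranking over biomarker pairs by average NORSE separation.

    Each pair is oriented so that the member with the larger aggregate
    NORSE (averaged over sexes and conditions) sits on the y axis, making
    the separation y - x positive for the fat-vs-lean pattern; the
    orientation is fixed per pair, identical across sexes and conditions.
    """
    registry = registry if registry is not None else default_registry()
    if pairs is None:
        pairs = list_pairs(registry.names())
    names = sorted({n for p in pairs for n in p})
    raw_rows = []
    for sex in sexes:
        sub = _sex_subset(table, sex, age_range)
        vecs = {n: _standardized(sub, n, registry) for n in names}
        for a, b in pairs:
            va, vb = vecs.get(a), vecs.get(b)
            if va is None or vb is None:
                continue
            try:
                grid = make_grid(va, vb)
                pmaps = {
                    cond: build_pmap(
                        (va, vb), sub[cond], grid, condition=cond,
                        min_cell=min_cell, min_fraction=min_fraction,
                    )
                    for cond in conditions
                }
            except (_maps.DegenerateGridError, InsufficientSupportError):
                continue
            for cond, pmap in pmaps.items():
                try:
                    res = norse_2d(pmap, (va.sigma, vb.sigma), stratum={"sex": sex},
                                   weighted=weighted, aggregate=aggregate)
                    raw_rows.append(
                        {
                            "sex": sex, "a": a, "b": b, "condition": cond,
                            "norse_a": res.x_norse, "norse_b": res.y_norse,
                            "n_used": res.n_used,
                        }
                    )
                except InsufficientSupportError:
                    raw_rows.append(
                        {
                            "sex": sex, "a": a, "b": b, "condition": cond,
                            "norse_a": np.nan, "norse_b": np.nan, "n_used": 0,
                        }
                    )
    raw = pd.DataFrame(raw_rows)
    if raw.empty:
        raise InsufficientSupportError("no pair produced a 2D score")
    # orient: y = member with larger overall mean NORSE
    rows = []
    for (a, b), g in raw.groupby(["a", "b"], sort=False):
        y_is_b = float(g["norse_b"].mean()) >= float(g["norse_a"].mean())
        x_name, y_name = (a, b) if y_is_b else (b, a)
        for _, r in g.iterrows():
            xn, yn = (r["norse_a"], r["norse_b"]) if y_is_b else (r["norse_b"], r["norse_a"])
            rows.append(
                {
                    "sex": r["sex"], "pair": f"{x_name}|{y_name}",
                    "x_biomarker": x_name, "y_biomarker": y_name,
                    "condition": r["condition"],
                    "x_norse": xn, "y_norse": yn, "separation": yn - xn,
                    "n_used": r["n_used"],
                }
            )
    return summarize_2d(pd.DataFrame(rows), conditions=conditions, sexes=sexes)


def age_stratified_norse(
    table: pd.DataFrame,
    biomarker: str,
    condition: str,
    brackets: Sequence[tuple[float, float]] = DEFAULT_AGE_BRACKETS,
    sexes: Sequence[str] = SEXES,
    registry: BiomarkerRegistry | None = None,
    min_cell: int = _maps.DEFAULT_MIN_CELL,
    min_fraction: float = _maps.DEFAULT_MIN_FRACTION,
) -> pd.DataFrame:
    """NORSE per (sex, age bracket): the NORSE-vs-age curve.

    Brackets are [lo, hi) except the last, which is closed, so adjacent
    decade brackets partition the adult range.  Moments and grids are
    recomputed within each stratum.  A bracket without enough support gets
    norse = NaN (available = False) rather than raising.
    """
    registry = registry if registry is not None else default_registry()
    brackets = sorted(brackets)
    last_hi = brackets[-1][1]
    rows = []
    for sex in sexes:
        for lo, hi in brackets:
            closed_top = hi == last_hi
            sel = (table["sex"] == sex) & (table["age"] >= lo)
            sel &= (table["age"] <= hi) if closed_top else (table["age"] < hi)
            sub = table[sel]
            row = {
                "sex": sex, "age_lo": lo, "age_hi": hi,
                "norse": np.nan, "sensitivity": np.nan, "n_used": 0,
                "available": False,
            }
            vec = _standardized(sub, biomarker, registry)
            if vec is not None:
                try:
                    pmap = build_pmap(
                        vec, sub[condition], condition=condition,
                        min_cell=min_cell, min_fraction=min_fraction,
                    )
                    res = norse_score(pmap, vec.sigma, stratum={"sex": sex, "age": (lo, hi)})
                    row.update(
                        norse=res.norse, sensitivity=res.sensitivity,
                        n_used=res.n_used, available=True,
                    )
                except (InsufficientSupportError, _maps.DegenerateGridError):
                    pass
            rows.append(row)
    return pd.DataFrame(rows)
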