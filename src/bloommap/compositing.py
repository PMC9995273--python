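"""Level-3 style compositing: annual per-pixel bloom counts, bloom-affected
areas, the 1-degree-cell bloom-frequency statistic, and polygon zonal
summaries.

Bloom frequency integrates the bloom count and affected area within a cell.
With ``M_i`` the annual bloom count of pixel i, ``n`` the number of
bloom-affected pixels (M_i > 0) and ``N`` the total pixels in the cell, the
default mode reports ``sum(M_i) / N`` — the affected fraction times the mean
count over affected pixels, a dimensionless density that does not scale with
cell pixel count.  A ``literal`` mode reports ``(n/N) * sum(M_i)`` for
auditability; the mode used is recorded in the output.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely

from .scene import BLOOM, INVALID, BloomMask, Grid

EQUATOR_PIXEL_KM2 = 1.0  # nominal area of one pixel at the equator


@dataclass
class AnnualCountGrid:
    """Per-pixel bloom counts M and valid-observation counts for one year."""

    grid: Grid
    M: np.ndarray
    n_valid: np.ndarray
    year: int

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=np.int64)
        self.n_valid = np.asarray(self.n_valid, dtype=np.int64)
        if self.M.shape != self.grid.shape or self.n_valid.shape != self.grid.shape:
            raise ValueError("count raster shape does not match grid")
        if (self.M > self.n_valid).any():
            raise ValueError("bloom count cannot exceed valid-observation count")


@dataclass
class CellFrequencyGrid:
    """Bloom frequency on a coarse lattice of square cells."""

    lat_edges: np.ndarray
    lon_edges: np.ndarray
    frequency: np.ndarray
    n_affected: np.ndarray
    N_total: np.ndarray
    sum_M: np.ndarray
    mode: str
    year: int
    meta: dict = field(default_factory=dict)


def accumulate_daily(
    masks: Iterable[BloomMask] | tuple, year: int | None = None
) -> AnnualCountGrid:
    """Sum dated daily masks into one year's count grid.

    ``masks`` is either an iterable of :class:`BloomMask` (all on one grid)
    or a ``(year, dates, states, grid)`` stack tuple.  M counts bloom days,
    n_valid counts days the pixel was not invalid; day order is immaterial.
    """
    if isinstance(masks, tuple) and len(masks) == 4:
        yr, dates, states, grid = masks
        states = np.asarray(states)
        M = (states == BLOOM).sum(axis=0)
        n_valid = (states != INVALID).sum(axis=0)
        return AnnualCountGrid(grid, M, n_valid, int(year if year is not None else yr))

    masks = list(masks)
    if not masks:
        raise ValueError("no masks to accumulate")
    grid = masks[0].grid
    years = {m.date.year for m in masks}
    if year is None:
        if len(years) != 1:
            raise ValueError(f"masks span several years {sorted(years)}; pass year=")
        year = years.pop()
    M = np.zeros(grid.shape, dtype=np.int64)
    n_valid = np.zeros(grid.shape, dtype=np.int64)
    for m in masks:
        if m.grid != grid:
            raise ValueError("masks are not on a common grid")
        if m.date.year != year:
            raise ValueError(f"mask dated {m.date} outside year {year}")
        M += m.bloom
        n_valid += m.valid
    return AnnualCountGrid(grid, M, n_valid, int(year))


def pixel_areas_km2(grid: Grid, mode: str = "coslat") -> np.ndarray:
    """Per-pixel areas: nominal 1 km^2, or cos(latitude)-weighted with the
    nominal value at the equator."""
    ny, nx = grid.shape
    if mode == "nominal":
        return np.full((ny, nx), EQUATOR_PIXEL_KM2)
    if mode == "coslat":
        w = np.cos(np.deg2rad(grid.lat))[:, None]
        return EQUATOR_PIXEL_KM2 * np.broadcast_to(w, (ny, nx)).copy()
    raise ValueError(f"unknown area mode {mode!r}")


def affected_area(counts: AnnualCountGrid, area_mode: str = "coslat") -> float:
    """Total area (km^2) of pixels with at least one bloom detection."""
    areas = pixel_areas_km2(counts.grid, area_mode)
    return float(areas[counts.M > 0].sum())


def bloom_frequency(
    counts: AnnualCountGrid, cell_deg: float = 1.0, mode: str = "default"
) -> CellFrequencyGrid:
    """Aggregate annual counts into cell-level bloom frequency.

    Cells are half-open intervals [edge, edge + cell_deg) anchored on the
    integer lattice, so every pixel centre lands in exactly one cell.
    Cells with no pixels are emitted as missing (nan frequency).
    """
    if mode not in ("default", "literal"):
        raise ValueError(f"unknown bloom-frequency mode {mode!r}")
    grid = counts.grid
    lat_idx = np.floor(grid.lat / cell_deg).astype(np.int64)
    lon_idx = np.floor(grid.lon / cell_deg).astype(np.int64)
    la_bins = np.arange(lat_idx.min(), lat_idx.max() + 1)
    lo_bins = np.arange(lon_idx.min(), lon_idx.max() + 1)
    nla, nlo = la_bins.size, lo_bins.size
    la_of = {v: i for i, v in enumerate(la_bins)}
    lo_of = {v: i for i, v in enumerate(lo_bins)}
    row = np.array([la_of[v] for v in lat_idx])
    col = np.array([lo_of[v] for v in lon_idx])

    sum_M = np.zeros((nla, nlo))
    n_aff = np.zeros((nla, nlo))
    N_tot = np.zeros((nla, nlo))
    np.add.at(sum_M, (row[:, None] * np.ones_like(col)[None, :],
                      np.ones_like(row)[:, None] * col[None, :]), counts.M)
    np.add.at(n_aff, (row[:, None] * np.ones_like(col)[None, :],
                      np.ones_like(row)[:, None] * col[None, :]), counts.M > 0)
    np.add.at(N_tot, (row[:, None] * np.ones_like(col)[None, :],
                      np.ones_like(row)[:, None] * col[None, :]), 1)

    with np.errstate(divide="ignore", invalid="ignore"):
        if mode == "default":
            freq = sum_M / N_tot
        else:
            freq = (n_aff / N_tot) * sum_M
    freq = np.where(N_tot == 0, np.nan, freq)

    return CellFrequencyGrid(
        lat_edges=la_bins * cell_deg,
        lon_edges=lo_bins * cell_deg,
        frequency=freq,
        n_affected=n_aff.astype(np.int64),
        N_total=N_tot.astype(np.int64),
        sum_M=sum_M,
        mode=mode,
        year=counts.year,
        meta={"cell_deg": cell_deg},
    )


def zonal_summary(
    yearly_counts: Mapping[int, AnnualCountGrid] | Sequence[AnnualCountGrid],
    polygons: Mapping[str, shapely.Geometry],
    area_mode: str = "coslat",
) -> pd.DataFrame:
    """Region statistics per year: affected area, mean/median count,
    frequency (default-mode, with the region as the cell).

    Pixels belong to a region when their centre falls inside its polygon.
    Regions with an empty intersection get a zero pixel count and missing
    statistics.  Returns one row per (region, year).
    """
    if not isinstance(yearly_counts, Mapping):
        yearly_counts = {c.year: c for c in yearly_counts}
    rows = []
    for region_id, geom in polygons.items():
        member_cache: np.ndarray | None = None
        cached_grid: Grid | None = None
        for year in sorted(yearly_counts):
            counts = yearly_counts[year]
            grid = counts.grid
            if cached_grid is None or grid != cached_grid:
                lon2d, lat2d = np.meshgrid(grid.lon, grid.lat)
                member_cache = shapely.contains_xy(geom, lon2d.ravel(), lat2d.ravel()).reshape(
                    grid.shape
                )
                cached_grid = grid
            inside = member_cache
            npix = int(inside.sum())
            if npix == 0:
                rows.append((region_id, year, 0, 0.0, np.nan, np.nan, np.nan))
                continue
            M = counts.M[inside]
            areas = pixel_areas_km2(grid, area_mode)[inside]
            rows.append(
                (
                    region_id,
                    year,
                    npix,
                    float(areas[M > 0].sum()),
                    float(M.mean()),
                    float(np.percentile(M, 50)),
                    float(M.sum() / npix),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "region", "year", "n_pixels", "affected_area_km2",
            "mean_count", "median_count", "frequency",
        ],
    )
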