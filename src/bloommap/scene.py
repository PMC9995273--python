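"""Core raster containers: geographic grid, multi-band scene, bloom mask.

A :class:`Scene` is one day's Rayleigh-corrected reflectance raster stack
plus per-pixel quality flags.  A :class:`BloomMask` is the trichotomous
detection result (no-bloom / bloom / invalid) on the same grid.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from enum import IntFlag

import numpy as np

# BloomMask byte encoding (also used on disk).
NO_BLOOM: int = 0
BLOOM: int = 1
INVALID: int = 255


class QualityFlag(IntFlag):
    """Level-2 style per-pixel quality bits that force removal."""

    STRAYLIGHT = 1
    CLOUD = 2
    LAND = 4
    HIGH_SUNGLINT = 8
    HIGH_SOLAR_ZENITH = 16
    HIGH_SENSOR_ZENITH = 32


ALL_FLAGS = (
    QualityFlag.STRAYLIGHT
    | QualityFlag.CLOUD
    | QualityFlag.LAND
    | QualityFlag.HIGH_SUNGLINT
    | QualityFlag.HIGH_SOLAR_ZENITH
    | QualityFlag.HIGH_SENSOR_ZENITH
)


@dataclass(frozen=True)
class Grid:
    """Regular geographic grid defined by 1-D cell-centre coordinates."""

    lat: np.ndarray
    lon: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "lat", np.asarray(self.lat, dtype=float))
        object.__setattr__(self, "lon", np.asarray(self.lon, dtype=float))
        if self.lat.ndim != 1 or self.lon.ndim != 1:
            raise ValueError("grid coordinates must be 1-D")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.lat.size, self.lon.size)

    @property
    def cell_size(self) -> tuple[float, float]:
        dlat = float(np.abs(np.diff(self.lat)).mean()) if self.lat.size > 1 else 1.0
        dlon = float(np.abs(np.diff(self.lon)).mean()) if self.lon.size > 1 else 1.0
        return dlat, dlon

    @classmethod
    def regular(cls, lat0: float, lon0: float, ny: int, nx: int, step: float) -> "Grid":
        """Grid of ``ny`` x ``nx`` cells with ``step``-degree spacing, first
        centre at (lat0, lon0), latitude increasing northward."""
        return cls(lat0 + step * np.arange(ny), lon0 + step * np.arange(nx))

    def __eq__(self, other: object) -> bool:  # value equality for tests
        return (
            isinstance(other, Grid)
            and np.array_equal(self.lat, other.lat)
            and np.array_equal(self.lon, other.lon)
        )


@dataclass
class Scene:
    """One dated multi-band Rrc raster with quality flags."""

    grid: Grid
    bands: dict[int, np.ndarray]
    flags: np.ndarray
    date: _dt.date = field(default_factory=lambda: _dt.date(2003, 1, 1))

    def __post_init__(self) -> None:
        shape = self.grid.shape
        self.bands = {int(wl): np.asarray(a, dtype=float) for wl, a in self.bands.items()}
        for wl, arr in self.bands.items():
            if arr.shape != shape:
                raise ValueError(f"band {wl} shape {arr.shape} != grid shape {shape}")
        self.flags = np.asarray(self.flags)
        if self.flags.shape != shape:
            raise ValueError("flag raster shape does not match grid")

    def band(self, wavelength: int) -> np.ndarray:
        try:
            return self.bands[int(wavelength)]
        except KeyError:
            raise KeyError(f"scene is missing the {wavelength} nm band") from None

    def copy(self) -> "Scene":
        return Scene(
            self.grid,
            {wl: a.copy() for wl, a in self.bands.items()},
            self.flags.copy(),
            self.date,
        )


@dataclass
class BloomMask:
    """Per-pixel detection state: 0 no-bloom, 1 bloom, 255 invalid."""

    grid: Grid
    state: np.ndarray
    date: _dt.date = field(default_factory=lambda: _dt.date(2003, 1, 1))

    def __post_init__(self) -> None:
        self.state = np.asarray(self.state, dtype=np.uint8)
        if self.state.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        bad = ~np.isin(self.state, (NO_BLOOM, BLOOM, INVALID))
        if bad.any():
            raise ValueError("mask state must be 0, 1 or 255")

    @property
    def bloom(self) -> np.ndarray:
        return self.state == BLOOM

    @property
    def valid(self) -> np.ndarray:
        return self.state != INVALID

    def n_bloom(self) -> int:
        return int(self.bloom.sum())
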