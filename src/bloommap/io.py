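"""NetCDF and tabular I/O.

Scenes and masks travel as NetCDF (classic format via the scipy backend):
one variable per band named ``rrc_<wavelength>``, CF-style ``lat``/``lon``
coordinate variables, an integer ``l2_flags`` bit mask (bit order documented
in :class:`bloommap.scene.QualityFlag` and written to the file attributes),
and a ``date`` attribute.  Masks use the byte encoding 0 = no-bloom,
1 = bloom, 255 = invalid.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .compositing import AnnualCountGrid, CellFrequencyGrid
from .scene import BloomMask, Grid, QualityFlag, Scene

_FLAG_DOC = "; ".join(f"bit {int(np.log2(f.value))}: {f.name}" for f in QualityFlag)


def scene_to_dataset(scene: Scene) -> xr.Dataset:
    data = {
        f"rrc_{wl}": (("lat", "lon"), arr.astype("f8")) for wl, arr in sorted(scene.bands.items())
    }
    data["l2_flags"] = (("lat", "lon"), scene.flags.astype("i4"))
    ds = xr.Dataset(
        data,
        coords={"lat": ("lat", scene.grid.lat), "lon": ("lon", scene.grid.lon)},
        attrs={"date": scene.date.isoformat(), "flag_bits": _FLAG_DOC},
    )
    ds["lat"].attrs.update(units="degrees_north", standard_name="latitude")
    ds["lon"].attrs.update(units="degrees_east", standard_name="longitude")
    return ds


def dataset_to_scene(ds: xr.Dataset) -> Scene:
    bands = {}
    for name, var in ds.data_vars.items():
        if name.startswith("rrc_"):
            bands[int(name[4:])] = np.asarray(var.values, dtype=float)
    if not bands:
        raise ValueError("dataset has no rrc_<wavelength> band variables")
    flags = (
        np.asarray(ds["l2_flags"].values)
        if "l2_flags" in ds
        else np.zeros(next(iter(bands.values())).shape, dtype=np.uint8)
    )
    date = _dt.date.fromisoformat(str(ds.attrs.get("date", "2003-01-01")))
    grid = Grid(np.asarray(ds["lat"].values), np.asarray(ds["lon"].values))
    return Scene(grid, bands, flags, date)


def save_scene(scene: Scene, path: str | Path) -> None:
    scene_to_dataset(scene).to_netcdf(path, engine="scipy")


def load_scene(path: str | Path) -> Scene:
    with xr.open_dataset(path, engine="scipy") as ds:
        return dataset_to_scene(ds.load())


def save_mask(mask: BloomMask, path: str | Path) -> None:
    ds = xr.Dataset(
        {"bloom_state": (("lat", "lon"), mask.state.astype("u1"))},
        coords={"lat": ("lat", mask.grid.lat), "lon": ("lon", mask.grid.lon)},
        attrs={
            "date": mask.date.isoformat(),
            "encoding": "0=no-bloom, 1=bloom, 255=invalid",
        },
    )
    ds.to_netcdf(path, engine="scipy")


def load_mask(path: str | Path) -> BloomMask:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    grid = Grid(np.asarray(ds["lat"].values), np.asarray(ds["lon"].values))
    date = _dt.date.fromisoformat(str(ds.attrs.get("date", "2003-01-01")))
    return BloomMask(grid, np.asarray(ds["bloom_state"].values, dtype=np.uint8), date)


def save_counts(counts: AnnualCountGrid, path: str | Path) -> None:
    ds = xr.Dataset(
        {
            "bloom_count": (("lat", "lon"), counts.M.astype("i4")),
            "n_valid": (("lat", "lon"), counts.n_valid.astype("i4")),
        },
        coords={"lat": ("lat", counts.grid.lat), "lon": ("lon", counts.grid.lon)},
        attrs={"year": int(counts.year)},
    )
    ds.to_netcdf(path, engine="scipy")


def save_frequency(cells: CellFrequencyGrid, path: str | Path) -> None:
    ds = xr.Dataset(
        {
            "bloom_frequency": (("cell_lat", "cell_lon"), cells.frequency),
            "n_affected": (("cell_lat", "cell_lon"), cells.n_affected.astype("i4")),
            "n_total": (("cell_lat", "cell_lon"), cells.N_total.astype("i4")),
        },
        coords={
            "cell_lat": ("cell_lat", cells.lat_edges),
            "cell_lon": ("cell_lon", cells.lon_edges),
        },
        attrs={"year": int(cells.year), "mode": cells.mode, **cells.meta},
    )
    ds.to_netcdf(path, engine="scipy")


def load_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["start", "end"])
    df["start"] = df["start"].dt.date
    df["end"] = df["end"].dt.date
    return df


def save_events(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, index=False)


def load_polygons(path: str | Path) -> dict:
    """Region polygons from GeoJSON (FeatureCollection keyed by feature id
    or an ``id``/``name`` property)."""
    import shapely.geometry as sgeom

    doc = json.loads(Path(path).read_text())
    polygons = {}
    features = doc["features"] if doc.get("type") == "FeatureCollection" else [doc]
    for i, feat in enumerate(features):
        props = feat.get("properties") or {}
        rid = feat.get("id") or props.get("id") or props.get("name") or f"region_{i}"
        polygons[str(rid)] = sgeom.shape(feat["geometry"])
    return polygons
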