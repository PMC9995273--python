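"""End-to-end pipeline orchestration: simulate -> detect -> composite ->
trends -> validate, with a manifest and line-delimited structured logs.

The configuration is a plain mapping (usually loaded from YAML); every
source of randomness derives from the single top-level ``seed`` so a rerun
with the same configuration produces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bio
from .boundary import DEFAULT_BOUNDARY, from_json, to_json
from .compositing import accumulate_daily, affected_area, bloom_frequency
from .phenology import cumulative_proportions, growth_curve, growth_window, tmbaa
from .scene import BloomMask
from .spectral import detect_blooms
from .synthetic import SeriesSpec, make_bloom_series, make_events, make_scene, make_sst
from .trends import linear_trend, windowed_mean
from .validation import match_events

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "scene": {"shape": [48, 48], "fractions": {"bloom": 0.2, "turbid": 0.1,
                                               "macroalgae": 0.05, "coccolithophore": 0.05}},
    "series": {"years": 6, "shape": [6, 6], "baseline": 0.1, "trend": 0.01,
               "cluster": "II", "hemisphere": "N"},
    "sst": {"shape": [8, 8], "pattern": "planar", "trend_per_year": 0.02,
            "seasonal_amplitude": 4.0},
    "events": {"n_events": 10, "detect_fraction": 0.8, "radius": 0.5},
    "frequency_mode": "default",
    "area_mode": "coslat",
}


class ConfigError(ValueError):
    pass


class DataError(RuntimeError):
    pass


def _validate_config(config: dict) -> dict:
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (config or {}).items():
        if key not in merged:
            raise ConfigError(f"unknown configuration key {key!r}")
        if isinstance(merged[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"configuration section {key!r} must be a mapping")
            for k2, v2 in val.items():
                if k2 not in merged[key]:
                    raise ConfigError(f"unknown key {key}.{k2}")
                merged[key][k2] = v2
        else:
            merged[key] = val
    if merged["frequency_mode"] not in ("default", "literal"):
        raise ConfigError("frequency_mode must be 'default' or 'literal'")
    return merged


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict | None, outdir: str | Path, boundary_file: str | None = None):
    """Run the full synthetic pipeline into ``outdir``; returns the manifest.

    Raises :class:`ConfigError` for schema violations and :class:`DataError`
    for unreadable inputs; partial outputs are preserved on failure.
    """
    cfg = _validate_config(config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run_log.jsonl"
    manifest: dict = {"config": cfg, "outputs": {}, "stages": {}}
    boundary = DEFAULT_BOUNDARY if boundary_file is None else from_json(boundary_file)
    manifest["boundary"] = json.loads(to_json(boundary))
    seed = int(cfg["seed"])
    root = np.random.default_rng(seed)
    stage_seeds = {name: int(root.integers(2**31)) for name in
                   ("scene", "series", "sst", "events")}
    manifest["stage_seeds"] = stage_seeds

    def log(stage: str, **fields) -> None:
        rec = {"stage": stage, "seed": seed, "time": round(time.time(), 3), **fields}
        with log_path.open("a") as fh:
            fh.write(json.dumps(rec) + "\n")

    def emit(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": path.name, "sha256": _sha256(path)}

    # --- simulate ------------------------------------------------------
    t0 = time.time()
    scn_cfg = cfg["scene"]
    scene, scene_truth = make_scene(
        fractions=scn_cfg["fractions"], shape=tuple(scn_cfg["shape"]),
        seed=stage_seeds["scene"],
    )
    bio.save_scene(scene, outdir / "scene.nc")
    emit("scene", outdir / "scene.nc")

    ser_cfg = cfg["series"]
    series, series_truth = make_bloom_series(
        SeriesSpec(
            years=int(ser_cfg["years"]), shape=tuple(ser_cfg["shape"]),
            baseline=float(ser_cfg["baseline"]), trend=float(ser_cfg["trend"]),
            cluster=ser_cfg["cluster"], hemisphere=ser_cfg["hemisphere"],
            seed=stage_seeds["series"],
        )
    )
    sst_cfg = cfg["sst"]
    sst_dates, sst_data, sst_grid, _ = make_sst(
        shape=tuple(sst_cfg["shape"]), years=int(ser_cfg["years"]),
        pattern=sst_cfg["pattern"], trend_per_year=float(sst_cfg["trend_per_year"]),
        seasonal_amplitude=float(sst_cfg["seasonal_amplitude"]), seed=stage_seeds["sst"],
    )
    log("simulate", elapsed=round(time.time() - t0, 3))

    # --- detect --------------------------------------------------------
    t0 = time.time()
    mask = detect_blooms(scene, boundary)
    bio.save_mask(mask, outdir / "scene_mask.nc")
    emit("scene_mask", outdir / "scene_mask.nc")
    log("detect", n_bloom=mask.n_bloom(), elapsed=round(time.time() - t0, 3))

    # --- composite -----------------------------------------------------
    t0 = time.time()
    from .scene import Grid

    series_grid = Grid.regular(40.0, -70.0, *series[0][2].shape[1:], 0.01)
    rows = []
    yearly = {}
    for year, dates, states in series:
        counts = accumulate_daily((year, dates, states, series_grid))
        yearly[year] = counts
        cells = bloom_frequency(counts, mode=cfg["frequency_mode"])
        rows.append(
            {
                "year": year,
                "affected_area_km2": affected_area(counts, cfg["area_mode"]),
                "median_frequency": float(np.nanmedian(cells.frequency)),
            }
        )
    annual = pd.DataFrame(rows)
    annual.to_csv(outdir / "annual_stats.csv", index=False)
    emit("annual_stats", outdir / "annual_stats.csv")
    log("composite", years=len(rows), elapsed=round(time.time() - t0, 3))

    # --- trends + phenology -------------------------------------------
    t0 = time.time()
    trend = linear_trend(annual["median_frequency"].to_numpy(), annual["year"].to_numpy())
    year0, dates0, states0 = series[0]
    curve = growth_curve(cumulative_proportions(states0))
    peak_day = tmbaa(curve) if not curve.flat else None
    window = growth_window("II", ser_cfg["hemisphere"])
    sst_series = windowed_mean(sst_dates, sst_data, window)
    trends_doc = {
        "frequency_trend": {"slope": trend.slope, "p_value": trend.p_value,
                            "r": trend.r, "n_years": trend.n},
        "tmbaa_first_year": peak_day,
        "growth_window": list(window),
        "windowed_sst": {str(k): v for k, v in sst_series.items()},
        "true_frequency_slope": series_truth["expected_count_slope"],
    }
    (outdir / "trends.json").write_text(json.dumps(trends_doc, indent=2))
    emit("trends", outdir / "trends.json")
    log("trends", slope=trend.slope, p=trend.p_value, elapsed=round(time.time() - t0, 3))

    # --- validate ------------------------------------------------------
    t0 = time.time()
    ev_cfg = cfg["events"]
    all_dates = [d for _, dates, _ in series for d in dates]
    all_states = np.concatenate([states for _, _, states in series], axis=0)
    events, ev_truth = make_events(
        all_dates, all_states, series_grid, n_events=int(ev_cfg["n_events"]),
        detect_fraction=float(ev_cfg["detect_fraction"]),
        radius=float(ev_cfg["radius"]), seed=stage_seeds["events"],
    )
    bio.save_events(events, outdir / "events.csv")
    emit("events", outdir / "events.csv")
    masks = [BloomMask(series_grid, all_states[i], all_dates[i])
             for i in range(0, len(all_dates), 7)]  # weekly subsample keeps this light
    report = match_events(events, masks, radius=float(ev_cfg["radius"]))
    validation_doc = {
        "scene_ratio": report.scene_ratio,
        "n_s": report.n_s,
        "event_fraction": report.event_fraction,
        "constructed_fraction": ev_truth["detect_fraction"],
    }
    (outdir / "validation.json").write_text(json.dumps(validation_doc, indent=2))
    emit("validation", outdir / "validation.json")
    log("validate", event_fraction=report.event_fraction,
        elapsed=round(time.time() - t0, 3))

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
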