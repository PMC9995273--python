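"""Synthetic MODIS-like inputs with controlled ground truth.

Every generator here is a pure function of its seed, and each output carries
the exact truth needed to score the downstream stage: spectra know their
water-type archetype, scenes carry a label raster, multi-year bloom series
record the imposed trend and seasonal profile, SST fields their closed-form
gradient, and event tables their constructed overlap with the detections.

Spectral archetypes (Rrc, dimensionless, 9 bands):

* ``bloom`` — fluorescence peak at 678 nm; ``strength`` is the target
  fluorescence line height in mW cm^-2 um^-1 above the 667–748 baseline.
  The red-band baselines are anchored so the detection boundary is crossed
  near strength 0.02, the minimum detectable fluorescence signal.
* ``clear`` — blue-elevated oligotrophic water, no 678 peak.
* ``turbid`` — bright, red-elevated sediment water, 678 collinear with the
  667–748 baseline (FLH = 0).
* ``macroalgae`` — red-edge spectrum (748 nm >> red bands), lands in the
  purple–red gamut far below the boundary.
* ``coccolithophore`` — bright blue-green water without a 678 peak.
* ``cloud`` — bright and flat; removed by the Rrc(869) threshold.
* ``cloud_shadow`` — dark with a blue-shape anomaly; removed by index1.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, SensorConstants
from .scene import BLOOM, NO_BLOOM, BloomMask, Grid, QualityFlag, Scene

KINDS = ("bloom", "clear", "turbid", "macroalgae", "coccolithophore", "cloud", "cloud_shadow")

LABELS = {
    "clear": 0,
    "bloom": 1,
    "turbid": 2,
    "macroalgae": 3,
    "coccolithophore": 4,
    "cloud": 5,
    "cloud_shadow": 6,
    "land": 7,
}

# Fixed band values per archetype; 678 nm is filled in by rule (collinear
# with the 667-748 baseline, plus the fluorescence bump for blooms).
_BASES: dict[str, dict[int, float]] = {
    "bloom": {443: 0.008, 469: 0.008, 488: 0.008, 555: 0.007, 645: 0.003,
              667: 0.002, 748: 0.001, 869: 0.0005},
    "clear": {443: 0.012, 469: 0.0115, 488: 0.011, 555: 0.008, 645: 0.002,
              667: 0.0015, 748: 0.0008, 869: 0.0004},
    "turbid": {443: 0.020, 469: 0.022, 488: 0.025, 555: 0.030, 645: 0.028,
               667: 0.030, 748: 0.015, 869: 0.005},
    "macroalgae": {443: 0.006, 469: 0.006, 488: 0.007, 555: 0.009, 645: 0.006,
                   667: 0.005, 678: 0.006, 748: 0.030, 869: 0.020},
    "coccolithophore": {443: 0.050, 469: 0.052, 488: 0.055, 555: 0.052, 645: 0.015,
                        667: 0.010, 748: 0.004, 869: 0.002},
    "cloud": {wl: 0.12 for wl in (443, 469, 488, 555, 645, 667, 678, 748, 869)},
    "cloud_shadow": {443: 0.004, 469: 0.0045, 488: 0.006, 555: 0.004, 645: 0.003,
                     667: 0.0028, 678: 0.0028, 748: 0.0025, 869: 0.002},
}

#: Default "strong bloom" strength (FLH, mW cm^-2 um^-1); well above the
#: ~0.02 detectability threshold.
STRONG_BLOOM_STRENGTH = 0.1


def _baseline_678(r667: float, r748: float, constants: SensorConstants) -> float:
    """Rrc(678) that sits exactly on the 667-748 radiance baseline (FLH=0)."""
    F = constants.F
    l = r667 * F[667] + (r748 * F[748] - r667 * F[667]) * (678.0 - 667.0) / (748.0 - 667.0)
    return l / F[678]


@dataclass(frozen=True)
class SpectrumArchetype:
    kind: str
    strength: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown archetype kind {self.kind!r}")
        if self.strength < 0:
            raise ValueError("strength must be >= 0")


def make_spectrum(
    archetype: SpectrumArchetype | str,
    strength: float | None = None,
    noise_sd: float | None = None,
    rng: np.random.Generator | None = None,
    constants: SensorConstants = DEFAULT_CONSTANTS,
) -> dict[int, float]:
    """One 9-band Rrc spectrum of the given archetype.

    For ``bloom`` the strength is the fluorescence line height target (the
    FLH of the noise-free spectrum equals it exactly under ``constants``);
    for other kinds the strength is a brightness multiplier.
    """
    if isinstance(archetype, str):
        archetype = SpectrumArchetype(
            archetype,
            strength=STRONG_BLOOM_STRENGTH if (archetype == "bloom" and strength is None)
            else (1.0 if strength is None else strength),
            noise_sd=0.0 if noise_sd is None else noise_sd,
        )
    kind = archetype.kind
    s = archetype.strength if strength is None else strength
    sd = archetype.noise_sd if noise_sd is None else noise_sd
    if rng is None:
        rng = np.random.default_rng(archetype.seed)

    base = dict(_BASES[kind])
    if kind == "bloom":
        base[678] = _baseline_678(base[667], base[748], constants) + s / constants.F[678]
    elif kind in ("clear", "turbid", "coccolithophore"):
        scale = s if s > 0 else 1.0
        base = {wl: v * scale for wl, v in base.items()}
        base[678] = _baseline_678(base[667], base[748], constants)
    elif kind in ("macroalgae", "cloud", "cloud_shadow"):
        scale = s if s > 0 else 1.0
        if kind != "cloud":  # keep cloud flat at its bright level
            base = {wl: v * scale for wl, v in base.items()}
    if sd > 0:
        noise = rng.normal(0.0, sd, size=len(base))
        base = {wl: v + n for (wl, v), n in zip(sorted(base.items()), noise)}
    return base


# ---------------------------------------------------------------------------
# scenes


def sample_bloom_strengths(
    n: int,
    rng: np.random.Generator,
    median: float = 0.1,
    sigma: float = 0.5,
    clip: tuple[float, float] = (0.02, 1.0),
) -> np.ndarray:
    """Lognormal weak-to-strong bloom FLH distribution, clipped."""
    return np.clip(rng.lognormal(np.log(median), sigma, size=n), *clip)


def make_scene(
    fractions: dict[str, float] | None = None,
    shape: tuple[int, int] = (64, 64),
    seed: int = 0,
    noise_sd: float = 1e-5,
    bloom_strength: float | None = None,
    lat0: float = 30.0,
    lon0: float = -80.0,
    step: float = 0.01,
    date: _dt.date = _dt.date(2010, 7, 1),
    constants: SensorConstants = DEFAULT_CONSTANTS,
) -> tuple[Scene, dict]:
    """A scene of spatially contiguous archetype patches with ground truth.

    ``fractions`` maps archetype kind (or ``"land"``) to its pixel fraction;
    the remainder is clear water.  Patches are contiguous row-major runs.
    Bloom strengths are drawn from the lognormal weak-to-strong distribution
    unless ``bloom_strength`` pins them to one value.  Returns the scene and
    a truth dict with ``labels`` (coded per :data:`LABELS`) and
    ``bloom_strength`` rasters.
    """
    if fractions is None:
        fractions = {"bloom": 0.2, "turbid": 0.1, "macroalgae": 0.05,
                     "coccolithophore": 0.05}
    total = sum(fractions.values())
    if total > 1.0 + 1e-9:
        raise ValueError("class fractions must sum to <= 1")
    rng = np.random.default_rng(seed)
    ny, nx = shape
    npix = ny * nx
    grid = Grid.regular(lat0, lon0, ny, nx, step)

    labels = np.zeros(npix, dtype=np.uint8)  # clear by default
    start = 0
    for kind, frac in fractions.items():
        count = int(round(frac * npix))
        labels[start : start + count] = LABELS[kind]
        start += count
    labels = labels.reshape(shape)

    strengths = np.zeros(shape)
    bloom_pix = labels == LABELS["bloom"]
    nb = int(bloom_pix.sum())
    if nb:
        strengths[bloom_pix] = (
            np.full(nb, bloom_strength) if bloom_strength is not None
            else sample_bloom_strengths(nb, rng)
        )

    wavelengths = sorted(constants.band_centres)
    bands = {wl: np.empty(shape) for wl in wavelengths}
    for kind, code in LABELS.items():
        pix = labels == code
        if not pix.any():
            continue
        spec_kind = "clear" if kind == "land" else kind
        if spec_kind == "bloom":
            base = dict(_BASES["bloom"])
            b678 = _baseline_678(base[667], base[748], constants)
            for wl in wavelengths:
                if wl == 678:
                    bands[wl][pix] = b678 + strengths[pix] / constants.F[678]
                else:
                    bands[wl][pix] = base[wl]
        else:
            spec = make_spectrum(spec_kind, strength=1.0, noise_sd=0.0, constants=constants)
            for wl in wavelengths:
                bands[wl][pix] = spec[wl]
    if noise_sd > 0:
        for wl in wavelengths:
            bands[wl] += rng.normal(0.0, noise_sd, size=shape)

    flags = np.zeros(shape, dtype=np.uint8)
    flags[labels == LABELS["land"]] = np.uint8(QualityFlag.LAND)

    scene = Scene(grid, bands, flags, date)
    return scene, {"labels": labels, "bloom_strength": strengths}


@dataclass(frozen=True)
class AerosolPerturbation:
    """Parametric maritime-like aerosol added to every band.

    The added reflectance follows a power law in wavelength,
    ``rho_a(lambda) = scattering_factor * delta_aot_869 * (lambda/869)^(-angstrom)``,
    a near-flat spectral shape for the default Angstrom exponent 0.2 with a
    single configurable single-scattering proportionality factor.
    """

    delta_aot_869: float
    angstrom_exponent: float = 0.2
    scattering_factor: float = 0.25

    def __post_init__(self) -> None:
        if self.delta_aot_869 < 0:
            raise ValueError("delta_aot_869 must be >= 0")

    def reflectance(self, wavelength) -> np.ndarray:
        wl = np.asarray(wavelength, dtype=float)
        return self.scattering_factor * self.delta_aot_869 * (wl / 869.0) ** (
            -self.angstrom_exponent
        )


def perturb_aerosol(scene: Scene, p: AerosolPerturbation) -> Scene:
    """New scene with the aerosol reflectance added to every band."""
    out = scene.copy()
    for wl in out.bands:
        out.bands[wl] = out.bands[wl] + float(p.reflectance(wl))
    return out


# ---------------------------------------------------------------------------
# multi-year daily bloom series

SOUTHERN_SHIFT_DAYS = 183


def seasonal_profile(cluster: str, hemisphere: str = "N") -> np.ndarray:
    """Day-of-year (1-365) bloom-probability profile, peak-normalised to 1.

    Cluster I peaks early in the year, cluster II mid-year (its cumulative
    curve inflects inside days 150-270), cluster III is uniform (affected
    area grows all year).  Southern-hemisphere profiles are rolled forward by
    183 days.
    """
    d = np.arange(1, 366, dtype=float)

    def wrapped_gauss(mu: float, sigma: float) -> np.ndarray:
        out = np.zeros_like(d)
        for k in (-365.0, 0.0, 365.0):
            out += np.exp(-0.5 * ((d - mu + k) / sigma) ** 2)
        return out / out.max()

    if cluster == "I":
        prof = wrapped_gauss(60.0, 40.0)
    elif cluster == "II":
        prof = wrapped_gauss(210.0, 25.0)
    elif cluster == "III":
        prof = np.ones_like(d)
    else:
        raise ValueError(f"unknown cluster {cluster!r}")
    if hemisphere.upper().startswith("S"):
        prof = np.roll(prof, SOUTHERN_SHIFT_DAYS)
    elif not hemisphere.upper().startswith("N"):
        raise ValueError(f"unknown hemisphere {hemisphere!r}")
    return prof


@dataclass(frozen=True)
class SeriesSpec:
    years: int = 18
    shape: tuple[int, int] = (8, 8)
    baseline: float = 0.1
    trend: float = 0.005
    cluster: str = "II"
    hemisphere: str = "N"
    start_year: int = 2003
    seed: int = 0


def year_dates(year: int) -> list[_dt.date]:
    """The 365 calendar dates of a year, 29 February dropped."""
    days = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    return [t.date() for t in days if not (t.month == 2 and t.day == 29)]


def make_bloom_series(spec: SeriesSpec) -> tuple[list[tuple[int, list, np.ndarray]], dict]:
    """Daily Bernoulli bloom-state stacks for each year, plus ground truth.

    The per-pixel daily bloom probability is
    ``profile(doy) * (baseline + trend * year_index)``, clipped to [0, 1]
    (clip events counted in the truth dict).  All pixels are valid every day.
    Returns a list of ``(year, dates, states)`` with ``states`` a uint8
    array of shape (365, ny, nx), and a truth dict recording the profile,
    the imposed trend and the expected slope of the default cell frequency
    (mean annual count per pixel), ``trend * profile.sum()``.
    """
    rng = np.random.default_rng(spec.seed)
    prof = seasonal_profile(spec.cluster, spec.hemisphere)
    ny, nx = spec.shape
    years_out = []
    n_clipped = 0
    for i in range(spec.years):
        level = spec.baseline + spec.trend * i
        p = prof * level
        clipped = (p > 1.0) | (p < 0.0)
        n_clipped += int(clipped.sum())
        p = np.clip(p, 0.0, 1.0)
        draws = rng.random((365, ny, nx)) < p[:, None, None]
        states = np.where(draws, BLOOM, NO_BLOOM).astype(np.uint8)
        year = spec.start_year + i
        years_out.append((year, year_dates(year), states))
    truth = {
        "profile": prof,
        "baseline": spec.baseline,
        "trend": spec.trend,
        "expected_count_slope": spec.trend * float(prof.sum()),
        "n_clipped_days": n_clipped,
    }
    return years_out, truth


def series_to_masks(series_year: tuple[int, list, np.ndarray], grid: Grid) -> list[BloomMask]:
    """Expand one year of a series into dated BloomMask objects."""
    _, dates, states = series_year
    return [BloomMask(grid, states[i], dates[i]) for i in range(len(dates))]


# ---------------------------------------------------------------------------
# SST fields

METRES_PER_DEGREE = 111195.0


def make_sst(
    shape: tuple[int, int] = (16, 16),
    years: int = 1,
    pattern: str = "planar",
    base: float = 15.0,
    meridional_gradient: float = 1e-5,
    zonal_gradient_deg: float = 0.0,
    front_amplitude: float = 2.0,
    front_width_m: float = 50_000.0,
    trend_per_year: float = 0.0,
    seasonal_amplitude: float = 0.0,
    seasonal_phase_day: float = 196.0,
    noise_sd: float = 0.0,
    lat0: float = 40.0,
    lon0: float = -70.0,
    step: float = 0.25,
    start_year: int = 2003,
    seed: int = 0,
) -> tuple[list[_dt.date], np.ndarray, Grid, dict]:
    """Daily SST raster series with a controlled spatial gradient and trend.

    Patterns: ``uniform`` (gradient 0); ``planar`` (linear in northward
    metres with slope ``meridional_gradient`` degC/m); ``zonal_planar``
    (linear in longitude degrees, per-metre slope
    ``zonal_gradient_deg / (111195 cos(lat))``); ``front`` (tanh front in
    the meridional direction, maximum gradient ``amplitude/width`` at the
    front centre).  Time axis adds ``trend_per_year`` and an optional
    sinusoidal seasonal cycle.
    """
    rng = np.random.default_rng(seed)
    ny, nx = shape
    grid = Grid.regular(lat0, lon0, ny, nx, step)
    lat2d = grid.lat[:, None] * np.ones((1, nx))
    north_m = (lat2d - lat0) * METRES_PER_DEGREE
    lon2d = np.ones((ny, 1)) * grid.lon[None, :]

    if pattern == "uniform":
        spatial = np.full(shape, base)
        truth_grad = np.zeros(shape)
    elif pattern == "planar":
        spatial = base + meridional_gradient * north_m
        truth_grad = np.full(shape, abs(meridional_gradient))
    elif pattern == "zonal_planar":
        spatial = base + zonal_gradient_deg * (lon2d - lon0)
        truth_grad = np.abs(zonal_gradient_deg) / (
            METRES_PER_DEGREE * np.cos(np.deg2rad(lat2d))
        )
    elif pattern == "front":
        centre = north_m.mean()
        spatial = base + front_amplitude * np.tanh((north_m - centre) / front_width_m)
        truth_grad = (front_amplitude / front_width_m) / np.cosh(
            (north_m - centre) / front_width_m
        ) ** 2
        truth_grad = np.abs(truth_grad)
    else:
        raise ValueError(f"unknown SST pattern {pattern!r}")

    dates: list[_dt.date] = []
    frames = []
    doy = np.arange(1, 366)
    for i in range(years):
        season = seasonal_amplitude * np.sin(2 * np.pi * (doy - seasonal_phase_day) / 365.0)
        level = trend_per_year * i
        yearly = spatial[None] + (season + level)[:, None, None]
        if noise_sd > 0:
            yearly = yearly + rng.normal(0.0, noise_sd, size=yearly.shape)
        frames.append(yearly)
        dates.extend(year_dates(start_year + i))
    data = np.concatenate(frames, axis=0)
    truth = {"gradient": truth_grad, "trend_per_year": trend_per_year, "pattern": pattern}
    return dates, data, grid, truth


# ---------------------------------------------------------------------------
# event tables (in-situ style bloom event records)


def make_events(
    dates: list[_dt.date],
    states: np.ndarray,
    grid: Grid,
    n_events: int = 20,
    detect_fraction: float = 0.8,
    radius: float = 0.5,
    period_days: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Event records with a constructed overlap to the detections.

    ``round(n_events * detect_fraction)`` events are centred on pixel-days
    with a bloom (guaranteed hit inside the radius); the rest are decoys
    placed where no bloom occurs within the radius during the whole series.
    Returns the event table (event_id, lat, lon, start, end) and a truth
    dict with the per-event detected flags and the exact constructed
    fraction.
    """
    rng = np.random.default_rng(seed)
    states = np.asarray(states)
    nt = states.shape[0]
    if nt != len(dates):
        raise ValueError("dates and state stack lengths differ")
    bloom = states == BLOOM
    lat2d = grid.lat[:, None] * np.ones((1, grid.lon.size))
    lon2d = np.ones((grid.lat.size, 1)) * grid.lon[None, :]

    n_hits = int(round(n_events * detect_fraction))
    n_decoys = n_events - n_hits
    t_hit, y_hit, x_hit = np.nonzero(bloom)
    if n_hits > 0 and t_hit.size == 0:
        raise ValueError("no bloom pixel-days available for hit events")

    def box(i: int, j: int) -> np.ndarray:
        return (np.abs(grid.lat - grid.lat[i])[:, None] <= radius) & (
            np.abs(grid.lon - grid.lon[j])[None, :] <= radius
        )

    rows = []
    detected_truth = []
    for k in range(n_hits):
        m = int(rng.integers(t_hit.size))
        t0 = max(0, int(t_hit[m]) - period_days // 2)
        t1 = min(nt - 1, t0 + period_days - 1)
        rows.append(
            (f"ev{k:03d}", lat2d[y_hit[m], x_hit[m]], lon2d[y_hit[m], x_hit[m]],
             dates[t0], dates[t1])
        )
        detected_truth.append(True)
    # decoys: a location and period with zero bloom overlap inside the
    # radius, found by scanning pixels (in seeded random order) for their
    # longest bloom-free run of days
    ny, nx = bloom.shape[1:]
    placed = 0
    for flat in rng.permutation(ny * nx):
        if placed >= n_decoys:
            break
        i, j = divmod(int(flat), nx)
        free = ~bloom[:, box(i, j)].any(axis=1)
        if not free.any():
            continue
        edges = np.flatnonzero(np.diff(np.r_[0, free.astype(np.int8), 0]))
        starts, ends = edges[::2], edges[1::2]
        run = int(np.argmax(ends - starts))
        t0 = int(starts[run])
        t1 = min(int(ends[run]) - 1, t0 + period_days - 1)
        rows.append((f"ev{n_hits + placed:03d}", lat2d[i, j], lon2d[i, j],
                     dates[t0], dates[t1]))
        detected_truth.append(False)
        placed += 1
    if placed < n_decoys:
        raise ValueError("could not place enough zero-overlap decoy events")

    events = pd.DataFrame(rows, columns=["event_id", "lat", "lon", "start", "end"])
    truth = {
        "detected": np.array(detected_truth),
        "detect_fraction": n_hits / n_events if n_events else float("nan"),
    }
    return events, truth


def make_annual_covariate(
    n_years: int, trend: float = 0.0, noise_sd: float = 1.0, base: float = 0.0, seed: int = 0
) -> np.ndarray:
    """A simple annual covariate series (climate index / fertilizer style)."""
    rng = np.random.default_rng(seed)
    return base + trend * np.arange(n_years) + rng.normal(0.0, noise_sd, n_years)


# ---------------------------------------------------------------------------
# archetype growth curves for clustering fixtures


def archetype_curves(days: np.ndarray | None = None) -> np.ndarray:
    """The three canonical cumulative growth curves (rows: clusters I-III)."""
    if days is None:
        days = np.arange(1, 366, dtype=float)
    curves = []
    for cluster in ("I", "II", "III"):
        prof = seasonal_profile(cluster)
        cum = np.cumsum(prof)
        curves.append(cum / cum[-1])
    return np.asarray(curves)


def make_cluster_fixture(
    n_per_cluster: int = 50, noise_sd: float = 0.0, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Replicated (optionally noisy) archetype curves with true labels."""
    rng = np.random.default_rng(seed)
    arch = archetype_curves()
    curves, labels = [], []
    for c in range(3):
        for _ in range(n_per_cluster):
            curve = arch[c] + (rng.normal(0.0, noise_sd, arch.shape[1]) if noise_sd > 0 else 0.0)
            curves.append(np.clip(curve, 0.0, 1.2))
            labels.append(c)
    return np.asarray(curves), np.asarray(labels)
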