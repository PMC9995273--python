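# bloommap

Detection and statistical analysis of coastal phytoplankton blooms from
multi-band Rayleigh-corrected reflectance (R<sub>rc</sub>, dimensionless),
as measured by MODIS-class ocean-colour sensors. The package implements a
complete desk-scale pipeline — per-pixel bloom classification, daily-to-annual
compositing, trend and driver analysis, phenology, and validation — and ships
a synthetic-data module that generates MODIS-like scenes, multi-year daily
bloom series, SST fields and in-situ-style event records with controlled
ground truth, so every stage is testable without satellite downloads.

It is written for ocean-colour and HAB researchers who need a reproducible,
configurable implementation of CIE-chromaticity bloom detection and the
level-3 statistics built on it.

## The algorithm

A pixel's R<sub>rc</sub> at 748, 678 and 667 nm is assigned to the (R, G, B)
channels of the CIE tristimulus conversion — note the deliberate inversion of
the usual channel order, with the 678 nm **fluorescence band** on G so that
the chromaticity ordinate *y* measures fluorescence strength:

```
X = 2.7689 R + 1.7517 G + 1.1302 B
Y = 1.0000 R + 4.5907 G + 0.0601 B
Z = 0.0000 R + 0.0565 G + 5.5943 B
x = X/(X+Y+Z),  y = Y/(X+Y+Z)
```

Equal channels map exactly to the white point (1/3, 1/3). A trained frontier
of two quadratics separates bloom colours from bloom-free water:

```
y1 = 4.8093 x² − 3.0958 x + 0.8357   (x < 1/3)
y2 = 4.9040 x² − 3.5759 x + 0.9862   (x ≥ 1/3)
```

A valid pixel is a **bloom** iff (x < 1/3 and y > y1) or (x ≥ 1/3 and
y > y2). Validity is decided first: level-2 quality flags (straylight, cloud,
land, sunglint, solar/sensor zenith), the R<sub>rc</sub>(869) < 0.027 cloud
rule, and two spectral-shape indices that remove residual cloud
(index2 < 0.012) and cloud shadow (index1 > 0.12).

The fluorescence line height
FLH = R<sub>rc678</sub>F₆₇₈ − [R<sub>rc667</sub>F₆₆₇ +
(R<sub>rc748</sub>F₇₄₈ − R<sub>rc667</sub>F₆₆₇)·(678−667)/(748−667)]
quantifies the 678 nm peak above its red/NIR baseline (mW cm⁻² μm⁻¹).

Downstream, daily bloom masks are composited into per-pixel annual counts
M<sub>i</sub>; the cell-level **bloom frequency** over a 1°×1° cell with N
pixels, n of them affected, is ΣM<sub>i</sub>/N by default (a literal
(n/N)·ΣM<sub>i</sub> mode is available); trends are OLS slopes with two-sided
t-tests; bloom phenology is summarised by penalized cyclic-spline growth
curves, their inflection day (TMBAA), fuzzy c-means clustering into three
seasonal archetypes, and per-cluster growth windows (full year, or days
150–270 for the mid-year cluster, shifted 183 days in the southern
hemisphere) over which SST and its spatial gradient (a mesoscale-current
proxy) are averaged.

## Worked example

```python
import numpy as np
from bloommap import (make_scene, detect_blooms, perturb_aerosol, AerosolPerturbation,
                      accumulate_daily, bloom_frequency, make_bloom_series,
                      SeriesSpec, linear_trend, Grid, growth_curve, tmbaa, growth_window)
from bloommap.phenology import cumulative_proportions

# a 128x128 synthetic coastal scene: clear water, bloom, turbid, macroalgae
# and coccolithophore patches, blooms spanning weak-to-strong fluorescence
scene, truth = make_scene(shape=(128, 128), seed=7)
mask = detect_blooms(scene)
print(f"detected bloom pixels: {mask.n_bloom()} "
      f"(ground truth: {(truth['labels'] == 1).sum()})")

# robustness to a +0.02 aerosol optical thickness perturbation at 869 nm
perturbed = perturb_aerosol(scene, AerosolPerturbation(delta_aot_869=0.02))
n0, n1 = mask.n_bloom(), detect_blooms(perturbed).n_bloom()
print(f"area change under +0.02 AOT(869): {100*abs(n1-n0)/n0:.2f}%")

# an 18-year daily series with an imposed frequency trend, recovered by OLS
series, _ = make_bloom_series(SeriesSpec(years=18, shape=(8, 8), baseline=0.1,
                                         trend=0.005, cluster="II", seed=7))
grid = Grid.regular(40.0, -70.0, 8, 8, 0.01)
freq = [float(bloom_frequency(accumulate_daily((y, d, s, grid))).frequency[0, 0])
        for y, d, s in series]
res = linear_trend(freq)
print(f"bloom-frequency trend: {res.slope:+.3f} yr^-1 (p = {res.p_value:.2g})")

# phenology of the first year
curve = growth_curve(cumulative_proportions(series[0][2]))
print(f"TMBAA: day {tmbaa(curve)}; cluster-II growth window: {growth_window('II')}")
```

Output:

```
detected bloom pixels: 3276 (ground truth: 3277)
area change under +0.02 AOT(869): 0.67%
bloom-frequency trend: +0.325 yr^-1 (p = 8.3e-12)
TMBAA: day 182; cluster-II growth window: (150, 270)
```

The detector recovers the constructed bloom patch to within one pixel; the
aerosol perturbation moves well under 2% of the detected area; the fitted
frequency slope matches the imposed trend (0.005 × Σprofile ≈ 0.31 per
year); and the mid-year cluster's growth curve inflects near its expected
day.

## Command line

`bloommap` exposes `simulate`, `detect`, `composite`, `trends`, `validate`
and `run` (full pipeline from a YAML config, writing a manifest with seeds
and output checksums). Scenes and masks travel as NetCDF; masks use the byte
encoding 0 = no-bloom, 1 = bloom, 255 = invalid. Exit codes: 0 success,
2 configuration error, 3 data error.

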