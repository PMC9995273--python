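# Methods

## Pixel classification model

Bloom detection is colourimetric. The Rayleigh-corrected reflectances at
748, 678 and 667 nm feed the (R, G, B) channels of the CIE tristimulus
transform; the fluorescence band occupies G so that the chromaticity
ordinate *y* is a monotone proxy for the chlorophyll fluorescence signal
(holding the red and NIR bands fixed, ∂y/∂R_rc678 > 0 — asserted numerically
in the tests). Chromaticity is invariant to overall brightness, which is
what makes a single global frontier possible where index-threshold
algorithms need regional tuning: only spectral *shape* matters.

The frontier is two quadratics in x meeting near the white point (1/3, 1/3),
evaluated piecewise (left of the split with y1, at/right of it with y2; the
split case is measure-zero and the two curves agree there to within 0.001).
A pixel is a bloom only if y strictly exceeds the frontier. Beyond x ≈ 0.73
the right quadratic exceeds 1 while every chromaticity point obeys
y ≤ 1 − x, so that region is automatically bloom-free; the boundary
validity check therefore requires positivity on [0, 1] but boundedness
below 1 only on [0.05, 0.7].

Masking precedes classification, cheapest tests first: level-2 quality
flags; the R_rc(869) ≥ 0.027 cloud rule; the cloud index
(index2 < 0.012 removes spectrally flat bright pixels) and the shadow index
(index1 > 0.12). Both indices are shape indices: bands are normalized by a
reference band — 488 nm for index1, 469 nm for index2 — so the thresholds
respond only to relative spectral shape. The reference band for index2 is
not uniquely determined by the construction of index1; we use the index's
own first difference band (469 nm), the choice that makes the two indices
structurally parallel. Pixels with any conversion band below −0.005
(residual atmospheric-correction failure) or with a non-positive tristimulus
sum are invalid.

Solar irradiances F₆₆₇/F₆₇₈/F₇₄₈ enter only the FLH in physical units; the
defaults are Thuillier-scale MODIS band irradiances (152.55, 148.05,
128.00 mW cm⁻² μm⁻¹) and are configurable. Exactness tests set F ≡ 1.

## Boundary fitting

`fit_boundary` reproduces the training procedure from labelled bloom
chromaticities: bin by x (default width 0.01), drop bins with fewer than 50
samples, take the 1st percentile of y per bin (linear interpolation between
order statistics — percentile conventions differ across tools, so this is
pinned), and fit an unweighted OLS quadratic per side of the split. Bin
width/occupancy are not dictated by the procedure itself; the defaults give
≈30 usable bins across the occupied gamut at the 5×10⁴-sample scale the
frontier was originally trained at. Fewer than three usable bins on a side
is an error naming the side. A percentile of 0.003 instead of 0.01 changes
the classified bloom area of a reference synthetic scene by < 1%,
mirroring the training sensitivity analysis at desk scale.

## Synthetic data: what it emulates, and what it does not

Archetype spectra (9 bands) encode the qualitative optics that matter to
the classifier: blooms have a 678 nm peak above the 667–748 radiance
baseline, with `strength` equal to the FLH in mW cm⁻² μm⁻¹; turbid water is
bright, red-elevated and exactly baseline-collinear at 678 (FLH = 0);
macroalgae carry a red edge (R_rc748 ≫ red bands, negative FLH) landing in
the purple–red gamut far below the frontier; coccolithophore water is bright
and blue-green elevated without a 678 peak; cloud is bright and flat
(caught by the 869 nm rule and index2); cloud shadow is dark with the
blue-shape anomaly index1 targets. The bloom red-band baselines
(R_rc667 = 0.002, R_rc748 = 0.001 — dark water plus a small residual
aerosol signal) are anchored so the frontier is crossed near
strength 0.02, the minimum detectable fluorescence signal; scene blooms
draw strengths from a lognormal (median 0.1, σ = 0.5, clipped to
[0.02, 1]), a realistic weak-to-strong range. Per-band Gaussian noise
(default sd 1e-5 in reflectance) represents radiometric noise small enough
to keep the classes separable, consistent with the >92% pixel accuracies of
the validated regime these fixtures emulate.

Scenes are contiguous row-major class patches on a regular lat/lon grid with
land flagged; there is no radiative-transfer fidelity, no sensor geometry,
no adjacency effects, and no spatial correlation in the noise. Passing tests
therefore demonstrate the correctness of the *machinery* (classification
geometry, masking order, compositing arithmetic, statistical calibration),
not detection skill on real imagery.

The aerosol perturbation is a parametric stand-in for a radiative-transfer
aerosol model: added reflectance ρ_a(λ) = f·ΔAOT·(λ/869)^(−α) with a
near-flat maritime-like Angstrom exponent α = 0.2 and a single
single-scattering proportionality factor f = 0.25 absorbing albedo, phase
function and geometry. Additive quasi-white light dilutes chromaticity
toward the white point, so only pixels near the frontier can flip — the
mechanism behind the ≤2% area-change robustness result.

Multi-year series draw daily per-pixel Bernoulli states with probability
profile(doy) × (baseline + trend·year), clipped to [0, 1] with clips
counted. The three seasonal profiles mirror the observed phenology
archetypes: an early-year peak (I, wrapped Gaussian at day 60, σ 40), a
mid-year peak (II, day 210, σ 25 — its cumulative curve inflects inside
days 150–270), and uniform year-round growth (III). Southern-hemisphere
profiles are rolled forward 183 days. The expected slope of the default
cell frequency is trend × Σprofile, recorded as ground truth. SST fields
are uniform, planar, zonal-planar or tanh-front patterns with closed-form
gradient truth, plus optional sinusoidal seasonality and a linear warming
trend. Event tables place a constructed fraction of events on bloom
pixel-days and the rest on locations/periods with zero bloom overlap within
the matching radius (found by scanning pixels for their longest bloom-free
run), so the event-level detection fraction is known exactly.

## Compositing and statistics

Annual counts M (bloom days per pixel) and n_valid accumulate from dated
daily masks; order is immaterial. Affected area sums pixel areas over
M > 0, cos(latitude)-weighted by default (1 km² at the equator) — nominal
equal-area weighting is available. The printed cell-frequency formula
(n/N)·ΣM_i scales with the number of pixels in a cell; the default mode
reports ΣM_i/N (affected fraction × mean count over affected pixels), the
dimensionless density the statistic is meant to capture, and the literal
mode is retained for auditability, with the mode recorded in output
metadata. Pixels map to cells by centre containment in half-open
[edge, edge+1°) intervals — a partition, no double counting. Zonal
summaries use pixel-centre-in-polygon membership (shapely), with medians as
linearly interpolated 50th percentiles.

Trends are OLS vs year with the two-sided t-test on the slope (scipy);
a constant series reports slope 0, p = 1. Correlations are Pearson r with
two-sided p, pairwise-complete. The SST gradient magnitude uses central
differences (one-sided at edges) with metric spacing: 111195 m per degree
of latitude, scaled by cos(latitude) zonally.

## Phenology

The growth curve of a cell-year is the cumulative proportion of
ever-affected pixels vs day of year. Smoothing uses a penalized cyclic
cubic B-spline (20 basis functions, circulant second-difference penalty)
under a log link, fitted to the *daily increments* of the cumulative curve —
the increments, not the cumulative level, are the periodic quantity, which
is why the periodic basis applies to them; the smoothed density is
integrated back, rescaled to the observed year-end level, and made monotone
by a running maximum. Smoothing strength is chosen by GCV over a log-spaced
λ grid, with a fixed 8-effective-df fallback if GCV degenerates; all
smoothing metadata is recorded on the curve. An all-zero year yields a flat
curve whose TMBAA is undefined (error).

TMBAA is the day of maximum first derivative of the smoothed cumulative
curve — the inflection of a sigmoidal growth curve — with ties broken to
the earliest day (a linear ramp reports its first day). Note one boundary
effect: when a season is truncated at the record start (southern mid-year
cluster viewed on the calendar axis), the raw steepest increment sits at
day 1 and the periodic smoother legitimately relocates it inward; the tests
therefore compare stochastic series against the smoothed noise-free
saturation curve 1 − Π(1−p_k) through the same smoother.

Fuzzy c-means (fuzzifier 2.0, tolerance 1e-5 on centroid shift, ≤1000
iterations, seeded random initial memberships) clusters cumulative curves
into k = 3 groups; distances within a relative 1e-12 of zero share
membership equally, so identical curves degrade gracefully to 1/3 each.
Clusters are relabelled to the I/II/III archetype order by the
minimum-cost permutation against reference archetype centroids. Growth
windows: full year for clusters I and III, days 150–270 for cluster II;
southern windows live on the 183-day-shifted axis, so the cluster-II window
wraps the calendar year as (332, 87). Windowed means average a daily field
over the window days of each year, handling the wrap.

## Validation

Event matching: for each event, dated masks inside its period are *valid*
scenes when ≥ 10% (configurable) of pixels within the 0.5° (configurable)
radius are unmasked, and *detected* when any bloom pixel lies within the
radius — the matching radius and valid-image criterion are not dictated by
the event records themselves, so both are config-exposed. Aggregates:
pooled detected/valid scene ratio, the count of events with ≥1 detection
(N_s), and the event-level detection fraction. Duplicate events merge when
centres are within 0.1° and periods overlap. Pixel confusion counts only
mutually valid pixels; producer accuracy TP/(TP+FN), user accuracy
TP/(TP+FP).

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale by design: scenes
up to 512×512 pixels, series of 18 years × 365 days on small grids, 500
replicates for slope-coverage calibration and 1000 for null-rejection
calibration (the 95% CI must cover the imposed slope in ≥93% of replicates;
the null rejects in 5% ± 2%). Global multi-petabyte archive statistics
(such as total affected areas of tens of millions of km²) are out of scope
by construction. Determinism: every generator is a pure function of its
seed; the pipeline derives per-stage seeds from one root seed and writes
them, with output checksums, to its manifest.

## Known limitations

- No Rayleigh or full atmospheric correction: inputs are assumed to already
  be R_rc; no Rrs/nFLH standard products.
- No species discrimination; a bloom is "detectable surface fluorescence".
- The synthetic archetypes are shape-constrained, not radiometrically
  calibrated; quantitative macroalgae/coccolithophore spectra vary widely
  in nature.
- GeoTIFF I/O is not provided; scenes and masks are NetCDF (classic
  format), with the mask byte encoding 0/1/255.
- The GAM smoother is a penalized cyclic P-spline with a log link, not a
  full GAM framework; its basis dimension (20) and λ grid are fixed,
  GCV-selected per fit.
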