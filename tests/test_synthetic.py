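"""The synthetic-data generators and their ground-truth contracts."""

import numpy as np
import pytest

from bloommap import (
    BLOOM,
    DEFAULT_BOUNDARY,
    DEFAULT_CONSTANTS,
    INVALID,
    AerosolPerturbation,
    SeriesSpec,
    chromaticity,
    detect_blooms,
    flh,
    make_bloom_series,
    make_events,
    make_scene,
    make_spectrum,
    make_sst,
    perturb_aerosol,
)
from bloommap.boundary import boundary_y
from bloommap.scene import Grid
from bloommap.synthetic import (
    LABELS,
    STRONG_BLOOM_STRENGTH,
    SpectrumArchetype,
    archetype_curves,
    make_cluster_fixture,
    sample_bloom_strengths,
    seasonal_profile,
)


def _classify(spectrum):
    p = chromaticity(spectrum)
    return bool(p.valid and p.y > boundary_y(p.x, DEFAULT_BOUNDARY))


class TestSpectra:
    def test_strong_bloom_is_classified_bloom(self):
        assert _classify(make_spectrum("bloom", strength=STRONG_BLOOM_STRENGTH))

    @pytest.mark.parametrize("kind", ["clear", "turbid", "macroalgae", "coccolithophore"])
    def test_bloom_free_archetypes_are_no_bloom(self, kind):
        for strength in (0.5, 1.0, 2.0):
            assert not _classify(make_spectrum(kind, strength=strength))

    def test_turbid_spectrum_is_baseline_collinear(self):
        spec = make_spectrum("turbid")
        assert flh(spec, DEFAULT_CONSTANTS) == pytest.approx(0.0, abs=1e-12)

    def test_macroalgae_has_red_edge_and_negative_flh(self):
        spec = make_spectrum("macroalgae")
        assert spec[748] > 3 * spec[667]
        assert flh(spec, DEFAULT_CONSTANTS) < 0

    def test_bloom_flh_equals_strength(self):
        for h in (0.02, 0.05, 0.3):
            spec = make_spectrum("bloom", strength=h)
            assert flh(spec, DEFAULT_CONSTANTS) == pytest.approx(h, abs=1e-12)

    def test_unknown_kind_raises(self):
        with pytest.raises(ValueError, match="unknown archetype"):
            SpectrumArchetype("algae_bloom")

    def test_noise_free_confusion_matrix_is_diagonal(self):
        # class separability: noise-free archetypes never cross the boundary
        rng = np.random.default_rng(3)
        for kind in ("bloom", "clear", "turbid", "macroalgae", "coccolithophore"):
            for _ in range(50):
                s = (
                    float(sample_bloom_strengths(1, rng, median=0.1)[0])
                    if kind == "bloom"
                    else float(rng.uniform(0.5, 2.0))
                )
                spec = make_spectrum(kind, strength=max(s, 0.03) if kind == "bloom" else s)
                assert _classify(spec) == (kind == "bloom")


class TestScenes:
    def test_layout_fractions_and_determinism(self):
        scene_a, truth_a = make_scene(shape=(40, 40), seed=9)
        scene_b, truth_b = make_scene(shape=(40, 40), seed=9)
        assert np.array_equal(truth_a["labels"], truth_b["labels"])
        for wl in scene_a.bands:
            assert np.array_equal(scene_a.bands[wl], scene_b.bands[wl])
        frac_bloom = (truth_a["labels"] == LABELS["bloom"]).mean()
        assert frac_bloom == pytest.approx(0.2, abs=1e-9)

    def test_noise_free_scene_recovers_bloom_fraction_exactly(self):
        scene, truth = make_scene(
            fractions={"bloom": 0.1}, shape=(40, 40), seed=2, noise_sd=0.0,
            bloom_strength=STRONG_BLOOM_STRENGTH,
        )
        mask = detect_blooms(scene)
        assert mask.n_bloom() == (truth["labels"] == LABELS["bloom"]).sum()

    def test_cloud_patch_is_invalid_never_bloom(self):
        scene, truth = make_scene(
            fractions={"bloom": 0.2, "cloud": 0.2}, shape=(30, 30), seed=4
        )
        mask = detect_blooms(scene)
        cloudy = truth["labels"] == LABELS["cloud"]
        assert (mask.state[cloudy] == INVALID).all()

    def test_land_flagged_pixels_are_invalid(self):
        scene, truth = make_scene(fractions={"land": 0.1}, shape=(20, 20), seed=0)
        mask = detect_blooms(scene)
        assert (mask.state[truth["labels"] == LABELS["land"]] == INVALID).all()

    def test_overfull_fractions_rejected(self):
        with pytest.raises(ValueError, match="<= 1"):
            make_scene(fractions={"bloom": 0.7, "turbid": 0.5})


class TestAerosol:
    def test_zero_delta_is_identity(self):
        scene, _ = make_scene(shape=(10, 10), seed=1)
        pert = perturb_aerosol(scene, AerosolPerturbation(0.0))
        for wl in scene.bands:
            assert np.array_equal(pert.bands[wl], scene.bands[wl])

    def test_positive_delta_increases_all_bands_monotonically(self):
        scene, _ = make_scene(shape=(10, 10), seed=1)
        p_small = perturb_aerosol(scene, AerosolPerturbation(0.01))
        p_large = perturb_aerosol(scene, AerosolPerturbation(0.02))
        for wl in scene.bands:
            assert (p_small.bands[wl] > scene.bands[wl]).all()
            assert (p_large.bands[wl] > p_small.bands[wl]).all()

    def test_strong_bloom_chromaticity_moves_toward_white_point(self):
        spec = make_spectrum("bloom", strength=0.3)
        p0 = chromaticity(spec)
        d0 = np.hypot(p0.x - 1 / 3, p0.y - 1 / 3)
        pert = AerosolPerturbation(0.5)  # deliberately large
        spec_p = {wl: v + float(pert.reflectance(wl)) for wl, v in spec.items()}
        p1 = chromaticity(spec_p)
        assert np.hypot(p1.x - 1 / 3, p1.y - 1 / 3) < d0

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            AerosolPerturbation(-0.01)


class TestBloomSeries:
    def test_seeded_series_is_reproducible(self):
        a, _ = make_bloom_series(SeriesSpec(years=2, shape=(4, 4), seed=6))
        b, _ = make_bloom_series(SeriesSpec(years=2, shape=(4, 4), seed=6))
        for (_, _, sa), (_, _, sb) in zip(a, b):
            assert np.array_equal(sa, sb)

    def test_cluster_ii_cumulative_inflects_inside_growth_window(self):
        prof = seasonal_profile("II")
        cum = np.cumsum(prof) / prof.sum()
        inflection_day = int(np.argmax(np.diff(cum))) + 1
        assert 150 <= inflection_day <= 270

    def test_southern_profile_is_shifted_183_days(self):
        north = seasonal_profile("II", "N")
        south = seasonal_profile("II", "S")
        assert np.array_equal(south, np.roll(north, 183))

    def test_imposed_trend_matches_expected_counts(self):
        spec = SeriesSpec(years=10, shape=(6, 6), baseline=0.1, trend=0.02,
                          cluster="III", seed=8)
        series, truth = make_bloom_series(spec)
        means = [float((states == BLOOM).sum(axis=0).mean()) for _, _, states in series]
        # expected count rises by trend * profile.sum() = 0.02 * 365 per year
        slope = np.polyfit(np.arange(10), means, 1)[0]
        assert slope == pytest.approx(truth["expected_count_slope"], rel=0.1)
        assert truth["expected_count_slope"] == pytest.approx(0.02 * 365)


class TestSST:
    def test_uniform_field_has_zero_gradient_truth(self):
        _, data, _, truth = make_sst(pattern="uniform", years=1)
        assert (truth["gradient"] == 0).all()
        assert np.ptp(data[0]) == 0

    def test_planar_field_matches_imposed_slope(self):
        _, data, grid, truth = make_sst(pattern="planar", meridional_gradient=3e-5, years=1)
        dT = np.diff(data[0], axis=0).mean()
        d_m = np.diff(grid.lat).mean() * 111195.0
        assert dT / d_m == pytest.approx(3e-5)

    def test_front_gradient_peaks_at_centre(self):
        _, data, grid, truth = make_sst(
            pattern="front", front_amplitude=2.0, front_width_m=30_000.0,
            shape=(21, 5), years=1,
        )
        g = truth["gradient"]
        centre_row = g[:, 0].argmax()
        assert g[centre_row, 0] == pytest.approx(2.0 / 30_000.0, rel=1e-6)
        assert centre_row == pytest.approx(10, abs=1)


class TestEvents:
    def test_constructed_overlap_bookkeeping(self):
        spec = SeriesSpec(years=1, shape=(10, 10), baseline=0.05, cluster="III", seed=3)
        series, _ = make_bloom_series(spec)
        year, dates, states = series[0]
        grid = Grid.regular(40.0, -70.0, 10, 10, 0.05)
        events, truth = make_events(dates, states, grid, n_events=10,
                                    detect_fraction=0.8, radius=0.2, seed=5)
        assert len(events) == 10
        assert truth["detected"].sum() == 8
        assert truth["detect_fraction"] == pytest.approx(0.8)
        assert (events["start"] <= events["end"]).all()


class TestClusterFixture:
    def test_archetype_curves_are_cumulative_profiles(self):
        arch = archetype_curves()
        assert arch.shape == (3, 365)
        assert np.allclose(arch[:, -1], 1.0)
        assert (np.diff(arch, axis=1) >= 0).all()

    def test_fixture_labels_and_noise(self):
        curves, labels = make_cluster_fixture(10, noise_sd=0.05, seed=1)
        assert curves.shape == (30, 365)
        assert np.bincount(labels).tolist() == [10, 10, 10]
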