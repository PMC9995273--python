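"""Per-pixel spectral operations: chromaticity, FLH, indices, masking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bloommap import (
    BLOOM,
    DEFAULT_BOUNDARY,
    DEFAULT_CONSTANTS,
    INVALID,
    NO_BLOOM,
    Grid,
    QualityFlag,
    Scene,
    apply_quality_masks,
    chromaticity,
    chromaticity_xy,
    cloud_shadow_indices,
    detect_blooms,
    ergb,
    flh,
)
from bloommap.boundary import boundary_y


def _scene_from_spectrum(spectrum, shape=(3, 3), flags=0):
    grid = Grid.regular(0.0, 0.0, *shape, 0.01)
    bands = {wl: np.full(shape, v) for wl, v in spectrum.items()}
    return Scene(grid, bands, np.full(shape, flags, dtype=np.uint8))


FULL = {443: 0.01, 469: 0.011, 488: 0.012, 555: 0.013, 645: 0.008,
        667: 0.006, 678: 0.007, 748: 0.004, 869: 0.002}


class TestChromaticity:
    def test_equal_bands_map_to_white_point_exactly(self):
        p = chromaticity({667: 0.01, 678: 0.01, 748: 0.01})
        assert p.valid
        assert abs(p.x - 1 / 3) < 1e-15
        assert abs(p.y - 1 / 3) < 1e-15

    def test_pure_fluorescence_channel_matches_matrix_column(self):
        # only G = Rrc(678) nonzero: x and y are the column ratios
        p = chromaticity({667: 0.0, 678: 1.0, 748: 0.0})
        assert p.x == pytest.approx(1.7517 / 6.3989, abs=1e-12)
        assert p.y == pytest.approx(4.5907 / 6.3989, abs=1e-12)

    def test_negative_sum_is_invalid(self):
        p = chromaticity({667: -0.01, 678: -0.01, 748: -0.01})
        assert not p.valid

    def test_missing_band_raises(self):
        with pytest.raises(KeyError, match="missing"):
            chromaticity({667: 0.01, 678: 0.01})

    @settings(derandomize=True, max_examples=200)
    @given(
        r=st.floats(1e-6, 0.2),
        g=st.floats(1e-6, 0.2),
        b=st.floats(1e-6, 0.2),
        c=st.floats(0.01, 100.0),
    )
    def test_normalization_and_scale_invariance(self, r, g, b, c):
        x, y, valid = chromaticity_xy(r, g, b)
        assert valid
        assert x >= 0 and y >= 0 and x + y <= 1 + 1e-12
        xs, ys, _ = chromaticity_xy(c * r, c * g, c * b)
        assert np.isclose(x, xs, atol=1e-12) and np.isclose(y, ys, atol=1e-12)

    def test_y_strictly_increases_with_fluorescence_band(self):
        # over a grid of base red/NIR values, y is monotone in Rrc(678)
        for r667 in (0.002, 0.01, 0.03):
            for r748 in (0.001, 0.005, 0.02):
                g = np.linspace(0.001, 0.05, 50)
                _, y, valid = chromaticity_xy(np.full_like(g, r748), g, np.full_like(g, r667))
                assert valid.all()
                assert (np.diff(y) > 0).all()


class TestFLH:
    def test_hand_evaluated_peak_and_dip(self, unit_f_constants):
        assert flh({667: 0.01, 678: 0.02, 748: 0.01}, unit_f_constants) == pytest.approx(0.01)
        assert flh({667: 0.02, 678: 0.01, 748: 0.02}, unit_f_constants) == pytest.approx(-0.01)

    def test_baseline_collinear_spectrum_has_zero_flh(self):
        # radiance-scaled values linear in wavelength lie on their own baseline
        F = DEFAULT_CONSTANTS.F
        slope, intercept = 3e-5, 0.01
        spec = {wl: (intercept + slope * (wl - 667)) / F[wl] for wl in (667, 678, 748)}
        assert flh(spec, DEFAULT_CONSTANTS) == pytest.approx(0.0, abs=1e-15)

    def test_sign_tracks_position_relative_to_baseline(self, unit_f_constants):
        base = {667: 0.01, 748: 0.004}
        baseline_678 = 0.01 + (0.004 - 0.01) * 11 / 81
        above = {**base, 678: baseline_678 + 1e-4}
        below = {**base, 678: baseline_678 - 1e-4}
        assert flh(above, unit_f_constants) > 0 > flh(below, unit_f_constants)


class TestERGB:
    def test_channel_mapping_and_stretch(self):
        scene = _scene_from_spectrum(FULL)
        img = ergb(scene)
        assert img.shape == (3, 3, 3)
        # 555 -> R channel; brightening 555 never decreases R
        scene2 = scene.copy()
        scene2.bands[555] += 0.01
        assert (ergb(scene2)[..., 0] >= img[..., 0]).all()
        dark = _scene_from_spectrum({wl: 0.0 for wl in FULL})
        assert (ergb(dark) == 0).all()

    def test_single_bright_555_pixel_dominates_red(self):
        scene = _scene_from_spectrum({wl: 0.0 for wl in FULL})
        scene.bands[555][1, 1] = 0.05
        img = ergb(scene)
        assert img[1, 1, 0] > img[1, 1, 1] and img[1, 1, 0] > img[1, 1, 2]


class TestCloudShadowIndices:
    def test_flat_spectrum_gives_zero_indices(self):
        flat = {wl: 0.02 for wl in (443, 469, 488, 555, 645)}
        i1, i2 = cloud_shadow_indices(flat)
        assert i1 == pytest.approx(0.0, abs=1e-12)
        assert i2 == pytest.approx(0.0, abs=1e-12)  # < 0.012 -> removed as cloud

    def test_hand_evaluated_index2(self):
        spec = {443: 0.01, 469: 0.01, 488: 0.01, 555: 0.02, 645: 0.01}
        _, i2 = cloud_shadow_indices(spec)
        assert i2 == pytest.approx(1.0)  # retained

    def test_zero_reference_band_is_undefined(self):
        spec = {443: 0.01, 469: 0.0, 488: 0.0, 555: 0.02, 645: 0.01}
        i1, i2 = cloud_shadow_indices(spec)
        assert np.isnan(i1) and np.isnan(i2)


class TestQualityMasks:
    def test_rrc869_cloud_threshold(self):
        scene = _scene_from_spectrum({**FULL, 869: 0.03})
        assert not apply_quality_masks(scene).any()
        scene = _scene_from_spectrum({**FULL, 869: 0.01})
        assert apply_quality_masks(scene).all()

    @pytest.mark.parametrize("flag", list(QualityFlag))
    def test_any_quality_flag_invalidates(self, flag):
        scene = _scene_from_spectrum(FULL)
        scene.flags[0, 0] = int(flag)
        valid = apply_quality_masks(scene)
        assert not valid[0, 0] and valid[1:].all()

    def test_flat_bright_pixel_removed_as_cloud(self):
        flat = {wl: 0.02 for wl in FULL}
        flat[869] = 0.02  # below the 869 threshold, caught by index2
        assert not apply_quality_masks(_scene_from_spectrum(flat)).any()

    def test_masking_is_idempotent(self, coastal_scene):
        scene, _ = coastal_scene
        v1 = apply_quality_masks(scene)
        v2 = apply_quality_masks(scene)
        assert np.array_equal(v1, v2)

    def test_negative_conversion_band_invalidates(self):
        scene = _scene_from_spectrum({**FULL, 678: -0.006})
        assert not apply_quality_masks(scene).any()


class TestDetectBlooms:
    def test_point_above_left_quadratic_is_bloom(self):
        # (x, y) = (0.30, 0.60): y1(0.30) = 0.339797, well exceeded
        assert boundary_y(0.30, DEFAULT_BOUNDARY) == pytest.approx(0.339797, abs=1e-6)
        spec = _bloom_spectrum_at(0.30, 0.60)
        scene = _scene_from_spectrum({**FULL, **spec})
        assert (detect_blooms(scene).state == BLOOM).all()

    def test_white_point_is_no_bloom(self):
        spec = {667: 0.01, 678: 0.01, 748: 0.01}
        scene = _scene_from_spectrum({**FULL, **spec})
        assert (detect_blooms(scene).state == NO_BLOOM).all()

    def test_fully_flagged_scene_has_zero_blooms(self):
        scene = _scene_from_spectrum(FULL, flags=int(QualityFlag.CLOUD))
        mask = detect_blooms(scene)
        assert (mask.state == INVALID).all() and mask.n_bloom() == 0

    def test_bloom_classification_monotone_in_fluorescence(self):
        # once a pixel is a bloom, increasing Rrc(678) keeps it a bloom
        for r667, r748 in [(0.002, 0.001), (0.01, 0.005), (0.02, 0.008)]:
            was_bloom = False
            for g in np.linspace(0.001, 0.08, 120):
                x, y, valid = chromaticity_xy(r748, g, r667)
                is_bloom = bool(valid and y > boundary_y(x, DEFAULT_BOUNDARY))
                assert not (was_bloom and not is_bloom)
                was_bloom = is_bloom
            assert was_bloom  # strong enough fluorescence always ends as bloom


def _bloom_spectrum_at(x, y):
    """Invert the chromaticity conversion for a target (x, y) with B fixed."""
    from bloommap.spectral import CIE_MATRIX

    # choose tristimulus (X, Y, Z) = s*(x, y, 1-x-y), solve M @ rgb = XYZ
    s = 0.05
    xyz = np.array([x, y, 1 - x - y]) * s
    rgb = np.linalg.solve(CIE_MATRIX, xyz)
    assert (rgb > 0).all(), "target colour must be reachable with positive Rrc"
    return {748: rgb[0], 678: rgb[1], 667: rgb[2]}
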