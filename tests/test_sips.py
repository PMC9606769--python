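"""Statistical image properties: definitions, degenerate cases, properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from sipscape.sips import (
    EIGHT_MODEL_SIPS,
    POOL_GRIDS,
    SIP_NAMES,
    DegenerateImageError,
    FilterBank,
    FormatError,
    GridError,
    SIPConfig,
    _variances_from_maps,
    color_statistics,
    compute_sip_table,
    compute_sip_vector,
    default_filter_bank,
    edge_orientation_entropies,
    filter_response_maps,
    filter_variance_features,
    gradient_complexity,
    histogram_intersection,
    mirror_symmetry_lrud,
    phog_features,
)
from sipscape.stimuli import RandomPhaseSpec, synthesize_colored_random_phase


def _grating(size=64, period=8, vertical=True):
    yy, xx = np.mgrid[0:size, 0:size]
    t = xx if vertical else yy
    g = 0.5 + 0.4 * np.sin(2 * np.pi * t / period)
    return np.stack([g] * 3, axis=-1)


def _checkerboard(size=64, cell=4):
    yy, xx = np.mgrid[0:size, 0:size]
    g = ((yy // cell + xx // cell) % 2).astype(float) * 0.6 + 0.2
    return np.stack([g] * 3, axis=-1)


class TestComplexity:
    def test_constant_image_zero(self):
        assert gradient_complexity(np.full((64, 64, 3), 0.4)) == 0.0

    def test_fine_checkerboard_exceeds_coarse(self):
        fine = gradient_complexity(_checkerboard(cell=2))
        coarse = gradient_complexity(_checkerboard(cell=8))
        assert fine > coarse

    def test_matches_loop_oracle_on_step_edge(self):
        img = np.full((64, 64, 3), 0.3)
        img[:, 32:, 0] = 0.8  # single-channel vertical step
        assert gradient_complexity(img) == pytest.approx(
            oracles.complexity(img), abs=1e-9
        )


class TestPHOG:
    def test_grid_aligned_tiling_perfectly_self_similar(self):
        tile = np.random.default_rng(0).uniform(0.2, 0.8, (8, 8, 3))
        img = np.tile(tile, (8, 8, 1))  # 64×64, tiles in register with level 3
        res = phog_features(img)
        assert res["self_similarity"] == pytest.approx(1.0, abs=1e-9)

    def test_grating_maximally_anisotropic(self, random_phase_64):
        iso = phog_features(random_phase_64)["anisotropy"]
        grating = phog_features(_grating())["anisotropy"]
        assert grating > 0.9
        assert grating > iso

    def test_outputs_bounded(self, collage_64):
        res = phog_features(collage_64)
        for v in res.values():
            assert 0.0 <= v <= 1.0

    def test_zero_gradient_raises(self):
        with pytest.raises(DegenerateImageError):
            phog_features(np.full((64, 64, 3), 0.7))


class TestEdgeEntropies:
    def test_single_orientation_grating_first_order_near_zero(self):
        res = edge_orientation_entropies(_grating(), SIPConfig(resolution=64))
        assert res["entropy_first_order"] < 0.05

    def test_isotropic_image_near_maximal(self):
        vals = [
            edge_orientation_entropies(
                synthesize_colored_random_phase(RandomPhaseSpec(128, -1.0, s)),
                SIPConfig(resolution=128),
            )["entropy_first_order"]
            for s in range(5)
        ]
        assert np.mean(vals) > 0.95

    def test_subsampled_matches_exhaustive(self, small_config):
        """Pair subsampling approximates the full enumeration closely."""
        img = synthesize_colored_random_phase(RandomPhaseSpec(64, -2.0, 21))
        import dataclasses

        full = edge_orientation_entropies(
            img, dataclasses.replace(small_config, max_pairs=2_000_000)
        )
        sub = edge_orientation_entropies(
            img, dataclasses.replace(small_config, max_pairs=20_000)
        )
        assert abs(full["entropy_second_order"] - sub["entropy_second_order"]) < 0.02

    def test_entropies_bounded(self, collage_64, small_config):
        res = edge_orientation_entropies(collage_64, small_config)
        assert 0.0 <= res["entropy_first_order"] <= 1.0
        assert 0.0 <= res["entropy_second_order"] <= 1.0


class TestFilterVariances:
    def test_default_bank_valid(self):
        bank = default_filter_bank()
        assert len(bank) == 50
        for k in bank.kernels:
            assert abs(k.sum()) < 1e-8
            assert np.sum(k**2) == pytest.approx(1.0, rel=1e-6)

    def test_constant_image_zero(self):
        res = filter_variance_features(np.full((64, 64, 3), 0.6), k=2)
        assert res["variance_Pa"] == pytest.approx(0.0, abs=1e-20)
        assert res["variance_Pf"] == pytest.approx(0.0, abs=1e-20)

    def test_hand_unrolled_toy(self):
        """16×16 image, two hand-written kernels, k=2, vs explicit arithmetic."""
        rng = np.random.default_rng(1)
        img = rng.uniform(size=(16, 16, 3))
        k1 = np.array([[1.0, -1.0]])
        k2 = np.array([[1.0], [-1.0]])
        bank = FilterBank(
            tuple(k / np.sqrt(2) for k in (k1, k2)),
            ({"channel": "lum"}, {"channel": "lum"}),
        )
        got = filter_variance_features(img, bank, k=2)
        exp = oracles.filter_variances(img, bank, 2)
        assert got["variance_Pa"] == pytest.approx(exp["variance_Pa"], abs=1e-12)
        assert got["variance_Pf"] == pytest.approx(exp["variance_Pf"], abs=1e-12)

    def test_pa2_pa4_rank_correlation(self):
        """Coarse- and fine-grid total variances rank images consistently."""
        from scipy.stats import spearmanr

        pa2, pa4 = [], []
        for s in range(30):
            img = synthesize_colored_random_phase(
                RandomPhaseSpec(64, -5.0 + (s % 6), s)
            )
            maps = filter_response_maps(img)
            pa2.append(_variances_from_maps(maps, 2)["variance_Pa"])
            pa4.append(_variances_from_maps(maps, 4)["variance_Pa"])
        assert spearmanr(pa2, pa4).statistic > 0.7

    def test_grid_error(self, random_phase_64):
        with pytest.raises(GridError):
            filter_variance_features(random_phase_64, k=3)


class TestColorStatistics:
    def test_neutral_gray(self):
        res = color_statistics(np.full((32, 32, 3), 0.5))
        assert abs(res["lab_a_mean"]) < 0.01 and abs(res["lab_b_mean"]) < 0.01
        assert res["hsv_S_mean"] == 0.0
        assert res["entropy_hsv_S"] == 0.0

    def test_solid_red(self):
        img = np.zeros((32, 32, 3))
        img[..., 0] = 1.0
        res = color_statistics(img)
        assert res["hsv_S_mean"] == 1.0
        assert res["entropy_hsv_H"] == 0.0

    def test_two_tone_blue_yellow_one_bit(self):
        img = np.zeros((32, 32, 3))
        img[:16] = [1.0, 1.0, 0.0]  # yellow
        img[16:] = [0.0, 0.0, 1.0]  # blue
        assert color_statistics(img)["entropy_hsv_H"] == pytest.approx(1.0, abs=1e-12)

    def test_hue_mean_circular(self):
        # hues at 350° and 10° average to 0°, not 180°
        from skimage.color import hsv2rgb

        img = np.zeros((32, 32, 3))
        img[:16] = hsv2rgb(np.array([[[350 / 360, 1.0, 1.0]]]))[0, 0]
        img[16:] = hsv2rgb(np.array([[[10 / 360, 1.0, 1.0]]]))[0, 0]
        mean = color_statistics(img)["hsv_H_mean"]
        assert min(mean, 360 - mean) < 1.0


class TestSymmetry:
    def test_mirror_symmetric_image(self, collage_64):
        left = collage_64[:, :32]
        img = np.concatenate([left, left[:, ::-1]], axis=1)
        res = mirror_symmetry_lrud(img)
        assert res["left_right"] == pytest.approx(1.0, abs=1e-12)

    def test_rotation_swaps_components(self, gradient_image_64):
        # needs an image with no gradient orientation exactly on a bin
        # boundary (flat patches yield exact 0°/45°/90° ties that bin
        # differently after rotation)
        res = mirror_symmetry_lrud(gradient_image_64)
        rot = mirror_symmetry_lrud(np.rot90(gradient_image_64))
        assert rot["up_down"] == pytest.approx(res["left_right"], abs=1e-9)

    def test_constant_image_raises(self):
        with pytest.raises(DegenerateImageError):
            mirror_symmetry_lrud(np.full((64, 64, 3), 0.2))


class TestSIPVector:
    def test_constant_image_degenerate_values(self):
        v = compute_sip_vector(np.full((64, 64, 3), 0.5), SIPConfig(resolution=64))
        assert v["complexity"] == 0.0
        assert v["entropy_hsv_S"] == 0.0
        assert v["hsv_S_mean"] == 0.0
        assert abs(v["lab_b_mean"]) < 0.01
        for k in POOL_GRIDS:
            assert v[f"variance_Pa_{k}"] == pytest.approx(0.0, abs=1e-20)
            assert v[f"variance_Pf_{k}"] == pytest.approx(0.0, abs=1e-20)

    def test_recovers_set_slope(self):
        img = synthesize_colored_random_phase(RandomPhaseSpec(128, -2.0, 13))
        v = compute_sip_vector(img, SIPConfig(resolution=128, n_edges=500))
        assert v["fourier_slope"] == pytest.approx(-2.0, abs=0.3)

    def test_resized_copy_identical(self, collage_64, small_config):
        """Fixed internal resolution makes stored size irrelevant."""
        upscaled = np.repeat(np.repeat(collage_64, 2, axis=0), 2, axis=1)
        a = compute_sip_vector(collage_64, small_config)
        b = compute_sip_vector(upscaled, small_config)
        for name in SIP_NAMES:
            assert a[name] == pytest.approx(b[name], abs=1e-9), name

    def test_column_order_and_model_subset(self, random_phase_64, small_config):
        v = compute_sip_vector(random_phase_64, small_config)
        assert tuple(v) == SIP_NAMES
        assert set(EIGHT_MODEL_SIPS) <= set(v)

    def test_grayscale_rejected_unless_allowed(self):
        gray = np.random.default_rng(0).uniform(size=(64, 64))
        with pytest.raises(FormatError):
            compute_sip_vector(gray, SIPConfig(resolution=64))
        v = compute_sip_vector(
            gray, SIPConfig(resolution=64, allow_grayscale=True, n_edges=300)
        )
        assert v["hsv_S_mean"] == 0.0

    def test_too_small_rejected(self):
        with pytest.raises(FormatError):
            compute_sip_vector(np.zeros((32, 32, 3)), SIPConfig(resolution=64))

    def test_table_categories(self, random_phase_64, collage_64, small_config):
        table = compute_sip_table(
            {"a": random_phase_64, "b": collage_64},
            small_config,
            {"a": "random_phase", "b": "style_transferred"},
        )
        assert list(table.index) == ["a", "b"]
        assert list(table["category"]) == ["random_phase", "style_transferred"]
        with pytest.raises(ValueError):
            compute_sip_table({"a": collage_64}, small_config, "no_such_category")


class TestHistogramIntersection:
    @given(
        st.lists(st.floats(0, 1e3, allow_nan=False), min_size=2, max_size=16),
        st.lists(st.floats(0, 1e3, allow_nan=False), min_size=2, max_size=16),
    )
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_symmetric(self, a, b):
        m = min(len(a), len(b))
        h = np.asarray(a[:m])
        g = np.asarray(b[:m])
        h = h / h.sum() if h.sum() > 0 else h
        g = g / g.sum() if g.sum() > 0 else g
        s = histogram_intersection(h, g)
        assert 0.0 <= s <= 1.0 + 1e-12
        assert s == pytest.approx(histogram_intersection(g, h))
        assert histogram_intersection(h, h) == pytest.approx(min(h.sum(), 1.0))
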