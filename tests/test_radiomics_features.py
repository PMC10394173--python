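"""Resampling, quantization, 3D GLCM, wavelets, first-order/shape features."""

import numpy as np
import pytest
import pywt

from tlskit import (
    MaskedVolume,
    PhantomConfig,
    RadiomicsConfig,
    basic_features,
    extract_feature_vector,
    glcm_compute,
    glcm_features,
    quantize,
    resample,
    simulate_ct_phantom,
    wavelet_subbands,
)
from tlskit.radiomics import DIRECTIONS_3D, GLCM


def brute_force_glcm(levels, mask, n_levels, distance=1):
    """Independent pair-counting over every voxel and the 13 offsets."""
    counts = np.zeros((n_levels, n_levels))
    dims = levels.shape
    for d in DIRECTIONS_3D:
        off = tuple(c * distance for c in d)
        for x in range(dims[0]):
            for y in range(dims[1]):
                for z in range(dims[2]):
                    if not mask[x, y, z]:
                        continue
                    x2, y2, z2 = x + off[0], y + off[1], z + off[2]
                    if not (0 <= x2 < dims[0] and 0 <= y2 < dims[1] and 0 <= z2 < dims[2]):
                        continue
                    if not mask[x2, y2, z2]:
                        continue
                    a, b = levels[x, y, z] - 1, levels[x2, y2, z2] - 1
                    counts[a, b] += 1
                    counts[b, a] += 1
    return counts / counts.sum()


def brute_force_entropies(P):
    """Naive loop evaluation of Entrop, sumEnt, InfCo1."""
    ng = P.shape[0]
    ent = 0.0
    for i in range(ng):
        for j in range(ng):
            if P[i, j] > 0:
                ent -= P[i, j] * np.log2(P[i, j])
    psum = {}
    for i in range(ng):
        for j in range(ng):
            psum[i + j + 2] = psum.get(i + j + 2, 0.0) + P[i, j]
    sument = -sum(v * np.log2(v) for v in psum.values() if v > 0)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    hx = -sum(p * np.log2(p) for p in px if p > 0)
    hy = -sum(p * np.log2(p) for p in py if p > 0)
    hxy1 = 0.0
    for i in range(ng):
        for j in range(ng):
            if P[i, j] > 0 and px[i] * py[j] > 0:
                hxy1 -= P[i, j] * np.log2(px[i] * py[j])
    infco1 = (ent - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    return ent, sument, infco1


class TestResample:
    def test_identity_at_target_spacing(self, rng):
        vol = MaskedVolume(rng.normal(size=(10, 10, 6)),
                           np.ones((10, 10, 6), bool), (1.0, 1.0, 3.0))
        out = resample(vol, (1.0, 1.0, 3.0))
        assert np.array_equal(out.intensities, vol.intensities)

    def test_dimension_arithmetic(self, rng):
        vol = MaskedVolume(rng.normal(size=(100, 100, 30)),
                           np.ones((100, 100, 30), bool), (0.7, 0.7, 5.0))
        out = resample(vol, (1.0, 1.0, 3.0))
        assert out.intensities.shape == (70, 70, 50)
        assert out.spacing == (1.0, 1.0, 3.0)

    def test_constant_volume_stays_constant(self):
        vol = MaskedVolume(np.full((20, 20, 10), 7.0),
                           np.ones((20, 20, 10), bool), (0.5, 0.5, 2.0))
        out = resample(vol)
        assert np.allclose(out.intensities, 7.0)
        assert out.mask.all()

    def test_mask_stays_binary(self):
        mask = np.zeros((20, 20, 10), bool)
        mask[5:15, 5:15, 3:7] = True
        vol = MaskedVolume(np.zeros((20, 20, 10)), mask, (0.5, 0.5, 2.0))
        out = resample(vol)
        assert out.mask.dtype == bool and out.mask.any()


class TestQuantize:
    def test_constant_region_single_level(self):
        levels, ng = quantize(np.full((4, 4, 4), 30.0), np.ones((4, 4, 4), bool))
        assert ng == 1 and np.all(levels == 1)

    def test_floor_arithmetic_by_hand(self):
        vals = np.array([-10.0, 0.0, 24.0, 25.0, 49.0, 50.0]).reshape(6, 1, 1)
        levels, ng = quantize(vals, np.ones((6, 1, 1), bool), 25.0)
        assert list(levels.ravel()) == [1, 1, 2, 2, 3, 3]
        assert ng == 3

    def test_hu_shift_invariance(self, rng):
        vals = rng.normal(0, 60, (6, 6, 4))
        mask = rng.random((6, 6, 4)) > 0.3
        a, _ = quantize(vals, mask)
        b, _ = quantize(vals + 100.0, mask)
        assert np.array_equal(a, b)

    def test_out_of_mask_voxels_zero(self, rng):
        vals = rng.normal(size=(5, 5, 5))
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        levels, ng = quantize(vals, mask)
        assert levels[~mask].max() == 0 and levels[2, 2, 2] == 1

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            quantize(np.zeros((3, 3, 3)), np.zeros((3, 3, 3), bool))


class TestGlcm:
    def test_single_level(self):
        levels = np.ones((3, 3, 3), dtype=np.int64)
        g = glcm_compute(levels, np.ones((3, 3, 3), bool))
        assert g.P.shape == (1, 1) and g.P[0, 0] == 1.0

    def test_strip_pair_counting(self):
        levels = np.array([1, 2, 1, 2]).reshape(1, 4, 1)
        g = glcm_compute(levels, np.ones((1, 4, 1), bool), directions=((0, 1, 0),))
        assert g.P[0, 1] == pytest.approx(0.5)
        assert g.P[1, 0] == pytest.approx(0.5)
        assert g.P[0, 0] == 0.0 and g.P[1, 1] == 0.0

    def test_normalization_and_symmetry(self, rng):
        levels = rng.integers(1, 5, (6, 6, 4))
        mask = rng.random((6, 6, 4)) > 0.2
        g = glcm_compute(levels, mask, n_levels=4)
        assert g.P.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(g.P, g.P.T)

    def test_matches_brute_force(self, rng):
        levels = rng.integers(1, 4, (5, 5, 3))
        mask = rng.random((5, 5, 3)) > 0.25
        g = glcm_compute(levels, mask, n_levels=3)
        ref = brute_force_glcm(levels, mask, 3)
        assert np.max(np.abs(g.P - ref)) < 1e-12

    def test_single_voxel_mask_error(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        with pytest.raises(ValueError, match="pairs"):
            glcm_compute(np.ones((3, 3, 3), dtype=np.int64), mask)


class TestGlcmFeatures:
    def test_degenerate_single_cell(self):
        f = glcm_features(GLCM(P=np.ones((1, 1)), n_levels=1))
        assert f["Entrop"] == 0.0 and f["sumEnt"] == 0.0 and f["InfCo1"] == 0.0

    def test_strip_closed_form(self):
        P = np.array([[0.0, 0.5], [0.5, 0.0]])
        f = glcm_features(GLCM(P=P, n_levels=2))
        assert f["Entrop"] == pytest.approx(1.0)   # two equiprobable cells
        assert f["sumEnt"] == pytest.approx(0.0)   # all mass at i+j=3

    def test_matches_brute_force_oracle(self, rng):
        P = rng.random((6, 6))
        P = P + P.T
        P /= P.sum()
        f = glcm_features(GLCM(P=P, n_levels=6))
        ent, sument, infco1 = brute_force_entropies(P)
        assert f["Entrop"] == pytest.approx(ent, abs=1e-10)
        assert f["sumEnt"] == pytest.approx(sument, abs=1e-10)
        assert f["InfCo1"] == pytest.approx(infco1, abs=1e-10)

    def test_entropy_bounds(self, rng):
        for _ in range(10):
            P = rng.random((4, 4))
            P = P + P.T
            P /= P.sum()
            f = glcm_features(GLCM(P=P, n_levels=4))
            assert 0 <= f["Entrop"] <= np.log2(16)
            assert f["sumEnt"] >= 0 and f["DiffEnt"] >= 0


class TestWavelets:
    def test_naming_contract(self, rng):
        bands = wavelet_subbands(rng.normal(size=(8, 8, 8)))
        assert sorted(bands) == sorted(
            ["LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH"]
        )
        assert all(b.shape == (8, 8, 8) for b in bands.values())

    def test_constant_volume_zero_detail(self):
        bands = wavelet_subbands(np.full((8, 8, 8), 5.0))
        for name, band in bands.items():
            if name != "LLL":
                assert np.max(np.abs(band)) < 1e-8
        assert np.allclose(bands["LLL"], bands["LLL"].ravel()[0])

    def test_perfect_reconstruction(self, rng):
        data = rng.normal(size=(32, 32, 32))
        bands = wavelet_subbands(data, "coif1")
        coeffs = [{k.replace("L", "a").replace("H", "d"): v for k, v in bands.items()}]
        rec = pywt.iswtn(coeffs, "coif1")
        assert np.max(np.abs(rec - data)) < 1e-8

    def test_odd_dimension_padding(self, rng):
        data = rng.normal(size=(9, 8, 7))
        bands = wavelet_subbands(data)
        assert all(b.shape == (9, 8, 7) for b in bands.values())

    def test_too_small_dimension_rejected(self, rng):
        with pytest.raises(ValueError, match="filter length"):
            wavelet_subbands(rng.normal(size=(4, 8, 8)), "coif1")


class TestBasicFeatures:
    def test_constant_region_closed_form(self):
        mask = np.ones((5, 5, 4), bool)
        vol = MaskedVolume(np.full((5, 5, 4), 3.0), mask, (1.0, 1.0, 1.0))
        f = basic_features(vol)["first_order"]
        assert f["sd"] == 0.0 and f["entropy"] == 0.0
        assert f["energy"] == pytest.approx(100 * 9.0)

    def test_digital_ball_sphericity(self):
        r = 10
        n = 2 * r + 3
        c = (n - 1) / 2
        idx = np.indices((n, n, n))
        mask = ((idx - c) ** 2).sum(axis=0) <= r**2
        vol = MaskedVolume(np.zeros((n, n, n)), mask, (1.0, 1.0, 1.0))
        f = basic_features(vol)["shape"]
        assert 0.9 <= f["sphericity"] <= 1.0
        assert f["max_diameter_mm"] == pytest.approx(2 * r, rel=0.1)

    def test_spacing_scales_volume(self, rng):
        mask = rng.random((8, 8, 8)) > 0.5
        mask[3, 3, 3] = True
        a = basic_features(MaskedVolume(np.zeros((8, 8, 8)), mask, (1, 1, 1)))["shape"]
        b = basic_features(MaskedVolume(np.zeros((8, 8, 8)), mask, (2, 2, 2)))["shape"]
        assert b["volume_mm3"] == pytest.approx(8 * a["volume_mm3"])

    def test_single_voxel_mask_degenerate(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[1, 1, 1] = True
        with pytest.warns(UserWarning, match="degenerate"):
            f = basic_features(MaskedVolume(np.zeros((4, 4, 4)), mask, (1, 1, 1)))
        assert np.isnan(f["shape"]["sphericity"])


class TestExtraction:
    def test_constant_phantom_zero_entropy(self):
        cfg = PhantomConfig(texture_sd_high=0.0, texture_sd_low=0.0, seed=0)
        vol = simulate_ct_phantom(cfg, 1)
        fv = extract_feature_vector(vol)
        assert fv["GLCM_Entrop_25HUgl"] == 0.0

    def test_model_features_always_present(self):
        vol = simulate_ct_phantom(PhantomConfig(seed=1), 0)
        fv = extract_feature_vector(vol)
        for name in ("GLCM_Entrop_25HUgl", "GLCM_InfCo1_HHL_25HUgl", "GLCM_sumEnt_HLL_25HUgl"):
            assert name in fv.index and np.isfinite(fv[name])

    def test_deterministic(self):
        vol = simulate_ct_phantom(PhantomConfig(seed=2), 1)
        a = extract_feature_vector(vol)
        b = extract_feature_vector(vol)
        assert a.equals(b)

    def test_pipeline_equals_manual_composition(self):
        """The driver matches stage-by-stage composition on the same volume."""
        vol = simulate_ct_phantom(PhantomConfig(seed=3), 1)
        cfg = RadiomicsConfig()
        fv = extract_feature_vector(vol, cfg)
        work = resample(vol, cfg.target_spacing)
        levels, ng = quantize(work.intensities, work.mask, cfg.bin_width)
        g = glcm_compute(levels, work.mask, n_levels=ng)
        manual = glcm_features(g)
        assert fv["GLCM_Entrop_25HUgl"] == pytest.approx(manual["Entrop"], abs=1e-12)
        band = wavelet_subbands(work.intensities, cfg.wavelet)["HLL"]
        lv2, ng2 = quantize(band, work.mask, cfg.bin_width)
        manual2 = glcm_features(glcm_compute(lv2, work.mask, n_levels=ng2))
        assert fv["GLCM_sumEnt_HLL_25HUgl"] == pytest.approx(manual2["sumEnt"], abs=1e-12)

    def test_failure_names_stage(self, rng):
        # 4 slices is shorter than the coif1 filter: the wavelet stage fails
        vol = MaskedVolume(rng.normal(size=(8, 8, 4)),
                           np.ones((8, 8, 4), bool), (1.0, 1.0, 3.0))
        with pytest.raises(RuntimeError, match="stage 'wavelet'"):
            extract_feature_vector(vol, RadiomicsConfig(resample_first=False))

    def test_direction_average_mode(self):
        vol = simulate_ct_phantom(PhantomConfig(seed=4), 0)
        fv = extract_feature_vector(
            vol, RadiomicsConfig(direction_aggregation="average")
        )
        assert np.isfinite(fv["GLCM_Entrop_25HUgl"])
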