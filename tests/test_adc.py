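"""ADC computation, brain extraction, erosion and standardization."""

import numpy as np
import pytest
from scipy import ndimage

from adcsurv.adc import (
    AdcMap, BrainMask, DwiPair, GridMismatchError,
    compute_adc, erode_mask, extract_brain_mask, standardize_adc,
    load_dwi_pair, save_dwi_pair, save_adc_map, load_adc_map,
)
from adcsurv.synthetic import synthesize_dwi_pair

from conftest import head_phantom


def cube(shape, lo, hi):
    m = np.zeros(shape, dtype=bool)
    m[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return m


def min_filter_erode(mask, iterations):
    """Independent erosion oracle: brute-force 3x3x3 minimum filter."""
    out = mask.astype(bool)
    for _ in range(iterations):
        padded = np.pad(out, 1, constant_values=False)
        new = np.ones_like(out)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    new &= padded[1 + dx:1 + dx + out.shape[0],
                                  1 + dy:1 + dy + out.shape[1],
                                  1 + dz:1 + dz + out.shape[2]]
        out = new
    return out


class TestComputeAdc:
    def test_equal_signals_give_zero(self):
        vol = np.full((4, 4, 4), 500.0)
        adc = compute_adc(DwiPair(s0=vol, sb=vol.copy(), b=1000.0))
        assert np.all(adc.data == 0.0)
        assert adc.mask.data.all()

    def test_log_ratio_closed_form(self):
        s0 = np.full((4, 4, 4), 2718.2818)
        sb = np.full((4, 4, 4), 1000.0)
        adc = compute_adc(DwiPair(s0=s0, sb=sb, b=1000.0))
        assert adc.data == pytest.approx(1.0e-3, rel=1e-6)

    def test_nonphysical_voxel_zeroed_and_excluded(self):
        s0 = np.full((4, 4, 4), 1000.0)
        sb = np.full((4, 4, 4), 500.0)
        sb[1, 1, 1] = 1200.0  # Sb > S0: noise-dominated
        adc = compute_adc(DwiPair(s0=s0, sb=sb, b=1000.0))
        assert adc.data[1, 1, 1] == 0.0
        assert not adc.mask.data[1, 1, 1]
        assert adc.standardization["n_nonphysical_excluded"] == 1

    def test_grid_mismatch_rejected(self):
        with pytest.raises(GridMismatchError):
            DwiPair(s0=np.ones((4, 4, 4)), sb=np.ones((4, 4, 5)), b=1000.0)

    def test_nonpositive_b_rejected(self):
        with pytest.raises(ValueError):
            DwiPair(s0=np.ones((2, 2, 2)), sb=np.ones((2, 2, 2)), b=0.0)

    def test_roundtrip_with_synthesis_is_identity(self, rng):
        adc_true = rng.uniform(0.2e-3, 3.5e-3, (12, 12, 8))
        s0 = rng.uniform(500, 1500, (12, 12, 8))
        pair = synthesize_dwi_pair(adc_true, s0, b=1000.0, noise_sigma=0.0)
        adc = compute_adc(pair)
        rel = np.abs(adc.data - adc_true) / adc_true
        assert rel.max() <= 1e-12


class TestBrainExtraction:
    def test_zero_volume_is_empty_mask_error(self):
        with pytest.raises(ValueError, match="threshold"):
            extract_brain_mask(np.zeros((8, 8, 8)))

    def test_phantom_recovered_exactly(self):
        vol, member = head_phantom()
        mask = extract_brain_mask(vol, threshold_fraction=0.5)
        assert np.array_equal(mask.data, member)
        assert mask.provenance == "extracted"

    def test_largest_component_retained(self):
        vol = np.zeros((20, 20, 12))
        big = cube(vol.shape, (2, 2, 2), (12, 12, 9))
        small = cube(vol.shape, (15, 15, 2), (18, 18, 5))
        vol[big] = 1000.0
        vol[small] = 1000.0
        mask = extract_brain_mask(vol, threshold_fraction=0.5)
        assert np.array_equal(mask.data, big)

    def test_interior_holes_filled(self):
        vol = np.zeros((16, 16, 12))
        solid = cube(vol.shape, (2, 2, 2), (13, 13, 10))
        vol[solid] = 1000.0
        vol[7, 7, 5] = 0.0  # interior cavity
        mask = extract_brain_mask(vol, threshold_fraction=0.5)
        assert mask.data[7, 7, 5]


class TestErosion:
    def test_cube_shrinks_by_one_voxel_per_face(self):
        m = BrainMask(cube((9, 9, 9), (2, 2, 2), (7, 7, 7)))  # 5x5x5 cube
        eroded = erode_mask(m, 1)
        assert eroded.n_voxels == 27
        assert np.array_equal(eroded.data, cube((9, 9, 9), (3, 3, 3), (6, 6, 6)))

    def test_single_voxel_erodes_to_empty(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[2, 2, 2] = True
        assert erode_mask(BrainMask(m), 1).n_voxels == 0

    def test_triple_erosion_equals_composition(self, rng):
        m = BrainMask(rng.random((14, 14, 10)) > 0.35)
        once = erode_mask(erode_mask(erode_mask(m, 1), 1), 1)
        assert np.array_equal(erode_mask(m, 3).data, once.data)

    def test_zero_iterations_is_identity(self, rng):
        m = BrainMask(rng.random((8, 8, 8)) > 0.5)
        assert erode_mask(m, 0) is m

    @pytest.mark.parametrize("iterations", [1, 2, 3])
    def test_matches_independent_min_filter_oracle(self, rng, iterations):
        shapes = [cube((15, 15, 11), (3, 3, 2), (12, 12, 9))]
        # sphere
        g = np.ogrid[0:15, 0:15, 0:11]
        shapes.append(((g[0] - 7) ** 2 + (g[1] - 7) ** 2 + (g[2] - 5) ** 2) <= 25)
        shapes.append(rng.random((15, 15, 11)) > 0.3)
        for m in shapes:
            got = erode_mask(BrainMask(m), iterations).data
            want = min_filter_erode(m, iterations)
            assert np.array_equal(got, want)

    def test_anti_extensive_and_decreasing(self, rng):
        m = BrainMask(rng.random((12, 12, 8)) > 0.3)
        prev = m
        for k in range(1, 4):
            cur = erode_mask(m, k)
            assert cur.issubset(prev)
            prev = cur


class TestStandardize:
    def _map(self, data, mask=None):
        mask = BrainMask(np.ones(data.shape, bool) if mask is None else mask)
        return AdcMap(data=data, mask=mask)

    def test_physical_idempotent_when_in_range(self, rng):
        data = rng.uniform(0, 4e-3, (6, 6, 6))
        out = standardize_adc(self._map(data))
        assert np.array_equal(out.data, data)
        twice = standardize_adc(out)
        assert np.array_equal(twice.data, out.data)

    def test_clipping_recorded(self):
        data = np.full((6, 6, 6), 1e-3)
        data[0, 0, 0] = 9e-3
        out = standardize_adc(self._map(data))
        assert out.data[0, 0, 0] == 4e-3
        assert out.standardization["n_clipped_high"] == 1

    def test_nonfinite_voxels_dropped_from_mask(self):
        data = np.full((4, 4, 4), 1e-3)
        data[1, 2, 3] = np.nan
        out = standardize_adc(self._map(data))
        assert not out.mask.data[1, 2, 3]
        assert out.standardization["n_nonfinite_excluded"] == 1

    def test_reference_scale_halves_and_preserves_skewness(self, rng):
        from scipy import stats
        data = rng.gamma(3.0, 0.4e-3, (8, 8, 8))
        out = standardize_adc(self._map(data), method="reference-scale",
                              params={"reference": 2.0})
        assert np.allclose(out.data, data / 2.0)
        assert stats.skew(out.data.ravel()) == pytest.approx(
            stats.skew(data.ravel()), rel=1e-12)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            standardize_adc(self._map(np.ones((3, 3, 3))), method="zscore")


class TestNiftiRoundtrip:
    def test_dwi_pair_and_adc_map_roundtrip(self, tmp_path, rng):
        adc_true = rng.uniform(0.2e-3, 3e-3, (10, 10, 6)).astype(np.float32)
        s0 = rng.uniform(500, 1500, (10, 10, 6)).astype(np.float32)
        pair = synthesize_dwi_pair(adc_true.astype(float), s0.astype(float),
                                   b=1000.0, voxel_size=(2.0, 2.0, 4.0))
        save_dwi_pair(pair, tmp_path / "b0.nii.gz", tmp_path / "b1000.nii.gz")
        loaded = load_dwi_pair(tmp_path / "b0.nii.gz", tmp_path / "b1000.nii.gz",
                               b=1000.0)
        assert loaded.voxel_size == (2.0, 2.0, 4.0)
        assert np.allclose(loaded.s0, pair.s0, rtol=1e-6)

        amap = compute_adc(loaded)
        save_adc_map(amap, tmp_path / "adc.nii.gz")
        back = load_adc_map(tmp_path / "adc.nii.gz")
        assert np.allclose(back.data, amap.data, atol=1e-9)
        assert np.array_equal(back.mask.data, amap.mask.data)
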