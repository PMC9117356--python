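"""First-order statistics, quantization, 3D co-occurrence and the registry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import adctex as at
from adctex.texture import (
    FEATURE_REGISTRY,
    HARALICK_NAMES,
    OFFSETS_3D_13,
    GlcmSpec,
    first_order_stats,
    glcm_3d,
    glcm_features,
    haralick_features,
    quantize,
    roi_volume,
)
from oracles import brute_force_glcm, textbook_haralick


class TestFirstOrder:
    def test_constant_input_degenerates(self):
        with pytest.warns(UserWarning, match="zero variance"):
            out = first_order_stats(np.full(10, 2.5))
        assert out["mean"] == 2.5 and out["p5"] == 2.5
        assert np.isnan(out["skewness"]) and np.isnan(out["kurtosis"])

    def test_symmetric_values(self):
        out = first_order_stats(np.array([1, 2, 3, 4, 5], float))
        assert out["mean"] == 3.0
        assert out["skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_standard_normal_moments(self, rng):
        x = rng.standard_normal(100_000)
        out = first_order_stats(x)
        assert out["skewness"] == pytest.approx(0.0, abs=0.05)
        assert out["kurtosis"] == pytest.approx(0.0, abs=0.1)
        assert out["p5"] == pytest.approx(-1.6449, abs=0.03)

    def test_p5_is_linear_interpolation(self):
        assert first_order_stats(np.arange(101, dtype=float))["p5"] == 5.0


class TestRoiVolume:
    def test_unit_conversion(self):
        mask = np.zeros((10, 10, 10), bool)
        mask.ravel()[:1000] = True
        assert roi_volume(mask, (1, 1, 1)) == pytest.approx(1.0)

    def test_empty_mask_is_zero(self):
        assert roi_volume(np.zeros((4, 4, 4), bool), (1, 2, 3)) == 0.0

    def test_sphere_volume_close_to_analytic(self):
        n = 31
        x, y, z = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        mask = (x - 15) ** 2 + (y - 15) ** 2 + (z - 15) ** 2 <= 10**2
        assert roi_volume(mask, (1, 1, 1)) == pytest.approx(4.18879, rel=0.05)


class TestQuantize:
    def test_linear_rule_on_unit_range(self):
        vals = np.array([0.0, 0.2, 0.25, 0.5, 0.75, 0.999, 1.0])
        vol = vals.reshape(-1, 1, 1)
        mask = np.ones(vol.shape, bool)
        levels = quantize(vol, mask, GlcmSpec(n_levels=4))
        assert list(levels.ravel()) == [0, 0, 1, 2, 3, 3, 3]

    def test_two_level_median_split(self, rng):
        vol = rng.uniform(0, 1, size=(4, 4, 4))
        mask = np.ones(vol.shape, bool)
        levels = quantize(vol, mask, GlcmSpec(n_levels=2))
        assert set(np.unique(levels)) == {0, 1}
        assert np.array_equal(levels == 1, vol >= (vol.min() + vol.max()) / 2)

    def test_histogram_matches_brute_force_binning(self, rng):
        vol = rng.uniform(0.5, 2.0, size=(6, 6, 6))
        mask = rng.random(vol.shape) < 0.7
        spec = GlcmSpec(n_levels=8)
        levels = quantize(vol, mask, spec)
        lo, hi = vol[mask].min(), vol[mask].max()
        expected = np.zeros(8, int)
        for v in vol[mask]:
            b = min(int((v - lo) / (hi - lo) * 8), 7)
            expected[b] += 1
        got = np.bincount(levels[mask], minlength=8)
        assert np.array_equal(got, expected)
        assert (levels[~mask] == -1).all()

    def test_constant_roi_rejected(self):
        vol = np.ones((3, 3, 3))
        with pytest.raises(ValueError, match="degenerate quantization"):
            quantize(vol, np.ones(vol.shape, bool), GlcmSpec())


def checkerboard_matrices():
    """2x2x1 checkerboard, offset (1,0,0): p(0,1)=p(1,0)=0.5."""
    levels = np.array([[[0], [1]], [[1], [0]]])
    spec = GlcmSpec(n_levels=2, offsets=((1, 0, 0),))
    return glcm_3d(levels, spec), spec


class TestGlcm:
    def test_checkerboard_small_case(self):
        glcm, _ = checkerboard_matrices()
        p = glcm["p"][0]
        assert p[0, 1] == p[1, 0] == 0.5
        assert p[0, 0] == p[1, 1] == 0.0
        assert glcm["counts"].sum() == 4  # 2 pairs, both orders

    def test_constant_roi_single_occupied_level(self):
        levels = np.zeros((3, 3, 3), dtype=int)
        glcm = glcm_3d(levels, GlcmSpec(n_levels=2))
        for p, ok in zip(glcm["p"], glcm["valid"]):
            assert ok and p[0, 0] == 1.0

    def test_matrices_symmetric_and_normalized(self, rng):
        vol = rng.uniform(0, 1, (7, 7, 7))
        mask = rng.random(vol.shape) < 0.6
        spec = GlcmSpec(n_levels=6)
        glcm = glcm_3d(quantize(vol, mask, spec), spec)
        for p, ok in zip(glcm["p"], glcm["valid"]):
            if ok:
                assert abs(p.sum() - 1.0) < 1e-12
                assert np.allclose(p, p.T)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 10_000), st.integers(2, 6))
    def test_counts_match_exhaustive_pair_enumeration(self, seed, ng):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(2, 8, size=3))
        vol = rng.uniform(0, 1, shape)
        mask = rng.random(shape) < 0.75
        if mask.sum() < 2 or np.ptp(vol[mask]) == 0:
            return
        spec = GlcmSpec(n_levels=ng)
        levels = quantize(vol, mask, spec)
        glcm = glcm_3d(levels, spec)
        for k, off in enumerate(spec.offsets):
            oracle = brute_force_glcm(levels, off)
            got = glcm["counts"][k]
            assert np.array_equal(got[: oracle.shape[0], : oracle.shape[1]], oracle)
            assert got[oracle.shape[0]:, :].sum() == 0


class TestHaralick:
    def test_checkerboard_closed_forms(self):
        glcm, _ = checkerboard_matrices()
        f = haralick_features(glcm["p"][0])
        assert f["contrast"] == pytest.approx(1.0)
        assert f["entropy"] == pytest.approx(np.log(2))
        assert f["difference_entropy"] == pytest.approx(0.0, abs=1e-14)
        assert f["asm"] == pytest.approx(0.5)
        assert f["correlation"] == pytest.approx(-1.0)

    def test_constant_matrix_closed_forms(self):
        p = np.zeros((4, 4))
        p[2, 2] = 1.0
        f = haralick_features(p)
        assert f["contrast"] == 0.0
        assert f["entropy"] == pytest.approx(0.0, abs=1e-14)
        assert f["difference_entropy"] == pytest.approx(0.0, abs=1e-14)
        assert f["idm"] == pytest.approx(1.0)

    def test_all_13_match_textbook_implementation(self, rng):
        for _ in range(20):
            shape = tuple(rng.integers(3, 6, size=3))
            vol = rng.uniform(0, 1, shape)
            mask = rng.random(shape) < 0.8
            if mask.sum() < 4 or np.ptp(vol[mask]) == 0:
                continue
            spec = GlcmSpec(n_levels=int(rng.integers(2, 9)))
            glcm = glcm_3d(quantize(vol, mask, spec), spec)
            for p, ok in zip(glcm["p"], glcm["valid"]):
                if not ok:
                    continue
                mine = haralick_features(p)
                ref = textbook_haralick(p)
                for name in HARALICK_NAMES:
                    if np.isnan(ref[name]):
                        assert np.isnan(mine[name]), name
                    else:
                        assert mine[name] == pytest.approx(ref[name], abs=1e-10), name

    def test_direction_average_permutation_invariant(self, rng):
        vol = rng.uniform(0, 1, (6, 6, 6))
        mask = np.ones(vol.shape, bool)
        spec = GlcmSpec(n_levels=5)
        perm_spec = GlcmSpec(n_levels=5, offsets=tuple(reversed(OFFSETS_3D_13)))
        f1 = glcm_features(glcm_3d(quantize(vol, mask, spec), spec))
        f2 = glcm_features(glcm_3d(quantize(vol, mask, perm_spec), perm_spec))
        for name in HARALICK_NAMES:
            assert f1[name] == pytest.approx(f2[name], abs=1e-12)


class TestExtraction:
    def test_registry_has_exactly_thirty_named_features(self, default_phantom):
        adc, m = default_phantom
        fv = at.extract_features(adc, m)
        assert len(FEATURE_REGISTRY) == 30
        assert tuple(fv.values.keys()) == FEATURE_REGISTRY
        assert np.isfinite(fv.as_array()).all()

    def test_noiseless_phantom_closed_form_ratios(self, noiseless_phantom):
        (adc, m), cfg = noiseless_phantom
        fv = at.extract_features(adc, m)
        means = {k: v[0] for k, v in at.synthetic.DEFAULT_ADC.items()}
        gmwmc_mean = (
            means["gm"] * m.gm.sum() + means["wm"] * m.wm.sum()
        ) / (m.gm.sum() + m.wm.sum())
        assert fv.values["norm_mean_adc_ce"] == pytest.approx(
            means["ce"] / gmwmc_mean, rel=1e-12
        )
        assert fv.values["norm_mean_adc_t2pz"] == pytest.approx(
            means["t2pz"] / gmwmc_mean, rel=1e-12
        )
        assert fv.values["norm_mean_adc_gmwmc"] == pytest.approx(
            gmwmc_mean / means["csf"], rel=1e-12
        )
        assert fv.values["adc_slope"] == pytest.approx(0.0, abs=1e-12)
        # constant compartments leave shape/texture features missing
        assert np.isnan(fv.values["skewness_3d_t2pz"])
        assert "skewness_3d_t2pz" in fv.missing

    def test_scale_equivariance_of_the_whole_vector(self, default_phantom):
        adc, m = default_phantom
        fv1 = at.extract_features(adc, m)
        scaled = at.AdcVolume(adc.values * 2.0, adc.spacing)
        fv2 = at.extract_features(scaled, m)
        for name in FEATURE_REGISTRY:
            if name == "adc_slope":
                assert fv2.values[name] == pytest.approx(
                    2.0 * fv1.values[name], rel=1e-9
                )
            else:
                assert fv2.values[name] == pytest.approx(
                    fv1.values[name], abs=1e-10
                ), name
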