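"""Map stitching, attenuation normalization, ROI metrics, and statistics."""

import numpy as np
import pytest
from scipy import stats as sps

from conftest import exhaustive_permutation_pvalue

from harmotrack.mechanics import DisplacementField
from harmotrack.metrics import (
    BiasProfile,
    HMIMap,
    P2PPatch,
    ROISpec,
    attenuation_correct,
    friedman_dunn,
    lateral_bias_profile,
    quality_metrics,
    stitch_raster,
)
from harmotrack.motion import InterframeDisplacement


def const_patch(value, x0=0.0, z0=31.0, half_x=0.6, half_z=1.6, n=13, m=41):
    lines = np.linspace(x0 - half_x, x0 + half_x, n)
    depths = np.linspace(z0 - half_z, z0 + half_z, m)
    return P2PPatch(np.full((n, m), float(value)), lines, depths, (x0, z0))


class TestStitching:
    def test_single_patch_identity_on_footprint(self):
        hmi = stitch_raster([const_patch(3.0)])
        assert np.allclose(hmi.values[np.isfinite(hmi.values)], 3.0)

    def test_two_constant_patches_blend_to_constant(self):
        hmi = stitch_raster([const_patch(5.0, x0=0.0),
                             const_patch(5.0, x0=0.8)])
        vals = hmi.values[np.isfinite(hmi.values)]
        assert np.allclose(vals, 5.0)

    def test_weights_sum_to_one(self):
        # constant-1 patches must reproduce exactly 1 wherever covered
        patches = [const_patch(1.0, x0=dx, z0=31 + dz)
                   for dx in (0.0, 0.8) for dz in (0.0, 2.0)]
        hmi = stitch_raster(patches)
        vals = hmi.values[np.isfinite(hmi.values)]
        assert np.allclose(vals, 1.0, atol=1e-12)

    def test_nan_patch_values_excluded(self):
        p1 = const_patch(2.0)
        p2 = const_patch(4.0)
        p2.values[:, :] = np.nan
        hmi = stitch_raster([p1, p2])
        vals = hmi.values[np.isfinite(hmi.values)]
        assert np.allclose(vals, 2.0)

    def test_no_patches_rejected(self):
        with pytest.raises(ValueError):
            stitch_raster([])


class TestAttenuationCorrection:
    def _map_with_depth_decay(self, decay):
        x = np.arange(-3.0, 3.01, 0.1)
        z = np.arange(28.0, 34.01, 0.1)
        vals = np.ones((len(x), 1)) * decay(z)[None, :]
        return HMIMap(x, z, vals)

    def test_own_background_curve_gives_ones(self):
        hmi = self._map_with_depth_decay(lambda z: np.exp(-(z - 28) / 4))
        out = attenuation_correct(hmi)
        assert np.allclose(out.values, 1.0)
        assert out.normalized

    def test_known_exponential_decay_inverted(self):
        hmi = self._map_with_depth_decay(lambda z: 2.0 * np.exp(-(z - 28) / 5))
        out = attenuation_correct(hmi, background_region=(-3.0, -1.0))
        assert np.allclose(out.values, 1.0, rtol=0.02)

    def test_gaussian_fit_extrapolates_missing_depths(self):
        # the background region has no coverage at depth; the normalizing
        # curve there comes from a Gaussian fit of the shallow part
        x = np.arange(-3.0, 3.01, 0.1)
        z = np.arange(26.0, 36.01, 0.1)
        true = 3.0 * np.exp(-0.5 * ((z - 31.0) / 2.5) ** 2)
        vals = np.ones((len(x), 1)) * true[None, :]
        hmi = HMIMap(x, z, vals)
        hmi.values[x <= -1.0, :] = np.where(z[None, :] > 31.0, np.nan,
                                            hmi.values[x <= -1.0, :])
        out = attenuation_correct(hmi, background_region=(-3.0, -1.0))
        deep = z > 31.0
        inner = x > -1.0
        assert np.allclose(out.values[np.ix_(inner, ~deep)], 1.0, rtol=1e-9)
        assert np.allclose(out.values[np.ix_(inner, deep)], 1.0, rtol=0.05)

    def test_empty_background_rejected(self):
        hmi = self._map_with_depth_decay(lambda z: np.ones_like(z))
        with pytest.raises(ValueError):
            attenuation_correct(hmi, background_region=(10.0, 11.0))


def synthetic_map(mu_i=0.2, mu_b=1.0, jitter=0.0, seed=0):
    x = np.arange(-4.0, 4.01, 0.1)
    z = np.arange(27.0, 35.01, 0.1)
    r = np.hypot(x[:, None], z[None, :] - 31.0)
    vals = np.where(r <= 1.8, mu_i, mu_b).astype(float)
    if jitter:
        rng = np.random.default_rng(seed)
        vals = vals + jitter * rng.standard_normal(vals.shape)
    return HMIMap(x, z, vals, normalized=True)


class TestQualityMetrics:
    ROI = ROISpec.for_inclusion((0.0, 31.0), 3.6)

    def test_roi_geometry(self):
        assert self.ROI.disc_diameter == pytest.approx(0.8 * 3.6)
        assert self.ROI.ring_inner_diameter == pytest.approx(1.7 * 3.6)
        hmi = synthetic_map()
        disc, ring = self.ROI.masks(hmi)
        assert not np.any(disc & ring)
        # equal-area rule: matched pixel counts within 10%
        assert abs(disc.sum() - ring.sum()) <= 0.1 * disc.sum()

    def test_modulus_ratio_contrast(self):
        hmi = synthetic_map(mu_i=5.3 / 56.0)
        qm = quality_metrics(hmi, self.ROI)
        assert qm.contrast == pytest.approx(1 - 5.3 / 56.0, abs=1e-12)
        assert round(qm.contrast, 1) == 0.9

    def test_equal_regions_zero_contrast(self):
        # degenerate flat map: contrast 0, DR 1, CNR 0 (flagged degenerate)
        hmi = synthetic_map(mu_i=1.0)
        with pytest.warns(UserWarning, match="CNR"):
            qm = quality_metrics(hmi, self.ROI)
        assert qm.contrast == 0.0
        assert qm.cnr == 0.0
        assert qm.dr == 1.0

    def test_cnr_arithmetic(self):
        qm_map = synthetic_map(mu_i=0.4)
        # impose exact sigmas by alternating +/- around the medians
        disc, ring = self.ROI.masks(qm_map)
        rng = np.random.default_rng(1)
        for mask in (disc, ring):
            n = mask.sum()
            signs = np.resize([1.0, -1.0], n)
            qm_map.values[mask] += 0.1 * signs
        qm = quality_metrics(qm_map, self.ROI)
        # definitions hold exactly on the stored mu/sigma ...
        assert qm.cnr == pytest.approx(
            (qm.mu_b - qm.mu_i) / np.hypot(qm.sigma_b, qm.sigma_i))
        assert qm.contrast == pytest.approx((qm.mu_b - qm.mu_i) / qm.mu_b)
        # ... and match the constructed 0.6 / sqrt(0.02) case
        assert qm.cnr == pytest.approx(0.6 / np.sqrt(0.02), rel=0.25)

    def test_contrast_plus_dr_is_one_and_scale_invariance(self):
        hmi = synthetic_map(mu_i=0.3, jitter=0.02)
        qm1 = quality_metrics(hmi, self.ROI)
        assert qm1.contrast + qm1.dr == pytest.approx(1.0, abs=1e-12)
        scaled = HMIMap(hmi.x, hmi.z, 3.7 * hmi.values, normalized=True)
        qm2 = quality_metrics(scaled, self.ROI)
        for f in ("contrast", "cnr", "snr_background", "snr_inclusion", "dr"):
            assert getattr(qm2, f) == pytest.approx(getattr(qm1, f), rel=1e-9)

    def test_too_few_pixels_rejected(self):
        hmi = synthetic_map()
        hmi.values[:] = np.nan
        with pytest.raises(ValueError, match="pixels"):
            quality_metrics(hmi, self.ROI)




class TestFriedmanDunn:
    def test_identical_columns_no_effect(self):
        tbl = np.tile(np.arange(6)[:, None], (1, 3)).astype(float)
        rep = friedman_dunn(tbl)
        assert rep.statistic == 0.0
        assert rep.pvalue == 1.0
        assert rep.comparisons == []

    def test_dominant_column_detected_vs_permutation_oracle(self):
        rng = np.random.default_rng(4)
        tbl = rng.standard_normal((6, 3))
        tbl[:, 0] += 10.0  # uniformly dominant
        rep = friedman_dunn(tbl)
        assert rep.exact
        assert rep.pvalue < 0.05
        assert rep.best == 0
        assert any(c["significant"] for c in rep.comparisons)
        assert rep.pvalue == pytest.approx(exhaustive_permutation_pvalue(tbl),
                                           abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_exact_pvalue_matches_oracle_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        tbl = rng.standard_normal((5, 3))
        rep = friedman_dunn(tbl)
        assert rep.exact
        assert rep.pvalue == pytest.approx(exhaustive_permutation_pvalue(tbl),
                                           abs=1e-12)

    def test_statistic_matches_scipy_on_large_table(self):
        rng = np.random.default_rng(9)
        tbl = rng.standard_normal((20, 8))
        rep = friedman_dunn(tbl)
        ref = sps.friedmanchisquare(*tbl.T)
        assert rep.statistic == pytest.approx(ref.statistic, rel=1e-9)
        assert rep.pvalue == pytest.approx(ref.pvalue, rel=1e-9)

    def test_tied_rows_still_defined(self):
        tbl = np.array([[1.0, 1.0, 2.0]] * 6)
        rep = friedman_dunn(tbl)
        assert np.isfinite(rep.statistic)

    def test_fewer_than_three_sequences_rejected(self):
        with pytest.raises(ValueError):
            friedman_dunn(np.zeros((6, 2)))


class TestBiasProfile:
    def _truth(self, sigma=0.6):
        x = np.arange(-3.0, 3.01, 0.1)
        z = np.array([30.0, 31.0, 32.0])
        t = np.arange(5) * 500.0
        u = np.zeros((len(x), len(z), len(t)))
        prof = np.exp(-0.5 * (x / sigma) ** 2)
        for k in range(len(t)):
            u[:, :, k] = prof[:, None] * np.sin(0.8 * k)
        return DisplacementField(x, z, t, u)

    def _est_from_truth(self, truth, lines):
        du = np.diff(truth.u[:, 1, :], axis=1)
        vals = np.empty((du.shape[1], len(lines), 3))
        for p in range(du.shape[1]):
            interp = np.interp(lines, truth.x, du[:, p])
            vals[p] = np.tile(interp[:, None], (1, 3))
        return InterframeDisplacement(vals, 0.79, 0.95, 2000.0, lines,
                                      np.array([30.5, 31.0, 31.5]))

    def test_truth_against_itself_unity_ratio(self):
        truth = self._truth()
        lines = np.arange(-2.0, 2.01, 0.1)
        est = self._est_from_truth(truth, lines)
        bp = lateral_bias_profile(est, truth, 31.0)
        assert bp.width_ratio == pytest.approx(1.0, abs=0.02)
        assert bp.peak_est_um == pytest.approx(bp.peak_truth_um, rel=0.02)

    def test_widened_estimate_ratio_above_one(self):
        truth = self._truth(sigma=0.5)
        wide = self._truth(sigma=0.8)
        lines = np.arange(-2.0, 2.01, 0.1)
        est = self._est_from_truth(wide, lines)
        bp = lateral_bias_profile(est, truth, 31.0)
        assert bp.width_ratio > 1.3

    def test_profile_not_reaching_half_max_flagged(self):
        truth = self._truth()
        lines = np.arange(-0.2, 0.21, 0.1)  # too narrow to fall to half max
        est = self._est_from_truth(truth, lines)
        with pytest.warns(UserWarning, match="truncated"):
            bp = lateral_bias_profile(est, truth, 31.0)
        assert bp.est_width_truncated
        assert bp.width_est == pytest.approx(0.4, abs=1e-9)
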