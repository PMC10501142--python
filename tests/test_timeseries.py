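"""Signal cleaning and the R/S Hurst / seed-connectivity estimators."""

import numpy as np
import pytest
from scipy import stats

from neurocascade.timeseries import (
    ConfoundSet,
    RoiTimeSeries,
    bandpass_filter,
    default_window_sizes,
    expected_rs_anis_lloyd,
    hurst_map,
    hurst_rs,
    regress_confounds,
    seed_connectivity,
)

from conftest import fgn_batch


class TestConfoundRegression:
    def test_empty_confounds_remove_temporal_mean(self):
        rng = np.random.default_rng(0)
        ts = RoiTimeSeries(rng.normal(5.0, 1.0, (50, 3)))
        out = regress_confounds(ts, ConfoundSet.empty(50))
        np.testing.assert_allclose(out.data, ts.data - ts.data.mean(0), atol=1e-12)

    def test_unit_equal_to_confound_vanishes(self):
        rng = np.random.default_rng(1)
        c = rng.standard_normal(60)
        ts = RoiTimeSeries(np.column_stack([c, rng.standard_normal(60)]))
        out = regress_confounds(ts, ConfoundSet(c[:, None], ["motion_x"]))
        np.testing.assert_allclose(out.data[:, 0], 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_regressors(self):
        rng = np.random.default_rng(2)
        conf = rng.standard_normal((100, 3))
        signal = conf @ [1.0, -2.0, 0.5] + rng.standard_normal(100)
        ts = RoiTimeSeries(signal[:, None])
        out = regress_confounds(ts, ConfoundSet(conf))
        for j in range(3):
            assert abs(np.dot(out.data[:, 0], conf[:, j])) < 1e-8

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        conf = ConfoundSet(rng.standard_normal((80, 2)))
        ts = RoiTimeSeries(rng.standard_normal((80, 4)))
        once = regress_confounds(ts, conf)
        twice = regress_confounds(once, conf)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-10)

    def test_rank_deficient_design_names_columns(self):
        c = np.ones((40, 1))  # duplicates the intercept
        ts = RoiTimeSeries(np.random.default_rng(4).standard_normal((40, 2)))
        with pytest.raises(ValueError, match="collinear"):
            regress_confounds(ts, ConfoundSet(c, ["global_mean"]))


class TestBandpass:
    def test_in_band_sinusoid_passes_unchanged(self):
        t = np.arange(200) * 2.0  # TR = 2 s
        x = np.sin(2 * np.pi * 0.05 * t)  # exactly on a DFT bin (k=20)
        out = bandpass_filter(RoiTimeSeries(x, dt=2.0), 0.01, 0.10)
        np.testing.assert_allclose(out.data[:, 0], x, atol=1e-10)

    def test_out_of_band_sinusoid_rejected(self):
        t = np.arange(200) * 2.0
        x = np.sin(2 * np.pi * 0.2 * t)
        out = bandpass_filter(RoiTimeSeries(x, dt=2.0), 0.01, 0.10)
        assert np.max(np.abs(out.data)) < 1e-10

    def test_white_noise_variance_scales_with_band_width(self):
        # Parseval: retained variance fraction = (0.10-0.01)/0.25
        rng = np.random.default_rng(5)
        x = rng.standard_normal((4000, 8))
        out = bandpass_filter(RoiTimeSeries(x, dt=2.0), 0.01, 0.10)
        ratio = out.data.var() / x.var()
        assert ratio == pytest.approx(0.36, abs=0.02)

    def test_band_outside_nyquist_rejected(self):
        ts = RoiTimeSeries(np.random.default_rng(6).standard_normal((64, 1)), dt=2.0)
        with pytest.raises(ValueError):
            bandpass_filter(ts, 0.01, 0.30)
        with pytest.raises(ValueError):
            bandpass_filter(ts, 0.2, 0.1)


class TestHurstRs:
    def test_affine_invariance(self):
        x = fgn_batch(0.7, 1024, 1, seed=10)[0]
        h1 = hurst_rs(x, [8, 16, 32, 64, 128]).H
        h2 = hurst_rs(3.5 * x + 11.0, [8, 16, 32, 64, 128]).H
        assert h1 == pytest.approx(h2, abs=1e-10)

    def test_white_noise_calibration(self):
        rng = np.random.default_rng(11)
        hs = [
            hurst_rs(rng.standard_normal(1024), [8, 16, 32, 64, 128]).H
            for _ in range(100)
        ]
        assert np.mean(hs) == pytest.approx(0.5, abs=0.03)

    def test_uncorrected_white_noise_is_biased_upward(self):
        rng = np.random.default_rng(12)
        hs = [
            hurst_rs(rng.standard_normal(1024), [8, 16, 32, 64, 128], corrected=False).H
            for _ in range(60)
        ]
        assert np.mean(hs) > 0.54  # the small-sample bias the correction removes

    def test_mean_estimate_increases_in_true_h(self):
        means = []
        for i, H in enumerate((0.2, 0.4, 0.6, 0.8)):
            xs = fgn_batch(H, 2048, 120, seed=20 + i)
            means.append(np.mean([hurst_rs(x).H for x in xs]))
        assert np.all(np.diff(means) > 0)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            hurst_rs(np.ones(512), [8, 16, 32])

    def test_estimate_outside_unit_interval_warns(self):
        # the estimator flags implausible H values instead of failing hard
        from neurocascade.timeseries import HurstEstimate

        with pytest.warns(UserWarning, match="outside"):
            HurstEstimate(H=1.2, window_sizes=[8, 16], rs_values=[1.0, 2.0], fit_r2=0.9)
        # extreme but well-formed inputs stay inside the physical range
        rng = np.random.default_rng(0)
        ramp = np.linspace(0, 1, 512) + 1e-6 * rng.standard_normal(512)
        alternating = (-1.0) ** np.arange(512) + 1e-3 * rng.standard_normal(512)
        assert 0.0 <= hurst_rs(ramp).H <= 1.0
        assert 0.0 <= hurst_rs(alternating).H <= 1.0

    def test_anis_lloyd_branches_are_continuous(self):
        # small-n Gamma branch and large-n Stirling branch agree at the seam
        jump = abs(expected_rs_anis_lloyd(341) - expected_rs_anis_lloyd(340))
        assert jump / expected_rs_anis_lloyd(340) < 0.005
        # monotone within each branch (the seam itself differs only by round-off)
        assert expected_rs_anis_lloyd(340) > expected_rs_anis_lloyd(330)
        assert expected_rs_anis_lloyd(350) > expected_rs_anis_lloyd(341)

    def test_default_ladder_adapts_to_length(self):
        assert default_window_sizes(1024) == [64, 128, 256, 512]
        assert default_window_sizes(4096) == [256, 512, 1024, 2048]
        assert 8 in default_window_sizes(64)


class TestHurstMap:
    def test_identical_units_identical_h(self):
        x = fgn_batch(0.6, 512, 1, seed=30)[0]
        ts = RoiTimeSeries(np.tile(x[:, None], (1, 4)))
        hs = hurst_map(ts, [8, 16, 32, 64])
        assert np.ptp(hs) == 0.0
        assert hs[0] == pytest.approx(hurst_rs(x, [8, 16, 32, 64]).H)

    def test_failed_unit_flagged_nan_not_zero(self):
        good = fgn_batch(0.5, 512, 1, seed=31)[0]
        ts = RoiTimeSeries(np.column_stack([good, np.ones(512)]))
        with pytest.warns(UserWarning, match="failed"):
            hs = hurst_map(ts, [8, 16, 32, 64])
        assert np.isfinite(hs[0]) and np.isnan(hs[1])

    def test_separates_mixed_h_populations(self):
        low = fgn_batch(0.5, 1024, 30, seed=32)
        high = fgn_batch(0.9, 1024, 30, seed=33)
        ts = RoiTimeSeries(np.vstack([low, high]).T)
        hs = hurst_map(ts)
        p = stats.ranksums(hs[:30], hs[30:]).pvalue
        assert p < 0.01
        assert hs[30:].mean() > hs[:30].mean()


class TestSeedConnectivity:
    def test_unit_equal_to_seed_reference(self):
        rng = np.random.default_rng(40)
        x = rng.standard_normal(128)
        ts = RoiTimeSeries(np.column_stack([x, x, rng.standard_normal(128)]))
        r = seed_connectivity(ts, [0])
        assert r[0] == pytest.approx(1.0) and r[1] == pytest.approx(1.0)

    def test_quadrature_pair_uncorrelated(self):
        t = np.arange(400)
        ts = RoiTimeSeries(
            np.column_stack([np.sin(2 * np.pi * t / 50), np.cos(2 * np.pi * t / 50)])
        )
        r = seed_connectivity(ts, [0])
        assert abs(r[1]) < 1e-10

    def test_recovers_designed_correlation(self):
        from neurocascade.synthetic import generate_seeded_timeseries

        ts = generate_seeded_timeseries(200, 0.6, 5000, seed=41)
        r = seed_connectivity(ts, [0])
        assert np.mean(r[1:]) == pytest.approx(0.6, abs=0.02)

    def test_affine_invariance_and_bounds(self):
        rng = np.random.default_rng(42)
        data = rng.standard_normal((256, 5))
        ts = RoiTimeSeries(data)
        r1 = seed_connectivity(ts, [0, 1])
        ts2 = RoiTimeSeries(data * 7.0 + 3.0)
        r2 = seed_connectivity(ts2, [0, 1])
        np.testing.assert_allclose(r1, r2, atol=1e-10)
        assert np.all(np.abs(r1) <= 1.0)

    def test_fisher_z_and_zero_variance(self):
        rng = np.random.default_rng(43)
        data = np.column_stack([rng.standard_normal((128, 2)), np.full(128, 2.0)])
        ts = RoiTimeSeries(data)
        with pytest.warns(UserWarning, match="zero-variance"):
            r = seed_connectivity(ts, [0], fisher_z=True)
        assert np.isnan(r[2])
        plain = seed_connectivity(RoiTimeSeries(data[:, :2]), [0])
        assert r[1] == pytest.approx(np.arctanh(plain[1]))
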