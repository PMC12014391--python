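"""Profile building, Weibull fitting, quantiles, QC and bands."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adhesiometry import chamber
from adhesiometry.profiles import (
    AdhesionProfile,
    CellObservationSet,
    FitError,
    WeibullParams,
    average_replicates,
    build_profile,
    confidence_bounds,
    fit_weibull,
    tau_quantile,
    track_metrics,
    weibull_survival,
)


def profile_from_params(params, tau):
    return AdhesionProfile.from_fractions(tau, params.survival(tau))


class TestBuildProfile:
    def _obs(self, phase, positions):
        return CellObservationSet("s1", "r1", phase, np.asarray(positions))

    def test_identical_pre_post_gives_unity(self, geometry, flow, rng):
        pos = rng.uniform(0, geometry.imaged_region_length, 500)
        prof = build_profile(
            self._obs("pre", pos), self._obs("post", pos), geometry, flow
        )
        assert np.all(prof.S[prof.usable] == 1.0)

    def test_empty_post_gives_zero(self, geometry, flow, rng):
        pos = rng.uniform(0, geometry.imaged_region_length, 500)
        prof = build_profile(
            self._obs("pre", pos), self._obs("post", []), geometry, flow
        )
        assert np.all(prof.S[prof.usable] == 0.0)

    def test_count_ratio(self, geometry, flow):
        # 10 cells in bin 3, 4 survivors
        step = geometry.imaged_region_length / geometry.n_bins
        inbin = 3 * step + step * (np.arange(10) + 0.5) / 10
        prof = build_profile(
            self._obs("pre", inbin), self._obs("post", inbin[:4]), geometry, flow
        )
        assert prof.n_pre[3] == 10
        assert prof.S[3] == pytest.approx(0.4)

    def test_pre_count_conserved(self, geometry, flow, rng):
        pos = rng.uniform(0, geometry.imaged_region_length, 4000)
        prof = build_profile(
            self._obs("pre", pos), self._obs("post", pos[:100]), geometry, flow
        )
        assert prof.n_pre.sum() == 4000

    def test_mismatched_ids_rejected(self, geometry, flow):
        pre = CellObservationSet("s1", "r1", "pre", [0.1])
        post = CellObservationSet("s2", "r1", "post", [0.1])
        with pytest.raises(ValueError, match="mismatched"):
            build_profile(pre, post, geometry, flow)

    def test_all_bins_empty_rejected(self, geometry, flow):
        pre = self._obs("pre", [])
        post = self._obs("post", [])
        with pytest.raises(FitError, match="empty profile"):
            build_profile(pre, post, geometry, flow)

    def test_drifted_cells_clamped(self, geometry, flow):
        step = geometry.imaged_region_length / geometry.n_bins
        pre = self._obs("pre", [0.5 * step] * 2)
        post = self._obs("post", [0.5 * step] * 5)
        prof = build_profile(pre, post, geometry, flow)
        assert prof.S[0] == 1.0
        assert prof.n_clamped == 1


class TestFitWeibull:
    # grid over the scale/shape ranges that put detachment inside the
    # imaged shear window (67-648 dyn/cm^2); combinations whose survival
    # is flat over that window carry no information and are tested
    # separately as degenerate
    @pytest.mark.parametrize(
        ("lam", "k"),
        [
            (20.0, 0.5), (100.0, 0.5), (600.0, 0.5),
            (100.0, 2.0), (300.0, 2.0), (600.0, 2.0),
            (100.0, 6.0), (300.0, 6.0), (600.0, 6.0),
            (50.0, 1.0), (200.0, 3.5),
        ],
    )
    def test_noiseless_self_consistency(self, bin_shears, lam, k):
        prof = profile_from_params(WeibullParams(lam=lam, k=k), bin_shears)
        fit = fit_weibull(prof)
        assert fit.lam == pytest.approx(lam, rel=1e-6)
        assert fit.k == pytest.approx(k, rel=1e-6)
        assert fit.r_squared > 1 - 1e-10

    def test_fully_detached_profile_rejected(self, bin_shears):
        # lam far below the shear window: every cell detaches in every bin
        prof = profile_from_params(WeibullParams(lam=20.0, k=6.0), bin_shears)
        with pytest.raises(FitError, match="no detachment information"):
            fit_weibull(prof)

    def test_tau50_closed_form(self, bin_shears):
        prof = profile_from_params(WeibullParams(lam=100.0, k=2.0), bin_shears)
        fit = fit_weibull(prof)
        assert fit.tau50 == pytest.approx(100.0 * math.log(2) ** 0.5, rel=1e-6)
        assert fit.tau50 == pytest.approx(83.26, abs=0.01)

    def test_constant_survival_rejected(self, bin_shears):
        prof = AdhesionProfile.from_fractions(bin_shears, np.ones_like(bin_shears))
        with pytest.raises(FitError, match="no detachment information"):
            fit_weibull(prof)

    def test_too_few_bins_rejected(self):
        prof = AdhesionProfile.from_fractions([100.0, 50.0], [0.3, 0.8])
        with pytest.raises(FitError, match=">= 3"):
            fit_weibull(prof)

    def test_grid_search_oracle_on_toy_profile(self):
        """The optimizer's minimum matches an exhaustive (lam, k) scan."""
        tau = np.array([250.0, 120.0, 60.0, 30.0])
        S = np.array([0.05, 0.35, 0.75, 0.93])
        fit = fit_weibull(AdhesionProfile.from_fractions(tau, S))
        lams = np.linspace(50, 200, 301)
        ks = np.linspace(0.5, 5, 226)
        ll, kk = np.meshgrid(lams, ks, indexing="ij")
        sse = (
            (np.exp(-((tau[None, None, :] / ll[..., None]) ** kk[..., None])) - S)
            ** 2
        ).sum(axis=-1)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        assert fit.lam == pytest.approx(lams[i], abs=(lams[1] - lams[0]))
        assert fit.k == pytest.approx(ks[j], abs=(ks[1] - ks[0]))


class TestTauQuantile:
    def test_exponential_median(self):
        p = WeibullParams(lam=200.0, k=1.0)
        assert tau_quantile(p, 0.5) == pytest.approx(200.0 * math.log(2), rel=1e-12)

    def test_scale_returned_at_1_over_e(self):
        p = WeibullParams(lam=137.0, k=3.7)
        assert tau_quantile(p, math.exp(-1)) == pytest.approx(137.0, rel=1e-12)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        lam=st.floats(1.0, 1000.0),
        k=st.floats(0.2, 15.0),
        f1=st.floats(0.05, 0.9),
        f2=st.floats(0.05, 0.9),
    )
    def test_strictly_decreasing_in_fraction(self, lam, k, f1, f2):
        if f1 == f2:
            return
        p = WeibullParams(lam=lam, k=k)
        lo, hi = sorted((f1, f2))
        assert tau_quantile(p, hi) < tau_quantile(p, lo)

    def test_tau75_below_tau50(self):
        for lam, k in [(50, 0.5), (100, 2), (600, 6)]:
            p = WeibullParams(lam=lam, k=k)
            assert p.tau75 < p.tau50

    def test_domain_error(self):
        p = WeibullParams(lam=100.0, k=2.0)
        for f in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                tau_quantile(p, f)


class TestAverageReplicates:
    def test_r2_filter_keeps_good_replicate(self, bin_shears, rng):
        good = profile_from_params(WeibullParams(lam=100, k=2), bin_shears)
        noise = AdhesionProfile.from_fractions(
            bin_shears, np.clip(rng.uniform(0.3, 0.9, bin_shears.size), 0, 1)
        )
        _, fit, kept = average_replicates([good, noise], r2_threshold=0.5)
        assert kept == [0]
        assert fit.lam == pytest.approx(100, rel=1e-4)

    def test_identical_replicates_average_to_themselves(self, bin_shears):
        prof = profile_from_params(WeibullParams(lam=100, k=2), bin_shears)
        avg, _, kept = average_replicates([prof, prof, prof])
        assert kept == [0, 1, 2]
        np.testing.assert_allclose(avg.S, prof.S)
        np.testing.assert_allclose(avg.sem, 0.0, atol=1e-12)

    def test_two_point_sem(self, bin_shears):
        decay = WeibullParams(lam=150, k=2).survival(bin_shears)
        a = AdhesionProfile.from_fractions(bin_shears, np.clip(decay - 0.1, 0, 1))
        b = AdhesionProfile.from_fractions(bin_shears, np.clip(decay + 0.1, 0, 1))
        avg, _, _ = average_replicates([a, b])
        mid = len(bin_shears) // 2
        assert avg.S[mid] == pytest.approx((a.S[mid] + b.S[mid]) / 2)
        # SEM of two points x +/- d is d
        assert avg.sem[mid] == pytest.approx(abs(a.S[mid] - b.S[mid]) / 2)

    def test_all_replicates_failing_qc_raises(self, bin_shears, rng):
        noise = AdhesionProfile.from_fractions(
            bin_shears, rng.uniform(0.2, 0.8, bin_shears.size)
        )
        with pytest.raises(FitError, match="no replicate passed QC"):
            average_replicates([noise], r2_threshold=0.5)


class TestConfidenceBounds:
    def test_prediction_band_contains_confidence_band(self, bin_shears, rng):
        truth = WeibullParams(lam=120, k=2.2)
        S = np.clip(truth.survival(bin_shears) + rng.normal(0, 0.03, bin_shears.size), 0, 1)
        prof = AdhesionProfile.from_fractions(bin_shears, S)
        fit = fit_weibull(prof)
        bands = confidence_bounds(fit, prof)
        assert np.all(bands.pred_lo <= bands.conf_lo + 1e-12)
        assert np.all(bands.pred_hi >= bands.conf_hi - 1e-12)
        assert np.all(bands.conf_lo <= bands.fitted + 1e-12)
        assert np.all(bands.conf_hi >= bands.fitted - 1e-12)

    def test_bands_collapse_without_noise(self, bin_shears):
        prof = profile_from_params(WeibullParams(lam=120, k=2.2), bin_shears)
        fit = fit_weibull(prof)
        bands = confidence_bounds(fit, prof)
        np.testing.assert_allclose(bands.conf_lo, bands.fitted, atol=1e-5)
        np.testing.assert_allclose(bands.pred_hi, bands.fitted, atol=1e-5)
        lo, hi = bands.tau75_ci
        assert hi - lo < 1e-3

    def test_tau75_ci_coverage(self, bin_shears):
        """95% tau75 interval covers the truth in >= 90% of replicates.

        Replicate profiles carry homoscedastic Gaussian bin noise — the
        error model under which the least-squares covariance and the
        delta-method interval are derived.
        """
        truth = WeibullParams(lam=120, k=2.2)
        t75 = truth.tau75
        rng = np.random.default_rng(7)
        n_cover = 0
        n_runs = 500
        base = truth.survival(bin_shears)
        ones = np.ones_like(bin_shears)
        for _ in range(n_runs):
            S = base + rng.normal(0, 0.04, bin_shears.size)
            prof = AdhesionProfile(tau=bin_shears, n_pre=ones, n_post=S, S=S)
            fit = fit_weibull(prof)
            lo, hi = confidence_bounds(fit, prof).tau75_ci
            n_cover += lo <= t75 <= hi
        assert n_cover / n_runs >= 0.90


class TestTrackMetrics:
    def test_straight_path(self):
        traj = np.array([[0.0, 0.0], [90.0, 0.0]])
        speed, disp = track_metrics(traj, duration_h=15.0)
        assert speed == pytest.approx(6.0)
        assert disp == pytest.approx(90.0)

    def test_closed_loop(self):
        traj = np.array([[0, 0], [10, 0], [10, 10], [0, 10], [0, 0]], dtype=float)
        speed, disp = track_metrics(traj, duration_h=15.0)
        assert disp == 0.0
        assert speed == pytest.approx(40 / 15)

    def test_right_angle_segments(self):
        traj = np.array([[0, 0], [30, 0], [30, 40]], dtype=float)
        speed, disp = track_metrics(traj, duration_h=15.0)
        assert speed == pytest.approx(70 / 15)
        assert disp == pytest.approx(50.0)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            track_metrics(np.array([[0.0, 0.0]]))


def test_subsampling_leaves_survival_unbiased(geometry, flow, rng):
    """Uniform subsampling of cells preserves per-bin S in expectation."""
    n = 10_000
    pos = rng.uniform(0, geometry.imaged_region_length, n)
    keep = rng.uniform(size=n) < 0.55
    pre = CellObservationSet("s", "r", "pre", pos)
    post = CellObservationSet("s", "r", "post", pos[keep])
    prof = build_profile(pre, post, geometry, flow)
    S = prof.S[prof.usable]
    # overall survival matches the thinning probability within binomial error
    se = math.sqrt(0.55 * 0.45 / n)
    assert abs(prof.n_post.sum() / prof.n_pre.sum() - 0.55) < 4 * se
    assert abs(S.mean() - 0.55) < 0.02
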