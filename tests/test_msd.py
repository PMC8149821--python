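import numpy as np
import pytest

from conftest import msd_brute_force, random_gapped_track
from sptfa.io import Trajectory
from sptfa.msd import (
    CONFINED,
    EXCLUDED,
    FREE,
    IMMOBILE,
    ClassifierConfig,
    MSDCurve,
    aggregate,
    classify,
    compute_msd,
    estimate_D,
    estimate_resolution,
    fit_confinement,
    immobile_threshold,
)
from sptfa.simulate import MotionMode, SimulationConfig, simulate_trajectory


def _msd_curve(lags, values, counts=None, dt=0.02):
    lags = np.asarray(lags, dtype=float)
    values = np.asarray(values, dtype=float)
    if counts is None:
        counts = np.arange(len(lags), 0, -1)
    return MSDCurve(lags=lags, values=values,
                    pair_counts=np.asarray(counts), frame_interval=dt)


class TestComputeMSD:
    def test_identical_points_zero(self):
        t = Trajectory(id=0, frames=np.arange(10), x=np.full(10, 2.0),
                       y=np.full(10, -1.0), frame_interval=0.02)
        msd = compute_msd(t)
        np.testing.assert_array_equal(msd.values, 0.0)

    def test_line_example(self, straight_track):
        msd = compute_msd(straight_track)
        np.testing.assert_allclose(msd.values, [1.0, 4.0, 9.0])
        np.testing.assert_allclose(msd.lags, [0.02, 0.04, 0.06])
        np.testing.assert_array_equal(msd.pair_counts, [3, 2, 1])

    def test_matches_brute_force_on_random_tracks(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            t = random_gapped_track(rng)
            msd = compute_msd(t)
            lags, values, counts = msd_brute_force(t)
            np.testing.assert_allclose(msd.lags, lags)
            np.testing.assert_allclose(msd.values, values, rtol=1e-12)
            np.testing.assert_array_equal(msd.pair_counts, counts)

    def test_gap_aware_lags(self):
        t = Trajectory(id=0, frames=[0, 1, 3], x=[0.0, 1.0, 3.0],
                       y=[0.0, 0.0, 0.0], frame_interval=0.02)
        msd = compute_msd(t)
        # lags present: 1 (0->1), 2 (1->3), 3 (0->3); no lag grid position abuse
        np.testing.assert_allclose(msd.lags, [0.02, 0.04, 0.06])
        np.testing.assert_allclose(msd.values, [1.0, 4.0, 9.0])

    def test_pair_counts_decreasing_for_gapless(self):
        rng = np.random.default_rng(1)
        t = Trajectory(id=0, frames=np.arange(20), x=rng.normal(size=20),
                       y=rng.normal(size=20), frame_interval=0.02)
        msd = compute_msd(t)
        assert np.all(np.diff(msd.pair_counts) < 0)

    def test_ensemble_mean_matches_closed_form(self):
        # E[MSD(n dt)] = 4 D n dt for free diffusion without noise
        D = 0.1
        cfg = SimulationConfig(pointing_accuracy=0.0, n_frames=200, D_free=D)
        acc = np.zeros(4)
        n_rep = 300
        for i in range(n_rep):
            t = simulate_trajectory(MotionMode.FREE, cfg, seed=i)
            acc += compute_msd(t).values[:4]
        mean = acc / n_rep
        np.testing.assert_allclose(mean, 4 * D * np.arange(1, 5) * 0.02, rtol=0.05)


class TestEstimateD:
    def test_hand_ols_example(self):
        msd = _msd_curve([0.02, 0.04, 0.06, 0.08], [0.008, 0.016, 0.024, 0.032])
        assert estimate_D(msd) == pytest.approx(0.1)

    def test_pure_noise_zero_slope(self):
        sigma = 0.025
        msd = _msd_curve([0.02, 0.04, 0.06, 0.08], [4 * sigma ** 2] * 4)
        assert estimate_D(msd) == pytest.approx(0.0, abs=1e-15)

    def test_too_few_lags_errors(self):
        msd = _msd_curve([0.02, 0.04, 0.06], [1.0, 4.0, 9.0])
        with pytest.raises(ValueError, match="at least 4"):
            estimate_D(msd)

    def test_negative_slope_unclamped(self):
        msd = _msd_curve([0.02, 0.04, 0.06, 0.08], [0.4, 0.3, 0.2, 0.1])
        assert estimate_D(msd) < 0


class TestImmobileThreshold:
    def test_printed_derivation(self):
        # (0.059 µm)^2 / (4 * 4 * 0.02 s) ~ 0.011 µm²/s
        th = immobile_threshold(ClassifierConfig())
        assert th == pytest.approx(0.059 ** 2 / (4 * 4 * 0.02))
        assert round(th, 3) == 0.011

    def test_zero_fwhm(self):
        assert immobile_threshold(ClassifierConfig(resolution_fwhm=1e-300)) \
            == pytest.approx(0.0, abs=1e-12)

    def test_doubled_fwhm_scales_4x(self):
        th = immobile_threshold(ClassifierConfig(resolution_fwhm=0.118))
        assert th == pytest.approx(0.0435125)

    def test_monotonicity(self):
        base = immobile_threshold(ClassifierConfig())
        assert immobile_threshold(ClassifierConfig(resolution_fwhm=0.07)) > base
        assert immobile_threshold(ClassifierConfig(frame_interval=0.04)) < base


class TestFitConfinement:
    def test_noiseless_self_consistency(self):
        r_true, tau_true = 0.1, 0.05
        lags = np.arange(1, 21) * 0.02
        values = (4 * r_true ** 2 / 3) * (1 - np.exp(-lags / tau_true))
        msd = _msd_curve(lags, values, counts=np.arange(100, 80, -1))
        r, tau, D_conf, ok = fit_confinement(msd)
        assert ok
        assert r == pytest.approx(r_true, rel=1e-6)
        assert tau == pytest.approx(tau_true, rel=1e-6)
        assert D_conf == pytest.approx(r_true ** 2 / (3 * tau_true), rel=1e-5)

    def test_linear_msd_pushes_tau_high(self):
        lags = np.arange(1, 21) * 0.02
        msd = _msd_curve(lags, 0.4 * lags, counts=np.arange(100, 80, -1))
        _, tau, _, _ = fit_confinement(msd)
        assert tau > 0.1

    def test_disc_simulation_recovers_r_conf(self):
        # plateau oracle: 4 r_conf² / 3 = R² -> r_conf = (sqrt 3 / 2) R
        R = 0.2
        cfg = SimulationConfig(pointing_accuracy=0.0, n_frames=2000,
                               D_conf=0.1, disc_radius=R)
        rs = []
        for seed in range(5):
            t = simulate_trajectory(MotionMode.CONFINED, cfg, seed=seed)
            r, _, _, _ = fit_confinement(compute_msd(t))
            rs.append(r)
        assert np.mean(rs) == pytest.approx(np.sqrt(3) / 2 * R, rel=0.10)


class TestClassify:
    def _track(self, n, seed, mode=MotionMode.IMMOBILE, **kw):
        cfg = SimulationConfig(n_frames=n, **kw)
        return simulate_trajectory(mode, cfg, seed=seed)

    def test_12_points_excluded(self):
        t = self._track(12, 0)
        assert classify(t).mode == EXCLUDED

    def test_13_points_classified(self):
        t = self._track(13, 0)
        assert classify(t).mode != EXCLUDED

    def test_immobile_monte_carlo(self):
        cfg = SimulationConfig(n_frames=50, pointing_accuracy=0.025)
        hits = sum(
            classify(simulate_trajectory(MotionMode.IMMOBILE, cfg, seed=i)).mode
            == IMMOBILE
            for i in range(200)
        )
        assert hits >= 0.95 * 200

    def test_free_monte_carlo(self):
        cfg = SimulationConfig(n_frames=50, D_free=0.2)
        hits = sum(
            classify(simulate_trajectory(MotionMode.FREE, cfg, seed=i)).mode == FREE
            for i in range(200)
        )
        assert hits >= 0.90 * 200

    def test_threshold_consistency(self):
        cfg = SimulationConfig(n_frames=30, D_free=0.05)
        th = immobile_threshold(ClassifierConfig())
        for i in range(100):
            c = classify(simulate_trajectory(MotionMode.FREE, cfg, seed=i))
            if c.mode == IMMOBILE:
                assert c.D < th
            elif c.mode in (CONFINED, FREE):
                assert c.D >= th
                assert np.isfinite(c.tau)

    def test_rigid_motion_invariance(self):
        cfg = SimulationConfig(n_frames=50, D_free=0.2)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        for i in range(20):
            t = simulate_trajectory(MotionMode.FREE, cfg, seed=i)
            xy = R @ np.vstack([t.x, t.y]) + np.array([[5.0], [-3.0]])
            t2 = Trajectory(id=t.id, frames=t.frames, x=xy[0], y=xy[1],
                            frame_interval=t.frame_interval)
            a, b = classify(t), classify(t2)
            assert a.mode == b.mode
            assert a.D == pytest.approx(b.D, rel=1e-9)

    def test_tau_split_derived_from_config(self):
        cfg = ClassifierConfig()
        assert cfg.tau_split == pytest.approx(0.1)
        assert ClassifierConfig(fit_min_points=20).tau_split == pytest.approx(0.2)
        assert ClassifierConfig(tau_threshold=0.05).tau_split == 0.05


class TestAggregate:
    def _cls(self, mode, D=0.1):
        from sptfa.msd import MotionClassification
        return MotionClassification(mode=mode, n_points=20, D=D)

    def test_single_cell_fractions(self):
        records = [(self._cls(m), "inside_fa", "c1")
                   for m in (IMMOBILE, IMMOBILE, FREE, CONFINED)]
        summaries, _ = aggregate(records)
        (s,) = summaries
        assert s.fractions == {IMMOBILE: 0.5, CONFINED: 0.25, FREE: 0.25}
        assert s.n_trajectories == 4

    def test_two_cell_pooled_mean_sem(self):
        records = (
            [(self._cls(IMMOBILE), "inside_fa", "a")] * 2
            + [(self._cls(FREE), "inside_fa", "b")] * 2
        )
        _, pooled = aggregate(records)
        p = pooled["inside_fa"]
        assert p["fractions_mean"][IMMOBILE] == pytest.approx(0.5)
        assert p["fractions_mean"][FREE] == pytest.approx(0.5)
        assert p["fractions_sem"][IMMOBILE] == pytest.approx(0.5)
        assert p["fractions_sem"][CONFINED] == pytest.approx(0.0)

    def test_histogram_normalized(self):
        rng = np.random.default_rng(0)
        records = [(self._cls(FREE, D=10 ** rng.uniform(-3, 0)), "inside_fa", "c")
                   for _ in range(50)]
        summaries, _ = aggregate(records)
        assert summaries[0].logD_histogram.sum() == pytest.approx(1.0)

    def test_excluded_ignored(self):
        records = [(self._cls(EXCLUDED), "inside_fa", "c"),
                   (self._cls(FREE), "inside_fa", "c")]
        summaries, _ = aggregate(records)
        assert summaries[0].n_trajectories == 1

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(5)
        modes = rng.choice([IMMOBILE, CONFINED, FREE], size=37)
        records = [(self._cls(m), "outside_fa", "c") for m in modes]
        summaries, _ = aggregate(records)
        assert sum(summaries[0].fractions.values()) == pytest.approx(1.0, abs=1e-9)


class TestEstimateResolution:
    def _cloud(self, sigma, n=100, seed=0, sigma_y=None):
        rng = np.random.default_rng(seed)
        sigma_y = sigma if sigma_y is None else sigma_y
        return Trajectory(
            id=seed, frames=np.arange(n),
            x=rng.normal(0, max(sigma, 1e-12), n),
            y=rng.normal(0, max(sigma_y, 1e-12), n),
            frame_interval=0.02,
        )

    def test_zero_noise_zero_fwhm(self):
        clouds = [Trajectory(id=i, frames=np.arange(60), x=np.full(60, 1.0),
                             y=np.full(60, 2.0), frame_interval=0.02)
                  for i in range(3)]
        est = estimate_resolution(clouds)
        assert est.fwhm == 0.0

    def test_25nm_clouds_give_57p5nm_fwhm(self):
        clouds = [self._cloud(0.025, n=400, seed=i) for i in range(50)]
        est = estimate_resolution(clouds)
        assert est.fwhm * 1000 == pytest.approx(57.5, abs=2.0)
        assert est.fwhm == pytest.approx(2.3 * est.s_xy)
        assert est.n_clouds == 50

    def test_anisotropic_mean_of_axis_sigmas(self):
        clouds = [self._cloud(0.02, n=2000, seed=i, sigma_y=0.04)
                  for i in range(20)]
        est = estimate_resolution(clouds)
        assert est.s_xy == pytest.approx(0.03, rel=0.05)

    def test_small_cloud_rejected(self):
        with pytest.raises(ValueError, match="< 50"):
            estimate_resolution([self._cloud(0.025, n=49)])
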