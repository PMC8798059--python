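"""Tip tracking, phase segmentation, event statistics and intensity ops."""

import numpy as np
import pytest

from mtdynamics.dynamics_model import ExperimentCondition, KineticParams
from mtdynamics.kymograph_render import (
    Kymograph,
    OpticsConfig,
    make_arc_filament,
    render_field,
    render_kymograph,
)
from mtdynamics.synthetic_data import (
    FilamentTrajectory,
    sample_nucleation_lags,
    sample_trajectory,
)
from mtdynamics.trace_analysis import (
    TipTrace,
    average_line_profiles,
    count_field_microtubules,
    curvature_intensity,
    depolymerization_rate,
    nucleation_lag,
    recruitment_ratio,
    segment_phases,
    summarize_dynamics,
    track_tip,
    trajectory_to_segments,
)


def ramp(v_um_min=1.0, duration_s=600.0):
    return FilamentTrajectory(
        np.array([0.0, duration_s]),
        np.array([0.0, v_um_min * duration_s / 60.0]),
        ["growth"],
    )


def make_trace(t_s, y_um):
    return TipTrace(np.asarray(t_s, float), np.asarray(y_um, float))


class TestTrackTip:
    def test_noiseless_ramp_within_half_pixel(self):
        kymo = render_kymograph(ramp(), noise=False)
        trace = track_tip(kymo)
        truth = ramp().length_at(trace.frame_times_s)
        obs = ~np.isnan(trace.tip_positions_um)
        err = trace.tip_positions_um[obs] - truth[obs]
        assert obs.sum() > 250
        assert np.max(np.abs(err)) < 0.5 * kymo.optics.pixel_size_um

    def test_background_only_all_missing(self):
        optics = OpticsConfig()
        rng = np.random.default_rng(0)
        img = rng.poisson(20.0, size=(100, 80)).astype(float)
        kymo = Kymograph({"lattice": img, "seed": img * 0}, optics)
        trace = track_tip(kymo)
        assert trace.n_present == 0

    def test_noisy_constant_growth_slope_within_5pct(self):
        from mtdynamics.trace_analysis import _ols_slope

        for seed in range(5):
            kymo = render_kymograph(ramp(), rng_seed=seed)
            trace = track_tip(kymo)
            obs = ~np.isnan(trace.tip_positions_um)
            slope = _ols_slope(trace.frame_times_s[obs], trace.tip_positions_um[obs])
            assert slope == pytest.approx(1.0, rel=0.05)


class TestSegmentPhases:
    def test_exact_two_piece_trace(self):
        t = np.arange(0, 420, 2.0)
        y = np.where(t <= 300, t / 60.0, 5.0 - 10.0 * (t - 300) / 60.0)
        y = np.clip(y, 0, None)
        segs = segment_phases(make_trace(t[t <= 330], y[t <= 330]))
        assert len(segs) == 2
        assert segs[0].phase == "growth" and segs[1].phase == "shrink"
        assert abs(segs[0].t_end_s - 300.0) <= 2.0  # breakpoint within one frame
        assert segs[0].slope_um_min == pytest.approx(1.0, rel=0.02)
        assert segs[1].slope_um_min == pytest.approx(-10.0, rel=0.02)

    def test_constant_trace_single_pause(self):
        t = np.arange(0, 200, 2.0)
        segs = segment_phases(make_trace(t, np.full_like(t, 3.0)))
        assert len(segs) == 1
        assert segs[0].phase == "pause"

    @pytest.mark.parametrize("v1,v2", [(0.5, 2.0), (1.0, 0.3), (2.0, 0.8)])
    def test_noiseless_grid_slope_and_breakpoint_recovery(self, v1, v2):
        # two growth slopes meeting at t = 240 s
        t = np.arange(0, 480, 2.0)
        brk = 240.0
        y = np.where(t <= brk, v1 * t / 60, v1 * brk / 60 + v2 * (t - brk) / 60)
        segs = segment_phases(make_trace(t, y))
        growth = [s for s in segs if s.phase == "growth"]
        assert len(growth) == 2
        assert growth[0].slope_um_min == pytest.approx(v1, rel=0.02)
        assert growth[1].slope_um_min == pytest.approx(v2, rel=0.02)
        assert abs(growth[0].t_end_s - brk) <= 2.0

    def test_too_short_trace_rejected(self):
        t = np.arange(0, 10, 2.0)
        with pytest.raises(ValueError):
            segment_phases(make_trace(t, t))

    def test_detected_catastrophes_match_generator(self, control):
        # long excursions (high tubulin) and fast frames so nearly every
        # catastrophe is resolvable in the rendered kymograph
        p = KineticParams(k_a=control.k_a, k_d=control.k_d, f_cat=0.5, v_shrink=10.0)
        cond = ExperimentCondition(45.0, label="test")
        optics = OpticsConfig(frame_interval_s=1.0)
        n_true = n_det = 0
        for k in range(40):
            traj = sample_trajectory(cond, p, 900.0, rng_seed=1000 + k)
            true_summary = summarize_dynamics([trajectory_to_segments(traj)])
            kymo = render_kymograph(traj, optics, rng_seed=2000 + k)
            segs = segment_phases(track_tip(kymo))
            det_summary = summarize_dynamics([segs])
            n_true += true_summary.n_catastrophes
            n_det += det_summary.n_catastrophes
        assert n_true >= 200
        assert abs(n_det - n_true) / n_true < 0.10


class TestSummarizeDynamics:
    def test_growth_shrink_pair_is_one_catastrophe(self):
        segs = [
            [
                _seg(0, 300, 1.0, "growth"),
                _seg(300, 330, -10.0, "shrink"),
            ]
        ]
        s = summarize_dynamics(segs)
        assert s.n_catastrophes == 1
        assert s.total_growth_time_min == pytest.approx(5.0)

    def test_censored_growth_counts_time_but_no_event(self):
        s = summarize_dynamics([[_seg(0, 300, 1.0, "growth")]])
        assert s.n_catastrophes == 0
        assert s.total_growth_time_min == pytest.approx(5.0)

    def test_time_conservation(self, control):
        traj = sample_trajectory(
            ExperimentCondition(10.0, label="c"), control, 600.0, rng_seed=5
        )
        segs = trajectory_to_segments(traj)
        total = sum(s.t_end_s - s.t_start_s for s in segs)
        assert total == pytest.approx(traj.duration_s, abs=1e-6)


def _seg(t0, t1, slope, phase):
    from mtdynamics.trace_analysis import PhaseSegment

    return PhaseSegment(float(t0), float(t1), float(slope), phase)


class TestNucleationLag:
    def test_interpolated_crossing(self):
        t = np.arange(0, 120, 2.0)
        rec = nucleation_lag(make_trace(t, t / 60.0), threshold_length_um=0.5)
        assert not rec.censored
        assert rec.lag_s == pytest.approx(30.0, abs=2.0)

    def test_no_growth_censored(self):
        t = np.arange(0, 120, 2.0)
        rec = nucleation_lag(make_trace(t, np.zeros_like(t)), t_max_s=60.0)
        assert rec.censored

    def test_rendered_lag_ecdf_matches_generator(self, control):
        # generator lags -> delayed-growth trajectories -> render -> track;
        # recovered crossing times, minus the deterministic threshold delay,
        # should reproduce the generator lag distribution (DKW band, n=200)
        v = 1.0  # µm/min growth once nucleated
        thresh = 0.5
        cond = ExperimentCondition(control.hill_C, label="nuc")
        recs = sample_nucleation_lags(cond, control, 200, t_max_s=180.0, rng_seed=9)
        rec_lags, gen_lags = [], []
        for k, r in enumerate(recs):
            if r.censored:
                continue
            gen_lags.append(r.lag_s)
            times = np.array([0.0, r.lag_s, 300.0])
            lengths = np.array([0.0, 0.0, (300.0 - r.lag_s) / 60.0 * v])
            traj = FilamentTrajectory(times, lengths, ["pause", "growth"])
            kymo = render_kymograph(traj, rng_seed=300 + k)
            rec = nucleation_lag(track_tip(kymo), thresh, t_max_s=300.0)
            assert not rec.censored
            rec_lags.append(rec.lag_s - thresh / v * 60.0)
        gen_lags, rec_lags = np.sort(gen_lags), np.sort(rec_lags)
        n = len(gen_lags)
        grid = np.linspace(0, 200, 400)
        f_gen = np.searchsorted(gen_lags, grid, side="right") / n
        f_rec = np.searchsorted(rec_lags, grid, side="right") / n
        dkw = np.sqrt(np.log(2 / 0.05) / (2 * n))
        assert np.max(np.abs(f_gen - f_rec)) < dkw


class TestFieldCounting:
    def test_separate_filaments_counted(self):
        chains = [
            np.array([[2.0, 2.0 + 2.0 * i], [8.0, 2.0 + 2.0 * i]]) for i in range(7)
        ]
        img = render_field(chains, field_size_um=18.0, rng_seed=0)
        n = count_field_microtubules(img, 0.107, min_length_um=1.0)
        assert n == 7

    def test_empty_field_zero(self):
        img = render_field([], field_size_um=10.0, rng_seed=0)
        assert count_field_microtubules(img, 0.107) == 0

    def test_crossing_filaments_counted_as_two(self):
        chains = [
            np.array([[2.0, 2.0], [8.0, 8.0]]),
            np.array([[2.0, 8.0], [8.0, 2.0]]),
        ]
        img = render_field(chains, field_size_um=10.0, rng_seed=1)
        assert count_field_microtubules(img, 0.107) == 2


class TestDepolymerizationRate:
    def test_exact_linear_shrink(self):
        t = np.arange(0, 600) * 60.0
        y = 8.0 - 0.013 * t / 60.0
        assert depolymerization_rate(make_trace(t, y)) == pytest.approx(0.013)

    def test_constant_trace_zero(self):
        t = np.arange(0, 100) * 60.0
        assert depolymerization_rate(make_trace(t, np.full_like(t, 5.0))) == 0.0

    def test_too_few_points(self):
        t = np.arange(0, 5) * 60.0
        with pytest.raises(ValueError):
            depolymerization_rate(make_trace(t, t))


class TestLineProfiles:
    def test_average_and_normalize(self):
        img = np.zeros((10, 10))
        img[5, 2:5] = [0.0, 2.0, 4.0]
        prof = average_line_profiles(
            [img, img],
            [((5.0, 2.0), (5.0, 4.0)), ((5.0, 2.0), (5.0, 4.0))],
            (slice(0, 2), slice(0, 2)),
            pixel_size_um=0.107,
            n_samples=3,
        )
        np.testing.assert_allclose(prof.mean_intensity, [0.0, 0.5, 1.0])
        np.testing.assert_allclose(prof.sem, 0.0)
        assert prof.n_profiles == 2

    def test_uniform_image_flagged_constant(self):
        img = np.full((10, 10), 7.0)
        prof = average_line_profiles(
            [img],
            [((5.0, 3.0), (5.0, 8.0))],
            (slice(0, 2), slice(0, 2)),
            pixel_size_um=0.107,
        )
        assert prof.constant

    def test_background_overlap_rejected(self):
        img = np.zeros((10, 10))
        with pytest.raises(ValueError, match="overlaps"):
            average_line_profiles(
                [img],
                [((1.0, 0.0), (1.0, 9.0))],
                (slice(0, 3), slice(0, 3)),
                pixel_size_um=0.107,
            )

    def test_rendered_tip_peak_position(self):
        # a short bright segment: profile peak should sit on the segment
        chains = [np.array([[3.0, 5.0], [7.0, 5.0]])]
        img = render_field(chains, field_size_um=10.0, rng_seed=3)
        px = 0.107
        row = 5.0 / px
        prof = average_line_profiles(
            [img],
            [((row, 3.0 / px), (row, 8.0 / px))],
            (slice(0, 10), slice(0, 10)),
            pixel_size_um=px,
            n_samples=60,
        )
        peak_offset = prof.offsets_um[np.argmax(prof.mean_intensity)]
        assert 0.0 <= peak_offset <= 4.2  # on the filament, not the empty tail


class TestRecruitmentRatio:
    def test_known_ratio(self):
        img = np.full((20, 20), 100.0)
        lattice = np.zeros_like(img, bool)
        bg = np.zeros_like(img, bool)
        lattice[5:8, :] = True
        bg[15:18, :] = True
        img[lattice] = 300.0
        assert recruitment_ratio(img, lattice, bg) == pytest.approx(3.0)

    def test_identical_statistics_give_unity(self):
        img = np.full((20, 20), 50.0)
        a = np.zeros_like(img, bool)
        b = np.zeros_like(img, bool)
        a[0:5, :] = True
        b[10:15, :] = True
        assert recruitment_ratio(img, a, b) == pytest.approx(1.0)

    def test_overlapping_masks_rejected(self):
        img = np.ones((20, 20))
        m = np.ones_like(img, bool)
        with pytest.raises(ValueError):
            recruitment_ratio(img, m, m)


class TestCurvatureIntensity:
    def test_circle_curvature(self):
        chain = make_arc_filament(2.0, 1.5 * np.pi, n_points=80, center=(5.0, 5.0))
        img = render_field([chain], field_size_um=10.0, rng_seed=4)
        samples, _ = curvature_intensity(chain, img, 0.107)
        kappas = np.array([s.kappa_per_um for s in samples])
        assert np.median(kappas) == pytest.approx(0.5, rel=0.05)

    def test_straight_line_near_zero_curvature(self):
        chain = np.column_stack([np.linspace(1, 9, 30), np.full(30, 5.0)])
        img = np.ones((100, 100))
        samples, _ = curvature_intensity(chain, img, 0.107)
        assert max(s.kappa_per_um for s in samples) < 1e-6

    def test_intensity_proportional_to_curvature(self):
        # clothoid-like curve with κ rising linearly along arc length,
        # painted into an image with I = 100·κ: binned means must rise
        # with slope ≈ 100
        s = np.linspace(0, 15.0, 2000)
        kappa = 0.05 + 0.05 * s
        theta = np.cumsum(kappa * np.gradient(s))
        x = 2.0 + np.cumsum(np.cos(theta) * np.gradient(s))
        y = 2.0 + np.cumsum(np.sin(theta) * np.gradient(s))
        chain = np.column_stack([x, y])
        px = 0.107
        n = int(np.ceil(20.0 / px))
        img = np.zeros((n, n))
        for xi, yi, ki in zip(x[::4], y[::4], kappa[::4]):
            r, c = int(yi / px), int(xi / px)
            img[max(r - 3, 0) : r + 4, max(c - 3, 0) : c + 4] = 100.0 * ki
        _, binned = curvature_intensity(chain[::20], img, px, n_bins=6)
        centers = binned["kappa_center"].to_numpy()
        means = binned["mean_intensity"].to_numpy()
        assert np.all(np.diff(means) > 0)
        slope = np.polyfit(centers, means, 1)[0]
        assert slope == pytest.approx(100.0, rel=0.10)

    def test_repeated_points_rejected(self):
        chain = np.array([[1, 1], [1, 1], [2, 2], [3, 3], [4, 4]], float)
        with pytest.raises(ValueError, match="degenerate"):
            curvature_intensity(chain, np.ones((50, 50)), 0.107)
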