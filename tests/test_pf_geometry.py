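"""Protofilament geometry: resampling, smoothing, curvature, aggregation."""

import numpy as np
import pytest

from conftest import circle_arc_points, random_rigid_motion
from tipshape.pf_geometry import (CurvatureProfile, MTEndRecord, PerEndStats, PFTrace,
                                  ResampledTrace, cap_statistics,
                                  coiled_coil_axial_length, curvature_length_correlation,
                                  curvature_profile, flare_origin, loess_smooth,
                                  per_end_stats, per_grid_cap_summary, pf_flare_length,
                                  resample_uniform, terminal_curvature,
                                  tip_aligned_profile)
from tipshape.synthetic import FlareGroundTruth, gen_flared_end


def make_trace(points, origin_index=0, **ids):
    return PFTrace(grid_id=ids.get("grid_id", "g"), mt_id=ids.get("mt_id", "m"),
                   pf_id=ids.get("pf_id", "p"), points=np.asarray(points, float),
                   origin_index=origin_index)


class TestResample:
    def test_straight_segment_uniform_subdivision(self):
        tr = make_trace([[0, 0, 0], [10, 0, 0]])
        rs = resample_uniform(tr, step=2.0)
        assert rs.n_points == 6
        np.testing.assert_allclose(rs.points[:, 0], [0, 2, 4, 6, 8, 10], atol=1e-12)
        np.testing.assert_allclose(rs.points[:, 1:], 0.0, atol=1e-12)

    def test_quarter_circle_arc_length_preserved(self):
        fine = circle_arc_points(20.0, 0.1)  # R=20 quarter circle, arc 10*pi
        rs = resample_uniform(make_trace(fine), step=2.0)
        brute = np.linalg.norm(np.diff(fine, axis=0), axis=1).sum()
        out = np.linalg.norm(np.diff(rs.points, axis=0), axis=1).sum()
        assert abs(out - 10 * np.pi) < 2.0
        assert abs(out - brute) < 2.0  # within one step of the fine polyline

    def test_single_point_flare_is_flagged_zero_length(self):
        tr = make_trace([[0, 0, 0], [5, 0, 0]], origin_index=1)
        rs = resample_uniform(tr, step=2.0)
        assert rs.degenerate
        assert pf_flare_length(rs) == 0.0

    def test_endpoints_preserved_final_interval_short(self, rng):
        for _ in range(20):
            pts = np.cumsum(rng.uniform(0.5, 3.0, size=(12, 3)), axis=0)
            rs = resample_uniform(make_trace(pts), step=2.0)
            np.testing.assert_allclose(rs.points[0], pts[0], atol=1e-9)
            np.testing.assert_allclose(rs.points[-1], pts[-1], atol=1e-9)
            gaps = np.linalg.norm(np.diff(rs.points, axis=0), axis=1)
            assert np.all(gaps <= 2.0 + 1e-9)

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(ValueError):
            make_trace([[0, 0, 0], [np.nan, 0, 0]])

    def test_nonpositive_step_rejected(self):
        with pytest.raises(ValueError):
            resample_uniform(make_trace([[0, 0, 0], [1, 0, 0]]), step=0.0)


class TestLoess:
    def test_quadratic_coordinates_reproduced(self):
        s = 1.5
        t = s * np.arange(20)
        pts = np.column_stack([1 + 2 * t + 0.1 * t**2,
                               3 - t + 0.05 * t**2,
                               0.5 - 0.02 * t**2])
        sm = loess_smooth(ResampledTrace(points=pts, step=s))
        np.testing.assert_allclose(sm.points, pts, atol=1e-9)

    def test_collinear_points_stay_collinear(self):
        t = 2.0 * np.arange(15)
        pts = np.column_stack([t, 2 * t, -t])
        sm = loess_smooth(ResampledTrace(points=pts, step=2.0))
        np.testing.assert_allclose(sm.points, pts, atol=1e-9)
        prof = curvature_profile(sm)
        np.testing.assert_allclose(prof.joint_angles, 0.0, atol=1e-7)

    def test_smoothing_reduces_rms_noise_on_arc(self, rng):
        truth = circle_arc_points(20.0, 2.0, sweep=np.pi)
        noisy = truth + rng.normal(0, 1.0, size=truth.shape)
        sm = loess_smooth(ResampledTrace(points=noisy, step=2.0))
        rms_before = np.sqrt(np.mean((noisy - truth) ** 2))
        rms_after = np.sqrt(np.mean((sm.points - truth) ** 2))
        assert rms_after < rms_before

    def test_short_trace_global_fit(self):
        # fewer points than the window: global quadratic, still exact
        t = 2.0 * np.arange(6)
        pts = np.column_stack([t, 0.3 * t**2, np.zeros_like(t)])
        sm = loess_smooth(ResampledTrace(points=pts, step=2.0), window_points=10)
        np.testing.assert_allclose(sm.points, pts, atol=1e-9)

    def test_point_count_never_changes(self, rng):
        for n in (3, 5, 9, 10, 11, 40):
            pts = np.cumsum(rng.uniform(0.5, 2.0, size=(n, 3)), axis=0)
            sm = loess_smooth(ResampledTrace(points=pts, step=1.0))
            assert sm.n_points == n

    def test_window_smaller_than_degree_rejected(self, circle_trace):
        with pytest.raises(ValueError):
            loess_smooth(circle_trace, window_points=3, degree=2)


class TestCurvature:
    def test_collinear_all_zero(self):
        pts = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        prof = curvature_profile(ResampledTrace(points=pts, step=1.0))
        np.testing.assert_allclose(prof.joint_angles, 0.0, atol=1e-12)

    def test_orthogonal_segments_90_degrees(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0]], float)
        prof = curvature_profile(ResampledTrace(points=pts, step=1.0))
        np.testing.assert_allclose(prof.joint_angles, [90.0], atol=1e-12)

    def test_circle_equal_chords_turn_by_arc_angle(self, circle_trace):
        prof = curvature_profile(circle_trace)
        np.testing.assert_allclose(prof.joint_angles, np.degrees(2.0 / 20.0),
                                   atol=1e-6)

    def test_rigid_motion_invariance(self, rng):
        pts = circle_arc_points(25.0, 2.0) + [0, 0, 3.0]
        pts[:, 2] += 0.2 * np.arange(len(pts))  # out-of-plane deviation
        base = curvature_profile(ResampledTrace(points=pts, step=2.0))
        base_len = pf_flare_length(ResampledTrace(points=pts, step=2.0))
        for _ in range(25):
            R, t = random_rigid_motion(rng)
            moved = ResampledTrace(points=pts @ R.T + t, step=2.0)
            prof = curvature_profile(moved)
            np.testing.assert_allclose(prof.joint_angles, base.joint_angles,
                                       atol=1e-9)
            assert abs(pf_flare_length(moved) - base_len) < 1e-9

    def test_two_point_trace_gives_empty_profile(self):
        prof = curvature_profile(ResampledTrace(
            points=np.array([[0, 0, 0], [1, 0, 0.0]]), step=1.0))
        assert prof.empty and len(prof) == 0


class TestFlareOriginAndLength:
    def test_all_points_inside_cylinder_no_flare(self):
        theta = np.linspace(0, 1, 8)
        pts = np.column_stack([12.5 * np.cos(theta), 12.5 * np.sin(theta),
                               8 * theta])
        idx = flare_origin(pts, [0, 0, 0], [0, 0, 1], mt_radius=12.5, delta=1.5)
        assert idx == len(pts) - 1

    def test_threshold_arithmetic(self):
        pts = np.array([[12.5, 0, 0], [12.5, 0, 2], [15, 0, 4], [18, 0, 6.0]])
        assert flare_origin(pts, [0, 0, 0], [0, 0, 1], mt_radius=12.5, delta=1.5) == 1

    def test_degenerate_axis_rejected(self):
        pts = np.array([[12.5, 0, 0], [15, 0, 2.0]])
        with pytest.raises(ValueError):
            flare_origin(pts, [0, 0, 0], [0, 0, 0])

    def test_generator_round_trip_low_noise(self):
        # a sharply curved flare leaves the cylinder within a point or two
        truth = FlareGroundTruth(radius=10.0, flare_arc_length=30.0,
                                 noise_sigma=0.3, n_pf=4, seed=5)
        end = gen_flared_end(truth)
        for tr in end.traces:
            idx = flare_origin(tr.points, [0, 0, 0], [0, 0, 1],
                               mt_radius=truth.mt_radius, delta=1.5)
            assert abs(idx - truth.origin_index) <= 2

    def test_length_zero_when_origin_is_last_point(self):
        tr = make_trace([[0, 0, 0], [1, 0, 0]], origin_index=1)
        assert pf_flare_length(tr) == 0.0

    def test_length_direct_arithmetic(self):
        tr = make_trace([[0, 0, 8], [1, 0, 10], [3, 0, 11]], origin_index=0)
        assert pf_flare_length(tr) == pytest.approx(2 * np.sqrt(5), abs=1e-9)

    def test_generated_arc_length_recovered_after_resampling(self):
        truth = FlareGroundTruth(radius=25.0, flare_arc_length=40.0,
                                 noise_sigma=0.0, n_pf=1, seed=2)
        end = gen_flared_end(truth)
        rs = resample_uniform(end.traces[0], step=2.0)
        assert pf_flare_length(rs) == pytest.approx(40.0, abs=0.1)


class TestTerminalCurvature:
    def test_mean_of_three_distal_joints(self):
        prof = CurvatureProfile(joint_angles=np.array([0.1, 0.2, 0.9, 1.0, 1.1]),
                                arc_positions=np.arange(5.0), step=1.0)
        assert terminal_curvature(prof, 3) == pytest.approx(1.0)

    def test_uniform_arc_terminal_equals_average(self, circle_trace):
        prof = curvature_profile(circle_trace)
        assert terminal_curvature(prof) == pytest.approx(prof.angles_per_nm.mean(),
                                                         abs=1e-9)

    def test_straight_trace_zero(self):
        pts = np.column_stack([np.arange(6.0), np.zeros(6), np.zeros(6)])
        prof = curvature_profile(ResampledTrace(points=pts, step=1.0))
        assert terminal_curvature(prof) == pytest.approx(0.0, abs=1e-12)

    def test_empty_profile_is_nan(self):
        prof = CurvatureProfile(joint_angles=np.empty(0), arc_positions=np.empty(0),
                                step=1.0, empty=True)
        assert np.isnan(terminal_curvature(prof))


class TestPerEndStats:
    def _arc_trace(self, pf_id, rot_deg=0.0):
        pts = circle_arc_points(20.0, 2.0)
        a = np.radians(rot_deg)
        R = np.array([[np.cos(a), 0, np.sin(a)], [0, 1, 0], [-np.sin(a), 0, np.cos(a)]])
        return make_trace(pts @ R.T, pf_id=pf_id)

    def test_identical_arcs_average_to_single_arc_values(self):
        traces = [self._arc_trace(f"p{i}") for i in range(3)]
        end = MTEndRecord(grid_id="g", mt_id="m", polarity="plus", n_pf=3,
                          traces=traces)
        stats = per_end_stats(end, step=2.0)
        single = pf_flare_length(loess_smooth(resample_uniform(traces[0], 2.0)))
        assert stats.mean_length == pytest.approx(single, abs=1e-9)
        assert stats.n_pf_nonzero == 3

    def test_blunt_pfs_excluded_but_counted(self):
        flared = [self._arc_trace("p0"), self._arc_trace("p1", rot_deg=10)]
        blunt = [make_trace([[12.5, 0, -8], [12.5, 0, 0]], origin_index=1,
                            pf_id=f"b{i}") for i in range(12)]
        end = MTEndRecord(grid_id="g", mt_id="m", polarity="plus", n_pf=14,
                          traces=flared + blunt)
        stats = per_end_stats(end, step=2.0)
        assert stats.n_pf_nonzero == 2
        assert stats.n_pf_total == 14
        # conservation: nonzero + zero-length = total
        assert stats.n_pf_total - stats.n_pf_nonzero == 12

    def test_all_blunt_end_undefined_means(self):
        blunt = [make_trace([[12.5, 0, -8], [12.5, 0, 0]], origin_index=1,
                            pf_id=f"b{i}") for i in range(3)]
        end = MTEndRecord(grid_id="g", mt_id="m", polarity="plus", n_pf=14,
                          traces=blunt)
        stats = per_end_stats(end)
        assert stats.n_pf_nonzero == 0
        assert np.isnan(stats.mean_length) and np.isnan(stats.mean_curvature)


class TestTipAlignedProfile:
    def _const_profile(self, n, value=0.1, step=2.0):
        return CurvatureProfile(joint_angles=np.full(n, value * step),
                                arc_positions=step * np.arange(1, n + 1), step=step)

    def test_constant_profile_flat_with_zero_slope(self):
        tap = tip_aligned_profile([self._const_profile(8)])
        np.testing.assert_allclose(tap.mean_curvature, 0.1, atol=1e-12)
        assert tap.fit_slope == pytest.approx(0.0, abs=1e-12)

    def test_counts_from_mixed_lengths(self):
        tap = tip_aligned_profile([self._const_profile(3), self._const_profile(5)])
        np.testing.assert_array_equal(tap.n_per_offset, [2, 2, 2, 1, 1])
        assert np.all(np.isnan(tap.sem_curvature[3:]))

    def test_mixed_steps_rejected(self):
        with pytest.raises(ValueError):
            tip_aligned_profile([self._const_profile(4, step=2.0),
                                 self._const_profile(4, step=1.0)])

    def test_linear_gradient_slope_recovered(self):
        # Curvature rising toward the tip at a known rate, on flares long
        # enough (120 nm) that the 10-point LOESS window stays local.  The
        # full-profile fit is attenuated by local-regression boundary bias
        # concentrated in the tip-most half window of joints; excluding
        # those offsets recovers the gradient without bias.
        from scipy import stats as sps

        from tipshape.synthetic import gen_flared_ends
        grad = 0.008  # deg/nm per nm
        window = 10
        truth = FlareGroundTruth(radius=25.0, flare_arc_length=120.0,
                                 noise_sigma=0.5, n_pf=14, seed=7,
                                 curvature_gradient=grad)
        profiles = []
        for end in gen_flared_ends(truth, 100):
            for tr in end.traces:
                rs = resample_uniform(tr, 4.0)
                if rs.degenerate or rs.n_points < 3:
                    continue
                prof = curvature_profile(loess_smooth(rs, window_points=window))
                if not prof.empty:
                    profiles.append(prof)
        tap = tip_aligned_profile(profiles)
        assert tap.fit_slope == pytest.approx(grad, rel=0.20)
        half = window // 2
        interior = sps.linregress(tap.offsets[half:], tap.mean_curvature[half:])
        assert interior.slope == pytest.approx(grad, rel=0.10)


class TestCorrelationAndCaps:
    def _stats(self, pairs):
        return [PerEndStats(grid_id="g", mt_id=f"m{i}", mean_length=ln,
                            mean_curvature=c, mean_terminal_curvature=c,
                            n_pf_nonzero=3, n_pf_total=14)
                for i, (c, ln) in enumerate(pairs)]

    def test_perfect_linearity(self):
        res = curvature_length_correlation(self._stats([(1, 2), (2, 4), (3, 6)]))
        assert res.r == pytest.approx(1.0)
        assert res.n == 3

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError):
            curvature_length_correlation(self._stats([(1, 2), (1, 4), (1, 6)]))

    def test_too_few_ends(self):
        with pytest.raises(ValueError):
            curvature_length_correlation(self._stats([(1, 2), (2, 4)]))

    def test_matches_closed_form(self, rng):
        pairs = rng.normal(size=(30, 2)) * [0.5, 10] + [2.0, 40]
        res = curvature_length_correlation(self._stats(pairs))
        x, y = pairs[:, 0], pairs[:, 1]
        manual = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
        assert res.r == pytest.approx(manual, abs=1e-12)

    def test_independent_curvature_length_null(self):
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            pairs = np.column_stack([r.normal(2.3, 0.3, 200), r.normal(40, 8, 200)])
            res = curvature_length_correlation(self._stats(pairs))
            if abs(res.r) < 0.2 and res.p > 0.01:
                hits += 1
        assert hits >= 95

    def _ends(self, spec):
        # spec: list of (grid, polarity, cap_state) triples
        return [MTEndRecord(grid_id=g, mt_id=f"m{i}", polarity=p, cap_state=c)
                for i, (g, p, c) in enumerate(spec)]

    def test_pooled_printed_counts(self):
        spec = [("g0", "plus", "full")] * 38 + [("g0", "plus", "none")] * 11
        table = cap_statistics(self._ends(spec), mode="pooled")
        frac = float(table.loc[table.polarity == "plus", "fraction_pct"].iloc[0])
        assert frac == pytest.approx(100 * 38 / 49)
        assert round(frac) == 78

    def test_zero_capped(self):
        spec = [("g0", "minus", "none")] * 20
        table = cap_statistics(self._ends(spec), mode="pooled")
        assert float(table["fraction_pct"].iloc[0]) == 0.0

    def test_per_grid_mean_sd(self):
        spec = ([("g0", "plus", "full")] * 2 + [("g0", "plus", "none")] * 2
                + [("g1", "plus", "attached")] * 3)
        table = cap_statistics(self._ends(spec), mode="per_grid")
        summary = per_grid_cap_summary(table)
        row = summary.loc[summary.polarity == "plus"].iloc[0]
        assert row.mean_pct == pytest.approx(75.0)
        assert row.sd_pct == pytest.approx(np.std([50.0, 100.0], ddof=1))


class TestCoiledCoil:
    def test_eighty_residues_twelve_nm(self):
        assert coiled_coil_axial_length(80) == pytest.approx(12.0)

    def test_single_residue(self):
        assert coiled_coil_axial_length(1) == pytest.approx(0.15)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            coiled_coil_axial_length(0)
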