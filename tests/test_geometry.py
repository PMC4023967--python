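"""Balance-geometry operations against analytic values and brute-force oracles."""

import math

import numpy as np
import pytest
from scipy import signal as sps

import geom_oracles as oracle
from gaitbalance.errors import FilterParameterError, FlightPhaseError, GeometryError
from gaitbalance.geometry import (
    build_bos,
    com_bos_distance,
    comv_bos_displacement,
    evaluate_trial,
    lowpass_filter,
    polygon_area,
)
from gaitbalance.trial import FootTimeSeries, GaitTrial

SQUARE_20CM = [(-0.1, -0.1), (0.1, -0.1), (0.1, 0.1), (-0.1, 0.1)]


def _single_support_trial(outline, com_xy, velocity, n=60, fs=60.0):
    """Trial with one static foot and a straight-line CoM; event mid-series."""
    com = np.column_stack([
        com_xy[0] + velocity[0] * np.arange(n) / fs,
        com_xy[1] + velocity[1] * np.arange(n) / fs,
        np.full(n, 0.9),
    ])
    com[:, :2] -= velocity[None, :] * (30 / fs)  # CoM hits com_xy at frame 30
    foot = FootTimeSeries(outline=[np.asarray(outline)] * n,
                          contact=np.ones(n, dtype=bool))
    other = FootTimeSeries(outline=[np.asarray(outline) + 5.0] * n,
                           contact=np.zeros(n, dtype=bool))
    return GaitTrial(sampling_rate=fs, com_position=com, left_foot=foot,
                     right_foot=other, events=[(30, "left")])


class TestLowpassFilter:
    def test_dc_gain_is_unity(self):
        const = np.full(100, 3.7)
        np.testing.assert_allclose(lowpass_filter(const, fs=60.0), const)

    @pytest.mark.parametrize("freq,rtol", [(1.0, 0.01), (25.0, 0.05)])
    def test_sinusoid_gain_matches_analytic_two_pass_response(self, freq, rtol):
        """Steady-state amplitude ratio equals |H(f)|^2 of the designed filter."""
        fs = 60.0
        t = np.arange(0, 40.0, 1 / fs)
        x = np.sin(2 * math.pi * freq * t)
        y = lowpass_filter(x, fs=fs)
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        gain = np.sqrt(np.mean(y[mid] ** 2) / np.mean(x[mid] ** 2))
        b, a = sps.butter(4, 8.0 / (fs / 2), btype="low")
        _, h = sps.freqz(b, a, worN=[freq], fs=fs)
        assert gain == pytest.approx(abs(h[0]) ** 2, rel=rtol)

    def test_parameter_errors(self):
        with pytest.raises(FilterParameterError):
            lowpass_filter(np.zeros(100), fs=15.0)  # fs <= 2*cutoff
        with pytest.raises(FilterParameterError):
            lowpass_filter(np.zeros(5), fs=60.0)  # too short


class TestBuildBos:
    def test_single_support_is_the_foot_outline(self):
        rect = [(0, 0), (0.25, 0), (0.25, 0.10), (0, 0.10)]
        trial = _single_support_trial(np.asarray(rect), np.array([0.1, 0.05]),
                                      np.array([1.0, 0.0]))
        bos = build_bos(trial, 30)
        assert bos.area * 1e4 == pytest.approx(250.0)

    def test_double_support_hull_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            sq1 = np.array([(0, 0), (1, 0), (1, 1), (0, 1)], dtype=float)
            sq2 = sq1 + rng.uniform(-0.5, 0.5, 2) + np.array([0.3, 0.0])
            pts = np.vstack([sq1, sq2])
            hull_oracle = oracle.brute_force_hull(pts)
            n = 4
            foot_l = FootTimeSeries([sq1] * n, np.ones(n, bool))
            foot_r = FootTimeSeries([sq2] * n, np.ones(n, bool))
            trial = GaitTrial(60.0, np.zeros((n, 3)), foot_l, foot_r, [(1, "left")])
            bos = build_bos(trial, 1)
            assert bos.area == pytest.approx(oracle.shoelace_area(hull_oracle),
                                             rel=1e-9)
            # hull contains every footprint vertex
            from shapely.geometry import Point
            assert all(bos.covers(Point(*p)) for p in pts)

    def test_double_support_area_dominates_single_foot(self, rng):
        sq1 = np.array([(0, 0), (0.2, 0), (0.2, 0.1), (0, 0.1)])
        sq2 = sq1 + np.array([0.15, 0.3])
        n = 2
        foot_l = FootTimeSeries([sq1] * n, np.ones(n, bool))
        foot_r = FootTimeSeries([sq2] * n, np.array([False, True]))
        trial = GaitTrial(60.0, np.zeros((n, 3)), foot_l, foot_r, [(0, "left")])
        single = build_bos(trial, 0).area
        double = build_bos(trial, 1).area
        assert double >= single

    def test_flight_phase_raises(self):
        n = 2
        sq = np.array(SQUARE_20CM)
        feet = FootTimeSeries([sq] * n, np.zeros(n, bool))
        trial = GaitTrial(60.0, np.zeros((n, 3)), feet, feet, [(0, "left")])
        with pytest.raises(FlightPhaseError):
            build_bos(trial, 0)


class TestComBosDistance:
    def test_square_center_and_edge(self):
        d, inside = com_bos_distance((0.0, 0.0), SQUARE_20CM)
        assert d == pytest.approx(10.0, abs=1e-9)
        assert inside
        d_edge, _ = com_bos_distance((0.1, 0.0), SQUARE_20CM)
        assert d_edge == pytest.approx(0.0, abs=1e-9)

    def test_agrees_with_dense_boundary_sampling(self, rng):
        for _ in range(200):
            poly = oracle.random_convex_polygon(rng)
            p = rng.uniform(poly.min(axis=0) - 0.05, poly.max(axis=0) + 0.05)
            d_cm, inside = com_bos_distance(p, poly)
            d_oracle = oracle.min_distance_dense(p, poly) * 100.0
            assert abs(d_cm - d_oracle) < 1e-3
            assert inside == oracle.point_in_polygon(p, poly)

    def test_rigid_motion_invariance(self, rng):
        poly = oracle.random_convex_polygon(rng)
        p = oracle.random_interior_point(rng, poly)
        d0, _ = com_bos_distance(p, poly)
        for _ in range(20):
            ang = rng.uniform(0, 2 * math.pi)
            shift = rng.uniform(-5, 5, 2)
            R = np.array([[math.cos(ang), -math.sin(ang)],
                          [math.sin(ang), math.cos(ang)]])
            d1, _ = com_bos_distance(R @ p + shift, poly @ R.T + shift)
            assert d1 == pytest.approx(d0, rel=1e-9)

    def test_degenerate_polygon_raises(self):
        with pytest.raises(GeometryError):
            com_bos_distance((0, 0), [(0, 0), (1, 1)])


class TestComvBosDisplacement:
    def test_square_center_axis_and_diagonal(self):
        d, _ = comv_bos_displacement((0, 0), (1.0, 0.0), SQUARE_20CM)
        assert d == pytest.approx(10.0, abs=1e-9)
        d, _ = comv_bos_displacement((0, 0), (1.0, 1.0), SQUARE_20CM)
        assert d == pytest.approx(10.0 * math.sqrt(2), abs=1e-9)

    def test_agrees_with_ray_marching_and_dominates_min_distance(self, rng):
        for _ in range(150):
            poly = oracle.random_convex_polygon(rng)
            p = oracle.random_interior_point(rng, poly)
            ang = rng.uniform(0, 2 * math.pi)
            u = (math.cos(ang), math.sin(ang))
            d_cm, reason = comv_bos_displacement(p, u, poly)
            assert reason is None
            d_oracle = oracle.ray_march_distance(p, u, poly) * 100.0
            assert abs(d_cm - d_oracle) < 1e-3
            d_min, _ = com_bos_distance(p, poly)
            assert d_cm >= d_min - 1e-9

    def test_near_zero_velocity_flagged(self):
        d, reason = comv_bos_displacement((0, 0), (1e-6, 0), SQUARE_20CM)
        assert d is None and "velocity" in reason

    def test_outside_point_moving_away_flagged(self):
        d, reason = comv_bos_displacement((0.5, 0.0), (1.0, 0.0), SQUARE_20CM)
        assert d is None and "boundary" in reason

    def test_outside_point_reentering_measures_to_near_edge(self):
        d, reason = comv_bos_displacement((0.5, 0.0), (-1.0, 0.0), SQUARE_20CM)
        assert reason is None
        assert d == pytest.approx(40.0, abs=1e-9)


class TestPolygonArea:
    @pytest.mark.parametrize("poly,expected", [
        ([(0, 0), (1, 0), (1, 1), (0, 1)], 10_000.0),
        ([(0, 0), (3, 0), (0, 4)], 60_000.0),
    ])
    def test_analytic_cases(self, poly, expected):
        assert polygon_area(poly) == pytest.approx(expected, rel=1e-12)

    def test_matches_fan_triangulation_oracle(self, rng):
        for _ in range(50):
            poly = oracle.random_convex_polygon(rng, n_points=8)
            assert polygon_area(poly) == pytest.approx(
                oracle.fan_triangulation_area(poly) * 1e4, rel=1e-6
            )

    def test_self_intersecting_rejected(self):
        with pytest.raises(GeometryError):
            polygon_area([(0, 0), (1, 1), (1, 0), (0, 1)])


class TestEvaluateTrial:
    def test_single_event_square_support(self):
        trial = _single_support_trial(np.asarray(SQUARE_20CM),
                                      np.array([0.0, 0.0]),
                                      np.array([1.0, 0.0]))
        events, summary, outcome = evaluate_trial(trial, filter_on=False)
        assert summary["n_events"] == 1
        assert summary["com_bos"] == pytest.approx(10.0, abs=1e-6)
        assert summary["comv_bos"] == pytest.approx(10.0, abs=1e-6)
        assert summary["bos_area"] == pytest.approx(400.0, rel=1e-9)
        assert events[0].com_inside

    def test_filtering_smooth_trial_changes_little(self):
        """A band-limited (<2 Hz) trajectory passes the 8 Hz filter unchanged."""
        fs, n = 60.0, 240
        t = np.arange(n) / fs
        com = np.column_stack([
            0.02 * np.sin(2 * math.pi * 1.0 * t),
            0.01 * np.sin(2 * math.pi * 0.5 * t),
            np.full(n, 0.9),
        ])
        sq = np.asarray(SQUARE_20CM)
        foot = FootTimeSeries([sq] * n, np.ones(n, bool))
        other = FootTimeSeries([sq + 5.0] * n, np.zeros(n, bool))
        trial = GaitTrial(fs, com, foot, other, [(120, "left")])
        _, raw, _ = evaluate_trial(trial, filter_on=False)
        _, filt, _ = evaluate_trial(trial, filter_on=True)
        for key in ("com_bos", "comv_bos", "bos_area"):
            assert filt[key] == pytest.approx(raw[key], rel=0.01)

    def test_event_frame_out_of_range_raises(self):
        trial = _single_support_trial(np.asarray(SQUARE_20CM),
                                      np.array([0.0, 0.0]), np.array([1.0, 0.0]))
        trial.events = [(10_000, "left")]
        with pytest.raises(IndexError):
            evaluate_trial(trial)
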