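"""Feature extraction: kinematics, entropies, geometry, and invariances."""

import math

import numpy as np
import pandas as pd
import pytest

from handkin.kinematic_features import (
    FEATURE_NAMES,
    KEY_COLUMNS,
    HandwritingFeatureExtractor,
    KinematicSeries,
    count_slowdowns,
    derive_kinematics,
    extract_features,
    extract_features_table,
    pressure_features,
    shannon_entropy,
    stroke_geometry,
    temporal_features,
    velocity_features,
)
from handkin.pen_stream import PenSample, Stroke, ValidationError, segment_strokes

from conftest import make_record, make_stroke

T, F = True, False


class TestDeriveKinematics:
    def test_three_four_five_triangle(self):
        stroke = make_stroke([(0, 0), (3, 4)], [0, 10])
        kin = derive_kinematics(stroke)
        assert kin.v.tolist() == [500.0]  # 5 mm over 10 ms
        assert kin.vx.tolist() == [300.0] and kin.vy.tolist() == [400.0]
        assert kin.a.size == 0

    def test_stationary_pen(self):
        stroke = make_stroke([(2, 2)] * 4, [0, 10, 20, 30])
        kin = derive_kinematics(stroke)
        assert np.all(kin.v == 0) and np.all(kin.a == 0)

    def test_uniform_motion_has_zero_acceleration(self):
        pts = [(i * 1.0, 0.0) for i in range(6)]
        kin = derive_kinematics(make_stroke(pts, range(0, 60, 10)))
        assert np.allclose(kin.v, 100.0) and np.allclose(kin.a, 0.0)

    def test_duplicate_timestamps_rejected(self):
        stroke = make_stroke([(0, 0), (1, 0), (2, 0)], [0, 10, 10])
        with pytest.raises(ValidationError):
            derive_kinematics(stroke)

    def test_speed_decomposition(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(8, 2)) * 5
        kin = derive_kinematics(make_stroke(pts, range(0, 80, 10)))
        assert np.allclose(kin.v**2, kin.vx**2 + kin.vy**2)
        assert np.all(kin.v >= 0)
        assert len(kin.v) == 7 and len(kin.a) == 6


class TestShannonEntropy:
    def test_constant_series_is_zero(self):
        assert shannon_entropy([7, 7, 7, 7]) == 0.0

    def test_uniform_over_four_bins(self):
        values = np.repeat([0.0, 1.0, 2.0, 3.0], 4) + 0.1
        assert shannon_entropy(values, n_bins=4) == pytest.approx(2.0)

    def test_two_thirds_split(self):
        # p = (1/3, 2/3): H = 0.9183 bits
        assert shannon_entropy([1, 1, 2, 2, 2, 2], n_bins=2) == pytest.approx(0.918296, abs=1e-6)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            shannon_entropy([])

    def test_single_bin_is_zero(self):
        assert shannon_entropy([1.0, 2.0, 5.0], n_bins=1) == 0.0


class TestCountSlowdowns:
    @pytest.mark.parametrize(
        "series, expected",
        [
            ([1, 2, 3, 4], 0),          # monotone increasing
            ([10, 5, 10, 5], 2),        # two separate deceleration episodes
            ([3], 0),                   # no differences
            ([5, 4, 3, 2], 1),          # one long episode
            ([1, 1, 1], 0),             # plateau is not a slowdown
            ([3, 2, 2, 1], 2),          # plateau splits the episodes
        ],
    )
    def test_episode_counting(self, series, expected):
        assert count_slowdowns(series) == expected


class TestStrokeGeometry:
    def test_straight_horizontal_segment(self):
        geo = stroke_geometry(make_stroke([(0, 0), (10, 0)], [0, 10]))
        assert geo["single_stroke_length"] == pytest.approx(10.0)
        assert geo["horizontal_length"] == pytest.approx(10.0)
        assert geo["vertical_length"] == 0.0
        assert geo["tilt_angle"] == pytest.approx(0.0)

    def test_tilt_sign_follows_visual_up(self):
        # page y grows downward: decreasing y is visually "up" -> +45 degrees
        up = stroke_geometry(make_stroke([(0, 0), (5, -5)], [0, 10]))
        down = stroke_geometry(make_stroke([(0, 0), (5, 5)], [0, 10]))
        assert up["tilt_angle"] == pytest.approx(45.0)
        assert down["tilt_angle"] == pytest.approx(-45.0)

    def test_vertical_stroke_tilt_is_90(self):
        geo = stroke_geometry(make_stroke([(0, 0), (0, 7)], [0, 10]))
        assert geo["tilt_angle"] == pytest.approx(90.0)

    def test_l_shaped_path(self):
        geo = stroke_geometry(make_stroke([(0, 0), (3, 0), (3, 4)], [0, 10, 20]))
        assert geo["single_stroke_length"] == pytest.approx(7.0)
        assert geo["horizontal_length"] == pytest.approx(3.0)
        assert geo["vertical_length"] == pytest.approx(4.0)

    def test_sd_squares_to_variance(self):
        rng = np.random.default_rng(1)
        geo = stroke_geometry(make_stroke(rng.normal(size=(9, 2)), range(0, 90, 10)))
        assert geo["horizontal_length_sd"] ** 2 == pytest.approx(geo["horizontal_length_var"])
        assert geo["vertical_length_sd"] ** 2 == pytest.approx(geo["vertical_length_var"])


class TestPressureAndVelocityFeatures:
    def test_constant_pressure(self):
        stroke = make_stroke([(0, 0), (1, 0), (2, 0)], [0, 10, 20], pressure=100)
        feats = pressure_features(stroke)
        assert (feats["pressure_mean"], feats["pressure_var"],
                feats["pressure_sd"], feats["pressure_entropy"]) == (100.0, 0.0, 0.0, 0.0)

    def test_two_point_population_moments(self):
        stroke = make_stroke([(0, 0), (1, 0)], [0, 10], pressure=[100, 300])
        feats = pressure_features(stroke)
        assert feats["pressure_mean"] == 200.0
        assert feats["pressure_var"] == 10000.0
        assert feats["pressure_sd"] == 100.0

    def test_velocity_summary_example(self):
        kin = KinematicSeries(
            v=np.array([100.0, 200.0, 100.0]),
            vx=np.array([100.0, 200.0, 100.0]),
            vy=np.zeros(3),
            a=np.array([10000.0, -10000.0]),
            t_v=np.array([10, 20, 30]),
            t_a=np.array([20, 30]),
        )
        feats = velocity_features(kin)
        assert feats["speed_max"] == 200.0 and feats["speed_min"] == 100.0
        assert feats["average_speed"] == pytest.approx(133.3333, abs=1e-3)
        assert feats["velocity_slowdowns"] == 1

    def test_constant_velocity_degenerate_stats(self):
        kin = derive_kinematics(make_stroke([(i, 0) for i in range(5)], range(0, 50, 10)))
        feats = velocity_features(kin)
        assert feats["speed_var"] == 0.0
        assert feats["velocity_slowdowns"] == 0
        assert feats["velocity_entropy"] == 0.0
        assert feats["speed_min"] <= feats["average_speed"] <= feats["speed_max"]


class TestTemporalFeatures:
    def test_contact_time_and_air_time(self):
        pattern = [T] * 10 + [F] * 6 + [T] * 6
        record = make_record(pattern)
        strokes = segment_strokes(record)
        durations, air = temporal_features(record, strokes)
        assert durations.tolist() == [90.0, 50.0]
        assert air.tolist() == [0.0, 70.0]  # first stroke: 0 by convention


class TestExtractFeatures:
    def test_schema_and_replication(self):
        pattern = ([T, T, T] + [F]) * 5
        record = make_record(pattern, task_score=2)
        table = extract_features(record)
        assert list(table.columns) == KEY_COLUMNS + FEATURE_NAMES
        assert len(table) == 5
        assert set(table["stroke_count"]) == {5.0}
        assert set(table["task_score"]) == {2.0}

    def test_task_score_locality(self):
        pattern = [T, T, T, F, T, T, T]
        r1 = make_record(pattern, task_score=0)
        r2 = make_record(pattern, task_score=2)
        t1, t2 = extract_features(r1), extract_features(r2)
        others = [c for c in FEATURE_NAMES if c != "task_score"]
        pd.testing.assert_frame_equal(t1[others], t2[others])
        assert set(t2["task_score"]) == {2.0}

    def test_record_without_strokes_yields_empty_schema(self):
        table = extract_features(make_record([F, F, F]))
        assert table.empty and list(table.columns) == KEY_COLUMNS + FEATURE_NAMES

    def test_time_shift_invariance(self):
        pattern = [T, T, T, F, F, T, T, T, T]
        base = make_record(pattern)
        shifted = make_record(pattern)
        shifted.samples = [
            PenSample(x=s.x, y=s.y, t=s.t + 5000, pressure=s.pressure, on_paper=s.on_paper)
            for s in base.samples
        ]
        pd.testing.assert_frame_equal(extract_features(base), extract_features(shifted))

    @pytest.mark.parametrize("c", [2.0, 0.5, 10.0])
    def test_scale_equivariance(self, c):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(12, 2)).cumsum(axis=0)
        times = range(0, 120, 10)
        base = stroke_features_of(make_stroke(pts, times))
        scaled = stroke_features_of(make_stroke(pts * c, times))
        length_speed = [
            "single_stroke_length", "horizontal_length", "vertical_length",
            "average_speed", "speed_max", "speed_min", "speed_sd",
            "horizontal_velocity_max", "vertical_velocity_max",
        ]
        for name in length_speed:
            assert scaled[name] == pytest.approx(c * base[name], rel=1e-9), name
        for name in ["speed_var", "horizontal_length_var", "vertical_length_var"]:
            assert scaled[name] == pytest.approx(c * c * base[name], rel=1e-9), name
        for name in ["tilt_angle", "pressure_entropy", "velocity_entropy",
                     "acceleration_entropy", "velocity_slowdowns", "acceleration_slowdowns"]:
            assert scaled[name] == pytest.approx(base[name], abs=1e-9), name


def stroke_features_of(stroke):
    feats = {}
    feats.update(pressure_features(stroke))
    feats.update(stroke_geometry(stroke))
    feats.update(velocity_features(derive_kinematics(stroke)))
    return feats


# ---------------------------------------------------------------------------
# brute-force oracle on tiny strokes


def brute_force_features(stroke, n_bins=16):
    """Plain-Python recomputation of the per-stroke features from definitions."""
    xs = [s.x for s in stroke.samples]
    ys = [s.y for s in stroke.samples]
    ts = [s.t for s in stroke.samples]
    ps = [float(s.pressure) for s in stroke.samples]
    n = len(xs)

    def mean(v):
        return sum(v) / len(v)

    def pvar(v):
        m = mean(v)
        return sum((x - m) ** 2 for x in v) / len(v)

    def entropy(v):
        lo, hi = min(v), max(v)
        if lo == hi:
            return 0.0
        counts = [0] * n_bins
        for x in v:
            k = min(int((x - lo) * n_bins / (hi - lo)), n_bins - 1)
            counts[k] += 1
        return -sum(c / len(v) * math.log2(c / len(v)) for c in counts if c)

    def slowdowns(v):
        count, in_run = 0, False
        for a, b in zip(v[:-1], v[1:]):
            if b < a:
                if not in_run:
                    count += 1
                in_run = True
            else:
                in_run = False
        return count

    vx = [(xs[i + 1] - xs[i]) / ((ts[i + 1] - ts[i]) / 1000) for i in range(n - 1)]
    vy = [(ys[i + 1] - ys[i]) / ((ts[i + 1] - ts[i]) / 1000) for i in range(n - 1)]
    v = [math.hypot(a, b) for a, b in zip(vx, vy)]
    acc = [(v[i + 1] - v[i]) / ((ts[i + 2] - ts[i + 1]) / 1000) for i in range(len(v) - 1)]
    adx = [abs(xs[i + 1] - xs[i]) for i in range(n - 1)]
    ady = [abs(ys[i + 1] - ys[i]) for i in range(n - 1)]
    avx, avy = [abs(u) for u in vx], [abs(u) for u in vy]

    # principal axis via explicit 2x2 eigendecomposition on (x, -y)
    mx, my = mean(xs), mean([-yy for yy in ys])
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((-yy - my) ** 2 for yy in ys)
    sxy = sum((x - mx) * (-yy - my) for x, yy in zip(xs, ys))
    if sxx == syy == 0 and sxy == 0:
        tilt = 0.0
    else:
        lam = (sxx + syy) / 2 + math.sqrt(((sxx - syy) / 2) ** 2 + sxy**2)
        if abs(sxy) > 1e-15:
            tilt = math.degrees(math.atan2(lam - sxx, sxy))
        else:
            tilt = 0.0 if sxx >= syy else 90.0
        if tilt <= -90:
            tilt += 180
        elif tilt > 90:
            tilt -= 180

    return {
        "pressure_mean": mean(ps), "pressure_var": pvar(ps),
        "pressure_sd": math.sqrt(pvar(ps)), "pressure_entropy": entropy(ps),
        "single_stroke_length": sum(math.hypot(a, b) for a, b in zip(
            [xs[i + 1] - xs[i] for i in range(n - 1)],
            [ys[i + 1] - ys[i] for i in range(n - 1)])),
        "horizontal_length": sum(adx), "vertical_length": sum(ady),
        "horizontal_length_var": pvar(adx), "horizontal_length_sd": math.sqrt(pvar(adx)),
        "vertical_length_var": pvar(ady), "vertical_length_sd": math.sqrt(pvar(ady)),
        "tilt_angle": tilt,
        "average_speed": mean(v), "horizontal_average_speed": mean(avx),
        "vertical_average_speed": mean(avy),
        "speed_max": max(v), "speed_min": min(v),
        "speed_var": pvar(v), "speed_sd": math.sqrt(pvar(v)),
        "velocity_entropy": entropy(v), "velocity_slowdowns": slowdowns(v),
        "horizontal_velocity_max": max(avx), "horizontal_velocity_min": min(avx),
        "vertical_velocity_max": max(avy), "vertical_velocity_min": min(avy),
        "horizontal_velocity_var": pvar(avx), "horizontal_velocity_sd": math.sqrt(pvar(avx)),
        "vertical_velocity_var": pvar(avy), "vertical_velocity_sd": math.sqrt(pvar(avy)),
        "acceleration_entropy": entropy(acc) if acc else 0.0,
        "acceleration_slowdowns": slowdowns(acc),
    }


@pytest.mark.parametrize("n_samples", [2, 3, 4, 5, 6])
def test_oracle_equivalence_on_tiny_strokes(n_samples):
    rng = np.random.default_rng(100 + n_samples)
    for _ in range(25):
        pts = np.round(rng.normal(scale=4.0, size=(n_samples, 2)), 3)
        pressures = rng.integers(1, 1025, size=n_samples)
        stroke = make_stroke(pts, range(0, n_samples * 10, 10), pressure=pressures)
        got = stroke_features_of(stroke)
        want = brute_force_features(stroke)
        for name, expected in want.items():
            assert got[name] == pytest.approx(expected, rel=1e-9, abs=1e-9), name


class TestTransformer:
    def test_fit_transform_matches_function(self, small_cohort, small_features):
        ext = HandwritingFeatureExtractor()
        table = ext.fit_transform(small_cohort)
        pd.testing.assert_frame_equal(table, small_features)
        assert ext.n_features_out_ == 35

    def test_sklearn_param_interface(self):
        from sklearn.base import clone

        ext = HandwritingFeatureExtractor(n_bins=8)
        ext2 = clone(ext)
        assert ext2.get_params()["n_bins"] == 8
        ext2.set_params(smooth=True)
        assert ext2.smooth is True

    def test_invalid_bins_rejected(self):
        with pytest.raises(ValueError):
            HandwritingFeatureExtractor(n_bins=0).fit([])

    def test_smoothing_changes_kinematics_only_lengths(self):
        record = make_record([T] * 8)
        rough = extract_features(record)
        smooth = extract_features(record, smooth=True)
        # a straight constant-speed stroke is unchanged by smoothing
        assert rough["average_speed"].iloc[0] == pytest.approx(smooth["average_speed"].iloc[0])
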