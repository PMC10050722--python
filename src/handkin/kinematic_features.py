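"""The 35 per-stroke handwriting characteristics.

Each segmented stroke yields one feature vector: four pressure statistics,
two timing values, eight geometry values (lengths, dispersions, tilt),
nineteen velocity/acceleration statistics (including Shannon entropies and
deceleration-episode counts), plus the task score and the task's stroke
count replicated onto every stroke.  Strokes — not participants — are the
analysis unit, so per-task annotations repeat across a task's strokes.

Conventions
-----------
* Velocities are finite differences of position over the recorded
  timestamps (converted to seconds); no smoothing by default, an optional
  centered 3-sample moving average of position behind a flag.
* Horizontal/vertical "average speed" and the per-component extrema and
  dispersions use absolute component velocities |vx|, |vy| — signed means
  would cancel on back-and-forth strokes.
* Entropies are Shannon entropies in bits over equal-width histograms
  (default 16 bins over [min, max]); a constant series has entropy 0.
* A "slowdown" is a deceleration episode: one maximal run of consecutive
  negative first differences.
* Moments are population (divide-by-n) by default; sample moments behind a
  flag.
* Tilt is the signed angle in (-90, 90] degrees of the first principal axis
  of the stroke's point cloud against the horizontal, computed in y-up
  terms (page y points down, so y is negated first): a stroke rising to the
  right has positive tilt.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .pen_stream import Stroke, ValidationError, WritingRecord, in_air_intervals, segment_strokes

logger = logging.getLogger(__name__)

#: Canonical feature names in characteristic-table row order 1..35.
ROW_TO_NAME = {
    1: "pressure_mean", 2: "pressure_entropy", 3: "time_in_air",
    4: "pressure_var", 5: "pressure_sd",
    6: "tilt_angle", 7: "single_stroke_time",
    8: "horizontal_length", 9: "vertical_length", 10: "single_stroke_length",
    11: "horizontal_length_var", 12: "horizontal_length_sd",
    13: "vertical_length_var", 14: "vertical_length_sd",
    15: "average_speed", 16: "horizontal_average_speed", 17: "vertical_average_speed",
    18: "speed_max", 19: "speed_min", 20: "velocity_entropy", 21: "velocity_slowdowns",
    22: "speed_var", 23: "speed_sd",
    24: "horizontal_velocity_max", 25: "horizontal_velocity_min",
    26: "vertical_velocity_max", 27: "vertical_velocity_min",
    28: "horizontal_velocity_var", 29: "horizontal_velocity_sd",
    30: "vertical_velocity_var", 31: "vertical_velocity_sd",
    32: "acceleration_entropy", 33: "acceleration_slowdowns",
    34: "task_score", 35: "stroke_count",
}

FEATURE_NAMES = [ROW_TO_NAME[i] for i in range(1, 36)]

#: The objective characteristics: everything except the (subjective) task
#: score and the per-task stroke count.
OBJECTIVE_FEATURES = [ROW_TO_NAME[i] for i in range(1, 34)]

#: Key columns carried alongside the features in extracted tables.
KEY_COLUMNS = ["participant_id", "group", "task_id", "stroke_index", "moca_bc", "mmse"]

DEFAULT_N_BINS = 16


@dataclass(frozen=True)
class KinematicSeries:
    """Finite-difference kinematics of one stroke.

    ``v``/``vx``/``vy`` have one value per sample interval (timestamped at
    the interval end, ``t_v`` in ms); ``a`` differences consecutive speeds
    over their timestamp spacing.
    """

    v: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    a: np.ndarray
    t_v: np.ndarray
    t_a: np.ndarray


def _moving_average3(x: np.ndarray) -> np.ndarray:
    if len(x) < 3:
        return x
    out = x.astype(float).copy()
    out[1:-1] = (x[:-2] + x[1:-1] + x[2:]) / 3.0
    return out


def derive_kinematics(stroke: Stroke, smooth: bool = False) -> KinematicSeries:
    """Velocity and acceleration series of a stroke.

    vx_i = dx_i/dt_i and vy_i = dy_i/dt_i over consecutive samples (dt in
    seconds), v = sqrt(vx^2 + vy^2); a differences consecutive speeds over
    the spacing of their timestamps.  Duplicate timestamps are invalid.
    """
    x, y, t, _ = stroke.arrays()
    if len(t) < 2:
        raise ValidationError("kinematics need a stroke of >= 2 samples")
    dt = np.diff(t) / 1000.0
    if np.any(dt <= 0):
        raise ValidationError("duplicate or decreasing timestamps within stroke")
    if smooth:
        x, y = _moving_average3(x), _moving_average3(y)
    vx = np.diff(x) / dt
    vy = np.diff(y) / dt
    v = np.hypot(vx, vy)
    t_v = t[1:]
    if len(v) >= 2:
        dtv = np.diff(t_v) / 1000.0
        a = np.diff(v) / dtv
        t_a = t_v[1:]
    else:
        a = np.array([])
        t_a = np.array([], dtype=t.dtype)
    return KinematicSeries(v=v, vx=vx, vy=vy, a=a, t_v=t_v, t_a=t_a)


def shannon_entropy(values, n_bins: int = DEFAULT_N_BINS) -> float:
    """Shannon entropy (bits) of an equal-width histogram of ``values``.

    Bins span [min, max]; only occupied bins contribute.  A constant series
    has zero entropy; an empty series is an error.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot compute the entropy of an empty series")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    lo, hi = float(arr.min()), float(arr.max())
    if lo == hi:
        return 0.0
    # equal-width binning over [lo, hi], top edge inclusive
    idx = np.minimum((arr - lo) * (n_bins / (hi - lo)), n_bins - 1).astype(np.intp)
    counts = np.bincount(idx, minlength=n_bins)
    p = counts[counts > 0] / arr.size
    return float(-np.sum(p * np.log2(p)))


def count_slowdowns(series) -> int:
    """Number of deceleration episodes: maximal runs of decreasing values."""
    arr = np.asarray(series, dtype=float)
    if arr.size < 2:
        return 0
    neg = np.diff(arr) < 0
    if not neg.any():
        return 0
    starts = np.diff(neg.astype(np.int8)) == 1
    return int(neg[0]) + int(np.count_nonzero(starts))


def _moments(arr: np.ndarray, sample: bool = False) -> tuple[float, float, float]:
    """(mean, variance, sd) with population (ddof=0) or sample (ddof=1) scaling."""
    ddof = 1 if sample else 0
    if arr.size <= ddof:
        return float(arr.mean()) if arr.size else math.nan, 0.0, 0.0
    var = float(arr.var(ddof=ddof))
    return float(arr.mean()), var, math.sqrt(var)


def stroke_geometry(stroke: Stroke, sample_moments: bool = False) -> dict[str, float]:
    """Lengths, per-axis displacement dispersions, and tilt of one stroke.

    Path length sums Euclidean segment lengths; horizontal/vertical lengths
    sum |dx| and |dy|; their variance/SD are taken over the per-sample
    absolute displacements within the stroke.  Tilt is the principal-axis
    angle described in the module docstring.
    """
    x, y, _, _ = stroke.arrays()
    return _geometry_stats(x, y, sample_moments)


def _principal_tilt(x: np.ndarray, y_up: np.ndarray) -> float:
    """Signed angle (deg) of the first principal axis in (-90, 90].

    Closed form for a 2x2 covariance: the major axis of [[sxx, sxy],
    [sxy, syy]] lies at angle atan2(2 sxy, sxx - syy) / 2.
    """
    xc = x - x.mean()
    yc = y_up - y_up.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    sxy = float(xc @ yc)
    if sxx == 0.0 and syy == 0.0 and sxy == 0.0:
        return 0.0
    tilt = math.degrees(0.5 * math.atan2(2.0 * sxy, sxx - syy))
    if tilt <= -90.0:
        tilt += 180.0
    elif tilt > 90.0:
        tilt -= 180.0
    return tilt


def _geometry_stats(x: np.ndarray, y: np.ndarray, sample_moments: bool) -> dict[str, float]:
    dx, dy = np.diff(x), np.diff(y)
    abs_dx, abs_dy = np.abs(dx), np.abs(dy)
    _, h_var, h_sd = _moments(abs_dx, sample_moments)
    _, v_var, v_sd = _moments(abs_dy, sample_moments)
    tilt = _principal_tilt(x, -y)  # flip page-down y into math convention
    return {
        "single_stroke_length": float(np.hypot(dx, dy).sum()),
        "horizontal_length": float(abs_dx.sum()),
        "vertical_length": float(abs_dy.sum()),
        "horizontal_length_var": h_var,
        "horizontal_length_sd": h_sd,
        "vertical_length_var": v_var,
        "vertical_length_sd": v_sd,
        "tilt_angle": tilt,
    }


def pressure_features(
    stroke: Stroke, n_bins: int = DEFAULT_N_BINS, sample_moments: bool = False
) -> dict[str, float]:
    """Mean, variance, SD and entropy of the stroke's pressure series."""
    _, _, _, p = stroke.arrays()
    return _pressure_stats(p, n_bins, sample_moments)


def _pressure_stats(p: np.ndarray, n_bins: int, sample_moments: bool) -> dict[str, float]:
    mean, var, sd = _moments(p, sample_moments)
    return {
        "pressure_mean": mean,
        "pressure_var": var,
        "pressure_sd": sd,
        "pressure_entropy": shannon_entropy(p, n_bins),
    }


def velocity_features(
    kin: KinematicSeries, n_bins: int = DEFAULT_N_BINS, sample_moments: bool = False
) -> dict[str, float]:
    """Speed, component-speed, entropy and slowdown statistics (rows 15-33).

    A two-sample stroke has a single velocity value and no acceleration;
    its acceleration entropy and slowdown count are 0 by convention.
    """
    v, avx, avy = kin.v, np.abs(kin.vx), np.abs(kin.vy)
    _, v_var, v_sd = _moments(v, sample_moments)
    _, hx_var, hx_sd = _moments(avx, sample_moments)
    _, vy_var, vy_sd = _moments(avy, sample_moments)
    return {
        "average_speed": float(v.mean()),
        "horizontal_average_speed": float(avx.mean()),
        "vertical_average_speed": float(avy.mean()),
        "speed_max": float(v.max()),
        "speed_min": float(v.min()),
        "speed_var": v_var,
        "speed_sd": v_sd,
        "velocity_entropy": shannon_entropy(v, n_bins),
        "velocity_slowdowns": count_slowdowns(v),
        "horizontal_velocity_max": float(avx.max()),
        "horizontal_velocity_min": float(avx.min()),
        "horizontal_velocity_var": hx_var,
        "horizontal_velocity_sd": hx_sd,
        "vertical_velocity_max": float(avy.max()),
        "vertical_velocity_min": float(avy.min()),
        "vertical_velocity_var": vy_var,
        "vertical_velocity_sd": vy_sd,
        "acceleration_entropy": shannon_entropy(kin.a, n_bins) if kin.a.size else 0.0,
        "acceleration_slowdowns": count_slowdowns(kin.a),
    }


def temporal_features(
    record: WritingRecord, strokes: list[Stroke]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-stroke contact time and preceding in-air time (ms).

    The first stroke's in-air time is 0 by convention (nothing precedes it).
    """
    durations = np.array([s.duration_ms for s in strokes], dtype=float)
    air = np.zeros(len(strokes))
    if len(strokes) >= 2:
        air[1:] = in_air_intervals(record, strokes)
    return durations, air


def extract_features(
    record: WritingRecord,
    n_bins: int = DEFAULT_N_BINS,
    smooth: bool = False,
    sample_moments: bool = False,
) -> pd.DataFrame:
    """One feature vector per stroke of a record.

    Returns a DataFrame with :data:`KEY_COLUMNS` followed by the 35
    :data:`FEATURE_NAMES`.  The per-task values (task score, stroke count)
    are replicated onto every stroke.  A record with no segmentable stroke
    yields an empty frame with the full schema and a logged warning.
    """
    rows = _feature_rows(record, n_bins, smooth, sample_moments)
    return pd.DataFrame(rows, columns=KEY_COLUMNS + FEATURE_NAMES)


def _feature_rows(
    record: WritingRecord, n_bins: int, smooth: bool, sample_moments: bool
) -> list[dict]:
    strokes = segment_strokes(record)
    if not strokes:
        logger.warning(
            "record %s/task %s has no segmentable strokes",
            record.participant_id, record.task_id,
        )
        return []
    durations, air = temporal_features(record, strokes)
    rows = []
    for i, stroke in enumerate(strokes):
        kin = derive_kinematics(stroke, smooth=smooth)
        x, y, _, p = stroke.arrays()
        feats: dict[str, float] = {}
        feats.update(_pressure_stats(p, n_bins, sample_moments))
        feats.update(_geometry_stats(x, y, sample_moments))
        feats.update(velocity_features(kin, n_bins, sample_moments))
        feats["single_stroke_time"] = float(durations[i])
        feats["time_in_air"] = float(air[i])
        feats["task_score"] = float(record.task_score)
        feats["stroke_count"] = float(len(strokes))
        row = {
            "participant_id": record.participant_id,
            "group": record.group,
            "task_id": record.task_id,
            "stroke_index": stroke.stroke_index,
            "moca_bc": record.moca_bc,
            "mmse": record.mmse,
        }
        row.update({name: feats[name] for name in FEATURE_NAMES})
        rows.append(row)
    return rows


def extract_features_table(
    records,
    n_bins: int = DEFAULT_N_BINS,
    smooth: bool = False,
    sample_moments: bool = False,
) -> pd.DataFrame:
    """Concatenated feature table over many records (one row per stroke)."""
    rows: list[dict] = []
    for r in records:
        rows.extend(_feature_rows(r, n_bins, smooth, sample_moments))
    return pd.DataFrame(rows, columns=KEY_COLUMNS + FEATURE_NAMES)


class HandwritingFeatureExtractor(BaseEstimator, TransformerMixin):
    """sklearn-style transformer: writing records -> per-stroke feature table.

    Parameters
    ----------
    n_bins : int
        Histogram bins for the entropy features.
    smooth : bool
        Apply a centered 3-sample moving average to positions before
        differencing.
    sample_moments : bool
        Use sample (ddof=1) instead of population moments.

    Examples
    --------
    >>> extractor = HandwritingFeatureExtractor()
    >>> table = extractor.fit_transform(records)   # doctest: +SKIP
    """

    def __init__(self, n_bins: int = DEFAULT_N_BINS, smooth: bool = False,
                 sample_moments: bool = False):
        self.n_bins = n_bins
        self.smooth = smooth
        self.sample_moments = sample_moments

    def fit(self, X, y=None):
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        self.feature_names_ = list(FEATURE_NAMES)
        self.n_features_out_ = len(FEATURE_NAMES)
        return self

    def transform(self, X) -> pd.DataFrame:
        return extract_features_table(
            X, n_bins=self.n_bins, smooth=self.smooth, sample_moments=self.sample_moments
        )

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)
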