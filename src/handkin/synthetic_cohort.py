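"""Synthetic AD-like / control-like pen-stream cohorts.

Generates digital-pen recordings whose group contrasts mirror what is
reported for Alzheimer's handwriting: the patient-like profile writes more
slowly, presses harder and less steadily, pauses longer in the air, uses
more strokes, and shows more positional tremor than the control-like
profile.  Every distributional choice is owned by a :class:`GroupProfile`,
so two identical profiles generate exchangeable groups — the null case that
downstream screening and classification are tested against.

Strokes follow stylized task templates (crosses, intersecting pentagons,
word-like zigzags): the kinematic features depend on trajectory dynamics,
not on glyph identity, so legible Chinese characters are not required.

Randomness comes from numpy's seeded PCG64 generators, with one substream
per (seed, group, participant, task) so cohorts are bit-reproducible and
order-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .pen_stream import (
    DEFAULT_SAMPLE_RATE_HZ,
    PRESSURE_LEVELS,
    PenSample,
    Stroke,
    TASK_IDS,
    WritingRecord,
)


class ConfigurationError(ValueError):
    """A generator profile or cohort configuration violates an invariant."""


#: Mean of the quick (non-hesitation) inter-stroke transition, ms.
QUICK_GAP_MEAN_MS = 150.0

#: Path length (mm) after which the writing speed is redrawn within a
#: stroke.  Re-drawing every few millimetres emulates the natural
#: within-stroke velocity modulation of handwriting, so per-stroke speed
#: maxima and dispersions scale with the profile's speed distribution.
SPEED_SEGMENT_MM = 3.0


@dataclass
class GroupProfile:
    """Generative writing profile for one diagnostic group.

    Parameters
    ----------
    speed_mean, speed_cv :
        Mean and coefficient of variation of the per-segment writing speed
        (mm/s), drawn log-normally for positivity.
    pressure_mean, pressure_sd :
        Per-sample tip-force draw (sensor levels), clamped normal.
    pause_rate :
        Expected number of deliberate (long) in-air hesitation pauses per
        task; remaining inter-stroke gaps are quick transitions.
    pause_mean_ms :
        Mean duration of a deliberate in-air pause (exponential).
    stroke_count_mean, stroke_count_sd :
        Strokes per task, rounded normal, at least 1.
    tremor_sd :
        Positional jitter (mm) added to every on-paper sample.
    score_dist :
        Per task id, a mapping score -> probability.
    moca_mean, moca_sd, mmse_mean, mmse_sd :
        Cognitive reference scores (0-30 scales), rounded clipped normal.
    male_fraction, age_mean, age_sd, education_mean, education_sd :
        Demographic annotation distributions.
    """

    speed_mean: float
    speed_cv: float
    pressure_mean: float
    pressure_sd: float
    pause_rate: float
    pause_mean_ms: float
    stroke_count_mean: float
    stroke_count_sd: float
    tremor_sd: float
    score_dist: dict[int, dict[int, float]]
    moca_mean: float
    moca_sd: float
    mmse_mean: float
    mmse_sd: float
    male_fraction: float = 0.44
    age_mean: float = 76.0
    age_sd: float = 8.0
    education_mean: float = 8.0
    education_sd: float = 3.5

    def validate(self) -> None:
        positive = {
            "speed_mean": self.speed_mean,
            "pressure_mean": self.pressure_mean,
            "pause_mean_ms": self.pause_mean_ms,
            "stroke_count_mean": self.stroke_count_mean,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ConfigurationError(f"{name} must be positive, got {value}")
        for name, value in (
            ("speed_cv", self.speed_cv), ("pressure_sd", self.pressure_sd),
            ("tremor_sd", self.tremor_sd), ("pause_rate", self.pause_rate),
            ("stroke_count_sd", self.stroke_count_sd),
        ):
            if value < 0:
                raise ConfigurationError(f"{name} must be non-negative, got {value}")
        if self.pressure_mean + 4 * self.pressure_sd > PRESSURE_LEVELS:
            raise ConfigurationError(
                "pressure_mean + 4*pressure_sd exceeds the "
                f"{PRESSURE_LEVELS}-level sensor scale"
            )
        for task, dist in self.score_dist.items():
            if task not in TASK_IDS:
                raise ConfigurationError(f"score_dist has unknown task id {task}")
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"score_dist for task {task} does not sum to 1")


@dataclass
class CohortConfig:
    """Cohort composition and acquisition settings."""

    n_ad: int
    n_hc: int
    tasks: tuple[int, ...] = TASK_IDS
    ad_profile: GroupProfile | None = None
    hc_profile: GroupProfile | None = None
    seed: int = 0
    sample_rate: float = DEFAULT_SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        if self.ad_profile is None or self.hc_profile is None:
            ad, hc = default_profiles()
            self.ad_profile = self.ad_profile or ad
            self.hc_profile = self.hc_profile or hc

    def validate(self) -> None:
        if self.n_ad < 0 or self.n_hc < 0:
            raise ConfigurationError("cohort counts must be non-negative")
        if self.sample_rate <= 0:
            raise ConfigurationError("sample_rate must be positive")
        for task in self.tasks:
            if task not in TASK_IDS:
                raise ConfigurationError(f"unknown task id {task}")
        self.ad_profile.validate()
        self.hc_profile.validate()

    def profile_for(self, group: str) -> GroupProfile:
        return self.ad_profile if group == "AD" else self.hc_profile


def default_profiles() -> tuple[GroupProfile, GroupProfile]:
    """Shipped AD-like and control-like profiles.

    Directions (AD vs HC): slower speed, higher and noisier pressure, more
    and longer in-air pauses, more strokes, more tremor, lower task scores,
    lower MoCA-BC/MMSE.  Magnitudes are set to plausible elderly-handwriting
    scales (speeds around 10-15 mm/s, pressure around 580-650 of 1024,
    deliberate pauses of 0.6-1.2 s).
    """
    common_scores_hc = {1: {2: 0.85, 1: 0.15}, 2: {3: 0.8, 2: 0.2},
                        3: {3: 0.8, 2: 0.15, 1: 0.05},
                        4: {10: 0.6, 9: 0.25, 8: 0.15}}
    common_scores_ad = {1: {2: 0.35, 1: 0.45, 0: 0.2}, 2: {3: 0.3, 2: 0.35, 1: 0.25, 0: 0.1},
                        3: {3: 0.3, 2: 0.35, 1: 0.25, 0: 0.1},
                        4: {10: 0.15, 9: 0.2, 8: 0.25, 7: 0.2, 6: 0.2}}
    ad = GroupProfile(
        speed_mean=10.0, speed_cv=0.5,
        pressure_mean=650.0, pressure_sd=90.0,
        pause_rate=3.0, pause_mean_ms=1200.0,
        stroke_count_mean=7.5, stroke_count_sd=1.5,
        tremor_sd=0.02,
        score_dist=common_scores_ad,
        moca_mean=14.88, moca_sd=4.27, mmse_mean=18.21, mmse_sd=4.05,
        male_fraction=0.441, age_mean=77.15, age_sd=10.5,
        education_mean=7.79, education_sd=3.4,
    )
    hc = GroupProfile(
        speed_mean=15.0, speed_cv=0.4,
        pressure_mean=580.0, pressure_sd=70.0,
        pause_rate=1.5, pause_mean_ms=600.0,
        stroke_count_mean=6.0, stroke_count_sd=1.5,
        tremor_sd=0.008,
        score_dist=common_scores_hc,
        moca_mean=28.93, moca_sd=1.64, mmse_mean=27.93, mmse_sd=1.64,
        male_fraction=0.444, age_mean=74.78, age_sd=10.0,
        education_mean=8.91, education_sd=3.9,
    )
    return ad, hc


# ---------------------------------------------------------------------------
# task templates


def _pentagon(cx: float, cy: float, r: float, phase: float = -math.pi / 2) -> np.ndarray:
    angles = phase + 2 * math.pi * np.arange(6) / 5  # closed: first vertex repeated
    return np.column_stack([cx + r * np.cos(angles), cy + r * np.sin(angles)])


def _zigzag(x0: float, y0: float, n_seg: int = 3, w: float = 3.0, h: float = 5.0) -> np.ndarray:
    pts = [(x0 + i * w, y0 + (h if i % 2 else 0.0)) for i in range(n_seg + 1)]
    return np.asarray(pts, dtype=float)


def task_templates(task_id: int) -> list[np.ndarray]:
    """Stylized stroke polylines (mm, page coordinates) for one task.

    Task 1: a cross and an X (connect fixed points); task 2: two
    intersecting pentagons; tasks 3-4: word-like zigzag stroke groups of
    increasing length.
    """
    if task_id == 1:
        return [
            np.array([[15.0, 30.0], [15.0, 42.0]]),   # cross, vertical bar
            np.array([[9.0, 36.0], [21.0, 36.0]]),    # cross, horizontal bar
            np.array([[35.0, 30.0], [45.0, 42.0]]),   # X, falling diagonal
            np.array([[45.0, 30.0], [35.0, 42.0]]),   # X, rising diagonal
        ]
    if task_id == 2:
        return [_pentagon(70.0, 60.0, 9.0), _pentagon(82.0, 66.0, 9.0, phase=math.pi / 2)]
    if task_id == 3:
        return [_zigzag(20.0 + 12.0 * k, 90.0, n_seg=3) for k in range(6)]
    if task_id == 4:
        return [_zigzag(15.0 + 10.0 * k, 120.0, n_seg=3, w=2.5, h=4.0) for k in range(10)]
    raise ConfigurationError(f"unknown task id {task_id}")


# ---------------------------------------------------------------------------
# generation


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def generate_stroke(
    profile: GroupProfile,
    template: np.ndarray,
    rng: np.random.Generator,
    sample_rate: float = DEFAULT_SAMPLE_RATE_HZ,
    start_t: int = 0,
    stroke_index: int = 0,
) -> Stroke:
    """Trace one template polyline into a sampled on-paper stroke.

    Per-segment speeds are log-normal with the profile's mean/CV; positions
    are arc-length interpolated at the fixed sampling interval, then
    jittered with N(0, tremor_sd) noise; pressure is a clamped normal draw
    per sample (at least 1, so the on-paper invariant holds).
    """
    profile.validate()
    template = np.asarray(template, dtype=float)
    if template.ndim != 2 or template.shape[0] < 2 or template.shape[1] != 2:
        raise ConfigurationError("template must be a polyline of >= 2 (x, y) vertices")

    seg = np.diff(template, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    keep = seg_len > 0
    if not np.any(keep):
        raise ConfigurationError("template has zero total length")
    verts = np.vstack([template[:1], template[1:][keep]])
    # subdivide so speed is redrawn about every SPEED_SEGMENT_MM of path
    parts = [verts[:1]]
    for a, b in zip(verts[:-1], verts[1:]):
        n_sub = max(1, int(math.ceil(np.hypot(*(b - a)) / SPEED_SEGMENT_MM)))
        frac = np.arange(1, n_sub + 1)[:, None] / n_sub
        parts.append(a + frac * (b - a))
    verts = np.vstack(parts)
    seg = np.diff(verts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])

    if profile.speed_cv > 0:
        mu, sigma = _lognormal_params(profile.speed_mean, profile.speed_cv)
        speeds = rng.lognormal(mu, sigma, size=len(seg_len))
    else:
        speeds = np.full(len(seg_len), profile.speed_mean)
    seg_time = seg_len / speeds                      # seconds
    t_knots = np.concatenate([[0.0], np.cumsum(seg_time)])
    s_knots = np.concatenate([[0.0], np.cumsum(seg_len)])

    dt = 1.0 / sample_rate
    n = max(2, int(round(t_knots[-1] / dt)) + 1)
    times = np.arange(n) * dt
    arc = np.interp(times, t_knots, s_knots)
    x = np.interp(arc, s_knots, verts[:, 0])
    y = np.interp(arc, s_knots, verts[:, 1])
    if profile.tremor_sd > 0:
        x = x + rng.normal(0.0, profile.tremor_sd, size=n)
        y = y + rng.normal(0.0, profile.tremor_sd, size=n)

    if profile.pressure_sd > 0:
        pressure = rng.normal(profile.pressure_mean, profile.pressure_sd, size=n)
    else:
        pressure = np.full(n, profile.pressure_mean)
    pressure = np.clip(np.rint(pressure), 1, PRESSURE_LEVELS).astype(int)

    step_ms = max(1, int(round(1000.0 / sample_rate)))
    samples = tuple(
        PenSample(x=float(x[i]), y=float(y[i]), t=start_t + i * step_ms,
                  pressure=int(pressure[i]), on_paper=True)
        for i in range(n)
    )
    return Stroke(samples=samples, stroke_index=stroke_index)


def _draw_score(dist: dict[int, float], rng: np.random.Generator) -> int:
    values = np.array(sorted(dist.keys()))
    probs = np.array([dist[v] for v in values], dtype=float)
    return int(rng.choice(values, p=probs / probs.sum()))


def _draw_bounded_int(rng: np.random.Generator, mean: float, sd: float, lo: int, hi: int) -> int:
    return int(np.clip(round(rng.normal(mean, sd)), lo, hi))


def _draw_demographics(profile: GroupProfile, rng: np.random.Generator) -> dict:
    return {
        "gender": "male" if rng.random() < profile.male_fraction else "female",
        "age": _draw_bounded_int(rng, profile.age_mean, profile.age_sd, 55, 95),
        "education_years": _draw_bounded_int(rng, profile.education_mean, profile.education_sd, 0, 20),
        "work_nature": "mental" if rng.random() < 0.5 else "physical",
        "residence_status": str(rng.choice(
            ["with_spouse", "with_spouse_children", "alone", "with_children", "other"],
            p=[0.55, 0.05, 0.14, 0.14, 0.12])),
        "residence_area": "city" if rng.random() < 0.62 else "rural",
        "income_band": int(rng.choice([0, 1, 2, 3], p=[0.22, 0.23, 0.18, 0.37])),
    }


def generate_record(
    config: CohortConfig,
    group: str,
    task_id: int,
    rng: np.random.Generator,
    participant_id: str = "P000",
) -> WritingRecord:
    """Generate one participant x task recording.

    Stroke count is a rounded normal around the profile's mean; templates
    are cycled (with a small horizontal shift per repetition) when the drawn
    count exceeds the template inventory.  Inter-stroke gaps are exponential:
    quick transitions by default, deliberate pauses (mean ``pause_mean_ms``)
    with probability ``pause_rate / n_gaps``.  Off-paper samples are emitted
    during each gap so stroke segmentation operates on realistic streams.
    """
    config.validate()
    if task_id not in config.tasks:
        raise ConfigurationError(f"task {task_id} not enabled in config.tasks {config.tasks}")
    profile = config.profile_for(group)
    templates = task_templates(task_id)

    if profile.stroke_count_sd > 0:
        n_strokes = max(1, int(round(rng.normal(profile.stroke_count_mean, profile.stroke_count_sd))))
    else:
        n_strokes = max(1, int(round(profile.stroke_count_mean)))

    step_ms = max(1, int(round(1000.0 / config.sample_rate)))
    n_gaps = max(1, n_strokes - 1)
    p_long = min(1.0, profile.pause_rate / n_gaps)

    samples: list[PenSample] = []
    t_cursor = 0
    prev_end: PenSample | None = None
    for i in range(n_strokes):
        template = templates[i % len(templates)] + np.array([2.0 * (i // len(templates)), 0.0])
        stroke = generate_stroke(
            profile, template, rng, sample_rate=config.sample_rate,
            start_t=t_cursor, stroke_index=i,
        )
        if prev_end is not None:
            gap_mean = profile.pause_mean_ms if rng.random() < p_long else QUICK_GAP_MEAN_MS
            gap_ms = max(2 * step_ms, int(round(rng.exponential(gap_mean) / step_ms)) * step_ms)
            # airborne samples strictly between the two strokes
            first = stroke.samples[0]
            for k, t_air in enumerate(range(prev_end.t + step_ms, prev_end.t + gap_ms, step_ms)):
                frac = (t_air - prev_end.t) / gap_ms
                samples.append(PenSample(
                    x=prev_end.x + frac * (first.x - prev_end.x),
                    y=prev_end.y + frac * (first.y - prev_end.y),
                    t=t_air, pressure=0, on_paper=False,
                ))
            stroke = Stroke(
                samples=tuple(
                    PenSample(x=s.x, y=s.y, t=s.t + (prev_end.t + gap_ms - t_cursor),
                              pressure=s.pressure, on_paper=True)
                    for s in stroke.samples
                ),
                stroke_index=i,
            )
        samples.extend(stroke.samples)
        prev_end = stroke.samples[-1]
        t_cursor = prev_end.t + step_ms

    record = WritingRecord(
        participant_id=participant_id,
        group=group,
        task_id=task_id,
        samples=samples,
        task_score=_draw_score(profile.score_dist[task_id], rng),
        moca_bc=_draw_bounded_int(rng, profile.moca_mean, profile.moca_sd, 0, 30),
        mmse=_draw_bounded_int(rng, profile.mmse_mean, profile.mmse_sd, 0, 30),
        demographics=_draw_demographics(profile, rng),
    )
    return record


def _record_rng(seed: int, group: str, index: int, task_id: int) -> np.random.Generator:
    group_code = {"AD": 0, "HC": 1}[group]
    return np.random.default_rng(np.random.SeedSequence([seed, group_code, index, task_id]))


def generate_cohort(config: CohortConfig) -> list[WritingRecord]:
    """Generate the full cohort: one record per participant x selected task.

    Each record draws from its own RNG substream keyed by (seed, group,
    participant index, task), so the output is bit-identical for a fixed
    seed regardless of generation order.
    """
    config.validate()
    records: list[WritingRecord] = []
    for group, n in (("AD", config.n_ad), ("HC", config.n_hc)):
        for i in range(n):
            pid = f"{group}{i + 1:03d}"
            for task_id in config.tasks:
                rng = _record_rng(config.seed, group, i, task_id)
                records.append(generate_record(config, group, task_id, rng, participant_id=pid))
    return records
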