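import numpy as np
import pytest

from handkin.pen_stream import PenSample, Stroke, WritingRecord
from handkin.synthetic_cohort import CohortConfig, generate_cohort


def make_record(
    pattern,
    participant_id="P001",
    group="HC",
    task_id=1,
    task_score=1,
    moca_bc=28,
    step_ms=10,
    start_xy=(5.0, 5.0),
    **kwargs,
):
    """Build a record whose on/off-paper pattern follows ``pattern``.

    Samples advance 1 mm in x per step so strokes have nonzero velocity.
    """
    samples = []
    x, y = start_xy
    for i, on in enumerate(pattern):
        samples.append(PenSample(
            x=x + i * 1.0, y=y, t=i * step_ms,
            pressure=500 if on else 0, on_paper=bool(on),
        ))
    return WritingRecord(
        participant_id=participant_id, group=group, task_id=task_id,
        samples=samples, task_score=task_score, moca_bc=moca_bc, **kwargs,
    )


def make_stroke(points, times, pressure=500, index=0):
    """Stroke from explicit (x, y) points and ms timestamps."""
    pressures = pressure if hasattr(pressure, "__len__") else [pressure] * len(times)
    samples = tuple(
        PenSample(x=float(px), y=float(py), t=int(t), pressure=int(p), on_paper=True)
        for (px, py), t, p in zip(points, times, pressures)
    )
    return Stroke(samples=samples, stroke_index=index)


@pytest.fixture(scope="session")
def small_cohort():
    """A 6+6-participant cohort over tasks 1-2 with the default profiles."""
    config = CohortConfig(n_ad=6, n_hc=6, tasks=(1, 2), seed=11)
    return generate_cohort(config)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    from handkin.kinematic_features import extract_features_table

    return extract_features_table(small_cohort)
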