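"""Data model, I/O, validation and stroke segmentation for digital-pen recordings.

A dot-matrix digital pen samples the pen tip at a nominal 100 Hz, reporting
page position (mm), a timestamp (ms), a tip-force reading on a 0-1024 sensor
scale, and whether the tip is in contact with the paper.  A *stroke* is a
maximal contiguous run of on-paper samples; strokes are the unit of analysis
for every downstream kinematic feature.

Coordinates follow the scanner/print convention: origin at the page top-left,
y increasing downward.  Timestamps are integer milliseconds; irregular sample
gaps are accepted and used exactly (no resampling).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Tip-force sensor resolution (levels 0..1024).
PRESSURE_LEVELS = 1024

#: Nominal pen sampling rate in Hz.
DEFAULT_SAMPLE_RATE_HZ = 100

#: Valid writing task identifiers.
TASK_IDS = (1, 2, 3, 4)

#: Maximum attainable score per task: task 1 (connect fixed points) scores one
#: point per correctly connected pair (2 pairs); task 2 (intersecting
#: pentagons) scores three criteria; task 3 dictates three words (one point
#: each); task 4 copies a ten-character sentence (one point per character).
TASK_MAX_SCORE = {1: 2, 2: 3, 3: 3, 4: 10}

GROUPS = ("AD", "HC")

#: Columns of the pen-stream CSV dialect, one row per sample.
CSV_COLUMNS = ("participant_id", "task_id", "t_ms", "x_mm", "y_mm", "pressure", "on_paper")

#: Minimum samples for a stroke to be kept: every per-stroke kinematic is a
#: finite difference, so singleton contacts carry no velocity information.
MIN_STROKE_SAMPLES = 2


class ValidationError(ValueError):
    """An object violates a pen-stream invariant."""


class ParseError(ValueError):
    """A file does not conform to the documented pen-stream dialect."""


@dataclass(frozen=True)
class PenSample:
    """One pen-tip observation.

    Attributes
    ----------
    x, y : float
        Page position in mm (origin top-left, y downward).
    t : int
        Timestamp in ms, non-negative.
    pressure : int
        Tip-force level in 0..1024; positive only while on paper.
    on_paper : bool
        Pen-contact state reported by the tip switch.
    """

    x: float
    y: float
    t: int
    pressure: int
    on_paper: bool


@dataclass(frozen=True)
class Stroke:
    """A maximal contiguous run of on-paper samples."""

    samples: tuple[PenSample, ...]
    stroke_index: int

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def start_t(self) -> int:
        return self.samples[0].t

    @property
    def end_t(self) -> int:
        return self.samples[-1].t

    @property
    def duration_ms(self) -> int:
        """Paper-and-pen contact time of this stroke."""
        return self.end_t - self.start_t

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Return (x, y, t, pressure) as float/int arrays."""
        x = np.array([s.x for s in self.samples], dtype=float)
        y = np.array([s.y for s in self.samples], dtype=float)
        t = np.array([s.t for s in self.samples], dtype=np.int64)
        p = np.array([s.pressure for s in self.samples], dtype=float)
        return x, y, t, p


@dataclass
class WritingRecord:
    """One participant performing one writing task.

    ``samples`` is the full ordered stream, on- and off-paper.  Scores and
    cognitive-test results are annotations supplied alongside the stream;
    the pipeline never derives them from the trajectory.
    """

    participant_id: str
    group: str
    task_id: int
    samples: list[PenSample]
    task_score: int = 0
    moca_bc: int | None = None
    mmse: int | None = None
    demographics: dict = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, int]:
        return (self.participant_id, self.task_id)


# ---------------------------------------------------------------------------
# validation


def validate_sample(sample: PenSample, where: str = "") -> None:
    """Check the PenSample invariants, raising :class:`ValidationError`.

    Rules: pressure within the 0-1024 sensor scale; positive pressure implies
    pen-on-paper; an airborne pen reads zero pressure.
    """
    ctx = f" ({where})" if where else ""
    if not 0 <= sample.pressure <= PRESSURE_LEVELS:
        raise ValidationError(
            f"pressure {sample.pressure} outside the 0-{PRESSURE_LEVELS} sensor bound{ctx}"
        )
    if sample.pressure > 0 and not sample.on_paper:
        raise ValidationError(
            f"positive pressure {sample.pressure} on an off-paper sample{ctx}"
        )
    if not sample.on_paper and sample.pressure != 0:
        raise ValidationError(f"off-paper sample with nonzero pressure{ctx}")
    if sample.t < 0:
        raise ValidationError(f"negative timestamp {sample.t}{ctx}")


def validate_record(record: WritingRecord) -> None:
    """Check all WritingRecord and per-sample invariants."""
    rid = f"record {record.participant_id}/task {record.task_id}"
    if record.group not in GROUPS:
        raise ValidationError(f"{rid}: group {record.group!r} not in {GROUPS}")
    if record.task_id not in TASK_IDS:
        raise ValidationError(f"{rid}: task_id must be one of {TASK_IDS}")
    if record.task_score < 0 or record.task_score > TASK_MAX_SCORE[record.task_id]:
        raise ValidationError(
            f"{rid}: task_score {record.task_score} exceeds task maximum "
            f"{TASK_MAX_SCORE[record.task_id]}"
        )
    for score, name in ((record.moca_bc, "moca_bc"), (record.mmse, "mmse")):
        if score is not None and not 0 <= score <= 30:
            raise ValidationError(f"{rid}: {name} {score} outside 0-30")
    t_prev = None
    for i, s in enumerate(record.samples):
        validate_sample(s, where=f"{rid}, sample {i}")
        if t_prev is not None and s.t <= t_prev:
            raise ValidationError(f"{rid}: timestamps not strictly increasing at sample {i}")
        t_prev = s.t


# ---------------------------------------------------------------------------
# segmentation


def segment_strokes(
    record: WritingRecord, return_dropped: bool = False
) -> list[Stroke] | tuple[list[Stroke], int]:
    """Split a record into strokes: maximal contiguous on-paper runs.

    Runs shorter than :data:`MIN_STROKE_SAMPLES` are dropped (and counted in
    the log) because per-stroke kinematics need at least one finite
    difference.  With ``return_dropped=True`` the number of dropped runs is
    returned alongside the strokes.
    """
    t = np.array([s.t for s in record.samples], dtype=np.int64)
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise ValidationError(
            f"record {record.participant_id}/task {record.task_id}: "
            "timestamps not strictly increasing"
        )
    strokes: list[Stroke] = []
    dropped = 0
    run: list[PenSample] = []
    for s in list(record.samples) + [None]:  # sentinel flushes the last run
        if s is not None and s.on_paper:
            run.append(s)
            continue
        if run:
            if len(run) >= MIN_STROKE_SAMPLES:
                strokes.append(Stroke(samples=tuple(run), stroke_index=len(strokes)))
            else:
                dropped += 1
            run = []
    if dropped:
        logger.info(
            "record %s/task %s: dropped %d singleton pen contact(s)",
            record.participant_id, record.task_id, dropped,
        )
    if return_dropped:
        return strokes, dropped
    return strokes


def in_air_intervals(record: WritingRecord, strokes: Sequence[Stroke]) -> np.ndarray:
    """Durations (ms) the pen spent airborne between consecutive strokes.

    Interval ``i`` runs from the last sample of stroke ``i`` to the first
    sample of stroke ``i+1``; a record with fewer than two strokes has none.
    """
    if len(strokes) < 2:
        return np.array([], dtype=np.int64)
    ends = np.array([s.end_t for s in strokes[:-1]], dtype=np.int64)
    starts = np.array([s.start_t for s in strokes[1:]], dtype=np.int64)
    gaps = starts - ends
    if np.any(gaps < 0):
        raise ValidationError("strokes are not in temporal order")
    return gaps


# ---------------------------------------------------------------------------
# I/O

def _meta_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def _records_to_frame(records: Iterable[WritingRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        for s in r.samples:
            rows.append((r.participant_id, r.task_id, s.t, s.x, s.y, s.pressure, int(s.on_paper)))
    return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def _annotations(records: Iterable[WritingRecord]) -> dict:
    ann = {}
    for r in records:
        ann[f"{r.participant_id}|{r.task_id}"] = {
            "group": r.group,
            "task_score": r.task_score,
            "moca_bc": r.moca_bc,
            "mmse": r.mmse,
            "demographics": r.demographics,
            "n_samples": len(r.samples),
        }
    return ann


def write_pen_stream(records: Sequence[WritingRecord], path: str | Path, dialect: str = "csv") -> None:
    """Write records in the documented CSV (+ JSON sidecar) or JSON dialect.

    The CSV holds one row per sample; annotations (group, scores,
    demographics) go to a ``<stem>.meta.json`` sidecar keyed by
    ``participant_id|task_id``.  Floats are written with round-trip precision
    so that ``read_pen_stream(write_pen_stream(x)) == x`` exactly.
    """
    path = Path(path)
    for r in records:
        validate_record(r)
    if dialect == "csv":
        frame = _records_to_frame(records)
        # shortest round-trip repr keeps read(write(x)) exact on floats
        frame.to_csv(path, index=False, float_format=lambda v: repr(float(v)))
        with open(_meta_path(path), "w", encoding="utf-8") as fh:
            json.dump({"records": _annotations(records)}, fh, indent=2, sort_keys=True)
    elif dialect == "json":
        payload = {
            "records": [
                {
                    "participant_id": r.participant_id,
                    "task_id": r.task_id,
                    "group": r.group,
                    "task_score": r.task_score,
                    "moca_bc": r.moca_bc,
                    "mmse": r.mmse,
                    "demographics": r.demographics,
                    "samples": [[s.t, s.x, s.y, s.pressure, int(s.on_paper)] for s in r.samples],
                }
                for r in records
            ]
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_pen_stream(path: str | Path, dialect: str = "csv") -> list[WritingRecord]:
    """Read records from the documented CSV or JSON dialect.

    Raises :class:`ParseError` for malformed content and
    :class:`ValidationError` when a record breaks an invariant.  An empty
    file yields an empty list with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "json":
        return _read_json(path)
    if dialect != "csv":
        raise ValueError(f"unknown dialect {dialect!r}")

    if path.stat().st_size == 0:
        logger.warning("%s is empty; returning no records", path)
        return []
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        logger.warning("%s has no rows; returning no records", path)
        return []
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = set(CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    if frame.empty:
        logger.warning("%s has a header but no sample rows", path)

    meta_file = _meta_path(path)
    annotations: dict = {}
    if meta_file.exists():
        with open(meta_file, encoding="utf-8") as fh:
            annotations = json.load(fh).get("records", {})
    else:
        logger.warning("no annotation sidecar %s; records default to group HC", meta_file)

    records: list[WritingRecord] = []
    # groupby(sort=False) keeps file order of first appearance
    for (pid, task_id), chunk in frame.groupby(["participant_id", "task_id"], sort=False):
        samples = [
            PenSample(
                x=float(row.x_mm), y=float(row.y_mm), t=int(row.t_ms),
                pressure=int(row.pressure), on_paper=bool(row.on_paper),
            )
            for row in chunk.itertuples(index=False)
        ]
        ann = annotations.get(f"{pid}|{task_id}", {})
        record = WritingRecord(
            participant_id=str(pid),
            group=ann.get("group", "HC"),
            task_id=int(task_id),
            samples=samples,
            task_score=int(ann.get("task_score", 0)),
            moca_bc=ann.get("moca_bc"),
            mmse=ann.get("mmse"),
            demographics=ann.get("demographics", {}),
        )
        validate_record(record)
        records.append(record)
    # sample-less records survive only through the sidecar
    for key, ann in annotations.items():
        if ann.get("n_samples", 0) == 0:
            pid, task_id = key.rsplit("|", 1)
            record = WritingRecord(
                participant_id=pid, group=ann.get("group", "HC"), task_id=int(task_id),
                samples=[], task_score=int(ann.get("task_score", 0)),
                moca_bc=ann.get("moca_bc"), mmse=ann.get("mmse"),
                demographics=ann.get("demographics", {}),
            )
            validate_record(record)
            records.append(record)
    return records


def _read_json(path: Path) -> list[WritingRecord]:
    if path.stat().st_size == 0:
        logger.warning("%s is empty; returning no records", path)
        return []
    try:
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: line {exc.lineno}: {exc.msg}") from exc
    records = []
    for entry in payload.get("records", []):
        samples = [
            PenSample(x=float(x), y=float(y), t=int(t), pressure=int(p), on_paper=bool(on))
            for t, x, y, p, on in entry.get("samples", [])
        ]
        record = WritingRecord(
            participant_id=str(entry["participant_id"]),
            group=entry.get("group", "HC"),
            task_id=int(entry["task_id"]),
            samples=samples,
            task_score=int(entry.get("task_score", 0)),
            moca_bc=entry.get("moca_bc"),
            mmse=entry.get("mmse"),
            demographics=entry.get("demographics", {}),
        )
        validate_record(record)
        records.append(record)
    return records
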