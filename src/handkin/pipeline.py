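"""End-to-end pipeline: simulate -> extract -> screen -> classify.

A run directory holds every intermediate artifact (cohort CSV + annotation
sidecar, per-stroke feature table, comparison table, per-task diagnostic
report JSONs) plus a manifest with the full configuration, package
versions and artifact checksums.  Data artifacts are bit-identical across
re-runs with the same configuration; the free-text log (which carries
wall-clock timestamps) is the one exception.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .diagnostics import default_roster, run_classifiers
from .group_stats import DEFAULT_ALPHA, screen_features
from .kinematic_features import DEFAULT_N_BINS, extract_features_table
from .pen_stream import TASK_IDS, write_pen_stream
from .synthetic_cohort import CohortConfig, GroupProfile, default_profiles, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything needed to replay a full run."""

    cohort: CohortConfig
    n_bins: int = DEFAULT_N_BINS
    alpha: float = DEFAULT_ALPHA
    alpha_gate: float = DEFAULT_ALPHA
    protocol: str = "cv5"
    roster: list[str] | None = None
    seed: int = 0
    out_dir: str = "handkin_run"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["tasks"] = list(self.cohort.tasks)
        return d


def _profile_from_dict(d: dict) -> GroupProfile:
    d = dict(d)
    if "score_dist" in d:
        d["score_dist"] = {int(k): {int(s): float(p) for s, p in v.items()}
                           for k, v in d["score_dist"].items()}
    return GroupProfile(**d)


def load_config(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file; absent keys use defaults."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    cohort_raw = dict(raw.pop("cohort", {}))
    ad, hc = default_profiles()
    if "ad_profile" in cohort_raw:
        ad = _profile_from_dict(cohort_raw.pop("ad_profile"))
    if "hc_profile" in cohort_raw:
        hc = _profile_from_dict(cohort_raw.pop("hc_profile"))
    cohort_raw.setdefault("n_ad", 34)
    cohort_raw.setdefault("n_hc", 45)
    if "tasks" in cohort_raw:
        cohort_raw["tasks"] = tuple(int(t) for t in cohort_raw["tasks"])
    cohort = CohortConfig(ad_profile=ad, hc_profile=hc, **cohort_raw)
    config = PipelineConfig(cohort=cohort, **raw)
    config.cohort.seed = config.seed if "seed" not in cohort_raw else config.cohort.seed
    return config


def default_config(seed: int = 0, out_dir: str = "handkin_run") -> PipelineConfig:
    """The shipped defaults: the study-sized cohort over all four tasks."""
    return PipelineConfig(
        cohort=CohortConfig(n_ad=34, n_hc=45, tasks=TASK_IDS, seed=seed),
        seed=seed,
        out_dir=out_dir,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _dump_json(obj, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, allow_nan=True)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline into ``config.out_dir`` and return it.

    Stages: cohort generation, feature extraction, per-task screening, and
    one diagnostic report per task over the task's significant features.
    If a task has no significant feature at the configured alpha, its
    classify stage is skipped with a notice in the manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("handkin")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    t_start = time.perf_counter()
    manifest: dict = {"config": config.to_dict(), "versions": _versions(), "stages": {}}

    try:
        t0 = time.perf_counter()
        records = generate_cohort(config.cohort)
        cohort_path = out / "cohort.csv"
        write_pen_stream(records, cohort_path)
        logger.info("simulate: %d records in %.2fs", len(records), time.perf_counter() - t0)
        manifest["stages"]["simulate"] = {"n_records": len(records)}

        t0 = time.perf_counter()
        features = extract_features_table(records, n_bins=config.n_bins)
        features_path = out / "features.csv"
        features.to_csv(features_path, index=False)
        logger.info("extract: %d strokes in %.2fs", len(features), time.perf_counter() - t0)
        manifest["stages"]["extract"] = {"n_strokes": len(features)}

        t0 = time.perf_counter()
        comparisons = screen_features(features, alpha=config.alpha, alpha_gate=config.alpha_gate)
        comparisons_path = out / "comparisons.csv"
        comparisons.to_csv(comparisons_path, index=False)
        n_sig = int(comparisons["significant"].sum())
        logger.info("screen: %d significant rows in %.2fs", n_sig, time.perf_counter() - t0)
        manifest["stages"]["screen"] = {"n_significant": n_sig}

        roster = None
        if config.roster is not None:
            full = default_roster(config.seed)
            roster = {name: full[name] for name in config.roster}
        classify_info = {}
        for task_id in config.cohort.tasks:
            t0 = time.perf_counter()
            sig = comparisons.query("task_id == @task_id and significant")["feature_name"].tolist()
            if not sig:
                logger.info("classify task %d: no significant features; skipped", task_id)
                classify_info[str(task_id)] = {"status": "skipped", "reason": "no significant features"}
                continue
            sub = features[features["task_id"] == task_id]
            reports = run_classifiers(
                sub[sig], sub["group"], groups=sub["participant_id"],
                protocol=config.protocol, roster=roster, seed=config.seed,
            )
            payload = {
                "task_id": task_id,
                "protocol": config.protocol,
                "seed": config.seed,
                "significant_features": sig,
                "reports": [r.to_dict() for r in reports],
            }
            _dump_json(payload, out / f"report_task{task_id}.json")
            classify_info[str(task_id)] = {
                "status": "ok", "n_features": len(sig),
                "n_classifiers": len(reports),
            }
            logger.info("classify task %d: %d classifiers in %.2fs",
                        task_id, len(reports), time.perf_counter() - t0)
        manifest["stages"]["classify"] = classify_info

        manifest["checksums"] = {
            p.name: _sha256(p)
            for p in sorted(out.glob("*"))
            if p.suffix in {".csv", ".json"} and p.name != "manifest.json"
        }
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = str(exc)
        _dump_json(manifest, out / "manifest.json")
        logger.exception("pipeline failed")
        raise
    finally:
        root.removeHandler(handler)
        handler.close()

    _dump_json(manifest, out / "manifest.json")
    logger.info("pipeline done in %.2fs", time.perf_counter() - t_start)
    return out


def _versions() -> dict:
    import numpy
    import scipy
    import sklearn
    import xgboost

    return {
        "handkin": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
        "xgboost": xgboost.__version__,
    }


def report_summary(run_dir: str | Path) -> pd.DataFrame:
    """Tabulate a completed run: one row per (task, classifier).

    Raises FileNotFoundError naming the first missing artifact.
    """
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing artifact: {manifest_path}")
    with open(manifest_path, encoding="utf-8") as fh:
        manifest = json.load(fh)
    tasks = manifest["config"]["cohort"]["tasks"]
    rows = []
    for task_id in tasks:
        status = manifest["stages"].get("classify", {}).get(str(task_id), {}).get("status")
        if status == "skipped":
            continue
        report_path = run_dir / f"report_task{task_id}.json"
        if not report_path.exists():
            raise FileNotFoundError(f"missing artifact: {report_path}")
        with open(report_path, encoding="utf-8") as fh:
            payload = json.load(fh)
        for rep in payload["reports"]:
            rows.append({
                "task_id": task_id,
                "classifier": rep["classifier_name"],
                "status": rep["status"],
                "accuracy": rep["accuracy"],
                "sensitivity": rep["sensitivity"],
                "specificity": rep["specificity"],
                "ppv": rep["ppv"],
                "npv": rep["npv"],
                "auc": rep["auc"],
                "optimal_threshold": rep["optimal_threshold"],
            })
    return pd.DataFrame(rows)
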