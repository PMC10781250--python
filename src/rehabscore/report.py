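"""Run configuration, session history and the end-to-end study pipeline.

``RunConfig`` captures every knob of a scoring run and round-trips through a
YAML file; its digest reproducibly identifies the configuration inside
session records. The session history is a local append-only JSON-lines file
(one record per scoring run) — a desk-scale stand-in for a cloud session
database. ``score_cohort``/``run_pipeline`` assemble the full validation
study on synthetic cohorts: two exercises × three body segments scored with
the three methods (angle agreement as the motion-capture comparator, batch
normalized DTW, and frame-wise cosine similarity), yielding the long trial
table the statistics layer consumes.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .angle_kinematics import DEFAULT_PAIRS, angle_agreement_score, angle_series
from .cosine_scoring import ScoringOptions, score_exercise
from .dtw_engine import dtw_exact, dtw_fast, normalize_batch, segment_dtw
from .errors import ConfigError, ValidationError
from .motion_model import (
    DEFAULT_SEGMENTS,
    MotionSequence,
    extract_segment,
    load_sequence,
    normalize_pose,
)
from .stats_compare import ComparisonReport, comparison_report
from .synthetic_motion import (
    DEGRADED_PARAMS,
    GOOD_PARAMS,
    POOR_PARAMS,
    generate_cohort,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a scoring run; every field has a documented default."""

    method: str = "cosine"  # cosine | dtw
    normalization: str = "hip_centered"
    threshold: float = 0.90  # cosine frame-correctness cutoff
    segments: tuple[str, ...] = ("head", "trunk", "shoulder")
    engine: str = "fast"  # dtw engine: exact | fast
    radius: int = 1  # fast-dtw refinement radius
    seed: int = 0
    min_visibility: float = 0.0
    reference: str | None = None
    trial: str | None = None
    out: str | None = None
    history: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.method not in ("cosine", "dtw"):
            raise ConfigError(f"method must be 'cosine' or 'dtw', got {self.method!r}")
        if self.engine not in ("exact", "fast"):
            raise ConfigError(f"engine must be 'exact' or 'fast', got {self.engine!r}")
        if not 0.0 < self.threshold <= 1.0:
            raise ConfigError(f"threshold must be in (0, 1], got {self.threshold}")
        if self.radius < 0:
            raise ConfigError("radius must be >= 0")

    def to_file(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        try:
            with open(path, encoding="utf-8") as fh:
                data = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"invalid config file {path}: {exc}") from exc
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        if "segments" in data and data["segments"] is not None:
            data["segments"] = tuple(data["segments"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["segments"] = list(self.segments)
        return d

    def digest(self) -> str:
        """Stable hex digest identifying this configuration."""
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class SessionRecord:
    """One line of the append-only session history."""

    timestamp: str
    exercise_id: str
    method: str
    score: float
    config_digest: str

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, line: str) -> "SessionRecord":
        obj = json.loads(line)
        return cls(
            timestamp=str(obj["timestamp"]),
            exercise_id=str(obj["exercise_id"]),
            method=str(obj["method"]),
            score=float(obj["score"]),
            config_digest=str(obj["config_digest"]),
        )


def append_session(path: str | Path, record: SessionRecord) -> None:
    with open(path, "a", encoding="utf-8") as fh:
        fh.write(record.to_json() + "\n")


def run_history(path: str | Path) -> list[SessionRecord]:
    """Read the session history, chronologically sorted.

    Corrupted lines are skipped with a warning instead of aborting.
    """
    path = Path(path)
    if not path.exists():
        return []
    records = []
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            try:
                records.append(SessionRecord.from_json(line))
            except (json.JSONDecodeError, KeyError, ValueError) as exc:
                logger.warning("%s: skipping corrupted record on line %d (%s)",
                               path.name, ln + 1, exc)
    records.sort(key=lambda r: r.timestamp)
    return records


def run_score(config: RunConfig) -> tuple[dict, SessionRecord]:
    """Score one trial against one reference per the configuration.

    Returns the report payload (bit-reproducible for a fixed config) and the
    session record appended to the history file (if configured).
    """
    if config.reference is None or config.trial is None:
        raise ConfigError("run_score needs both 'reference' and 'trial' paths")
    ref = load_sequence(config.reference)
    pat = load_sequence(config.trial)

    if config.method == "cosine":
        opts = ScoringOptions(
            normalization=config.normalization,
            min_visibility=config.min_visibility,
        )
        score = score_exercise(ref, pat, threshold=config.threshold, options=opts)
        payload = {
            "method": "cosine",
            "exercise_id": pat.exercise_id,
            "normalization": config.normalization,
            **score.to_dict(),
        }
        scalar = score.percent_correct
    else:
        specs = []
        for name in config.segments:
            if name not in DEFAULT_SEGMENTS:
                raise ConfigError(f"unknown segment {name!r}")
            specs.append(DEFAULT_SEGMENTS[name])
        results = segment_dtw(
            ref,
            pat,
            specs,
            engine=config.engine,
            radius=config.radius,
            normalization=config.normalization,
        )
        payload = {
            "method": "dtw",
            "exercise_id": pat.exercise_id,
            "engine": config.engine,
            "radius": config.radius,
            "normalization": config.normalization,
            "segments": {
                name: {
                    "distance": res.distance,
                    "path_length": len(res.path),
                }
                for name, res in results.items()
            },
            "total_distance": sum(r.distance for r in results.values()),
            "note": "raw distances; percentages need batch normalization",
        }
        scalar = payload["total_distance"]

    record = SessionRecord(
        timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(),
        exercise_id=pat.exercise_id,
        method=config.method,
        score=float(scalar),
        config_digest=config.digest(),
    )
    if config.history:
        append_session(config.history, record)
    if config.out:
        with open(config.out, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return payload, record


# -- study pipeline ------------------------------------------------------

_SEGMENT_SUFFIX = {"head": "HEAD", "trunk": "TRUNK", "shoulder": "SHOULDER"}
_TEMPLATE_SUFFIX = {"seated_rotation": "ROT", "standing_diagonal": "DIAG"}

DEFAULT_COHORT_GRID = (GOOD_PARAMS, DEGRADED_PARAMS, POOR_PARAMS)


def score_cohort(
    ref: MotionSequence,
    trials: list[MotionSequence],
    template_name: str,
    threshold: float = 0.90,
    engine: str = "exact",
    radius: int = 1,
) -> pd.DataFrame:
    """Score one cohort with all three methods on all three segments.

    Methods: ``APP`` (frame-wise cosine percent-correct), ``DTW`` (raw
    segment distance batch-normalized over the cohort, reported as
    100 - percent so that higher = better like the other methods have
    higher = closer), and ``QTM`` (angle-agreement against the reference's
    angle series). Scoring is segment-wise: sequences are hip-centered
    first, then each segment's landmark subset is compared.
    """
    suffix = _TEMPLATE_SUFFIX.get(template_name)
    if suffix is None:
        raise ValidationError(f"unknown template {template_name!r}")
    rows = []
    ref_c = normalize_pose(ref, "hip_centered")
    ref_segments = {
        name: extract_segment(ref_c, DEFAULT_SEGMENTS[name])
        for name in ("head", "trunk", "shoulder")
    }
    ref_angles = {
        name: angle_series(ref, DEFAULT_PAIRS[name])
        for name in ("head", "trunk", "shoulder")
    }
    raw_distances: dict[str, list[float]] = {n: [] for n in ref_segments}

    for si, trial in enumerate(trials):
        trial_c = normalize_pose(trial, "hip_centered")
        for seg_name, ref_seg in ref_segments.items():
            exercise = f"{_SEGMENT_SUFFIX[seg_name]}_{suffix}"
            trial_seg = extract_segment(trial_c, DEFAULT_SEGMENTS[seg_name])
            app = score_exercise(
                ref_seg,
                trial_seg,
                threshold=threshold,
                options=ScoringOptions(normalization="raw"),
            )
            rows.append(
                {
                    "subject": si,
                    "exercise": exercise,
                    "method": "APP",
                    "score": app.percent_correct,
                }
            )
            dtw_fn = dtw_exact if engine == "exact" else (
                lambda a, b: dtw_fast(a, b, radius=radius)
            )
            res = dtw_fn(ref_seg, trial_seg)
            raw_distances[seg_name].append(res.distance)
            qtm = angle_agreement_score(
                ref_angles[seg_name],
                angle_series(trial, DEFAULT_PAIRS[seg_name]),
            )
            rows.append(
                {
                    "subject": si,
                    "exercise": exercise,
                    "method": "QTM",
                    "score": qtm,
                }
            )

    # Batch-normalize DTW distances per (exercise, method) group, then flip
    # so that, like the other methods, higher means closer to the reference.
    for seg_name, dists in raw_distances.items():
        exercise = f"{_SEGMENT_SUFFIX[seg_name]}_{suffix}"
        percents, _ = normalize_batch(dists)
        for si, pct in enumerate(percents):
            rows.append(
                {
                    "subject": si,
                    "exercise": exercise,
                    "method": "DTW",
                    "score": 100.0 - pct,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(
    n_subjects: int = 15,
    seed: int = 0,
    n_frames: int = 240,
    fps: float = 30.0,
    params_grid=DEFAULT_COHORT_GRID,
    engine: str = "exact",
) -> tuple[pd.DataFrame, ComparisonReport]:
    """simulate → score → compare: the full validation study on synthetics.

    Generates one cohort per exercise template, scores every trial with the
    three methods on the three segments (six exercise labels), and runs the
    descriptive/ANOVA/Tukey comparison on the pooled trial table.
    """
    tables = []
    for ti, template in enumerate(("seated_rotation", "standing_diagonal")):
        ref, labeled = generate_cohort(
            n_subjects,
            template,
            params_grid,
            seed=seed + ti,
            n_frames=n_frames,
            fps=fps,
        )
        trials = [t for t, _ in labeled]
        tables.append(score_cohort(ref, trials, template, engine=engine))
    table = pd.concat(tables, ignore_index=True)
    return table, comparison_report(table)
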