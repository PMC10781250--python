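"""Data model for keypoint motion sequences.

A :class:`MotionSequence` is the universal input of the package: an ordered
series of frames, each holding the 3-D position and visibility of a set of
body landmarks (the full map has 33 points, see :mod:`rehabscore.landmarks`).
The module also provides serialization to/from a JSON reference format and a
wide CSV dialect, linear-in-time resampling, segment extraction and pose
coordinate normalization.

Internally a sequence is array-backed: timestamps ``t`` of shape ``(n,)``,
coordinates of shape ``(n, k, 3)`` and visibilities of shape ``(n, k)``,
where ``k`` is the number of landmarks carried (33 for a full-body sequence,
fewer after segment extraction). ``landmark_indices`` records which landmark
ids the ``k`` columns correspond to.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .landmarks import (
    LEFT_HIP,
    LEFT_SHOULDER,
    N_LANDMARKS,
    RIGHT_HIP,
    RIGHT_SHOULDER,
)

logger = logging.getLogger(__name__)

SOURCES = ("recorded", "reference", "synthetic")
NORMALIZATIONS = ("raw", "hip_centered", "hip_centered_scaled")

_CSV_COL_RE = re.compile(r"^kp(\d{2})_([xyzv])$")


@dataclass(frozen=True)
class Keypoint:
    """One tracked landmark in one frame."""

    index: int
    x: float
    y: float
    z: float
    visibility: float

    def __post_init__(self) -> None:
        if not 0 <= self.index < N_LANDMARKS:
            raise ValidationError(f"landmark index {self.index} outside 0..32")
        if not 0.0 <= self.visibility <= 1.0:
            raise ValidationError(
                f"visibility {self.visibility} outside [0, 1] for landmark {self.index}"
            )

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class Frame:
    """One time sample: a timestamp plus a collection of keypoints."""

    t: float
    keypoints: tuple[Keypoint, ...]

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValidationError(f"negative timestamp {self.t}")
        idx = [kp.index for kp in self.keypoints]
        if len(set(idx)) != len(idx):
            dupes = sorted({i for i in idx if idx.count(i) > 1})
            raise ValidationError(f"duplicate landmark index {dupes} within a frame")

    @property
    def is_complete(self) -> bool:
        return len(self.keypoints) == N_LANDMARKS

    def keypoint(self, index: int) -> Keypoint:
        for kp in self.keypoints:
            if kp.index == index:
                return kp
        raise KeyError(f"landmark {index} not present in frame")


@dataclass(frozen=True)
class SegmentSpec:
    """A named subset of landmarks that scores and angles operate on."""

    name: str
    indices: frozenset[int]

    def __post_init__(self) -> None:
        if not self.indices:
            raise ValidationError(f"segment {self.name!r} has an empty index set")
        bad = sorted(i for i in self.indices if not 0 <= i < N_LANDMARKS)
        if bad:
            raise ValidationError(f"segment {self.name!r} has out-of-range indices {bad}")

    @property
    def sorted_indices(self) -> tuple[int, ...]:
        return tuple(sorted(self.indices))


# Default segment definitions. The evaluation protocol splits each exercise
# into head, trunk and shoulder parts; the landmark sets below are the minimal
# anatomically coherent choices (face for the head, the torso quadrilateral for
# the trunk, and the moving arm chain for the shoulder).
HEAD_SEGMENT = SegmentSpec("head", frozenset(range(0, 11)))
TRUNK_SEGMENT = SegmentSpec(
    "trunk", frozenset({LEFT_SHOULDER, RIGHT_SHOULDER, LEFT_HIP, RIGHT_HIP})
)
SHOULDER_SEGMENT_RIGHT = SegmentSpec("shoulder", frozenset({12, 14, 16}))
SHOULDER_SEGMENT_LEFT = SegmentSpec("shoulder", frozenset({11, 13, 15}))

DEFAULT_SEGMENTS: dict[str, SegmentSpec] = {
    "head": HEAD_SEGMENT,
    "trunk": TRUNK_SEGMENT,
    "shoulder": SHOULDER_SEGMENT_RIGHT,
    "shoulder_left": SHOULDER_SEGMENT_LEFT,
}


@dataclass
class MotionSequence:
    """An ordered, validated keypoint time series.

    Parameters
    ----------
    exercise_id:
        Free-text label of the exercise the sequence belongs to.
    fps:
        Nominal frame rate in frames/second (> 0). Timestamps are authoritative;
        fps is metadata used when a source supplies no timestamps.
    source:
        One of ``recorded``, ``reference``, ``synthetic``.
    t:
        Strictly increasing timestamps in seconds, shape ``(n,)``.
    coords:
        Landmark coordinates, shape ``(n, k, 3)`` ordered ``x, y, z``.
    visibility:
        Per-landmark confidence in ``[0, 1]``, shape ``(n, k)``.
    landmark_indices:
        Sorted landmark ids for the ``k`` columns.
    """

    exercise_id: str
    fps: float
    source: str
    t: np.ndarray
    coords: np.ndarray
    visibility: np.ndarray
    landmark_indices: np.ndarray = field(
        default_factory=lambda: np.arange(N_LANDMARKS)
    )

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.visibility = np.asarray(self.visibility, dtype=float)
        self.landmark_indices = np.asarray(self.landmark_indices, dtype=int)
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> list[str]:
        """Check structural invariants; return a list of non-fatal warnings."""
        if self.fps <= 0:
            raise ValidationError(f"fps must be > 0, got {self.fps}")
        if self.source not in SOURCES:
            raise ValidationError(f"source must be one of {SOURCES}, got {self.source!r}")
        n = self.t.shape[0]
        k = self.landmark_indices.shape[0]
        if self.coords.shape != (n, k, 3):
            raise ValidationError(
                f"coords shape {self.coords.shape} inconsistent with "
                f"{n} frames x {k} landmarks"
            )
        if self.visibility.shape != (n, k):
            raise ValidationError(
                f"visibility shape {self.visibility.shape} inconsistent with "
                f"{n} frames x {k} landmarks"
            )
        if k == 0:
            raise ValidationError("sequence carries no landmarks")
        if len(np.unique(self.landmark_indices)) != k:
            raise ValidationError("duplicate landmark indices in sequence")
        if self.landmark_indices.min(initial=0) < 0 or self.landmark_indices.max(
            initial=0
        ) >= N_LANDMARKS:
            raise ValidationError("landmark indices outside 0..32")
        if not np.all(np.diff(self.landmark_indices) > 0):
            raise ValidationError("landmark indices must be sorted ascending")
        if n and self.t[0] < 0:
            raise ValidationError("timestamps must be >= 0")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            bad = int(np.flatnonzero(np.diff(self.t) <= 0)[0]) + 1
            raise ValidationError(
                f"timestamps must strictly increase; violation at frame {bad}"
            )
        if np.any(~np.isfinite(self.coords)):
            raise ValidationError("non-finite coordinate values")
        if np.any((self.visibility < 0) | (self.visibility > 1)):
            raise ValidationError("visibility values outside [0, 1]")

        warnings: list[str] = []
        xy = self.coords[:, :, :2]
        n_off = int(np.count_nonzero((xy < 0) | (xy > 1)))
        if n_off:
            warnings.append(
                f"{n_off} x/y values outside [0, 1] (landmarks leaving the frame)"
            )
        if k < N_LANDMARKS and set(self.landmark_indices) == set(range(k)):
            pass  # a deliberately partial sequence; nothing to flag
        for w in warnings:
            # debug level: off-frame values are routine for body-centered
            # conventions and only noteworthy for raw image coordinates
            logger.debug("%s: %s", self.exercise_id, w)
        return warnings

    # -- basic accessors -------------------------------------------------

    @property
    def n_frames(self) -> int:
        return int(self.t.shape[0])

    @property
    def n_landmarks(self) -> int:
        return int(self.landmark_indices.shape[0])

    @property
    def is_complete(self) -> bool:
        return self.n_landmarks == N_LANDMARKS

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.n_frames > 1 else 0.0

    def column_of(self, landmark_id: int) -> int:
        pos = np.searchsorted(self.landmark_indices, landmark_id)
        if pos >= self.n_landmarks or self.landmark_indices[pos] != landmark_id:
            raise KeyError(f"landmark {landmark_id} not present in sequence")
        return int(pos)

    def frame(self, i: int) -> Frame:
        kps = tuple(
            Keypoint(
                int(idx),
                float(self.coords[i, c, 0]),
                float(self.coords[i, c, 1]),
                float(self.coords[i, c, 2]),
                float(self.visibility[i, c]),
            )
            for c, idx in enumerate(self.landmark_indices)
        )
        return Frame(float(self.t[i]), kps)

    def iter_frames(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def copy(self) -> "MotionSequence":
        return replace(
            self,
            t=self.t.copy(),
            coords=self.coords.copy(),
            visibility=self.visibility.copy(),
            landmark_indices=self.landmark_indices.copy(),
        )


def sequences_allclose(
    a: MotionSequence, b: MotionSequence, atol: float = 1e-9
) -> bool:
    """Numeric equality of two sequences within ``atol`` (metadata excluded
    except the landmark set)."""
    return (
        a.n_frames == b.n_frames
        and np.array_equal(a.landmark_indices, b.landmark_indices)
        and np.allclose(a.t, b.t, atol=atol, rtol=0)
        and np.allclose(a.coords, b.coords, atol=atol, rtol=0)
        and np.allclose(a.visibility, b.visibility, atol=atol, rtol=0)
    )


def frames_to_sequence(
    frames: Sequence[Frame],
    exercise_id: str,
    fps: float,
    source: str,
) -> MotionSequence:
    """Assemble a validated sequence from :class:`Frame` objects.

    All frames must carry the same landmark index set; the first frame is the
    reference and any deviation is reported with the offending frame number
    and the missing/extra indices (incomplete frames are never silently
    padded).
    """
    if not frames:
        return MotionSequence(
            exercise_id,
            fps,
            source,
            np.empty(0),
            np.empty((0, N_LANDMARKS, 3)),
            np.empty((0, N_LANDMARKS)),
        )
    ref_set = {kp.index for kp in frames[0].keypoints}
    for fi, fr in enumerate(frames):
        got = {kp.index for kp in fr.keypoints}
        if got != ref_set:
            missing = sorted(ref_set - got)
            extra = sorted(got - ref_set)
            parts = []
            if missing:
                parts.append(f"missing index {missing}")
            if extra:
                parts.append(f"unexpected index {extra}")
            raise ValidationError(f"frame {fi}: {'; '.join(parts)}")
    order = sorted(ref_set)
    t = np.array([fr.t for fr in frames], dtype=float)
    sort = np.argsort(t, kind="stable")
    coords = np.empty((len(frames), len(order), 3))
    vis = np.empty((len(frames), len(order)))
    for out_i, fi in enumerate(sort):
        by_idx = {kp.index: kp for kp in frames[fi].keypoints}
        for c, idx in enumerate(order):
            kp = by_idx[idx]
            coords[out_i, c] = (kp.x, kp.y, kp.z)
            vis[out_i, c] = kp.visibility
    return MotionSequence(
        exercise_id, fps, source, t[sort], coords, vis, np.array(order)
    )


# -- serialization -------------------------------------------------------


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("json", "csv"):
            raise ValueError(f"format must be 'json' or 'csv', got {fmt!r}")
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("json", "csv"):
        return suffix
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def save_sequence(
    seq: MotionSequence, path: str | Path, format: str | None = None
) -> None:
    """Write a sequence to disk (JSON reference schema or wide CSV).

    Field ordering is fixed and floats are written at full precision, so the
    output is byte-stable for a given sequence and round-trips losslessly.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        obj = {
            "exercise_id": seq.exercise_id,
            "fps": seq.fps,
            "source": seq.source,
            "frames": [
                {
                    "t": float(seq.t[i]),
                    "keypoints": [
                        {
                            "i": int(seq.landmark_indices[c]),
                            "x": float(seq.coords[i, c, 0]),
                            "y": float(seq.coords[i, c, 1]),
                            "z": float(seq.coords[i, c, 2]),
                            "v": float(seq.visibility[i, c]),
                        }
                        for c in range(seq.n_landmarks)
                    ],
                }
                for i in range(seq.n_frames)
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh, indent=1)
            fh.write("\n")
    else:
        cols = ["t"]
        for idx in seq.landmark_indices:
            for ch in "xyzv":
                cols.append(f"kp{int(idx):02d}_{ch}")
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(f"# exercise_id={seq.exercise_id}\n")
            fh.write(f"# fps={seq.fps!r}\n")
            fh.write(f"# source={seq.source}\n")
            fh.write(",".join(cols) + "\n")
            for i in range(seq.n_frames):
                row = [repr(float(seq.t[i]))]
                for c in range(seq.n_landmarks):
                    row.extend(repr(float(v)) for v in seq.coords[i, c])
                    row.append(repr(float(seq.visibility[i, c])))
                fh.write(",".join(row) + "\n")


def load_sequence(path: str | Path, format: str | None = None) -> MotionSequence:
    """Load and validate a sequence from a JSON or CSV file.

    Raises :class:`ParseError` for malformed files (naming the offending frame
    or field) and :class:`ValidationError` for structurally invalid content
    such as duplicate or missing landmark indices.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        try:
            with open(path, encoding="utf-8") as fh:
                obj = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path.name}: invalid JSON ({exc})") from exc
        for key in ("exercise_id", "fps", "source", "frames"):
            if key not in obj:
                raise ParseError(f"{path.name}: missing top-level field {key!r}")
        frames = []
        for fi, fobj in enumerate(obj["frames"]):
            try:
                kps = tuple(
                    Keypoint(
                        int(k["i"]),
                        float(k["x"]),
                        float(k["y"]),
                        float(k["z"]),
                        float(k["v"]),
                    )
                    for k in fobj["keypoints"]
                )
                frames.append(Frame(float(fobj["t"]), kps))
            except (KeyError, TypeError) as exc:
                raise ParseError(f"{path.name}: frame {fi}: bad field ({exc})") from exc
        return frames_to_sequence(
            frames, str(obj["exercise_id"]), float(obj["fps"]), str(obj["source"])
        )

    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, _, val = line.lstrip("# ").rstrip("\n").partition("=")
                meta[key.strip()] = val.strip()
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"{path.name}: invalid CSV ({exc})") from exc
    if "t" not in df.columns:
        raise ParseError(f"{path.name}: missing 't' column")
    ids: list[int] = []
    for col in df.columns:
        m = _CSV_COL_RE.match(col)
        if m and m.group(2) == "x":
            ids.append(int(m.group(1)))
    if not ids:
        raise ParseError(f"{path.name}: no kpNN_x columns found")
    ids.sort()
    n = len(df)
    coords = np.empty((n, len(ids), 3))
    vis = np.empty((n, len(ids)))
    for c, idx in enumerate(ids):
        for ch_i, ch in enumerate("xyz"):
            col = f"kp{idx:02d}_{ch}"
            if col not in df.columns:
                raise ParseError(f"{path.name}: missing column {col!r}")
            coords[:, c, ch_i] = df[col].to_numpy(dtype=float)
        vcol = f"kp{idx:02d}_v"
        if vcol not in df.columns:
            raise ParseError(f"{path.name}: missing column {vcol!r}")
        vis[:, c] = df[vcol].to_numpy(dtype=float)
    t = df["t"].to_numpy(dtype=float)
    order = np.argsort(t, kind="stable")
    return MotionSequence(
        meta.get("exercise_id", path.stem),
        float(meta.get("fps", 30.0)),
        meta.get("source", "recorded"),
        t[order],
        coords[order],
        vis[order],
        np.array(ids),
    )


# -- transformations -----------------------------------------------------


def resample_sequence(seq: MotionSequence, n_frames: int) -> MotionSequence:
    """Resample to exactly ``n_frames`` by linear interpolation in time.

    Endpoints are preserved exactly; resampling to the current length is the
    identity. Affine-in-time trajectories are reproduced exactly at any
    target length.
    """
    if n_frames < 2:
        raise ValueError(f"n_frames must be >= 2, got {n_frames}")
    if seq.n_frames < 2:
        raise ValidationError("resampling needs at least 2 frames")
    if n_frames == seq.n_frames:
        return seq.copy()
    new_t = np.linspace(seq.t[0], seq.t[-1], n_frames)
    new_t[0], new_t[-1] = seq.t[0], seq.t[-1]
    flat = seq.coords.reshape(seq.n_frames, -1)
    new_flat = np.empty((n_frames, flat.shape[1]))
    for c in range(flat.shape[1]):
        new_flat[:, c] = np.interp(new_t, seq.t, flat[:, c])
    new_vis = np.empty((n_frames, seq.n_landmarks))
    for c in range(seq.n_landmarks):
        new_vis[:, c] = np.interp(new_t, seq.t, seq.visibility[:, c])
    return replace(
        seq,
        t=new_t,
        coords=new_flat.reshape(n_frames, seq.n_landmarks, 3),
        visibility=np.clip(new_vis, 0.0, 1.0),
        landmark_indices=seq.landmark_indices.copy(),
    )


def extract_segment(seq: MotionSequence, spec: SegmentSpec) -> MotionSequence:
    """Restrict the sequence to the landmarks of ``spec`` (order preserved)."""
    missing = sorted(set(spec.indices) - set(seq.landmark_indices.tolist()))
    if missing:
        raise ValidationError(
            f"segment {spec.name!r}: landmarks {missing} absent from sequence"
        )
    cols = [seq.column_of(i) for i in spec.sorted_indices]
    return replace(
        seq,
        t=seq.t.copy(),
        coords=seq.coords[:, cols, :].copy(),
        visibility=seq.visibility[:, cols].copy(),
        landmark_indices=np.array(spec.sorted_indices),
    )


def hip_midpoint(seq: MotionSequence) -> np.ndarray:
    """Per-frame midpoint of the two hip landmarks, shape ``(n, 3)``."""
    try:
        lc = seq.column_of(LEFT_HIP)
        rc = seq.column_of(RIGHT_HIP)
    except KeyError as exc:
        raise ValidationError(
            "hip-based normalization needs landmarks 23 and 24"
        ) from exc
    return 0.5 * (seq.coords[:, lc, :] + seq.coords[:, rc, :])


def shoulder_midpoint(seq: MotionSequence) -> np.ndarray:
    try:
        lc = seq.column_of(LEFT_SHOULDER)
        rc = seq.column_of(RIGHT_SHOULDER)
    except KeyError as exc:
        raise ValidationError(
            "scaled normalization needs landmarks 11 and 12"
        ) from exc
    return 0.5 * (seq.coords[:, lc, :] + seq.coords[:, rc, :])


def normalize_pose(seq: MotionSequence, convention: str = "hip_centered") -> MotionSequence:
    """Re-express coordinates under a body-centered convention.

    ``raw`` is the identity (image-origin coordinates); ``hip_centered``
    subtracts the per-frame hip midpoint; ``hip_centered_scaled`` additionally
    divides by the per-frame torso length (hip midpoint to shoulder midpoint).
    """
    if convention not in NORMALIZATIONS:
        raise ValueError(f"convention must be one of {NORMALIZATIONS}")
    if convention == "raw":
        return seq.copy()
    hm = hip_midpoint(seq)
    centered = seq.coords - hm[:, None, :]
    if convention == "hip_centered_scaled":
        torso = np.linalg.norm(shoulder_midpoint(seq) - hm, axis=1)
        if np.any(torso < 1e-9):
            raise ValidationError("zero torso length under scaled convention")
        centered = centered / torso[:, None, None]
    return replace(
        seq,
        t=seq.t.copy(),
        coords=centered,
        visibility=seq.visibility.copy(),
        landmark_indices=seq.landmark_indices.copy(),
    )
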