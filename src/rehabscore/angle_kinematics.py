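"""Joint-angle kinematics from keypoints, in the style of optical motion
capture analysis.

An angle is computed per frame between two lines, each defined by a pair of
anatomical points; a point is either a single landmark id or a tuple of ids
(their midpoint). One line of a pair may instead be the fixed vertical
reference (the unit vector along −y of image coordinates), needed because a
marker-based lab system's external axes have no keypoint equivalent.

By default lines are undirected (the angle uses the absolute dot product and
lies in [0, 90]); a directed option keeps vector orientation and reports
angles in [0, 180] — appropriate for joint angles such as elbow flexion
where the two rays share an endpoint.

The angular-agreement score condenses two angle series into a 0–100 scale:
``100 * (1 - mean|Δangle| / 180)``, clamped. It is an explicit stand-in for
a lab system's summary score, not a reconstruction of any proprietary one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .errors import ValidationError
from .landmarks import (
    LEFT_EAR,
    LEFT_HIP,
    LEFT_SHOULDER,
    NOSE,
    RIGHT_EAR,
    RIGHT_ELBOW,
    RIGHT_HIP,
    RIGHT_SHOULDER,
    RIGHT_WRIST,
)
from .motion_model import MotionSequence

PointSpec = Union[int, tuple[int, ...]]
VERTICAL = "vertical"
_VERTICAL_DIR = np.array([0.0, -1.0, 0.0])

Line = tuple[PointSpec, PointSpec]


@dataclass(frozen=True)
class LinePair:
    """Two lines whose mutual angle is tracked over time."""

    line1: Line
    line2: Line | str  # a line, or VERTICAL for the fixed reference
    segment: str = "custom"
    directed: bool = False

    def __post_init__(self) -> None:
        for line in (self.line1, self.line2):
            if line == VERTICAL:
                continue
            a, b = line  # type: ignore[misc]
            if _point_key(a) == _point_key(b):
                raise ValidationError(
                    f"line endpoints must differ, got {line!r}"
                )


def _point_key(p: PointSpec) -> tuple[int, ...]:
    return (p,) if isinstance(p, int) else tuple(sorted(p))


@dataclass(frozen=True)
class AngleSeries:
    """Per-frame angle (degrees) of one line pair over a sequence."""

    segment: str
    t: np.ndarray
    angle_deg: np.ndarray

    def __post_init__(self) -> None:
        if self.t.shape != self.angle_deg.shape:
            raise ValidationError("t and angle_deg must have equal length")
        if np.any((self.angle_deg < -1e-9) | (self.angle_deg > 180.0 + 1e-9)):
            raise ValidationError("angles must lie in [0, 180] degrees")


def line_angle(
    p1: np.ndarray,
    p2: np.ndarray,
    q1: np.ndarray,
    q2: np.ndarray,
    directed: bool = False,
) -> float:
    """Angle in degrees between lines p1<->p2 and q1<->q2.

    Undirected (default): arccos(|u.v| / |u||v|) in [0, 90]. Directed:
    arccos(u.v / |u||v|) in [0, 180] with u = p2 - p1, v = q2 - q1.
    """
    u = np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float)
    v = np.asarray(q2, dtype=float) - np.asarray(q1, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise ValidationError("degenerate line: coincident points")
    c = np.dot(u, v) / (nu * nv)
    if not directed:
        c = abs(c)
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _resolve_points(seq: MotionSequence, p: PointSpec) -> np.ndarray:
    """Per-frame position of a point spec, shape (n, 3)."""
    if isinstance(p, int):
        return seq.coords[:, seq.column_of(p), :]
    cols = [seq.column_of(i) for i in p]
    return seq.coords[:, cols, :].mean(axis=1)


def angle_series(seq: MotionSequence, pair: LinePair) -> AngleSeries:
    """Evaluate a line pair's angle on every frame of a sequence."""
    a1 = _resolve_points(seq, pair.line1[0])
    a2 = _resolve_points(seq, pair.line1[1])
    u = a2 - a1
    if pair.line2 == VERTICAL:
        v = np.broadcast_to(_VERTICAL_DIR, u.shape)
    else:
        b1 = _resolve_points(seq, pair.line2[0])  # type: ignore[index]
        b2 = _resolve_points(seq, pair.line2[1])  # type: ignore[index]
        v = b2 - b1
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    if np.any(nu < 1e-12) or np.any(nv < 1e-12):
        bad = int(np.flatnonzero((nu < 1e-12) | (nv < 1e-12))[0])
        raise ValidationError(f"degenerate line at frame {bad}")
    c = np.einsum("ij,ij->i", u, v) / (nu * nv)
    if not pair.directed:
        c = np.abs(c)
    ang = np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
    return AngleSeries(segment=pair.segment, t=seq.t.copy(), angle_deg=ang)


def angle_agreement_score(ref: AngleSeries, pat: AngleSeries) -> float:
    """0–100 agreement between two angle series.

    The patient series is linearly resampled onto the reference timestamps
    (after mapping both onto a common normalized time axis), then
    ``100 * (1 - mean|Δ| / 180)`` clamped to [0, 100]; 100 iff identical.
    """
    if len(ref.t) < 2 or len(pat.t) < 2:
        raise ValidationError("agreement needs >= 2 samples per series")
    ref_u = (ref.t - ref.t[0]) / (ref.t[-1] - ref.t[0])
    pat_u = (pat.t - pat.t[0]) / (pat.t[-1] - pat.t[0])
    pat_on_ref = np.interp(ref_u, pat_u, pat.angle_deg)
    mad = float(np.mean(np.abs(ref.angle_deg - pat_on_ref)))
    return float(np.clip(100.0 * (1.0 - mad / 180.0), 0.0, 100.0))


# Default line pairs: anatomically standard stand-ins for a marker-based
# protocol. The trunk line is shoulder-midpoint <-> hip-midpoint.
_TRUNK_LINE: Line = ((LEFT_SHOULDER, RIGHT_SHOULDER), (LEFT_HIP, RIGHT_HIP))

TRUNK_PAIR = LinePair(line1=_TRUNK_LINE, line2=VERTICAL, segment="trunk")
SHOULDER_PAIR_RIGHT = LinePair(
    line1=(RIGHT_SHOULDER, RIGHT_ELBOW), line2=_TRUNK_LINE, segment="shoulder"
)
HEAD_PAIR = LinePair(
    line1=(NOSE, (LEFT_EAR, RIGHT_EAR)), line2=_TRUNK_LINE, segment="head"
)
# The standing diagonal's target geometry: full arm line vs head line.
ARM_HEAD_PAIR_RIGHT = LinePair(
    line1=(RIGHT_SHOULDER, RIGHT_WRIST),
    line2=(NOSE, (LEFT_EAR, RIGHT_EAR)),
    segment="arm_head",
)
# Elbow flexion: upper arm vs forearm, sharing the elbow vertex (directed).
ELBOW_PAIR_RIGHT = LinePair(
    line1=(RIGHT_ELBOW, RIGHT_SHOULDER),
    line2=(RIGHT_ELBOW, RIGHT_WRIST),
    segment="elbow",
    directed=True,
)

DEFAULT_PAIRS: dict[str, LinePair] = {
    "trunk": TRUNK_PAIR,
    "shoulder": SHOULDER_PAIR_RIGHT,
    "head": HEAD_PAIR,
    "arm_head": ARM_HEAD_PAIR_RIGHT,
    "elbow": ELBOW_PAIR_RIGHT,
}
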