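"""Frame-wise cosine-similarity exercise scoring.

For each frame, the 3-D position vector of every landmark in the patient
trial is compared with the corresponding landmark of the reference using
cosine similarity, ``sim(u, v) = u.v / (|u||v|)``, which is rescaled from
``[-1, 1]`` onto ``[0, 1]`` via ``(s + 1) / 2``. The mean of the rescaled
similarities over the frame's landmarks is the frame score; a frame whose
mean exceeds the correctness threshold (default 0.90) counts as "correct",
and the exercise score is the percentage of correct frames.

Position vectors are, by default, expressed relative to the per-frame hip
midpoint (``hip_centered``): with image-origin vectors the similarity is
dominated by where the person stands in the frame rather than by posture.
Both conventions are available.

Length mismatch between reference and trial is reconciled by linearly
resampling the reference to the trial's frame count and pairing frames
index-by-index. Note this exactly compensates a uniform speed difference on
a noiseless trial; timing robustness beyond that is the DTW engine's job.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateVectorError, ValidationError
from .motion_model import Frame, MotionSequence, normalize_pose, resample_sequence

logger = logging.getLogger(__name__)

_ZERO_NORM = 1e-12


@dataclass(frozen=True)
class ScoringOptions:
    """Options for frame and exercise scoring.

    normalization:
        coordinate convention applied to both sequences before comparison
        (``raw``, ``hip_centered``, ``hip_centered_scaled``). Use ``raw`` if
        the inputs are already normalized.
    min_visibility:
        landmarks whose visibility falls below this cutoff in either frame
        are excluded from the frame mean (default 0: include all).
    threshold_on_rescaled:
        if True (default) the correctness threshold applies to the mean
        rescaled similarity in [0, 1]; if False it applies to the mean raw
        cosine in [-1, 1].
    """

    normalization: str = "hip_centered"
    min_visibility: float = 0.0
    threshold_on_rescaled: bool = True


@dataclass(frozen=True)
class FrameScore:
    """Similarity of one reference/trial frame pair."""

    frame_index: int
    per_keypoint_similarity: np.ndarray  # rescaled to [0, 1]; NaN = excluded
    mean_similarity: float  # mean of included rescaled similarities
    correct: bool
    n_excluded: int = 0


@dataclass(frozen=True)
class ExerciseScore:
    """Percent-correct score over a whole trial."""

    percent_correct: float
    n_frames: int
    n_correct: int
    threshold: float
    frame_scores: tuple[FrameScore, ...] = field(repr=False, default=())

    def to_dict(self) -> dict:
        return {
            "percent_correct": self.percent_correct,
            "n_frames": self.n_frames,
            "n_correct": self.n_correct,
            "threshold": self.threshold,
            "frame_mean_similarity": [
                fs.mean_similarity for fs in self.frame_scores
            ],
        }


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two nonzero 3-vectors, in [-1, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu < _ZERO_NORM or nv < _ZERO_NORM:
        raise DegenerateVectorError("cosine similarity undefined for zero vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def rescale_similarity(s: float) -> float:
    """Map a cosine similarity from [-1, 1] onto [0, 1] via (s + 1) / 2."""
    if not -1.0 - 1e-9 <= s <= 1.0 + 1e-9:
        raise ValueError(f"similarity {s} outside [-1, 1]")
    return float(np.clip((s + 1.0) / 2.0, 0.0, 1.0))


def _pairwise_rescaled(
    ref_xyz: np.ndarray,
    pat_xyz: np.ndarray,
    include: np.ndarray,
) -> np.ndarray:
    """Rescaled similarities for (k, 3) landmark arrays; NaN where excluded.

    Landmarks with a zero-length vector in either frame (possible after hip
    centering) are excluded — the cosine is undefined there.
    """
    nu = np.linalg.norm(ref_xyz, axis=-1)
    nv = np.linalg.norm(pat_xyz, axis=-1)
    ok = include & (nu > _ZERO_NORM) & (nv > _ZERO_NORM)
    sims = np.full(ref_xyz.shape[0], np.nan)
    dots = np.einsum("...i,...i->...", ref_xyz, pat_xyz)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.clip(dots / (nu * nv), -1.0, 1.0)
    sims[ok] = (raw[ok] + 1.0) / 2.0
    n_zero = int(np.count_nonzero(include & ~ok))
    if n_zero:
        logger.debug("excluded %d zero-length keypoint vectors", n_zero)
    return sims


def frame_similarity(
    ref_frame: Frame,
    pat_frame: Frame,
    threshold: float = 0.90,
    options: ScoringOptions = ScoringOptions(normalization="raw"),
    frame_index: int = 0,
) -> FrameScore:
    """Score one frame pair (assumed already expressed under one convention).

    One rescaled similarity per landmark; the mean is over landmarks passing
    the visibility cutoff and having nonzero vectors in both frames.
    """
    ref_ids = tuple(kp.index for kp in ref_frame.keypoints)
    pat_ids = tuple(kp.index for kp in pat_frame.keypoints)
    if ref_ids != pat_ids:
        raise ValidationError("frames carry different landmark sets")
    ref_xyz = np.array([kp.vector for kp in ref_frame.keypoints])
    pat_xyz = np.array([kp.vector for kp in pat_frame.keypoints])
    vis_ok = np.array(
        [
            kr.visibility >= options.min_visibility
            and kp.visibility >= options.min_visibility
            for kr, kp in zip(ref_frame.keypoints, pat_frame.keypoints)
        ]
    )
    sims = _pairwise_rescaled(ref_xyz, pat_xyz, vis_ok)
    included = ~np.isnan(sims)
    if not included.any():
        raise ValidationError("no landmarks left to compare after filtering")
    mean_rescaled = float(np.mean(sims[included]))
    correct = _is_correct(mean_rescaled, threshold, options)
    return FrameScore(
        frame_index=frame_index,
        per_keypoint_similarity=sims,
        mean_similarity=mean_rescaled,
        correct=correct,
        n_excluded=int(np.count_nonzero(~included)),
    )


def _is_correct(mean_rescaled: float, threshold: float, options: ScoringOptions) -> bool:
    if options.threshold_on_rescaled:
        return mean_rescaled > threshold
    return (2.0 * mean_rescaled - 1.0) > threshold


def score_exercise(
    ref: MotionSequence,
    pat: MotionSequence,
    threshold: float = 0.90,
    options: ScoringOptions = ScoringOptions(),
) -> ExerciseScore:
    """Percent-correct cosine score of a trial against a reference.

    The reference is resampled to the trial's frame count, both sequences are
    re-expressed under ``options.normalization``, and frames are paired
    index-by-index. Deterministic.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if ref.n_frames < 2 or pat.n_frames < 2:
        raise ValidationError("scoring needs at least 2 frames per sequence")
    if not np.array_equal(ref.landmark_indices, pat.landmark_indices):
        raise ValidationError("sequences carry different landmark sets")
    ref_rs = resample_sequence(ref, pat.n_frames)
    ref_n = normalize_pose(ref_rs, options.normalization)
    pat_n = normalize_pose(pat, options.normalization)

    vis_ok = (ref_n.visibility >= options.min_visibility) & (
        pat_n.visibility >= options.min_visibility
    )
    frame_scores = []
    n_correct = 0
    for i in range(pat_n.n_frames):
        sims = _pairwise_rescaled(ref_n.coords[i], pat_n.coords[i], vis_ok[i])
        included = ~np.isnan(sims)
        if not included.any():
            raise ValidationError(f"frame {i}: no landmarks left to compare")
        mean_rescaled = float(np.mean(sims[included]))
        correct = _is_correct(mean_rescaled, threshold, options)
        n_correct += int(correct)
        frame_scores.append(
            FrameScore(
                frame_index=i,
                per_keypoint_similarity=sims,
                mean_similarity=mean_rescaled,
                correct=correct,
                n_excluded=int(np.count_nonzero(~included)),
            )
        )
    n = pat_n.n_frames
    return ExerciseScore(
        percent_correct=100.0 * n_correct / n,
        n_frames=n,
        n_correct=n_correct,
        threshold=threshold,
        frame_scores=tuple(frame_scores),
    )
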