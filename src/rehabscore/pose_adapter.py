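"""Optional video → keypoints adapter.

This is the only module allowed to touch video. A backend turns a video
path into per-frame landmark arrays; the adapter subsamples frames by a
fixed stride, flags low-visibility landmarks and assembles a validated
:class:`~rehabscore.motion_model.MotionSequence`. The core library never
imports a pose-estimation or video library: the reference backend
(MediaPipe + imageio) raises a capability error when those packages are
absent, and a scripted stub backend keeps everything testable offline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol

import numpy as np

from .errors import BackendUnavailableError, ValidationError
from .landmarks import N_LANDMARKS
from .motion_model import MotionSequence, load_sequence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AdapterConfig:
    """Frame selection and flagging policy for keypoint extraction.

    frame_stride:
        keep every k-th video frame (>= 1); reproducible, unlike adaptive
        sampling.
    min_visibility:
        landmarks below this confidence keep their coordinates but are
        counted and logged as low-confidence.
    backend:
        backend identifier (see :func:`get_backend`).
    """

    frame_stride: int = 1
    min_visibility: float = 0.0
    backend: str = "stub"

    def __post_init__(self) -> None:
        if self.frame_stride < 1:
            raise ValidationError("frame_stride must be >= 1")
        if not 0.0 <= self.min_visibility <= 1.0:
            raise ValidationError("min_visibility must be in [0, 1]")


class PoseBackend(Protocol):
    """A pose-estimation backend: video path → (fps, per-frame landmarks).

    Each frame is a float array of shape (33, 4): x, y, z, visibility. A
    frame with no detectable person is reported as None.
    """

    name: str

    def read(self, video_path: str | Path) -> tuple[float, list[np.ndarray | None]]:
        ...


class StubBackend:
    """Scripted backend for tests and offline use.

    Either constructed with explicit per-frame landmark arrays, or pointed
    at a saved motion file (JSON/CSV) which it replays as if it were the
    decoded video.
    """

    name = "stub"

    def __init__(
        self,
        frames: list[np.ndarray | None] | None = None,
        fps: float = 30.0,
    ) -> None:
        self._frames = frames
        self._fps = fps

    def read(self, video_path: str | Path) -> tuple[float, list[np.ndarray | None]]:
        if self._frames is not None:
            return self._fps, list(self._frames)
        seq = load_sequence(video_path)
        frames: list[np.ndarray | None] = []
        for i in range(seq.n_frames):
            arr = np.empty((seq.n_landmarks, 4))
            arr[:, :3] = seq.coords[i]
            arr[:, 3] = seq.visibility[i]
            frames.append(arr)
        return seq.fps, frames


class MediaPipeBackend:
    """Reference backend calling the external pose model on decoded frames.

    Requires the optional ``mediapipe`` and ``imageio`` packages; raises
    :class:`BackendUnavailableError` at construction when they are missing
    so the core library stays importable and testable without them.
    """

    name = "mediapipe"

    def __init__(self) -> None:
        try:
            import imageio.v3 as iio  # noqa: F401
            import mediapipe as mp
        except ImportError as exc:
            raise BackendUnavailableError(
                "the 'mediapipe' backend needs the mediapipe and imageio "
                "packages (install the [video] extra)"
            ) from exc
        self._mp = mp

    def read(self, video_path: str | Path) -> tuple[float, list[np.ndarray | None]]:
        import imageio.v3 as iio

        meta = iio.immeta(video_path, plugin="pyav")
        fps = float(meta.get("fps", 30.0))
        pose = self._mp.solutions.pose.Pose(static_image_mode=False)
        frames: list[np.ndarray | None] = []
        for frame in iio.imiter(video_path, plugin="pyav"):
            result = pose.process(frame)
            if result.pose_landmarks is None:
                frames.append(None)
                continue
            arr = np.array(
                [
                    (lm.x, lm.y, lm.z, lm.visibility)
                    for lm in result.pose_landmarks.landmark
                ]
            )
            frames.append(arr)
        pose.close()
        return fps, frames


_BACKENDS = {"stub": StubBackend, "mediapipe": MediaPipeBackend}


def get_backend(name: str) -> PoseBackend:
    try:
        factory = _BACKENDS[name]
    except KeyError:
        raise BackendUnavailableError(
            f"unknown backend {name!r}; available: {sorted(_BACKENDS)}"
        ) from None
    return factory()


def extract_keypoints(
    video_path: str | Path,
    config: AdapterConfig = AdapterConfig(),
    backend: PoseBackend | None = None,
) -> MotionSequence:
    """Extract a MotionSequence from a video via a pose backend.

    Every ``config.frame_stride``-th decoded frame is kept; the output fps
    is the source fps divided by the stride and timestamps are re-derived
    as frame_index / fps. Landmarks below ``min_visibility`` keep their
    coordinates and their (low) visibility value. Frames with no detected
    person are dropped with a warning; a clip with none at all yields an
    empty sequence.
    """
    if backend is None:
        backend = get_backend(config.backend)
    src_fps, raw_frames = backend.read(video_path)
    kept = raw_frames[:: config.frame_stride]
    out_fps = src_fps / config.frame_stride

    arrays = [f for f in kept if f is not None]
    n_missing = len(kept) - len(arrays)
    if n_missing:
        logger.warning(
            "%s: %d of %d retained frames had no detectable person",
            Path(video_path).name,
            n_missing,
            len(kept),
        )
    if not arrays:
        logger.warning("%s: no person detected in any frame", Path(video_path).name)
        return MotionSequence(
            exercise_id=Path(video_path).stem,
            fps=out_fps,
            source="recorded",
            t=np.empty(0),
            coords=np.empty((0, N_LANDMARKS, 3)),
            visibility=np.empty((0, N_LANDMARKS)),
        )
    k = arrays[0].shape[0]
    for i, arr in enumerate(arrays):
        if arr.shape != (k, 4):
            raise ValidationError(
                f"backend frame {i}: expected shape ({k}, 4), got {arr.shape}"
            )
    coords = np.stack([a[:, :3] for a in arrays])
    vis = np.clip(np.stack([a[:, 3] for a in arrays]), 0.0, 1.0)
    n_low = int(np.count_nonzero(vis < config.min_visibility))
    if n_low:
        logger.info(
            "%s: %d landmark samples below min_visibility=%.2f",
            Path(video_path).name,
            n_low,
            config.min_visibility,
        )
    t = np.arange(len(arrays)) / out_fps
    return MotionSequence(
        exercise_id=Path(video_path).stem,
        fps=out_fps,
        source="recorded",
        t=t,
        coords=coords,
        visibility=vis,
        landmark_indices=np.arange(k),
    )
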