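"""Dynamic time warping between keypoint sequences.

``dtw_exact`` solves the classical DTW problem by full dynamic programming
with the symmetric step pattern {(1,0), (0,1), (1,1)}, unit weights and no
window; the local cost is the Euclidean distance between the concatenated
landmark coordinate vectors of the paired frames. ``dtw_fast`` is a
multiresolution approximation in the style of FastDTW: the sequences are
repeatedly halved, the coarse optimal path is projected up and refined
within a given radius. The approximation optimizes over a subset of warping
paths, so its distance is always an upper bound on the exact distance and
coincides with it when the radius reaches the sequence length.

Batch normalization maps raw distances to the percentage scale used for
reporting: 0% is anchored at the batch mean distance and 100% at the batch
maximum, with values below the mean clamped to 0; conventional z-scores are
exposed alongside for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DegenerateBatchError, ValidationError
from .motion_model import MotionSequence, SegmentSpec, extract_segment, normalize_pose

_STEPS = ((-1, -1), (-1, 0), (0, -1))  # backtracking preference: diagonal first


@dataclass
class DTWResult:
    """Outcome of one DTW alignment.

    ``distance`` is the sum of local costs along the optimal monotone path
    ``path`` (index pairs from (0,0) to (n-1,m-1)); ``normalized_percent``
    stays None until batch normalization assigns it.
    """

    distance: float
    path: list[tuple[int, int]]
    segment: str = "all"
    normalized_percent: float | None = None


@dataclass(frozen=True)
class BatchNormalization:
    """Affine distance-to-percent mapping anchored at the batch statistics.

    ``percent(mean_distance) == 0`` and ``percent(max_distance) == 100``;
    distances below the mean clamp to 0, above the max to 100.
    """

    mean_distance: float
    max_distance: float
    sd_distance: float

    def percent(self, d: float) -> float:
        span = self.max_distance - self.mean_distance
        return float(np.clip(100.0 * (d - self.mean_distance) / span, 0.0, 100.0))

    def zscore(self, d: float) -> float:
        """Auxiliary conventional z-score of a distance within the batch."""
        if self.sd_distance == 0:
            return 0.0
        return float((d - self.mean_distance) / self.sd_distance)


def _features(seq: MotionSequence) -> np.ndarray:
    return seq.coords.reshape(seq.n_frames, -1)


def _dp_matrix(cost: np.ndarray, window: np.ndarray | None = None) -> np.ndarray:
    """Accumulated-cost matrix via anti-diagonal vectorized DP.

    ``window`` (boolean mask) restricts admissible cells; cells outside stay
    at +inf. D[i, j] = cost[i, j] + min(D[i-1, j], D[i, j-1], D[i-1, j-1]).
    """
    n, m = cost.shape
    if window is not None:
        cost = np.where(window, cost, np.inf)
    D = np.full((n, m), np.inf)
    D[0, 0] = cost[0, 0]
    for k in range(1, n + m - 1):
        i0 = max(0, k - m + 1)
        i1 = min(n - 1, k)
        i = np.arange(i0, i1 + 1)
        j = k - i
        best = np.full(i.shape, np.inf)
        up = i > 0
        best[up] = D[i[up] - 1, j[up]]
        left = j > 0
        best[left] = np.minimum(best[left], D[i[left], j[left] - 1])
        diag = up & left
        best[diag] = np.minimum(best[diag], D[i[diag] - 1, j[diag] - 1])
        D[i, j] = cost[i, j] + best
    return D


def _backtrack(D: np.ndarray) -> list[tuple[int, int]]:
    n, m = D.shape
    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        best = None
        best_val = np.inf
        for di, dj in _STEPS:
            pi, pj = i + di, j + dj
            if pi < 0 or pj < 0:
                continue
            if D[pi, pj] < best_val:
                best_val = D[pi, pj]
                best = (pi, pj)
        assert best is not None, "disconnected DP matrix"
        i, j = best
        path.append((i, j))
    path.reverse()
    return path


def _dtw_arrays(
    x: np.ndarray, y: np.ndarray, window: np.ndarray | None = None
) -> tuple[float, list[tuple[int, int]]]:
    cost = cdist(x, y)
    D = _dp_matrix(cost, window)
    dist = float(D[-1, -1])
    if not np.isfinite(dist):
        raise ValidationError("DTW window disconnected; no admissible path")
    return dist, _backtrack(D)


def _check_pair(a: MotionSequence, b: MotionSequence) -> None:
    if a.n_frames < 1 or b.n_frames < 1:
        raise ValidationError("DTW needs nonempty sequences")
    if not np.array_equal(a.landmark_indices, b.landmark_indices):
        raise ValidationError("sequences carry different landmark sets")


def dtw_exact(
    a: MotionSequence, b: MotionSequence, metric: str = "euclidean"
) -> DTWResult:
    """Optimal DTW alignment by full dynamic programming."""
    if metric != "euclidean":
        raise ValueError("only the euclidean local metric is supported")
    _check_pair(a, b)
    dist, path = _dtw_arrays(_features(a), _features(b))
    return DTWResult(distance=dist, path=path)


def _reduce_by_half(x: np.ndarray) -> np.ndarray:
    n = len(x) - (len(x) % 2)
    return 0.5 * (x[0:n:2] + x[1:n:2])


def _expand_window(
    path: list[tuple[int, int]], n: int, m: int, radius: int
) -> np.ndarray:
    """Project a half-resolution path up and dilate it by ``radius``."""
    mask = np.zeros((n, m), dtype=bool)
    for li, lj in path:
        i_lo = max(0, 2 * li - radius)
        i_hi = min(n, 2 * li + 2 + radius)
        j_lo = max(0, 2 * lj - radius)
        j_hi = min(m, 2 * lj + 2 + radius)
        mask[i_lo:i_hi, j_lo:j_hi] = True
    mask[0, 0] = True
    mask[n - 1, m - 1] = True
    return mask


def _fastdtw_arrays(
    x: np.ndarray, y: np.ndarray, radius: int
) -> tuple[float, list[tuple[int, int]]]:
    min_size = radius + 2
    if len(x) <= min_size or len(y) <= min_size:
        return _dtw_arrays(x, y)
    coarse_dist, coarse_path = _fastdtw_arrays(
        _reduce_by_half(x), _reduce_by_half(y), radius
    )
    window = _expand_window(coarse_path, len(x), len(y), radius)
    return _dtw_arrays(x, y, window)


def dtw_fast(
    a: MotionSequence,
    b: MotionSequence,
    metric: str = "euclidean",
    radius: int = 1,
) -> DTWResult:
    """FastDTW-style approximate alignment.

    ``radius`` controls the refinement width; ``radius >= max(n, m)`` makes
    the constraint vacuous and reproduces :func:`dtw_exact` exactly. The
    returned distance never undercuts the exact distance.
    """
    if metric != "euclidean":
        raise ValueError("only the euclidean local metric is supported")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    _check_pair(a, b)
    dist, path = _fastdtw_arrays(_features(a), _features(b), radius)
    return DTWResult(distance=dist, path=path)


def segment_dtw(
    ref: MotionSequence,
    pat: MotionSequence,
    specs: Sequence[SegmentSpec],
    engine: str = "exact",
    radius: int = 1,
    normalization: str = "hip_centered",
) -> dict[str, DTWResult]:
    """DTW per body segment.

    Both sequences are first re-expressed under ``normalization`` (the same
    convention the cosine scorer uses), then each segment's landmark subset
    is extracted and aligned independently.
    """
    if engine not in ("exact", "fast"):
        raise ValueError("engine must be 'exact' or 'fast'")
    ref_n = normalize_pose(ref, normalization)
    pat_n = normalize_pose(pat, normalization)
    out: dict[str, DTWResult] = {}
    for spec in specs:
        r = extract_segment(ref_n, spec)
        p = extract_segment(pat_n, spec)
        res = (
            dtw_exact(r, p)
            if engine == "exact"
            else dtw_fast(r, p, radius=radius)
        )
        out[spec.name] = replace(res, segment=spec.name)
    return out


def normalize_batch(
    distances: Sequence[float],
) -> tuple[list[float], BatchNormalization]:
    """Map a batch of raw DTW distances onto the 0–100% reporting scale.

    0% is the batch mean distance, 100% the batch maximum; distances below
    the mean clamp to 0. Needs at least two distances with max > mean.
    """
    d = np.asarray(list(distances), dtype=float)
    if d.size < 2:
        raise DegenerateBatchError("batch normalization needs >= 2 distances")
    if np.any(d < 0) or np.any(~np.isfinite(d)):
        raise DegenerateBatchError("distances must be finite and >= 0")
    mean = float(d.mean())
    mx = float(d.max())
    if mx - mean <= 1e-12 * max(mx, 1.0):
        raise DegenerateBatchError(
            "degenerate batch: max distance equals mean distance"
        )
    bn = BatchNormalization(
        mean_distance=mean,
        max_distance=mx,
        sd_distance=float(d.std(ddof=1)),
    )
    return [bn.percent(v) for v in d], bn


def max_consecutive_step(seq: MotionSequence) -> float:
    """Largest Euclidean feature-space step between consecutive frames."""
    f = _features(seq)
    if len(f) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(f, axis=0), axis=1).max())


def warp_cost_bound(ref: MotionSequence, n_trial: int) -> float:
    """Analytic upper bound on the DTW distance of an on-trajectory re-timing.

    If every trial frame lies on the reference's piecewise-linear trajectory
    (pure idle lead-in and/or uniform speed change, no noise), the monotone
    merge-by-time alignment pairs frames whose positions differ by at most
    one local step, so its total cost — and hence the optimal DTW distance —
    is bounded by ``(n + m) * max_step * max(1, (n-1)/(m-1))``.
    """
    n = ref.n_frames
    step = max_consecutive_step(ref)
    stretch = max(1.0, (n - 1) / max(1, n_trial - 1))
    return (n + n_trial) * step * stretch
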