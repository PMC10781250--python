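"""DTW engine: exact DP vs path enumeration, FastDTW bounds, normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rehabscore.dtw_engine import (
    dtw_exact,
    dtw_fast,
    max_consecutive_step,
    normalize_batch,
    segment_dtw,
    warp_cost_bound,
)
from rehabscore.errors import DegenerateBatchError, ValidationError
from rehabscore.motion_model import (
    DEFAULT_SEGMENTS,
    MotionSequence,
    extract_segment,
    normalize_pose,
)
from rehabscore.synthetic_motion import PerturbationParams, perturb

from conftest import make_random_sequence


def seq_1d(values, fps: float = 1.0) -> MotionSequence:
    """A single-landmark sequence whose x coordinate carries the series."""
    values = np.asarray(values, dtype=float)
    coords = np.zeros((len(values), 1, 3))
    coords[:, 0, 0] = values
    return MotionSequence(
        "1d", fps, "synthetic", np.arange(len(values)) / fps,
        coords, np.ones((len(values), 1)), np.array([0]),
    )


def enumerate_min_path_cost(cost: np.ndarray) -> float:
    """Independent oracle: exhaustive DFS over every monotone warping path."""
    n, m = cost.shape
    best = [np.inf]

    def walk(i, j, acc):
        acc += cost[i, j]
        if acc >= best[0]:
            return  # cannot improve (all costs nonnegative)
        if i == n - 1 and j == m - 1:
            best[0] = acc
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, acc)
        if i + 1 < n:
            walk(i + 1, j, acc)
        if j + 1 < m:
            walk(i, j + 1, acc)

    walk(0, 0, 0.0)
    return best[0]


def _path_is_valid(path, n, m):
    if path[0] != (0, 0) or path[-1] != (n - 1, m - 1):
        return False
    for (i0, j0), (i1, j1) in zip(path, path[1:]):
        if (i1 - i0, j1 - j0) not in ((1, 0), (0, 1), (1, 1)):
            return False
    return True


class TestExactDTW:
    def test_identity_gives_zero_and_diagonal_path(self, random_seq):
        res = dtw_exact(random_seq, random_seq)
        assert res.distance == pytest.approx(0.0, abs=1e-12)
        assert res.path == [(i, i) for i in range(random_seq.n_frames)]

    def test_singleton_sequences(self):
        res = dtw_exact(seq_1d([1.0]), seq_1d([4.0]))
        assert res.distance == pytest.approx(3.0)
        assert res.path == [(0, 0)]

    def test_small_example_matches_enumeration(self):
        a, b = seq_1d([1, 2, 3]), seq_1d([1, 3])
        cost = np.abs(np.subtract.outer([1.0, 2.0, 3.0], [1.0, 3.0]))
        assert dtw_exact(a, b).distance == pytest.approx(
            enumerate_min_path_cost(cost)
        )

    def test_random_instances_match_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            n, m = rng.integers(2, 9, size=2)
            a = seq_1d(rng.normal(size=n))
            b = seq_1d(rng.normal(size=m))
            res = dtw_exact(a, b)
            cost = np.abs(
                np.subtract.outer(a.coords[:, 0, 0], b.coords[:, 0, 0])
            )
            assert res.distance == pytest.approx(enumerate_min_path_cost(cost))
            assert _path_is_valid(res.path, n, m)
            # distance equals the sum of local costs along the path
            assert res.distance == pytest.approx(
                sum(cost[i, j] for i, j in res.path), abs=1e-9
            )

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = seq_1d(rng.normal(size=rng.integers(2, 12)))
        b = seq_1d(rng.normal(size=rng.integers(2, 12)))
        assert dtw_exact(a, b).distance == pytest.approx(
            dtw_exact(b, a).distance, abs=1e-9
        )

    def test_mismatched_landmark_sets_rejected(self, random_seq):
        head = extract_segment(random_seq, DEFAULT_SEGMENTS["head"])
        with pytest.raises(ValidationError):
            dtw_exact(random_seq, head)


class TestFastDTW:
    def test_identical_sequences_zero_any_radius(self, random_seq):
        for radius in (0, 1, 5):
            assert dtw_fast(random_seq, random_seq, radius=radius).distance == (
                pytest.approx(0.0, abs=1e-12)
            )

    def test_vacuous_radius_equals_exact(self):
        rng = np.random.default_rng(1)
        for seed in range(10):
            n, m = rng.integers(10, 40, size=2)
            a = seq_1d(rng.normal(size=n))
            b = seq_1d(rng.normal(size=m))
            exact = dtw_exact(a, b).distance
            fast = dtw_fast(a, b, radius=int(max(n, m))).distance
            assert fast == pytest.approx(exact, abs=1e-12)

    def test_never_undercuts_exact(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            a = seq_1d(np.cumsum(rng.normal(size=50)))
            b = seq_1d(np.cumsum(rng.normal(size=50)))
            exact = dtw_exact(a, b).distance
            fast = dtw_fast(a, b, radius=1).distance
            assert fast >= exact - 1e-9

    def test_path_valid(self):
        rng = np.random.default_rng(3)
        a = seq_1d(rng.normal(size=37))
        b = seq_1d(rng.normal(size=50))
        res = dtw_fast(a, b, radius=2)
        assert _path_is_valid(res.path, 37, 50)


class TestSegmentDTW:
    def test_identity_gives_zero_per_segment(self, standing_ref):
        specs = [DEFAULT_SEGMENTS[n] for n in ("head", "trunk", "shoulder")]
        out = segment_dtw(standing_ref, standing_ref, specs)
        assert set(out) == {"head", "trunk", "shoulder"}
        for res in out.values():
            assert res.distance == pytest.approx(0.0, abs=1e-12)

    def test_arm_only_perturbation_hits_shoulder_segment_most(self, standing_ref):
        specs = [DEFAULT_SEGMENTS[n] for n in ("head", "trunk", "shoulder")]
        arm_cols = [standing_ref.column_of(i) for i in (14, 16)]
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pat = standing_ref.copy()
            pat.coords[:, arm_cols, :] += rng.normal(0, 0.02, (pat.n_frames, 2, 3))
            out = segment_dtw(standing_ref, pat, specs, engine="fast")
            if (
                out["shoulder"].distance > out["head"].distance
                and out["shoulder"].distance > out["trunk"].distance
            ):
                wins += 1
        assert wins == 20

    def test_three_specs_in_three_results_out(self, random_seq):
        specs = [DEFAULT_SEGMENTS[n] for n in ("head", "trunk", "shoulder")]
        out = segment_dtw(random_seq, make_random_sequence(seed=5), specs)
        assert len(out) == 3


class TestBatchNormalization:
    def test_mean_anchors_zero_and_max_anchors_hundred(self):
        percents, bn = normalize_batch([2.0, 4.0, 6.0])
        assert percents == [0.0, 0.0, 100.0]
        assert bn.percent(bn.mean_distance) == 0.0
        assert bn.percent(bn.max_distance) == 100.0

    def test_two_point_batch(self):
        percents, _ = normalize_batch([0.0, 10.0])
        assert percents == [0.0, 100.0]

    def test_affine_map_between_anchors(self):
        _, bn = normalize_batch([1.0, 2.0, 3.0, 10.0])
        assert bn.mean_distance == pytest.approx(4.0)
        assert bn.percent(7.0) == pytest.approx(50.0)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        scale=st.floats(0.01, 100.0),
    )
    def test_invariant_to_positive_scaling(self, seed, scale):
        rng = np.random.default_rng(seed)
        d = rng.uniform(0.0, 5.0, size=6)
        d[0] += 1.0  # guarantee max > mean
        p1, _ = normalize_batch(d)
        p2, _ = normalize_batch(scale * d)
        np.testing.assert_allclose(p1, p2, atol=1e-9)

    def test_degenerate_batch_rejected(self):
        with pytest.raises(DegenerateBatchError):
            normalize_batch([3.0, 3.0, 3.0])
        with pytest.raises(DegenerateBatchError):
            normalize_batch([1.0])

    def test_zscore_auxiliary_output(self):
        _, bn = normalize_batch([2.0, 4.0, 6.0])
        assert bn.zscore(bn.mean_distance) == pytest.approx(0.0)
        assert bn.zscore(6.0) == pytest.approx(1.0)  # sd([2,4,6]) = 2


class TestWarpBound:
    def test_speed_change_stays_below_analytic_bound(self, standing_ref):
        ref_seg = extract_segment(
            normalize_pose(standing_ref, "hip_centered"),
            DEFAULT_SEGMENTS["shoulder"],
        )
        for seed, speed in enumerate((0.7, 0.85, 1.2, 1.4)):
            pat = perturb(standing_ref, PerturbationParams(speed_factor=speed, seed=seed))
            pat_seg = extract_segment(
                normalize_pose(pat, "hip_centered"), DEFAULT_SEGMENTS["shoulder"]
            )
            d = dtw_exact(ref_seg, pat_seg).distance
            assert d <= warp_cost_bound(ref_seg, pat_seg.n_frames)

    def test_max_step_of_static_sequence_is_zero(self):
        seq = seq_1d([2.0, 2.0, 2.0])
        assert max_consecutive_step(seq) == 0.0
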