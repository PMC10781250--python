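"""Frame-wise cosine scoring: formula, rescaling, thresholds, invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rehabscore.cosine_scoring import (
    ScoringOptions,
    cosine_similarity,
    frame_similarity,
    rescale_similarity,
    score_exercise,
)
from rehabscore.errors import DegenerateVectorError, ValidationError
from rehabscore.motion_model import (
    DEFAULT_SEGMENTS,
    Frame,
    Keypoint,
    extract_segment,
    normalize_pose,
)
from rehabscore.synthetic_motion import PerturbationParams, perturb

from conftest import make_random_sequence

RAW_OPTS = ScoringOptions(normalization="raw")


class TestCosineSimilarity:
    def test_identical_vectors_give_one(self):
        assert cosine_similarity((0.3, 0.5, 0.1), (0.3, 0.5, 0.1)) == pytest.approx(1.0)

    def test_orthogonal_vectors_give_zero(self):
        assert cosine_similarity((1, 0, 0), (0, 1, 0)) == pytest.approx(0.0, abs=1e-12)

    def test_parallel_vectors_scale_invariant(self):
        assert cosine_similarity((1, 2, 3), (2, 4, 6)) == pytest.approx(1.0)

    def test_symmetry(self):
        u, v = (0.2, -0.4, 0.1), (0.9, 0.3, -0.5)
        assert cosine_similarity(u, v) == cosine_similarity(v, u)

    def test_zero_vector_rejected(self):
        with pytest.raises(DegenerateVectorError):
            cosine_similarity((0, 0, 0), (1, 0, 0))


class TestRescale:
    @pytest.mark.parametrize("s, expected", [(1.0, 1.0), (-1.0, 0.0), (0.0, 0.5)])
    def test_endpoints_and_midpoint(self, s, expected):
        assert rescale_similarity(s) == pytest.approx(expected)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.floats(-1.0, 1.0), st.floats(-1.0, 1.0))
    def test_monotone_bijection_onto_unit_interval(self, a, b):
        ra, rb = rescale_similarity(a), rescale_similarity(b)
        assert 0.0 <= ra <= 1.0
        if a < b:
            assert ra <= rb
        if b - a > 1e-12:
            assert ra < rb

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rescale_similarity(1.5)


def _frame_from(coords: np.ndarray, vis: float = 1.0) -> Frame:
    kps = tuple(
        Keypoint(i, float(x), float(y), float(z), vis)
        for i, (x, y, z) in enumerate(coords)
    )
    return Frame(0.0, kps)


class TestFrameSimilarity:
    def test_identical_frames_score_one_and_correct(self):
        coords = np.random.default_rng(0).uniform(-0.4, 0.4, (33, 3))
        f = _frame_from(coords)
        fs = frame_similarity(f, f)
        assert fs.mean_similarity == pytest.approx(1.0)
        assert fs.correct
        assert len(fs.per_keypoint_similarity) == 33

    def test_negated_frame_scores_zero_and_incorrect(self):
        coords = np.random.default_rng(1).uniform(-0.4, 0.4, (33, 3))
        fs = frame_similarity(_frame_from(coords), _frame_from(-coords))
        assert fs.mean_similarity == pytest.approx(0.0, abs=1e-12)
        assert not fs.correct

    def test_mean_matches_independent_per_keypoint_recomputation(self):
        rng = np.random.default_rng(2)
        a, b = rng.uniform(-0.5, 0.5, (2, 33, 3))
        fs = frame_similarity(_frame_from(a), _frame_from(b))
        # independent oracle: plain math per landmark, then the average
        sims = []
        for u, v in zip(a, b):
            dot = sum(ui * vi for ui, vi in zip(u, v))
            nu = math.sqrt(sum(ui * ui for ui in u))
            nv = math.sqrt(sum(vi * vi for vi in v))
            sims.append((dot / (nu * nv) + 1.0) / 2.0)
        assert fs.mean_similarity == pytest.approx(sum(sims) / 33, abs=1e-12)
        np.testing.assert_allclose(fs.per_keypoint_similarity, sims, atol=1e-12)

    def test_zero_vector_landmark_excluded_from_mean(self):
        coords = np.random.default_rng(3).uniform(0.1, 0.5, (33, 3))
        zeroed = coords.copy()
        zeroed[4] = 0.0
        fs = frame_similarity(_frame_from(coords), _frame_from(zeroed))
        assert fs.n_excluded == 1
        assert np.isnan(fs.per_keypoint_similarity[4])
        assert fs.mean_similarity == pytest.approx(1.0)

    def test_visibility_filter_excludes_landmarks(self):
        coords = np.random.default_rng(4).uniform(0.1, 0.5, (33, 3))
        kps = list(_frame_from(coords).keypoints)
        kps[0] = Keypoint(0, *coords[0], 0.1)
        low_vis = Frame(0.0, tuple(kps))
        fs = frame_similarity(
            low_vis,
            _frame_from(coords),
            options=ScoringOptions(normalization="raw", min_visibility=0.5),
        )
        assert fs.n_excluded == 1

    def test_mismatched_landmark_sets_rejected(self):
        coords = np.random.default_rng(5).uniform(0.1, 0.5, (33, 3))
        full = _frame_from(coords)
        partial = Frame(0.0, full.keypoints[:32])
        with pytest.raises(ValidationError):
            frame_similarity(full, partial)


class TestScoreExercise:
    def test_identical_sequences_score_hundred(self, standing_ref):
        score = score_exercise(standing_ref, standing_ref)
        assert score.percent_correct == 100.0
        assert score.n_correct == score.n_frames

    def test_neutral_perturbation_scores_hundred(self, standing_ref):
        pat = perturb(standing_ref, PerturbationParams())
        assert score_exercise(standing_ref, pat).percent_correct == 100.0

    def test_percent_equals_ratio_invariant(self, standing_ref):
        pat = perturb(standing_ref, PerturbationParams(noise_sd=0.05, seed=9))
        score = score_exercise(standing_ref, pat)
        assert score.percent_correct == pytest.approx(
            100.0 * score.n_correct / score.n_frames, abs=1e-12
        )

    def test_noise_sweep_is_monotone_on_average(self, standing_ref):
        # on the target segment, correctness cannot improve with noise
        ref_seg = extract_segment(
            normalize_pose(standing_ref, "hip_centered"),
            DEFAULT_SEGMENTS["shoulder"],
        )
        sweeps = {0.0: [], 0.01: [], 0.05: []}
        for seed in range(20):
            for sd in sweeps:
                pat = perturb(standing_ref, PerturbationParams(noise_sd=sd, seed=seed))
                pat_seg = extract_segment(
                    normalize_pose(pat, "hip_centered"), DEFAULT_SEGMENTS["shoulder"]
                )
                sweeps[sd].append(
                    score_exercise(ref_seg, pat_seg, options=RAW_OPTS).percent_correct
                )
        means = [np.mean(sweeps[sd]) for sd in (0.0, 0.01, 0.05)]
        assert means[0] >= means[1] >= means[2]
        assert means[0] == 100.0

    def test_scale_invariance(self, random_seq):
        pat = make_random_sequence(seed=42)
        s1 = score_exercise(random_seq, pat, options=RAW_OPTS)
        ref2, pat2 = random_seq.copy(), pat.copy()
        ref2.coords *= 3.7
        pat2.coords *= 3.7
        s2 = score_exercise(ref2, pat2, options=RAW_OPTS)
        for a, b in zip(s1.frame_scores, s2.frame_scores):
            assert a.mean_similarity == pytest.approx(b.mean_similarity, abs=1e-9)
        assert s1.percent_correct == s2.percent_correct

    def test_reordering_both_sequences_identically_preserves_score(self, random_seq):
        pat = make_random_sequence(seed=7)
        base = score_exercise(random_seq, pat, options=RAW_OPTS)
        perm = np.random.default_rng(0).permutation(random_seq.n_frames)
        ref2, pat2 = random_seq.copy(), pat.copy()
        ref2.coords = ref2.coords[perm]
        pat2.coords = pat2.coords[perm]
        shuffled = score_exercise(ref2, pat2, options=RAW_OPTS)
        assert shuffled.percent_correct == base.percent_correct

    def test_length_mismatch_resamples_reference(self, standing_ref):
        pat = perturb(standing_ref, PerturbationParams(speed_factor=1.5))
        score = score_exercise(standing_ref, pat)
        assert score.n_frames == pat.n_frames

    def test_threshold_domain_checked(self, random_seq):
        with pytest.raises(ValueError):
            score_exercise(random_seq, random_seq, threshold=0.0)

    def test_raw_threshold_mode_is_stricter(self, standing_ref):
        pat = perturb(standing_ref, PerturbationParams(noise_sd=0.03, seed=4))
        rescaled = score_exercise(standing_ref, pat)
        raw_mode = score_exercise(
            standing_ref, pat,
            options=ScoringOptions(threshold_on_rescaled=False),
        )
        assert raw_mode.percent_correct <= rescaled.percent_correct
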