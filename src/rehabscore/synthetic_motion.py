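"""Synthetic keypoint trajectories for the two shoulder-rehabilitation exercises.

The study's recordings are not published, so this module stands in for them
with fully controlled ground truth. Two exercise templates are provided:

``seated_rotation``
    Seated, the arm abducted to shoulder height (90° to the trunk) with the
    elbow flexed 90°; the shoulder and trunk externally rotate as far as
    comfortable, the end position is held for 3 s, then the movement reverses.

``standing_diagonal``
    Standing, the hand starts closed beside the opposite hip with the elbow
    extended; the arm sweeps up across the body while the hand opens, ending
    at exactly 45° to the head line, then returns.

Postures are built from a neutral full-body landmark layout plus analytic arm
kinematics (fixed segment lengths), and stages are blended with minimum-jerk
profiles, which are smooth and have zero velocity at keyframes — so the
geometric cues (90° elbow at the start, 45° arm-to-head at the peak) are met
essentially exactly at the sampled frames.

Perturbations model the ways a home recording deviates from the reference:
coordinate noise (tracking jitter or sloppy execution), uniform speed change,
an idle lead-in before the movement starts, range-of-motion scaling about the
hip midpoint, and visibility dropout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .errors import ValidationError
from .landmarks import N_LANDMARKS
from .motion_model import MotionSequence, resample_sequence

# Segment lengths in normalized image units (adult frontal view ~2 m away;
# upper arm ~0.19 and forearm+carpus ~0.18 of standing height, so the hand
# hangs at hip level and can reach the opposite hip).
L_UPPER_ARM = 0.15
L_FOREARM = 0.14

# Default study conditions: ~8 s exercises filmed at 30 fps.
DEFAULT_N_FRAMES = 240
DEFAULT_FPS = 30.0


def minimum_jerk(u: np.ndarray | float) -> np.ndarray | float:
    """Minimum-jerk position profile 6u^5 - 15u^4 + 10u^3 on [0, 1]."""
    u = np.clip(u, 0.0, 1.0)
    return u * u * u * (10.0 + u * (-15.0 + 6.0 * u))


def _rot_y(phi: float) -> np.ndarray:
    """Rotation about the vertical (y) image axis; acts on (x, z)."""
    c, s = np.cos(phi), np.sin(phi)
    return np.array([[c, 0.0, -s], [0.0, 1.0, 0.0], [s, 0.0, c]])


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalize zero vector")
    return v / n


def _slerp(a: np.ndarray, b: np.ndarray, u: float) -> np.ndarray:
    """Spherical interpolation between unit vectors a and b."""
    dot = float(np.clip(np.dot(a, b), -1.0, 1.0))
    omega = np.arccos(dot)
    if omega < 1e-9:
        return a
    so = np.sin(omega)
    return (np.sin((1.0 - u) * omega) * a + np.sin(u * omega) * b) / so


def _base_posture(seated: bool) -> np.ndarray:
    """Neutral frontal posture for all 33 landmarks, shape (33, 3)."""
    p = np.zeros((N_LANDMARKS, 3))
    p[0] = (0.50, 0.200, -0.030)  # nose
    p[1] = (0.515, 0.185, -0.025)
    p[2] = (0.525, 0.185, -0.025)
    p[3] = (0.535, 0.185, -0.020)
    p[4] = (0.485, 0.185, -0.025)
    p[5] = (0.475, 0.185, -0.025)
    p[6] = (0.465, 0.185, -0.020)
    p[7] = (0.555, 0.200, 0.020)  # left ear
    p[8] = (0.445, 0.200, 0.020)  # right ear
    p[9] = (0.515, 0.225, -0.020)
    p[10] = (0.485, 0.225, -0.020)
    p[11] = (0.58, 0.35, 0.0)  # left shoulder
    p[12] = (0.42, 0.35, 0.0)  # right shoulder
    p[13] = (0.60, 0.498, 0.0)  # left elbow (arm hanging)
    p[14] = (0.40, 0.498, 0.0)  # right elbow
    p[15] = (0.615, 0.637, 0.0)  # left wrist
    p[16] = (0.385, 0.637, 0.0)  # right wrist
    # hands: small offsets below the wrists
    p[17] = p[15] + (0.005, 0.035, 0.0)
    p[18] = p[16] + (-0.005, 0.035, 0.0)
    p[19] = p[15] + (0.015, 0.030, 0.0)
    p[20] = p[16] + (-0.015, 0.030, 0.0)
    p[21] = p[15] + (0.020, 0.020, -0.005)
    p[22] = p[16] + (-0.020, 0.020, -0.005)
    p[23] = (0.56, 0.62, 0.0)  # left hip
    p[24] = (0.44, 0.62, 0.0)  # right hip
    if seated:
        p[25] = (0.575, 0.76, -0.12)  # knees forward
        p[26] = (0.425, 0.76, -0.12)
        p[27] = (0.565, 0.92, -0.10)
        p[28] = (0.435, 0.92, -0.10)
        p[29] = (0.570, 0.95, -0.08)
        p[30] = (0.430, 0.95, -0.08)
        p[31] = (0.555, 0.95, -0.16)
        p[32] = (0.445, 0.95, -0.16)
    else:
        p[25] = (0.555, 0.80, 0.0)
        p[26] = (0.445, 0.80, 0.0)
        p[27] = (0.55, 0.95, 0.0)
        p[28] = (0.45, 0.95, 0.0)
        p[29] = (0.555, 0.975, 0.010)
        p[30] = (0.445, 0.975, 0.010)
        p[31] = (0.545, 0.985, -0.030)
        p[32] = (0.455, 0.985, -0.030)
    return p


def _place_right_arm(
    p: np.ndarray,
    upper_dir: np.ndarray,
    fore_dir: np.ndarray,
    hand_scale: float = 1.0,
) -> None:
    """Place elbow/wrist/hand landmarks of the right arm in-place.

    ``upper_dir`` and ``fore_dir`` are unit directions of the upper arm
    (shoulder->elbow) and forearm (elbow->wrist). Hand landmarks sit in the
    orthonormal frame of the forearm so segment lengths stay constant;
    ``hand_scale`` models hand opening and only affects the small hand spread.
    """
    shoulder = p[12]
    elbow = shoulder + L_UPPER_ARM * upper_dir
    wrist = elbow + L_FOREARM * fore_dir
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(fore_dir, ref)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    g = _unit(np.cross(fore_dir, ref))
    p[14] = elbow
    p[16] = wrist
    p[18] = wrist + hand_scale * (0.030 * fore_dir + 0.010 * g)
    p[20] = wrist + hand_scale * 0.035 * fore_dir
    p[22] = wrist + hand_scale * (0.020 * fore_dir - 0.012 * g)


@dataclass(frozen=True)
class ExerciseTemplate:
    """A parametric exercise: a posture function over time.

    ``posture_fn(t, duration)`` returns the (33, 3) landmark layout at time
    ``t`` seconds into a performance lasting ``duration`` seconds. Phase 0 and
    phase 1 return to the start posture; ``peak_phase`` marks where the
    exercise-specific target geometry is attained.
    """

    name: str
    posture_fn: Callable[[float, float], np.ndarray] = field(repr=False)
    hold_duration: float = 0.0
    peak_phase: float = 0.5
    min_duration: float = 2.0

    def posture(self, t: float, duration: float) -> np.ndarray:
        if duration < self.min_duration:
            raise ValidationError(
                f"{self.name}: duration {duration:.2f}s below minimum "
                f"{self.min_duration:.2f}s"
            )
        return self.posture_fn(float(np.clip(t, 0.0, duration)), duration)


def _seated_posture(t: float, duration: float, hold: float, max_trunk_rad: float) -> np.ndarray:
    move = (duration - hold) / 2.0
    if t <= move:
        u = float(minimum_jerk(t / move))
    elif t <= move + hold:
        u = 1.0
    else:
        u = float(minimum_jerk((duration - t) / move))
    theta = u * (np.pi / 2.0)  # external rotation of the forearm
    phi = u * max_trunk_rad  # trunk rotation toward the exercising side

    p = _base_posture(seated=True)
    center = np.array([0.5, 0.0, 0.0])
    r_upper = _rot_y(phi)
    r_lower = _rot_y(phi / 2.0)
    # head, shoulders and arms rotate with the trunk; the seated pelvis and
    # legs follow with half the twist
    upper_ids = list(range(0, 23))
    lower_ids = list(range(23, 33))
    p[upper_ids] = (p[upper_ids] - center) @ r_upper.T + center
    p[lower_ids] = (p[lower_ids] - center) @ r_lower.T + center

    # Arm: abducted to shoulder height (90° to the vertical trunk line), elbow
    # flexed 90°; external rotation swings the forearm from horizontal-forward
    # to vertical-up. Directions rotate rigidly with the trunk.
    upper_dir = r_upper @ np.array([-1.0, 0.0, 0.0])
    f_fwd = r_upper @ np.array([0.0, 0.0, -1.0])
    f_up = r_upper @ np.array([0.0, -1.0, 0.0])
    fore_dir = np.cos(theta) * f_fwd + np.sin(theta) * f_up
    _place_right_arm(p, upper_dir, fore_dir)
    return p


def _standing_posture(t: float, duration: float) -> np.ndarray:
    half = duration / 2.0
    u = float(minimum_jerk(t / half)) if t <= half else float(minimum_jerk((duration - t) / half))

    p = _base_posture(seated=False)
    shoulder = p[12]
    # Start: hand closed beside the opposite (left) hip, elbow extended.
    a_start = _unit(p[23] + np.array([0.02, 0.04, 0.0]) - shoulder)
    # Peak: arm extended at exactly 45° to the head line (nose <-> ear
    # midpoint), tilted toward 'up' within the plane spanned by the head line
    # and the vertical.
    head_dir = _unit(0.5 * (p[7] + p[8]) - p[0])
    up = np.array([0.0, -1.0, 0.0])
    w = _unit(up - np.dot(up, head_dir) * head_dir)
    a_peak = np.cos(np.pi / 4.0) * (-head_dir) + np.sin(np.pi / 4.0) * w

    a = _unit(_slerp(a_start, a_peak, u))
    hand_scale = 0.7 + 0.6 * u  # hand gradually opens
    _place_right_arm(p, a, a, hand_scale=hand_scale)
    return p


def seated_rotation_template(
    hold_duration: float = 3.0, max_trunk_deg: float = 15.0
) -> ExerciseTemplate:
    """Seated external-rotation exercise with a hold at full rotation."""
    rad = np.deg2rad(max_trunk_deg)
    return ExerciseTemplate(
        name="seated_rotation",
        posture_fn=lambda t, d: _seated_posture(t, d, hold_duration, rad),
        hold_duration=hold_duration,
        peak_phase=0.5,
        min_duration=hold_duration + 1.0,
    )


def standing_diagonal_template() -> ExerciseTemplate:
    """Standing diagonal raise ending at 45° to the head line."""
    return ExerciseTemplate(
        name="standing_diagonal",
        posture_fn=_standing_posture,
        hold_duration=0.0,
        peak_phase=0.5,
        min_duration=2.0,
    )


_TEMPLATE_FACTORIES: dict[str, Callable[[], ExerciseTemplate]] = {
    "seated_rotation": seated_rotation_template,
    "standing_diagonal": standing_diagonal_template,
}


def get_template(name: str) -> ExerciseTemplate:
    try:
        return _TEMPLATE_FACTORIES[name]()
    except KeyError:
        raise ValidationError(
            f"unknown template {name!r}; available: {sorted(_TEMPLATE_FACTORIES)}"
        ) from None


def generate_reference(
    template: ExerciseTemplate | str,
    n_frames: int = DEFAULT_N_FRAMES,
    fps: float = DEFAULT_FPS,
    seed: int | None = None,
    jitter_sd: float = 0.0,
) -> MotionSequence:
    """Sample a template into a reference sequence.

    Deterministic for a fixed seed; the default reference is noiseless
    (``jitter_sd=0``) so geometric cues hold exactly.
    """
    if isinstance(template, str):
        template = get_template(template)
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    t = np.arange(n_frames) / fps
    duration = float(t[-1])
    coords = np.stack([template.posture(ti, duration) for ti in t])
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(0.0, jitter_sd, coords.shape)
    return MotionSequence(
        exercise_id=template.name,
        fps=fps,
        source="reference",
        t=t,
        coords=coords,
        visibility=np.ones((n_frames, N_LANDMARKS)),
    )


# -- perturbations -------------------------------------------------------


@dataclass(frozen=True)
class PerturbationParams:
    """Controlled deviations of a patient trial from the reference.

    noise_sd:
        sd of i.i.d. Gaussian displacement per coordinate, image units.
    speed_factor:
        uniform time scaling (> 1 = faster, shorter trial).
    phase_offset:
        idle lead-in in seconds: the start posture is replicated before the
        movement begins (a patient starting after the recording does).
    amplitude_scale:
        scales each frame's displacement about the hip midpoint
        (range-of-motion error).
    dropout_rate:
        probability a landmark-frame's visibility collapses toward 0.
    """

    noise_sd: float = 0.0
    speed_factor: float = 1.0
    phase_offset: float = 0.0
    amplitude_scale: float = 1.0
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.speed_factor <= 0:
            raise ValidationError("speed_factor must be > 0")
        if self.phase_offset < 0:
            raise ValidationError("phase_offset must be >= 0")
        if self.amplitude_scale <= 0:
            raise ValidationError("amplitude_scale must be > 0")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValidationError("dropout_rate must be in [0, 1]")


# Quality classes are a fixed, documented function of the perturbation
# magnitudes; they exist as ground truth for recovery/separation tests.
def classify_quality(params: PerturbationParams) -> str:
    if params.noise_sd >= 0.03 or params.amplitude_scale <= 0.6:
        return "poor"
    if params.noise_sd <= 0.005 and 0.9 <= params.amplitude_scale <= 1.1:
        return "good"
    return "degraded"


@dataclass(frozen=True)
class TrialLabel:
    quality_class: str
    params: PerturbationParams

    @classmethod
    def from_params(cls, params: PerturbationParams) -> "TrialLabel":
        return cls(classify_quality(params), params)


# Default cohort prototypes (study conditions). "Poor" models gross execution
# error — deviations around 12% of the image scale plus a heavily reduced
# range of motion — not mere tracking jitter; "good" has near-clean tracking
# and full range of motion. Both satisfy the fixed quality-class rule above.
GOOD_PARAMS = PerturbationParams(noise_sd=0.003, amplitude_scale=1.0)
DEGRADED_PARAMS = PerturbationParams(noise_sd=0.015, amplitude_scale=0.8)
POOR_PARAMS = PerturbationParams(noise_sd=0.12, amplitude_scale=0.55)

# Patient lead-in condition for timing-robustness studies: the seconds needed
# to assume the start posture after triggering recording on a phone.
LEAD_IN_RANGE = (2.0, 5.0)
SPEED_RANGE = (0.7, 1.4)


def perturb(seq: MotionSequence, params: PerturbationParams) -> MotionSequence:
    """Apply a perturbation; neutral parameters return an identical sequence.

    Order of application: amplitude scaling (about the per-frame hip
    midpoint), uniform speed change (timestamps rescale, frame count adjusts
    at constant fps), idle lead-in (replicates the first posture), coordinate
    noise, visibility dropout. Deterministic for a fixed ``params.seed``.
    """
    out = seq.copy()
    rng = np.random.default_rng(params.seed)

    if params.amplitude_scale != 1.0:
        from .motion_model import hip_midpoint

        hm = hip_midpoint(out)
        out.coords = hm[:, None, :] + params.amplitude_scale * (
            out.coords - hm[:, None, :]
        )

    if params.speed_factor != 1.0:
        n_new = max(2, int(round((out.n_frames - 1) / params.speed_factor)) + 1)
        t0 = out.t[0]
        out = resample_sequence(out, n_new)
        out.t = t0 + (out.t - t0) / params.speed_factor

    if params.phase_offset > 0:
        n_idle = int(round(params.phase_offset * out.fps))
        if n_idle > 0:
            idle_t = np.arange(n_idle) / out.fps
            shifted = out.t - out.t[0] + n_idle / out.fps
            out = replace(
                out,
                t=np.concatenate([idle_t, shifted]),
                coords=np.concatenate(
                    [np.repeat(out.coords[:1], n_idle, axis=0), out.coords]
                ),
                visibility=np.concatenate(
                    [np.repeat(out.visibility[:1], n_idle, axis=0), out.visibility]
                ),
                landmark_indices=out.landmark_indices.copy(),
            )

    if params.noise_sd > 0:
        out.coords = out.coords + rng.normal(0.0, params.noise_sd, out.coords.shape)

    if params.dropout_rate > 0:
        mask = rng.random(out.visibility.shape) < params.dropout_rate
        out.visibility = out.visibility.copy()
        out.visibility[mask] = rng.uniform(0.0, 0.2, int(mask.sum()))

    out.source = "synthetic"
    return out


def generate_cohort(
    n_subjects: int,
    template: ExerciseTemplate | str,
    params_grid: Sequence[PerturbationParams],
    seed: int = 0,
    n_frames: int = DEFAULT_N_FRAMES,
    fps: float = DEFAULT_FPS,
) -> tuple[MotionSequence, list[tuple[MotionSequence, TrialLabel]]]:
    """Generate a labeled cohort of perturbed trials of one exercise.

    Each subject receives a prototype from ``params_grid`` (cycled) with a
    per-subject seed derived from ``seed``; returns the shared reference and
    the list of (trial, label) pairs. Reproducible for fixed inputs.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if not params_grid:
        raise ValueError("params_grid must not be empty")
    ref = generate_reference(template, n_frames=n_frames, fps=fps)
    rng = np.random.default_rng(seed)
    subject_seeds = rng.integers(0, 2**31 - 1, size=n_subjects)
    trials: list[tuple[MotionSequence, TrialLabel]] = []
    for i in range(n_subjects):
        proto = params_grid[i % len(params_grid)]
        params = replace(proto, seed=int(subject_seeds[i]))
        trial = perturb(ref, params)
        trial.exercise_id = f"{ref.exercise_id}/subject{i:02d}"
        trials.append((trial, TrialLabel.from_params(params)))
    return ref, trials
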