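"""Synthetic TUG trial generator with ground-truth labels.

The generator emits the kinematic signatures the detection algorithm keys
on, not a biomechanically faithful body model:

* trunk a_z: one smooth raised-cosine pulse spanning the stand-up phase and
  one spanning the sit-down phase (the two dominant postural peaks);
* hip a_y: a smooth step up during stand-up and down during sit-down, so
  its time derivative is positive at the stand peak and negative at the
  sit peak (the stand/sit disambiguation rule);
* trunk / head omega_y: two large pulses, one per 180-degree turn (head
  at reduced amplitude, verifying the trunk); by default the two turns go
  opposite ways (out-turn left, pre-sit turn right), as when a subject
  turns toward the chair to sit;
* hip omega_x: a stride-frequency oscillation with smooth onset/offset
  envelopes during both walking bouts, mirrored at reduced amplitude on
  hip omega_y;
* thigh/shin orientation quaternions: transient knee-flexion excursions
  (0 -> ~90 deg -> 0) during stand-up and sit-down, relative to the pose
  held at t = 0;
* every channel carries linear drift (drift_slope * t) plus white Gaussian
  noise, emulating sensor drift and broadband sensor noise.

Phase boundaries used to build the templates are emitted verbatim as the
seven ground-truth transitions, so downstream recovery can be scored
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .rom import quat_from_axis_angle
from .types import (
    GroundTruth,
    SEGMENT_NAMES,
    SegmentInterval,
    SensorTrace,
    TransitionSet,
    TrialRecording,
)


def _default_amplitudes() -> dict[str, float]:
    # Unitless template amplitudes; absolute scale is irrelevant downstream
    # because every channel is normalized during conditioning.
    return {
        "trunk_az_stand": 1.0,
        "trunk_az_sit": 1.0,
        "hip_az_scale": 0.9,  # hip a_z mirrors trunk a_z at this fraction
        "hip_ay_step": 1.0,
        "trunk_wy_turn": 1.0,
        "head_wy_turn": 0.8,
        "head_wx_turn": 0.5,
        "hip_wy_turn": 1.0,
        "hip_wx_stride": 1.0,
        "hip_wy_stride": 0.25,  # stride leak onto the turn axis
        "knee_rom_deg": 90.0,
    }


@dataclass
class SimulationParams:
    """Study-condition parameters of one simulated TUG trial."""

    distance_m: float = 10.0
    walk_speed_mps: float = 1.0
    stride_freq_hz: float = 1.8
    stand_duration_s: float = 1.5
    turn_duration_s: float = 2.0
    sit_duration_s: float = 1.5
    lead_in_s: float = 0.75  # seated idle before the stand-up cue
    lead_out_s: float = 0.75  # seated idle after sit-down
    turn_directions: tuple[int, int] = (1, -1)  # yaw sign per turn (+1 left)
    amplitudes: dict[str, float] = field(default_factory=_default_amplitudes)
    drift_slope: float = 0.01  # units/s linear sensor drift, every channel
    noise_sd: float = 0.03  # white noise sd, inertial channels
    quat_noise_rad: float = 0.002  # small random-axis angular noise on quats
    rate_hz: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "distance_m",
            "walk_speed_mps",
            "stride_freq_hz",
            "stand_duration_s",
            "turn_duration_s",
            "sit_duration_s",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.lead_in_s < 0 or self.lead_out_s < 0:
            raise ValidationError("lead-in/lead-out must be non-negative")
        if self.noise_sd < 0 or self.quat_noise_rad < 0:
            raise ValidationError("noise_sd must be non-negative")
        if tuple(self.turn_directions) not in {(1, 1), (1, -1), (-1, 1), (-1, -1)}:
            raise ValidationError("turn_directions must be a pair of +1/-1")

    @property
    def walk_duration_s(self) -> float:
        return self.distance_m / self.walk_speed_mps


def _raised_cosine(t: np.ndarray, start: float, end: float) -> np.ndarray:
    """Smooth 0->1->0 bump supported on [start, end]."""
    out = np.zeros_like(t)
    inside = (t >= start) & (t <= end)
    phase = (t[inside] - start) / (end - start)
    out[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
    return out


def _half_sine(t: np.ndarray, start: float, end: float) -> np.ndarray:
    """Single-peaked, strictly concave 0->1->0 lobe on [start, end]."""
    out = np.zeros_like(t)
    inside = (t >= start) & (t <= end)
    out[inside] = np.sin(np.pi * (t[inside] - start) / (end - start))
    return out


def _skewed_lobe(t: np.ndarray, start: float, end: float, rise_frac: float = 0.45) -> np.ndarray:
    """Single-peaked lobe with a fast rise and a slow fall, C1 at both ends."""
    split = start + rise_frac * (end - start)
    return _smooth_step(t, start, split) * (1.0 - _smooth_step(t, split, end))


def _activity_pulse(
    t: np.ndarray,
    start: float,
    end: float,
    shape: str = "dome",
    lobe_depth: float = 0.12,
    lobe_halfwidth_s: float = 0.4,
) -> np.ndarray:
    """Kinematic pulse of one activity phase, flanked by counter-motion dips.

    The main lobe spans [start, end]: a raised-cosine dome for the postural
    pulses, or a broader half-sine for turns (yaw rate of a continuous turn
    rises to a single mid-turn peak; its strict concavity keeps the filtered
    pulse unimodal, so the first-extremum scan meets no interior minima).
    Small opposite-sign lobes centered exactly at the phase boundaries
    emulate the anticipatory and braking counter-motions real recordings
    show at movement onset and termination (the dips the first-extremum
    segmentation rule keys on); their depth is kept well under the 30% peak
    threshold so they never register as activity peaks themselves. Each
    boundary is a local minimum of the template.
    """
    if shape == "dome":
        main = _raised_cosine(t, start, end)
    elif shape == "halfsine":
        main = _half_sine(t, start, end)
    elif shape == "skewed":
        main = _skewed_lobe(t, start, end)
    else:
        raise ValidationError(f"unknown pulse shape {shape!r}")
    lw = min(lobe_halfwidth_s, 0.75 * (end - start))
    return (
        main
        - lobe_depth * _raised_cosine(t, start - lw, start + lw)
        - lobe_depth * _raised_cosine(t, end - lw, end + lw)
    )


def _smooth_step(t: np.ndarray, start: float, end: float) -> np.ndarray:
    """Smooth 0->1 ramp (raised-cosine sigmoid) over [start, end]."""
    out = np.zeros_like(t)
    out[t >= end] = 1.0
    inside = (t >= start) & (t < end)
    phase = (t[inside] - start) / (end - start)
    out[inside] = 0.5 * (1.0 - np.cos(np.pi * phase))
    return out


def _stride_envelope(t: np.ndarray, start: float, end: float, ramp_s: float) -> np.ndarray:
    """Unit plateau over [start, end] with raised-cosine ramps of ramp_s."""
    ramp = min(ramp_s, (end - start) / 2.0)
    return _smooth_step(t, start, start + ramp) * (1.0 - _smooth_step(t, end - ramp, end))


def simulate_tug(params: SimulationParams) -> tuple[TrialRecording, GroundTruth]:
    """Generate one labeled TUG trial.

    Returns the multi-channel recording and its ground truth (six segments,
    seven transitions, per-sample activity labels). Identical params
    (including seed) give bit-identical output.
    """
    if params.walk_duration_s < 1.0 / params.stride_freq_hz:
        raise ValidationError(
            "degenerate walk: walking bout shorter than one stride period"
        )
    rng = np.random.default_rng(params.seed)
    amp = {**_default_amplitudes(), **params.amplitudes}

    # Phase boundary times: the seven ground-truth transitions.
    t0 = params.lead_in_s
    t1 = t0 + params.stand_duration_s
    t2 = t1 + params.walk_duration_s
    t3 = t2 + params.turn_duration_s
    t4 = t3 + params.walk_duration_s
    t5 = t4 + params.turn_duration_s
    t6 = t5 + params.sit_duration_s
    total_s = t6 + params.lead_out_s
    n = int(round(total_s * params.rate_hz))
    t = np.arange(n) / params.rate_hz

    stand_bump = _activity_pulse(t, t0, t1, shape="dome")
    sit_bump = _activity_pulse(t, t5, t6, shape="dome")
    # Turn dips are wider than the postural ones: gait deceleration into a
    # turn and re-acceleration out of it span about a stride (~1 s). The
    # pelvis yaw counter-swings much harder than the trunk when stepping
    # into/out of a turn (each stride yaws the pelvis), so the hip channel
    # gets deeper, wider dips than the trunk/head channels.
    sign1, sign2 = (float(d) for d in params.turn_directions)

    def turn_pulses(shape: str, lobe_depth: float, lobe_halfwidth_s: float) -> np.ndarray:
        one = _activity_pulse(t, t2, t3, shape=shape, lobe_depth=lobe_depth,
                              lobe_halfwidth_s=lobe_halfwidth_s)
        two = _activity_pulse(t, t4, t5, shape=shape, lobe_depth=lobe_depth,
                              lobe_halfwidth_s=lobe_halfwidth_s)
        return sign1 * one + sign2 * two

    turns = turn_pulses("halfsine", lobe_depth=0.15, lobe_halfwidth_s=0.6)  # trunk/head
    # Pelvis yaw spikes with the step into the turn and derotates gradually
    # while stepping out: fast rise, slow fall.
    turns_hip = turn_pulses("skewed", lobe_depth=0.40, lobe_halfwidth_s=1.5)

    stride_env = _stride_envelope(t, t1, t2, 0.5) + _stride_envelope(t, t3, t4, 0.5)
    stride = np.sin(2.0 * np.pi * params.stride_freq_hz * (t - t1)) * stride_env

    def channel(clean: np.ndarray) -> np.ndarray:
        return clean + params.drift_slope * t + rng.normal(0.0, params.noise_sd, n)

    def vector_trace(site: str, quantity: str, x, y, z) -> SensorTrace:
        comp = [np.broadcast_to(np.asarray(c, dtype=float), t.shape) for c in (x, y, z)]
        data = np.stack([channel(c) for c in comp], axis=1)
        return SensorTrace(site=site, quantity=quantity, samples=data, rate_hz=params.rate_hz)

    zero = np.zeros(n)
    traces: dict[tuple[str, str], SensorTrace] = {}

    traces[("trunk", "acceleration")] = vector_trace(
        "trunk", "acceleration",
        zero, zero,
        amp["trunk_az_stand"] * stand_bump + amp["trunk_az_sit"] * sit_bump,
    )
    traces[("hip", "acceleration")] = vector_trace(
        "hip", "acceleration",
        zero,
        amp["hip_ay_step"] * (_smooth_step(t, t0, t1) - _smooth_step(t, t5, t6)),
        amp["hip_az_scale"] * (amp["trunk_az_stand"] * stand_bump + amp["trunk_az_sit"] * sit_bump),
    )
    traces[("trunk", "angular_velocity")] = vector_trace(
        "trunk", "angular_velocity", zero, amp["trunk_wy_turn"] * turns, zero
    )
    traces[("head", "angular_velocity")] = vector_trace(
        "head", "angular_velocity",
        amp["head_wx_turn"] * turns, amp["head_wy_turn"] * turns, zero,
    )
    traces[("hip", "angular_velocity")] = vector_trace(
        "hip", "angular_velocity",
        amp["hip_wx_stride"] * stride,
        amp["hip_wy_turn"] * turns_hip + amp["hip_wy_stride"] * stride,
        zero,
    )

    # Orientation: transient knee flexion (shin rotates about the sensor x
    # axis) during stand-up and sit-down; thigh and pelvis stay in the
    # reference pose up to quaternion noise.
    # Joint angles are non-negative, so the knee excursion is a plain bump
    # (no counter-motion lobes) spanning each postural phase.
    knee_angle_rad = np.radians(amp["knee_rom_deg"]) * (
        _raised_cosine(t, t0, t1) + _raised_cosine(t, t5, t6)
    )

    def orientation_trace(site: str, angles_rad: np.ndarray) -> SensorTrace:
        q = quat_from_axis_angle(np.array([1.0, 0.0, 0.0]), angles_rad)
        if params.quat_noise_rad > 0:
            axes = rng.normal(size=(n, 3))
            axes /= np.linalg.norm(axes, axis=1, keepdims=True)
            jitter_angle = rng.normal(0.0, params.quat_noise_rad, n)
            half = jitter_angle / 2.0
            jitter = np.concatenate(
                [np.cos(half)[:, None], np.sin(half)[:, None] * axes], axis=1
            )
            # Hamilton product jitter * q, unrolled for speed.
            aw, ax, ay, az = jitter.T
            bw, bx, by, bz = q.T
            q = np.stack(
                [
                    aw * bw - ax * bx - ay * by - az * bz,
                    aw * bx + ax * bw + ay * bz - az * by,
                    aw * by - ax * bz + ay * bw + az * bx,
                    aw * bz + ax * by - ay * bx + az * bw,
                ],
                axis=1,
            )
            q /= np.linalg.norm(q, axis=1, keepdims=True)
        return SensorTrace(site=site, quantity="orientation", samples=q, rate_hz=params.rate_hz)

    traces[("hip", "orientation")] = orientation_trace("hip", np.zeros(n))
    traces[("thigh_left", "orientation")] = orientation_trace("thigh_left", np.zeros(n))
    traces[("shin_left", "orientation")] = orientation_trace("shin_left", knee_angle_rad)

    transitions = TransitionSet(t0, t1, t2, t3, t4, t5, t6)
    segments = transitions.to_segments()
    labels = np.full(n, "Idle", dtype=object)
    activity_by_segment = ("Standing", "Walking", "Turning", "Walking", "Turning", "Sitting")
    for seg, activity in zip(segments, activity_by_segment):
        labels[(t >= seg.start_s) & (t < seg.end_s)] = activity

    trial = TrialRecording(traces=traces, distance_m=params.distance_m)
    truth = GroundTruth(
        segments=segments, transitions=transitions, labels=labels, rate_hz=params.rate_hz
    )
    return trial, truth


def simulate_cohort(
    n_subjects: int,
    trials_per_subject: int,
    distance_m: float,
    base_params: SimulationParams | None = None,
    variability: float = 0.05,
    seed: int = 0,
) -> list[tuple[TrialRecording, GroundTruth]]:
    """Simulate a cohort with per-subject parameter jitter.

    Each subject's walking speed, stride frequency and phase durations are
    drawn once by scaling the base values with independent factors
    N(1, variability) (clipped to +/- 2.5 sd and a 0.5 floor); each trial
    then gets a fresh noise realization. Fully deterministic under a fixed
    seed.
    """
    if n_subjects < 1 or trials_per_subject < 1:
        raise ValidationError("need at least one subject and one trial")
    if variability < 0:
        raise ValidationError("variability must be non-negative")
    base = base_params if base_params is not None else SimulationParams()
    base = replace(base, distance_m=distance_m)
    rng = np.random.default_rng(seed)
    out: list[tuple[TrialRecording, GroundTruth]] = []
    for subject in range(n_subjects):
        def jitter() -> float:
            f = 1.0 + variability * float(np.clip(rng.normal(), -2.5, 2.5))
            return max(f, 0.5)

        subject_params = replace(
            base,
            walk_speed_mps=base.walk_speed_mps * jitter(),
            stride_freq_hz=base.stride_freq_hz * jitter(),
            stand_duration_s=base.stand_duration_s * jitter(),
            turn_duration_s=base.turn_duration_s * jitter(),
            sit_duration_s=base.sit_duration_s * jitter(),
        )
        for trial_idx in range(trials_per_subject):
            trial_seed = int(rng.integers(0, 2**31 - 1))
            trial, truth = simulate_tug(replace(subject_params, seed=trial_seed))
            trial.subject_id = f"S{subject + 1:02d}"
            trial.trial_id = f"T{trial_idx}"
            out.append((trial, truth))
    return out
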