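"""Quaternion algebra and joint range-of-motion (ROM) computation.

Orientation comes from the suit's fusion output as unit quaternions
q = [w x y z] (scalar first, Hamilton product convention). The angle
between two limb segments is obtained from the relative quaternion
q_rel = q1^-1 * q2, referenced to a standard pose captured at the start of
the trial: q_delta = q_ref^-1 * q_rel. The scalar joint angle is

    theta = 2 * acos(|w(q_delta)|)   (degrees)

Taking |w| both resolves the q/-q double cover and enforces the
small-angle (< 180 deg) representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MissingChannelError, ValidationError
from .types import TrialRecording

#: Joint name -> (proximal site, distal site) orientation pair.
JOINT_PAIRS: dict[str, tuple[str, str]] = {
    "knee_left": ("thigh_left", "shin_left"),
    "knee_right": ("thigh_right", "shin_right"),
    "hip_left": ("hip", "thigh_left"),
    "hip_right": ("hip", "thigh_right"),
}


def _as_quat(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.shape[-1] != 4:
        raise ValidationError("quaternions must have 4 components [w x y z]")
    return q


def quat_normalize(q: np.ndarray) -> np.ndarray:
    q = _as_quat(q)
    norm = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(norm < 1e-12):
        raise ValidationError("zero-norm quaternion")
    return q / norm


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product a * b (scalar-first layout, broadcasting over rows)."""
    a, b = _as_quat(a), _as_quat(b)
    aw, ax, ay, az = np.moveaxis(a, -1, 0)
    bw, bx, by, bz = np.moveaxis(b, -1, 0)
    out = np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )
    return quat_normalize(out)


def quat_inverse(q: np.ndarray) -> np.ndarray:
    """Inverse of a unit quaternion: its conjugate."""
    q = quat_normalize(q)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def relative_quaternion(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """q_rel = q1^-1 * q2, the rotation from segment 1's frame to segment 2's."""
    return quat_multiply(quat_inverse(q1), q2)


def delta_quaternion(q_ref: np.ndarray, q_rel: np.ndarray) -> np.ndarray:
    """q_delta = q_ref^-1 * q_rel, the change relative to the reference pose."""
    return quat_multiply(quat_inverse(q_ref), q_rel)


def rom_angle(q_delta: np.ndarray) -> np.ndarray | float:
    """Scalar rotation angle in degrees, in [0, 180], sign-ambiguity free."""
    q = quat_normalize(q_delta)
    w = np.abs(q[..., 0])
    angle = np.degrees(2.0 * np.arccos(np.clip(w, 0.0, 1.0)))
    return float(angle) if angle.ndim == 0 else angle


def quat_from_axis_angle(axis: np.ndarray, angle_rad: float | np.ndarray) -> np.ndarray:
    """Unit quaternion(s) for rotation(s) of angle_rad about a fixed axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    angle = np.atleast_1d(np.asarray(angle_rad, dtype=float))
    half = angle / 2.0
    q = np.concatenate(
        [np.cos(half)[:, None], np.sin(half)[:, None] * axis[None, :]], axis=1
    )
    return q[0] if np.isscalar(angle_rad) else q


def enforce_sign_continuity(quats: np.ndarray) -> np.ndarray:
    """Flip quaternion signs along time so consecutive samples stay close.

    q and -q encode the same rotation; fusion output may hop between the
    two sheets. Flipping whenever the dot product with the previous sample
    is negative restores a continuous curve on the 3-sphere.
    """
    quats = _as_quat(quats).copy()
    dots = np.sum(quats[1:] * quats[:-1], axis=1)
    flips = np.cumprod(np.where(dots < 0, -1.0, 1.0))
    quats[1:] *= flips[:, None]
    return quats


@dataclass
class RomTrace:
    """Per-sample joint angle (degrees) for one joint over one trial."""

    joint: str
    angles_deg: np.ndarray
    rate_hz: float
    reference_time_s: float = 0.0

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.angles_deg)) / self.rate_hz


def rom_trace(trial: TrialRecording, joint: str) -> RomTrace:
    """Joint-angle time series referenced to the pose at the trial start.

    The proximal/distal orientation traces are sign-continuity corrected,
    the per-sample relative quaternion is referenced to its value at t = 0
    (the standard pose), and the scalar angle is extracted with the
    small-angle rule. At 60 Hz the result is continuous by construction
    (no inter-sample jump can exceed 90 deg for physiological motion).
    """
    try:
        proximal_site, distal_site = JOINT_PAIRS[joint]
    except KeyError:
        raise ValidationError(
            f"unknown joint {joint!r}; known: {sorted(JOINT_PAIRS)}"
        ) from None
    context = f"{joint} ROM"
    q_prox = enforce_sign_continuity(
        trial.get(proximal_site, "orientation", context).samples
    )
    q_dist = enforce_sign_continuity(
        trial.get(distal_site, "orientation", context).samples
    )
    q_rel = relative_quaternion(q_prox, q_dist)
    q_rel = enforce_sign_continuity(q_rel)
    q_ref = q_rel[0]
    q_delta = delta_quaternion(np.broadcast_to(q_ref, q_rel.shape), q_rel)
    angles = np.asarray(rom_angle(q_delta))
    return RomTrace(joint=joint, angles_deg=angles, rate_hz=trial.rate_hz)
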