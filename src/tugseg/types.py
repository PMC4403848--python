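"""Core domain types for TUG trial recordings and analysis results.

Time is represented in seconds from trial start throughout; samples are
0-based and uniformly spaced at ``rate_hz`` (60 Hz for the motion-capture
suit this package models).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .errors import MissingChannelError, ValidationError

#: The 17 sensor sites of a full-body inertial motion-capture suit.
SITES: tuple[str, ...] = (
    "head",
    "trunk",  # midline over T1
    "hip",  # level of L5
    "shoulder_left",
    "shoulder_right",
    "upper_arm_left",
    "upper_arm_right",
    "forearm_left",
    "forearm_right",
    "hand_left",
    "hand_right",
    "thigh_left",
    "thigh_right",
    "shin_left",
    "shin_right",
    "foot_left",
    "foot_right",
)

QUANTITIES: tuple[str, ...] = ("acceleration", "angular_velocity", "orientation")

VECTOR_AXES: tuple[str, ...] = ("x", "y", "z")
QUATERNION_AXES: tuple[str, ...] = ("w", "x", "y", "z")

ACTIVITIES: tuple[str, ...] = ("Standing", "Walking", "Turning", "Sitting")

#: The six segments of a TUG trial, in temporal order.
SEGMENT_NAMES: tuple[str, ...] = (
    "Stand up",
    "Walk-out",
    "Turn 180 (first)",
    "Walk-in",
    "Turn 180 (second)",
    "Sit down",
)

#: Activity performed within each segment, in the same order.
SEGMENT_ACTIVITIES: tuple[str, ...] = (
    "Standing",
    "Walking",
    "Turning",
    "Walking",
    "Turning",
    "Sitting",
)

#: The seven transition points separating consecutive postures, in order.
TRANSITION_NAMES: tuple[str, ...] = (
    "sit_to_stand",
    "stand_to_walk_out",
    "walk_out_to_turn",
    "turn_to_walk_in",
    "walk_in_to_turn",
    "turn_to_stand",
    "stand_to_sit",
)


def _axes_for(quantity: str) -> tuple[str, ...]:
    return QUATERNION_AXES if quantity == "orientation" else VECTOR_AXES


@dataclass
class SensorTrace:
    """One channel's uniformly sampled time series.

    ``samples`` is a 2-D float array of shape (n_samples, n_components):
    3 components (x, y, z) for acceleration and angular velocity, 4
    (w, x, y, z, scalar first) for orientation quaternions.
    """

    site: str
    quantity: str
    samples: np.ndarray
    rate_hz: float = 60.0

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValidationError(f"unknown site {self.site!r}")
        if self.quantity not in QUANTITIES:
            raise ValidationError(f"unknown quantity {self.quantity!r}")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 1:
            self.samples = self.samples[:, None]
        if self.samples.shape[0] == 0:
            raise ValidationError("samples must be non-empty")
        if self.rate_hz <= 0:
            raise ValidationError("rate_hz must be positive")
        expected = len(_axes_for(self.quantity))
        if self.samples.shape[1] != expected:
            raise ValidationError(
                f"{self.site} {self.quantity}: expected {expected} components, "
                f"got {self.samples.shape[1]}"
            )
        if self.quantity == "orientation":
            norms = np.linalg.norm(self.samples, axis=1)
            if np.any(norms < 1e-12):
                raise ValidationError("zero-norm quaternion in orientation trace")
            if np.any(np.abs(norms - 1.0) > 1e-3):
                raise ValidationError(
                    "orientation quaternions deviate from unit norm by more than 1e-3"
                )
            # Renormalize residual deviation on construction.
            self.samples = self.samples / norms[:, None]

    @property
    def axes(self) -> tuple[str, ...]:
        return _axes_for(self.quantity)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate_hz

    def component(self, axis: str) -> np.ndarray:
        """Return the 1-D series of one axis ('x'/'y'/'z', or 'w' for quaternions)."""
        try:
            idx = self.axes.index(axis)
        except ValueError:
            raise ValidationError(
                f"axis {axis!r} not valid for {self.quantity} (has {self.axes})"
            ) from None
        return self.samples[:, idx]


@dataclass
class TrialRecording:
    """Full multi-sensor recording of one TUG trial."""

    traces: dict[tuple[str, str], SensorTrace]
    distance_m: float
    subject_id: str = "S00"
    trial_id: str = "T0"

    def __post_init__(self) -> None:
        if not self.traces:
            raise ValidationError("no channels")
        rates = {t.rate_hz for t in self.traces.values()}
        if len(rates) != 1:
            raise ValidationError(f"mixed sampling rates in trial: {sorted(rates)}")
        counts = {t.n_samples for t in self.traces.values()}
        if len(counts) != 1:
            raise ValidationError(f"mixed sample counts in trial: {sorted(counts)}")
        if self.distance_m <= 0:
            raise ValidationError("distance_m must be positive")

    @property
    def rate_hz(self) -> float:
        return next(iter(self.traces.values())).rate_hz

    @property
    def n_samples(self) -> int:
        return next(iter(self.traces.values())).n_samples

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def has(self, site: str, quantity: str) -> bool:
        return (site, quantity) in self.traces

    def get(self, site: str, quantity: str, context: str = "") -> SensorTrace:
        try:
            return self.traces[(site, quantity)]
        except KeyError:
            raise MissingChannelError(site, quantity, context) from None

    def channel(self, site: str, quantity: str, axis: str, context: str = "") -> np.ndarray:
        return self.get(site, quantity, context).component(axis)


@dataclass
class ActivityEvent:
    """A detected activity, located at its governing kinematic extremum."""

    label: str
    peak_time_s: float
    peak_value: float
    direction: str = "none"  # 'left' / 'right' for Turning, else 'none'

    def __post_init__(self) -> None:
        if self.label not in ACTIVITIES:
            raise ValidationError(f"unknown activity label {self.label!r}")
        if (self.direction != "none") != (self.label == "Turning"):
            raise ValidationError(
                "direction must be set for Turning events and 'none' otherwise"
            )
        if self.peak_time_s < 0:
            raise ValidationError("peak_time_s must be non-negative")


@dataclass
class SegmentInterval:
    """A labeled [start, end) interval of the trial."""

    name: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.start_s >= self.end_s:
            raise ValidationError(
                f"segment {self.name!r}: start {self.start_s} >= end {self.end_s}"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def activity(self) -> str:
        try:
            return SEGMENT_ACTIVITIES[SEGMENT_NAMES.index(self.name)]
        except ValueError:
            raise ValidationError(f"unknown segment name {self.name!r}") from None


@dataclass
class TransitionSet:
    """The seven named transition timestamps (seconds) of one TUG trial."""

    sit_to_stand: float
    stand_to_walk_out: float
    walk_out_to_turn: float
    turn_to_walk_in: float
    walk_in_to_turn: float
    turn_to_stand: float
    stand_to_sit: float

    def __post_init__(self) -> None:
        times = self.as_array()
        if np.any(np.diff(times) <= 0):
            bad = int(np.argmax(np.diff(times) <= 0))
            raise ValidationError(
                "transition times must be strictly increasing: "
                f"{TRANSITION_NAMES[bad]}={times[bad]:.3f} !< "
                f"{TRANSITION_NAMES[bad + 1]}={times[bad + 1]:.3f}"
            )
        if times[0] < 0:
            raise ValidationError("transition times must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in TRANSITION_NAMES], dtype=float)

    def as_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in TRANSITION_NAMES}

    def __getitem__(self, name: str) -> float:
        if name not in TRANSITION_NAMES:
            raise KeyError(name)
        return float(getattr(self, name))

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return iter(self.as_dict().items())

    @classmethod
    def from_array(cls, times: np.ndarray | list[float]) -> "TransitionSet":
        times = np.asarray(times, dtype=float)
        if times.shape != (7,):
            raise ValidationError("a TransitionSet needs exactly 7 times")
        return cls(*times)

    def to_segments(self) -> list[SegmentInterval]:
        """The six segments delimited by consecutive transitions."""
        t = self.as_array()
        return [
            SegmentInterval(name, t[i], t[i + 1])
            for i, name in enumerate(SEGMENT_NAMES)
        ]


@dataclass
class GroundTruth:
    """Simulator-emitted truth: segments, transitions and per-sample labels."""

    segments: list[SegmentInterval]
    transitions: TransitionSet
    labels: np.ndarray = field(repr=False)  # per-sample activity label strings
    rate_hz: float = 60.0

    def __post_init__(self) -> None:
        if len(self.segments) != 6:
            raise ValidationError("ground truth must contain exactly 6 segments")
        bounds = self.transitions.as_array()
        for i, seg in enumerate(self.segments):
            if not (
                abs(seg.start_s - bounds[i]) < 1e-9
                and abs(seg.end_s - bounds[i + 1]) < 1e-9
            ):
                raise ValidationError(
                    "segments must tile the transition boundaries"
                )
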