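"""Activity detection from conditioned channels.

The four TUG activities are detected from a handful of channels:

* Standing / Sitting: major peaks of trunk a_z, disambiguated by the sign
  of the hip a_y time derivative at the peak (positive -> Standing,
  negative -> Sitting);
* Turning: major peaks of trunk omega_y, each verified by a same-sign head
  omega_y peak nearby (the head confirms that a whole-body turn occurred
  and gives its direction);
* Walking: a 500 ms sliding window over the hip angular velocity
  (conditioned up to the Nyquist frequency so stride content survives),
  positive when the window both oscillates (>= 2 zero crossings) and
  carries energy (RMS above 10% of the whole-trial RMS).

Samples flagged as both Walking and Turning are labeled Turning: turning
involves steps, so the walking detector fires during turns by design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .conditioning import ConditionedTrace, condition
from .config import SegmentationConfig, default_config
from .errors import AmbiguousEventError, MissingChannelError, ValidationError
from .types import ActivityEvent, TrialRecording


def local_extrema(samples: np.ndarray, kind: str) -> list[int]:
    """Indices of strict local extrema; plateaus yield their earliest sample.

    A local maximum is a sample (or run of equal samples, represented by
    its first index) strictly greater than the nearest differing neighbors
    on both sides. Trace endpoints are never extrema.
    """
    if kind not in ("min", "max"):
        raise ValidationError("kind must be 'min' or 'max'")
    x = np.asarray(samples, dtype=float)
    if len(x) < 3:
        return []
    # Compress runs of equal consecutive values.
    change = np.flatnonzero(np.diff(x) != 0.0)
    starts = np.concatenate(([0], change + 1))  # first index of each run
    values = x[starts]
    if len(values) < 3:
        return []
    if kind == "max":
        hits = (values[1:-1] > values[:-2]) & (values[1:-1] > values[2:])
    else:
        hits = (values[1:-1] < values[:-2]) & (values[1:-1] < values[2:])
    return [int(starts[i + 1]) for i in np.flatnonzero(hits)]


def find_major_extrema(
    conditioned: ConditionedTrace,
    polarity: str = "both",
    min_separation_s: float = 1.0,
    threshold_fraction: float = 0.30,
) -> list[tuple[float, float]]:
    """Large peaks of a conditioned trace: the activity-marking extrema.

    Returns (time_s, value) pairs, sorted by time, for local extrema with
    |value| >= threshold_fraction * max|trace|, thinned so no two survivors
    are closer than min_separation_s (larger |value| wins; earlier time
    breaks ties).
    """
    if polarity not in ("max", "min", "both"):
        raise ValidationError("polarity must be 'max', 'min' or 'both'")
    x = conditioned.samples
    scale = float(np.max(np.abs(x))) if len(x) else 0.0
    if scale == 0.0:
        return []
    candidates: list[tuple[int, float]] = []
    if polarity in ("max", "both"):
        candidates += [(i, x[i]) for i in local_extrema(x, "max") if x[i] > 0]
    if polarity in ("min", "both"):
        candidates += [(i, x[i]) for i in local_extrema(x, "min") if x[i] < 0]
    threshold = threshold_fraction * scale
    candidates = [(i, v) for i, v in candidates if abs(v) >= threshold]
    # Greedy thinning, strongest first.
    candidates.sort(key=lambda iv: (-abs(iv[1]), iv[0]))
    min_sep = min_separation_s * conditioned.rate_hz
    kept: list[tuple[int, float]] = []
    for i, v in candidates:
        if all(abs(i - j) >= min_sep for j, _ in kept):
            kept.append((i, v))
    kept.sort(key=lambda iv: iv[0])
    return [(i / conditioned.rate_hz, float(v)) for i, v in kept]


def _derivative_sign_at(samples: np.ndarray, idx: int, rate_hz: float) -> float:
    deriv = np.gradient(samples) * rate_hz
    s = float(np.sign(deriv[idx]))
    if s == 0.0:
        lo, hi = max(0, idx - 2), min(len(samples), idx + 3)
        s = float(np.sign(np.mean(deriv[lo:hi])))
    return s


def detect_stand_sit(
    trunk_az: ConditionedTrace,
    hip_ay: ConditionedTrace,
    min_separation_s: float = 1.0,
    threshold_fraction: float = 0.30,
) -> list[ActivityEvent]:
    """Stand-up / sit-down events from trunk a_z peaks + hip a_y derivative sign."""
    events = []
    for time_s, value in find_major_extrema(
        trunk_az, "both", min_separation_s, threshold_fraction
    ):
        idx = int(round(time_s * hip_ay.rate_hz))
        idx = min(idx, len(hip_ay.samples) - 1)
        sign = _derivative_sign_at(hip_ay.samples, idx, hip_ay.rate_hz)
        if sign == 0.0:
            raise AmbiguousEventError(
                f"hip a_y derivative is zero around t={time_s:.3f} s; "
                "cannot classify stand vs. sit"
            )
        label = "Standing" if sign > 0 else "Sitting"
        events.append(ActivityEvent(label=label, peak_time_s=time_s, peak_value=value))
    return events


def detect_turning(
    trunk_wy: ConditionedTrace,
    head_wy: ConditionedTrace,
    min_separation_s: float = 1.0,
    threshold_fraction: float = 0.30,
    verify_window_s: float = 0.5,
) -> list[ActivityEvent]:
    """Turning events: trunk omega_y peaks verified by same-sign head peaks."""
    trunk_peaks = find_major_extrema(trunk_wy, "both", min_separation_s, threshold_fraction)
    head_peaks = find_major_extrema(head_wy, "both", min_separation_s, threshold_fraction)
    events = []
    for time_s, value in trunk_peaks:
        confirmations = [
            (ht, hv)
            for ht, hv in head_peaks
            if abs(ht - time_s) <= verify_window_s and np.sign(hv) == np.sign(value)
        ]
        if not confirmations:
            continue  # unverified trunk peak: dropped
        _, head_value = min(confirmations, key=lambda hv: abs(hv[0] - time_s))
        direction = "left" if head_value > 0 else "right"
        events.append(
            ActivityEvent(
                label="Turning", peak_time_s=time_s, peak_value=value, direction=direction
            )
        )
    return events


def detect_walking(hip_w: ConditionedTrace, window_s: float = 0.5) -> np.ndarray:
    """Per-sample walking mask from the oscillation of hip angular velocity.

    A window is walking-positive when it contains at least two zero
    crossings and its RMS exceeds 0.1x the whole-trial RMS; the mask is
    the union of all positive windows.
    """
    x = hip_w.samples
    n = len(x)
    win = int(round(window_s * hip_w.rate_hz))
    if win < 2 or win > n:
        raise ValidationError(
            f"walking window of {window_s} s ({win} samples) does not fit the trial"
        )
    signs = np.where(np.signbit(x), -1.0, 1.0)
    crossing = (signs[1:] * signs[:-1]) < 0  # crossing between i and i+1
    crossing_cum = np.concatenate(([0], np.cumsum(crossing)))
    sq_cum = np.concatenate(([0.0], np.cumsum(x * x)))
    trial_rms = np.sqrt(np.mean(x * x))

    starts = np.arange(0, n - win + 1)
    n_crossings = crossing_cum[starts + win - 1] - crossing_cum[starts]
    window_rms = np.sqrt((sq_cum[starts + win] - sq_cum[starts]) / win)
    positive = (n_crossings >= 2) & (window_rms > 0.1 * trial_rms)

    mask = np.zeros(n, dtype=bool)
    for s in np.flatnonzero(positive):
        mask[s : s + win] = True
    return mask


@dataclass
class SquareSignal:
    """Binary indicator of one detected activity (30% of peak threshold)."""

    event: ActivityEvent
    samples: np.ndarray  # 0/1, aligned with the trial
    threshold_fraction: float = 0.30


def square_signal(
    conditioned: ConditionedTrace, event: ActivityEvent, fraction: float = 0.30
) -> SquareSignal:
    """Square indicator: the contiguous region around the event's peak where
    the (peak-oriented) trace exceeds fraction x |peak amplitude|."""
    if not (0.0 < fraction < 1.0):
        raise ValidationError(f"fraction must be in (0, 1), got {fraction}")
    x = conditioned.samples * np.sign(event.peak_value)
    peak_idx = int(round(event.peak_time_s * conditioned.rate_hz))
    peak_idx = min(max(peak_idx, 0), len(x) - 1)
    threshold = fraction * abs(event.peak_value)
    above = x > threshold
    out = np.zeros(len(x), dtype=int)
    if not above[peak_idx]:
        out[peak_idx] = 1  # degenerate: region collapses onto the peak sample
        return SquareSignal(event=event, samples=out, threshold_fraction=fraction)
    lo = peak_idx
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = peak_idx
    while hi < len(x) - 1 and above[hi + 1]:
        hi += 1
    out[lo : hi + 1] = 1
    return SquareSignal(event=event, samples=out, threshold_fraction=fraction)


@dataclass
class TrialClassification:
    """All detected events plus the per-sample activity label sequence."""

    events: list[ActivityEvent]
    labels: np.ndarray  # per-sample in {Standing, Walking, Turning, Sitting, Idle}
    walking_mask: np.ndarray
    squares: list[SquareSignal]
    rate_hz: float


def _conditioned(trial: TrialRecording, site: str, quantity: str, axis: str,
                 config: SegmentationConfig, context: str) -> ConditionedTrace:
    w2 = config.detection_bands.get((site, quantity, axis), config.walking_w2_hz)
    return condition(trial.get(site, quantity, context), axis, config.w1_hz, w2)


def classify_trial(
    trial: TrialRecording, config: SegmentationConfig | None = None
) -> TrialClassification:
    """Run all detectors on a trial and fuse their outputs.

    Label precedence: walking-mask samples are Walking; stand/sit square
    regions override Walking; Turning square regions override everything
    (turning contains steps, so the walking detector fires during turns).
    """
    config = config if config is not None else default_config()
    required = [
        ("trunk", "acceleration", "Standing/Sitting"),
        (config.stand_sit_derivative_site, "acceleration", "Standing/Sitting"),
        ("trunk", "angular_velocity", "Turning"),
        ("head", "angular_velocity", "Turning"),
        ("hip", "angular_velocity", "Walking"),
    ]
    missing = [(s, q) for s, q, _ in required if not trial.has(s, q)]
    if missing:
        raise MissingChannelError.many(missing, context="activity detection")
    trunk_az = _conditioned(trial, "trunk", "acceleration", "z", config, "Standing/Sitting")
    hip_ay = _conditioned(
        trial, config.stand_sit_derivative_site, "acceleration", "y", config,
        "Standing/Sitting",
    )
    trunk_wy = _conditioned(trial, "trunk", "angular_velocity", "y", config, "Turning")
    head_wy = _conditioned(trial, "head", "angular_velocity", "y", config, "Turning")
    hip_walk = condition(
        trial.get("hip", "angular_velocity", "Walking"),
        config.walking_axis, config.w1_hz, config.walking_w2_hz,
    )

    stand_sit = detect_stand_sit(
        trunk_az, hip_ay, config.min_separation_s, config.threshold_fraction
    )
    turning = detect_turning(
        trunk_wy, head_wy, config.min_separation_s, config.threshold_fraction,
        config.turn_verify_window_s,
    )
    walking_mask = detect_walking(hip_walk, config.walking_window_s)

    events = sorted(stand_sit + turning, key=lambda e: e.peak_time_s)
    squares = []
    for event in events:
        source = trunk_az if event.label in ("Standing", "Sitting") else trunk_wy
        squares.append(square_signal(source, event, config.threshold_fraction))

    n = trial.n_samples
    labels = np.full(n, "Idle", dtype=object)
    labels[walking_mask] = "Walking"
    for sq in squares:
        if sq.event.label in ("Standing", "Sitting"):
            labels[sq.samples == 1] = sq.event.label
    for sq in squares:
        if sq.event.label == "Turning":
            labels[sq.samples == 1] = "Turning"
    return TrialClassification(
        events=events,
        labels=labels,
        walking_mask=walking_mask,
        squares=squares,
        rate_hz=trial.rate_hz,
    )
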