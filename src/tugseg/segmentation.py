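"""Transition estimation and trial segmentation (first-extremum rule).

Each of the seven transitions is anchored to one detected activity peak
(e.g. sit-to-stand and stand-to-walk-out to the stand-up peak). For every
channel configured for that transition, the channel is re-conditioned at
its own calibrated high cut, the activity peak is re-located on that band,
and the transition candidate is the time of the first local extremum of
opposite polarity scanning outward from the peak (first minima around a
maximum-type peak, first maxima around a minimum-type peak); the trace
boundary is returned if no extremum is found first. The combined estimate
is the mean of the per-channel candidates; boundary-fallback candidates
are discarded from the mean when interior candidates exist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .conditioning import ConditionedTrace, condition_samples
from .config import ChannelSpec, SegmentationConfig, TRANSITION_ANCHORS, default_config
from .detection import TrialClassification, classify_trial, local_extrema
from .errors import SegmentationError, ValidationError
from .rom import rom_trace
from .types import (
    ActivityEvent,
    SegmentInterval,
    TransitionSet,
    TrialRecording,
    TRANSITION_NAMES,
)

logger = logging.getLogger(__name__)


def first_extremum_left(
    conditioned: ConditionedTrace, peak_time_s: float, kind: str
) -> float:
    """Time of the first local extremum of `kind` left of the peak sample.

    Scans outward sample by sample; returns the trace start time (0) if the
    boundary is reached without finding one.
    """
    return _first_extremum(conditioned, peak_time_s, kind, step=-1)


def first_extremum_right(
    conditioned: ConditionedTrace, peak_time_s: float, kind: str
) -> float:
    """Mirror of :func:`first_extremum_left`, scanning toward the trace end."""
    return _first_extremum(conditioned, peak_time_s, kind, step=+1)


def _is_extremum(x: np.ndarray, i: int, kind: str) -> bool:
    """Strict local extremum test with plateaus owned by their first sample."""
    n = len(x)
    if i <= 0 or i >= n - 1:
        return False
    if x[i] == x[i - 1]:
        return False  # plateaus take the earliest sample
    j = i + 1
    while j < n and x[j] == x[i]:
        j += 1
    if j >= n:
        return False
    if kind == "max":
        return x[i] > x[i - 1] and x[i] > x[j]
    return x[i] < x[i - 1] and x[i] < x[j]


def _first_extremum(
    conditioned: ConditionedTrace, peak_time_s: float, kind: str, step: int
) -> float:
    if kind not in ("min", "max"):
        raise ValidationError("kind must be 'min' or 'max'")
    x = conditioned.samples
    n = len(x)
    idx = int(round(peak_time_s * conditioned.rate_hz))
    if not (0 <= idx < n):
        raise ValidationError(
            f"peak time {peak_time_s:.3f} s outside the trace [0, {n / conditioned.rate_hz:.3f})"
        )
    i = idx + step
    while 0 < i < n - 1:
        if _is_extremum(x, i, kind):
            return i / conditioned.rate_hz
        i += step
    # boundary fallback
    return 0.0 if step < 0 else (n - 1) / conditioned.rate_hz


@dataclass
class TransitionEstimate:
    """One transition's per-channel candidates and their combined time."""

    name: str
    candidate_times_s: list[float]
    channels: list[ChannelSpec]
    combined_time_s: float
    boundary_flags: list[bool]

    def __post_init__(self) -> None:
        if not self.candidate_times_s:
            raise ValidationError(f"transition {self.name!r}: no candidate times")


def _channel_samples(trial: TrialRecording, spec: ChannelSpec) -> np.ndarray:
    if spec.quantity == "rom":
        return rom_trace(trial, spec.site).angles_deg
    return trial.channel(spec.site, spec.quantity, spec.axis, context=spec.site)


def _nearest_peak(
    cond: ConditionedTrace, anchor_time_s: float, search_window_s: float = 1.5
) -> tuple[float, int]:
    """Locate the governing extremum on a transition-specific band.

    Returns (peak_time_s, polarity) where polarity is +1 for a maximum-type
    peak and -1 for a minimum-type. The peak is the local extremum of
    largest |value| within +/- search_window_s of the anchor; if none
    exists there, the sample of largest |value| in the window is used.
    """
    x = cond.samples
    rate = cond.rate_hz
    lo = max(0, int(round((anchor_time_s - search_window_s) * rate)))
    hi = min(len(x), int(round((anchor_time_s + search_window_s) * rate)) + 1)
    ext = [i for i in local_extrema(x, "max") + local_extrema(x, "min") if lo <= i < hi]
    if ext:
        best = max(ext, key=lambda i: (abs(x[i]), -i))
    else:
        best = lo + int(np.argmax(np.abs(x[lo:hi])))
    return best / rate, (1 if x[best] >= 0 else -1)


def estimate_transition(
    trial: TrialRecording,
    name: str,
    config: SegmentationConfig | None = None,
    classification: TrialClassification | None = None,
) -> TransitionEstimate:
    """Estimate one named transition by the first-extremum rule.

    Needs the trial's activity events to anchor the search; they are
    computed on demand if not supplied.
    """
    config = config if config is not None else default_config()
    if name not in TRANSITION_NAMES:
        raise ValidationError(f"unknown transition {name!r}")
    if classification is None:
        classification = classify_trial(trial, config)
    anchor = _anchor_event(classification.events, name)
    channels = config.combinations[name]
    side = TRANSITION_ANCHORS[name][2]
    candidates: list[float] = []
    flags: list[bool] = []
    for spec in channels:
        cond = condition_samples(
            _channel_samples(trial, spec),
            trial.rate_hz,
            config.w1_hz,
            spec.w2_hz,
            source=spec.key,
        )
        peak_time, polarity = _nearest_peak(cond, anchor.peak_time_s)
        bound_kind = "min" if polarity > 0 else "max"
        finder = first_extremum_left if side == "left" else first_extremum_right
        t = finder(cond, peak_time, bound_kind)
        at_boundary = t <= 0.0 or t >= (cond.n_samples - 1) / cond.rate_hz
        candidates.append(t)
        flags.append(at_boundary)
    interior = [t for t, b in zip(candidates, flags) if not b]
    if interior and len(interior) < len(candidates):
        logger.warning(
            "transition %s: dropping %d boundary-fallback candidate(s) from the mean",
            name, len(candidates) - len(interior),
        )
    used = interior if interior else candidates
    return TransitionEstimate(
        name=name,
        candidate_times_s=candidates,
        channels=list(channels),
        combined_time_s=float(np.mean(used)),
        boundary_flags=flags,
    )


def _anchor_event(events: list[ActivityEvent], name: str) -> ActivityEvent:
    activity, occurrence, _side = TRANSITION_ANCHORS[name]
    matching = [e for e in events if e.label == activity]
    if len(matching) <= occurrence:
        raise SegmentationError(
            f"transition {name!r} needs {activity} event #{occurrence + 1}, "
            f"but only {len(matching)} {activity} event(s) were detected"
        )
    return matching[occurrence]


def _check_event_sequence(events: list[ActivityEvent]) -> None:
    counts = {"Standing": 0, "Turning": 0, "Sitting": 0}
    for e in events:
        if e.label in counts:
            counts[e.label] += 1
    missing = [
        f"{need} {label} (found {counts[label]})"
        for label, need in (("Standing", 1), ("Turning", 2), ("Sitting", 1))
        if counts[label] < need
    ]
    if missing:
        raise SegmentationError("incomplete TUG event sequence: need " + ", ".join(missing))


def segment_trial(
    trial: TrialRecording, config: SegmentationConfig | None = None
) -> tuple[TransitionSet, list[SegmentInterval]]:
    """Estimate all seven transitions and build the six segments.

    Raises SegmentationError when required activity events are missing or
    when the combined transition estimates are not strictly increasing.
    """
    config = config if config is not None else default_config()
    classification = classify_trial(trial, config)
    _check_event_sequence(classification.events)
    estimates = [
        estimate_transition(trial, name, config, classification)
        for name in TRANSITION_NAMES
    ]
    times = np.array([e.combined_time_s for e in estimates])
    diffs = np.diff(times)
    if np.any(diffs <= 0):
        bad = int(np.argmax(diffs <= 0))
        raise SegmentationError(
            "inconsistent segmentation: "
            f"{TRANSITION_NAMES[bad]}={times[bad]:.3f} s !< "
            f"{TRANSITION_NAMES[bad + 1]}={times[bad + 1]:.3f} s"
        )
    transitions = TransitionSet.from_array(times)
    return transitions, transitions.to_segments()


def compare_transitions(
    estimated: TransitionSet, reference: TransitionSet
) -> dict[str, dict[str, float]]:
    """Per-transition signed (estimated - reference) and absolute differences."""
    out = {}
    for name in TRANSITION_NAMES:
        signed = estimated[name] - reference[name]
        out[name] = {"signed_s": signed, "absolute_s": abs(signed)}
    return out
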