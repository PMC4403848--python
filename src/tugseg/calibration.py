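"""Exhaustive-search calibration of per-channel high-cut frequencies.

The high cut w2 of each (channel, transition) pair is chosen by minimizing
the sum of squared differences between the channel's transition estimate
and a reference time across trials,

    cost(w2) = sum_k (T_reference,k - T_sensor,k(w2))^2

over an exhaustive grid of 2000 evenly spaced frequencies in
[0.5, 10] Hz (endpoints included; ties go to the lowest frequency).
References come from the simulator's ground truth here; in a clinical
deployment they would be human-annotated times.

Grid evaluation is exact but cached: per trial, the channel is detrended
and normalized once and its real FFT stored, so each grid point costs one
masked inverse FFT plus the peak/extremum scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations as _combinations

import numpy as np

from .conditioning import ConditionedTrace, detrend, normalize
from .config import ChannelSpec, SegmentationConfig, TRANSITION_ANCHORS, default_config
from .detection import classify_trial
from .errors import TugsegError, ValidationError
from .segmentation import (
    _anchor_event,
    _channel_samples,
    _nearest_peak,
    first_extremum_left,
    first_extremum_right,
)
from .types import GroundTruth, TrialRecording

#: Default exhaustive-search grid: (low Hz, high Hz, number of points).
DEFAULT_GRID: tuple[float, float, int] = (0.5, 10.0, 2000)


def grid_frequencies(grid: tuple[float, float, int] = DEFAULT_GRID) -> np.ndarray:
    low, high, steps = grid
    if not (0 < low < high) or steps < 2:
        raise ValidationError(f"bad grid {grid}")
    return np.linspace(low, high, int(steps))


class _CachedChannelEstimator:
    """Per-trial FFT cache for re-estimating one transition at many w2."""

    def __init__(
        self,
        trials: list[TrialRecording],
        channel: ChannelSpec,
        transition: str,
        config: SegmentationConfig,
    ) -> None:
        self.transition = transition
        self.side = TRANSITION_ANCHORS[transition][2]
        self.w1 = config.w1_hz
        self._cache = []
        for trial in trials:
            events = classify_trial(trial, config).events
            anchor = _anchor_event(events, transition)
            x = normalize(detrend(_channel_samples(trial, channel)))
            n = len(x)
            self._cache.append(
                {
                    "spectrum": np.fft.rfft(x),
                    "freqs": np.fft.rfftfreq(n, d=1.0 / trial.rate_hz),
                    "n": n,
                    "rate": trial.rate_hz,
                    "anchor_time": anchor.peak_time_s,
                    "source": channel.key,
                }
            )

    def estimate(self, trial_index: int, w2_hz: float) -> float:
        c = self._cache[trial_index]
        keep = (c["freqs"] >= self.w1) & (c["freqs"] <= w2_hz)
        spectrum = np.where(keep, c["spectrum"], 0.0)
        cond = ConditionedTrace(
            source=c["source"],
            samples=np.fft.irfft(spectrum, n=c["n"]),
            rate_hz=c["rate"],
            w1_hz=self.w1,
            w2_hz=w2_hz,
        )
        peak_time, polarity = _nearest_peak(cond, c["anchor_time"])
        kind = "min" if polarity > 0 else "max"
        finder = first_extremum_left if self.side == "left" else first_extremum_right
        return finder(cond, peak_time, kind)

    def __len__(self) -> int:
        return len(self._cache)


def transition_cost(
    w2_hz: float,
    trials: list[TrialRecording],
    references: list[float],
    channel: ChannelSpec,
    transition: str,
    config: SegmentationConfig | None = None,
    failure_penalty: float | None = None,
    _estimator: _CachedChannelEstimator | None = None,
) -> float:
    """Eq.-style squared-error cost of one channel at one w2 across trials.

    ``references`` are the per-trial reference times (seconds) for this
    transition. A trial whose estimation fails contributes
    ``failure_penalty`` (seconds-squared) if given, otherwise it is
    excluded with a warning.
    """
    if len(trials) != len(references):
        raise ValidationError("trials and references must pair up")
    if not trials:
        raise ValidationError("need at least one (trial, reference) pair")
    config = config if config is not None else default_config()
    est = _estimator or _CachedChannelEstimator(trials, channel, transition, config)
    cost = 0.0
    for k, ref in enumerate(references):
        try:
            t = est.estimate(k, w2_hz)
        except TugsegError as exc:
            if failure_penalty is not None:
                cost += failure_penalty
            else:
                warnings.warn(
                    f"trial {k}: estimation failed at w2={w2_hz:.3f} Hz ({exc}); excluded",
                    stacklevel=2,
                )
            continue
        cost += (ref - t) ** 2
    return cost


@dataclass
class CalibrationResult:
    """Outcome of the exhaustive search for one (channel, transition)."""

    channel: ChannelSpec
    transition: str
    grid_hz: np.ndarray
    costs: np.ndarray
    optimal_w2_hz: float
    optimal_cost: float

    def __post_init__(self) -> None:
        if self.optimal_w2_hz not in self.grid_hz:
            raise ValidationError("optimal w2 must be a grid member")


def optimize_w2(
    trials: list[TrialRecording],
    references: list[float],
    channel: ChannelSpec,
    transition: str,
    config: SegmentationConfig | None = None,
    grid: tuple[float, float, int] = DEFAULT_GRID,
    failure_penalty: float | None = None,
) -> CalibrationResult:
    """Exhaustive search for the cost-minimizing high cut on the grid.

    Every grid point is evaluated; the argmin is returned, with ties broken
    toward the lowest frequency. The full cost curve is retained for
    convergence inspection.
    """
    config = config if config is not None else default_config()
    freqs = grid_frequencies(grid)
    nyq = config.rate_hz / 2.0
    if freqs[-1] > nyq:
        raise ValidationError(f"grid top {freqs[-1]} Hz above Nyquist {nyq} Hz")
    est = _CachedChannelEstimator(trials, channel, transition, config)
    costs = np.empty(len(freqs))
    n_failed = 0
    for i, w2 in enumerate(freqs):
        try:
            costs[i] = transition_cost(
                w2, trials, references, channel, transition, config,
                failure_penalty=failure_penalty, _estimator=est,
            )
        except TugsegError:
            costs[i] = np.inf
            n_failed += 1
    if n_failed == len(freqs):
        raise TugsegError(
            f"calibration failed at every grid point for {channel} / {transition}"
        )
    best = int(np.argmin(costs))  # first minimum = lowest frequency on ties
    return CalibrationResult(
        channel=channel,
        transition=transition,
        grid_hz=freqs,
        costs=costs,
        optimal_w2_hz=float(freqs[best]),
        optimal_cost=float(costs[best]),
    )


def select_sensor_combination(
    trials: list[TrialRecording],
    references: list[float],
    candidates: list[ChannelSpec],
    transition: str,
    config: SegmentationConfig | None = None,
    grid: tuple[float, float, int] = DEFAULT_GRID,
    max_size: int | None = None,
) -> tuple[list[ChannelSpec], float]:
    """Choose the channel subset whose mean transition time has lowest cost.

    Each candidate channel is first calibrated on its own; every non-empty
    subset (up to max_size) is then scored by the squared error of the
    mean of its members' estimates, each member at its calibrated w2.
    Returns (chosen channels with calibrated w2, cost). Ties prefer fewer
    channels, then candidate order.
    """
    if not candidates:
        raise ValidationError("need at least one candidate channel")
    config = config if config is not None else default_config()
    calibrated: list[tuple[ChannelSpec, _CachedChannelEstimator]] = []
    for spec in candidates:
        result = optimize_w2(trials, references, spec, transition, config, grid)
        tuned = ChannelSpec(spec.site, spec.quantity, spec.axis, result.optimal_w2_hz)
        calibrated.append(
            (tuned, _CachedChannelEstimator(trials, tuned, transition, config))
        )

    best_subset: list[ChannelSpec] | None = None
    best_cost = np.inf
    limit = max_size or len(calibrated)
    for size in range(1, limit + 1):
        for subset in _combinations(range(len(calibrated)), size):
            cost = 0.0
            for k, ref in enumerate(references):
                times = [
                    calibrated[j][1].estimate(k, calibrated[j][0].w2_hz) for j in subset
                ]
                cost += (ref - float(np.mean(times))) ** 2
            if cost < best_cost - 1e-12:
                best_cost = cost
                best_subset = [calibrated[j][0] for j in subset]
    assert best_subset is not None
    return best_subset, float(best_cost)


def references_from_truth(truths: list[GroundTruth], transition: str) -> list[float]:
    """Per-trial reference times for one transition from simulator truth."""
    return [truth.transitions[transition] for truth in truths]
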