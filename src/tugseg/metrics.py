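"""Evaluation metrics: transition-time error (Delta-T) and detection scoring.

Delta-T for one transition is the mean absolute difference between
algorithmic and reference transition times across trials,

    Delta_T = (1/K) * sum_k |T_reference,k - T_sensor,k|

with the spread reported as the standard deviation of the signed
differences.

Detection is scored per ground-truth segment instance (6 per trial). A
segment counts as a true positive when its activity is detected inside it:
for Standing/Turning/Sitting, an event of that activity with its peak time
inside the segment; for Walking, at least half the segment's samples
labeled Walking. The negative universe (never defined operationally in the
source study) is one opportunity per segment slot: a spurious detection of
an activity (an event outside every ground-truth segment of that activity,
or a walking run not touching any true walking segment) consumes one of
that activity's slots in its trial as a false positive; untouched slots
are true negatives. Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
each over trials x 6 slots opportunities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detection import TrialClassification
from .errors import ValidationError
from .types import GroundTruth, TransitionSet, TRANSITION_NAMES


def delta_T(
    estimates: list[TransitionSet], references: list[TransitionSet]
) -> dict[str, dict[str, float]]:
    """Per-transition mean absolute difference and spread across trials.

    Returns {transition: {"delta_t_s", "sigma_s", "n"}}; sigma is the
    sample standard deviation (ddof=1) of the signed differences, 0.0 for a
    single pair.
    """
    if len(estimates) != len(references):
        raise ValidationError(
            f"unpaired trials: {len(estimates)} estimates vs {len(references)} references"
        )
    if not estimates:
        raise ValidationError("need at least one (estimate, reference) pair")
    out = {}
    for name in TRANSITION_NAMES:
        diffs = np.array([e[name] - r[name] for e, r in zip(estimates, references)])
        sigma = float(np.std(diffs, ddof=1)) if len(diffs) > 1 else 0.0
        out[name] = {
            "delta_t_s": float(np.mean(np.abs(diffs))),
            "sigma_s": sigma,
            "n": len(diffs),
        }
    return out


@dataclass
class EvaluationReport:
    """Confusion counts and derived rates for activity detection."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    per_activity: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    @property
    def n_instances(self) -> int:
        return self.tp + self.fn


def _walking_runs(labels: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end) runs of Walking-labeled samples."""
    walking = np.asarray(labels) == "Walking"
    runs: list[tuple[int, int]] = []
    in_run = False
    start = 0
    for i, w in enumerate(walking):
        if w and not in_run:
            in_run, start = True, i
        elif not w and in_run:
            runs.append((start, i))
            in_run = False
    if in_run:
        runs.append((start, len(walking)))
    return runs


def score_detection(
    predictions: list[TrialClassification],
    truths: list[GroundTruth],
    walking_coverage: float = 0.5,
) -> EvaluationReport:
    """Score detections against ground truth over all segment instances."""
    if len(predictions) != len(truths):
        raise ValidationError(
            f"unpaired trials: {len(predictions)} predictions vs {len(truths)} truths"
        )
    report = EvaluationReport()
    acts = ("Standing", "Walking", "Turning", "Sitting")
    per_activity = {a: {"tp": 0, "fp": 0, "tn": 0, "fn": 0} for a in acts}

    for pred, truth in zip(predictions, truths):
        rate = truth.rate_hz
        segments_by_activity: dict[str, list] = {a: [] for a in acts}
        for seg in truth.segments:
            segments_by_activity[seg.activity].append(seg)

        for activity in acts:
            segs = segments_by_activity[activity]
            slots = len(segs)
            if activity == "Walking":
                matched = 0
                for seg in segs:
                    lo = int(round(seg.start_s * rate))
                    hi = int(round(seg.end_s * rate))
                    frac = float(np.mean(pred.labels[lo:hi] == "Walking")) if hi > lo else 0.0
                    if frac >= walking_coverage:
                        matched += 1
                    else:
                        per_activity[activity]["fn"] += 1
                per_activity[activity]["tp"] += matched
                spurious = 0
                for lo, hi in _walking_runs(pred.labels):
                    run_lo, run_hi = lo / rate, hi / rate
                    if not any(
                        min(run_hi, s.end_s) > max(run_lo, s.start_s) for s in segs
                    ):
                        spurious += 1
            else:
                events = [e for e in pred.events if e.label == activity]
                used = [False] * len(events)
                matched = 0
                for seg in segs:
                    hit = next(
                        (
                            i
                            for i, e in enumerate(events)
                            if not used[i] and seg.start_s <= e.peak_time_s < seg.end_s
                        ),
                        None,
                    )
                    if hit is None:
                        per_activity[activity]["fn"] += 1
                    else:
                        used[hit] = True
                        matched += 1
                per_activity[activity]["tp"] += matched
                spurious = sum(1 for i, u in enumerate(used) if not u)
            fp = min(spurious, slots)
            per_activity[activity]["fp"] += fp
            per_activity[activity]["tn"] += slots - fp

    for counts in per_activity.values():
        report.tp += counts["tp"]
        report.fp += counts["fp"]
        report.tn += counts["tn"]
        report.fn += counts["fn"]
    report.per_activity = per_activity
    return report
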