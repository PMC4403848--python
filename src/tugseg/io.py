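"""On-disk trial format: a documented plain-text columnar CSV.

No public format exists for the proprietary motion-capture suit this
package models, so trials are exchanged in a long/columnar CSV:

    # tugseg-trial v1 rate_hz=<float> distance_m=<float>
    subject_id,trial_id,site,quantity,axis,sample_index,value
    S01,T0,trunk,acceleration,z,0,0.0123
    ...

One row per (channel axis, sample). Orientation quaternions are stored as
four axis rows (w, x, y, z) per time point and renormalized on load.
Floats are written at full precision so a write/read round trip is
lossless well below 1e-9.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .types import (
    GroundTruth,
    SegmentInterval,
    SensorTrace,
    TransitionSet,
    TrialRecording,
    _axes_for,
)

_HEADER_PREFIX = "# tugseg-trial v1"
_COLUMNS = ["subject_id", "trial_id", "site", "quantity", "axis", "sample_index", "value"]


def write_trial(trial: TrialRecording, path: str | Path) -> None:
    """Write a trial to the columnar CSV format (lossless round trip)."""
    path = Path(path)
    frames = []
    for (site, quantity), trace in sorted(trial.traces.items()):
        axes = _axes_for(quantity)
        n = trace.n_samples
        for j, axis in enumerate(axes):
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": trial.subject_id,
                        "trial_id": trial.trial_id,
                        "site": site,
                        "quantity": quantity,
                        "axis": axis,
                        "sample_index": np.arange(n),
                        "value": trace.samples[:, j],
                    }
                )
            )
    table = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(
            f"{_HEADER_PREFIX} rate_hz={trial.rate_hz!r} distance_m={trial.distance_m!r}\n"
        )
        table.to_csv(fh, index=False, float_format="%.17g")


def read_trial(path: str | Path) -> TrialRecording:
    """Read a trial written by :func:`write_trial`, validating the schema."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith(_HEADER_PREFIX):
            raise ValidationError(
                f"{path}: not a tugseg trial file (bad header line)"
            )
        meta = dict(
            item.split("=", 1) for item in header[len(_HEADER_PREFIX):].split() if "=" in item
        )
        try:
            rate_hz = float(meta["rate_hz"])
            distance_m = float(meta["distance_m"])
        except KeyError as exc:
            raise ValidationError(f"{path}: header missing {exc}") from None
        table = pd.read_csv(fh, dtype={"axis": str})
    missing_cols = set(_COLUMNS) - set(table.columns)
    if missing_cols:
        raise ValidationError(f"{path}: missing columns {sorted(missing_cols)}")
    if table.empty:
        raise ValidationError(f"{path}: no channels")
    subjects = table["subject_id"].unique()
    trials = table["trial_id"].unique()
    if len(subjects) != 1 or len(trials) != 1:
        raise ValidationError(f"{path}: file must contain exactly one trial")

    traces: dict[tuple[str, str], SensorTrace] = {}
    for (site, quantity), group in table.groupby(["site", "quantity"], sort=True):
        axes = _axes_for(str(quantity))
        pivot = group.pivot_table(
            index="sample_index", columns="axis", values="value", aggfunc="first"
        )
        got_axes = set(pivot.columns)
        if got_axes != set(axes):
            raise ValidationError(
                f"{path}: channel ({site}, {quantity}) has axes {sorted(got_axes)}, "
                f"expected {sorted(axes)}"
            )
        n = len(pivot)
        if not np.array_equal(pivot.index.to_numpy(), np.arange(n)):
            raise ValidationError(
                f"{path}: channel ({site}, {quantity}) has non-contiguous sample indices"
            )
        samples = pivot[list(axes)].to_numpy(dtype=float)
        if np.any(~np.isfinite(samples)):
            raise ValidationError(
                f"{path}: channel ({site}, {quantity}) has missing or non-finite values"
            )
        traces[(str(site), str(quantity))] = SensorTrace(
            site=str(site), quantity=str(quantity), samples=samples, rate_hz=rate_hz
        )
    return TrialRecording(
        traces=traces,
        distance_m=distance_m,
        subject_id=str(subjects[0]),
        trial_id=str(trials[0]),
    )


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Write a ground-truth sidecar (transitions + segments) as JSON."""
    data = {
        "rate_hz": truth.rate_hz,
        "transitions": truth.transitions.as_dict(),
        "segments": [
            {"name": s.name, "start_s": s.start_s, "end_s": s.end_s}
            for s in truth.segments
        ],
        "labels": truth.labels.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(data, fh)


def read_ground_truth(path: str | Path) -> GroundTruth:
    with open(path) as fh:
        data = json.load(fh)
    return GroundTruth(
        segments=[
            SegmentInterval(d["name"], float(d["start_s"]), float(d["end_s"]))
            for d in data["segments"]
        ],
        transitions=TransitionSet(**{k: float(v) for k, v in data["transitions"].items()}),
        labels=np.asarray(data["labels"], dtype=object),
        rate_hz=float(data["rate_hz"]),
    )
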