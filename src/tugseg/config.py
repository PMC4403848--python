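"""Segmentation configuration: sensor combinations and band-pass cutoffs.

The defaults encode the calibrated high-cut frequencies for each sensor at
each transition together with the sensor combinations whose mean transition
time best approximated reference segmentation. Two published sources are
reconciled here: the frequency table lists every calibrated (transition,
sensor) pair, while the sensor-combination flow chart names which of those
sensors are actually averaged for each transition. Entries written "v_y" in
the frequency table are angular velocity ω_y (the same channels the
flow chart names); this interpretation is a config default and can be
overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

from .errors import ValidationError
from .types import TRANSITION_NAMES

#: Calibrated high-cut frequencies (Hz), one row per (transition, channel).
#: Channels are (site, quantity, axis); quantity "rom" denotes a joint-angle
#: channel (site holds the joint name). All 14 published cells are encoded.
TABLE1_FREQUENCIES: dict[str, dict[tuple[str, str, str], float]] = {
    "sit_to_stand": {
        ("trunk", "acceleration", "z"): 1.57,
        ("hip", "angular_velocity", "x"): 0.69,
    },
    "stand_to_walk_out": {
        ("trunk", "acceleration", "z"): 2.44,
        ("knee_left", "rom", ""): 8.30,
    },
    "walk_out_to_turn": {
        ("trunk", "angular_velocity", "y"): 1.32,
        ("head", "angular_velocity", "x"): 0.79,
        ("hip", "angular_velocity", "y"): 0.98,
    },
    "turn_to_walk_in": {
        ("hip", "angular_velocity", "y"): 0.53,
        ("head", "angular_velocity", "x"): 0.41,
    },
    "walk_in_to_turn": {
        ("trunk", "angular_velocity", "y"): 1.00,
        ("hip", "angular_velocity", "y"): 0.59,
    },
    "turn_to_stand": {
        ("trunk", "angular_velocity", "y"): 1.00,
        ("hip", "angular_velocity", "y"): 0.81,
    },
    "stand_to_sit": {
        ("hip", "acceleration", "z"): 1.07,
    },
}


@dataclass(frozen=True)
class ChannelSpec:
    """One conditioned channel used for a transition estimate."""

    site: str  # sensor site, or joint name when quantity == "rom"
    quantity: str  # acceleration | angular_velocity | rom
    axis: str  # x/y/z for vector quantities, "" for rom
    w2_hz: float

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.site, self.quantity, self.axis)


#: Anchoring of each transition: which detected activity's peak governs it,
#: which occurrence of that activity (0-based), and on which side of the
#: peak the first extremum is sought.
TRANSITION_ANCHORS: dict[str, tuple[str, int, str]] = {
    "sit_to_stand": ("Standing", 0, "left"),
    "stand_to_walk_out": ("Standing", 0, "right"),
    "walk_out_to_turn": ("Turning", 0, "left"),
    "turn_to_walk_in": ("Turning", 0, "right"),
    "walk_in_to_turn": ("Turning", 1, "left"),
    "turn_to_stand": ("Turning", 1, "right"),
    "stand_to_sit": ("Sitting", 0, "right"),
}


def _default_combinations() -> dict[str, list[ChannelSpec]]:
    """Default per-transition sensor combinations (flow-chart assignments).

    Sit-to-stand averages trunk a_z with the left-knee joint angle;
    stand-to-walk-out and stand-to-sit use trunk a_z alone; transitions
    into/out of the turns average trunk and hip ω_y, except turn-to-walk-in
    which uses hip ω_y alone (it approximated the reference best on its
    own). The knee-angle high cut uses the one published knee-ROM frequency
    (8.30 Hz); stand-to-sit uses the published 1.07 Hz for the sit-down
    acceleration channel.
    """
    f = TABLE1_FREQUENCIES
    return {
        "sit_to_stand": [
            ChannelSpec("trunk", "acceleration", "z",
                        f["sit_to_stand"][("trunk", "acceleration", "z")]),
            ChannelSpec("knee_left", "rom", "",
                        f["stand_to_walk_out"][("knee_left", "rom", "")]),
        ],
        "stand_to_walk_out": [
            ChannelSpec("trunk", "acceleration", "z",
                        f["stand_to_walk_out"][("trunk", "acceleration", "z")]),
        ],
        "walk_out_to_turn": [
            ChannelSpec("trunk", "angular_velocity", "y",
                        f["walk_out_to_turn"][("trunk", "angular_velocity", "y")]),
            ChannelSpec("hip", "angular_velocity", "y",
                        f["walk_out_to_turn"][("hip", "angular_velocity", "y")]),
        ],
        "turn_to_walk_in": [
            ChannelSpec("hip", "angular_velocity", "y",
                        f["turn_to_walk_in"][("hip", "angular_velocity", "y")]),
        ],
        "walk_in_to_turn": [
            ChannelSpec("trunk", "angular_velocity", "y",
                        f["walk_in_to_turn"][("trunk", "angular_velocity", "y")]),
            ChannelSpec("hip", "angular_velocity", "y",
                        f["walk_in_to_turn"][("hip", "angular_velocity", "y")]),
        ],
        "turn_to_stand": [
            ChannelSpec("trunk", "angular_velocity", "y",
                        f["turn_to_stand"][("trunk", "angular_velocity", "y")]),
            ChannelSpec("hip", "angular_velocity", "y",
                        f["turn_to_stand"][("hip", "angular_velocity", "y")]),
        ],
        "stand_to_sit": [
            ChannelSpec("trunk", "acceleration", "z",
                        f["stand_to_sit"][("hip", "acceleration", "z")]),
        ],
    }


def _default_detection_bands() -> dict[tuple[str, str, str], float]:
    """High cuts for the detection channels (activity peaks, not bounds).

    The stand/sit channels reuse the sit-to-stand trunk a_z cut. The turn
    channels use 2.0 Hz, wider than the boundary-calibrated sub-hertz turn
    cuts: peak *detection* wants the gross pulse shape preserved, while the
    narrow cuts are tuned for boundary precision. The walking oscillation
    channel is deliberately left at the Nyquist frequency (30 Hz at 60 Hz
    sampling) so the stride content survives.
    """
    return {
        ("trunk", "acceleration", "z"): 1.57,
        ("hip", "acceleration", "y"): 1.57,
        ("trunk", "angular_velocity", "y"): 2.0,
        ("head", "angular_velocity", "y"): 2.0,
        ("hip", "angular_velocity", "x"): 30.0,
    }


@dataclass
class SegmentationConfig:
    """Everything the detection/segmentation pipeline is parameterized by."""

    rate_hz: float = 60.0
    w1_hz: float = 0.0025  # low cut: removes DC while keeping slow dynamics
    walking_w2_hz: float = 30.0  # Nyquist at 60 Hz: keep stride content
    threshold_fraction: float = 0.30  # square-signal / major-peak threshold
    walking_window_s: float = 0.5  # oscillation-detection window
    min_separation_s: float = 1.0  # peak thinning distance
    turn_verify_window_s: float = 0.5  # head/trunk peak agreement window
    walking_axis: str = "x"  # hip angular-velocity axis used for Walking
    stand_sit_derivative_site: str = "hip"  # a_y derivative channel site
    detection_bands: dict[tuple[str, str, str], float] = field(
        default_factory=_default_detection_bands
    )
    combinations: dict[str, list[ChannelSpec]] = field(
        default_factory=_default_combinations
    )

    def __post_init__(self) -> None:
        nyq = self.rate_hz / 2.0
        if not (0.0 < self.threshold_fraction < 1.0):
            raise ValidationError(
                f"threshold fraction must be in (0, 1), got {self.threshold_fraction}"
            )
        if self.walking_window_s <= 0:
            raise ValidationError("walking window must be positive")
        for w2 in [self.walking_w2_hz, *self.detection_bands.values()]:
            self._check_band(self.w1_hz, w2, nyq)
        for name, chans in self.combinations.items():
            if name not in TRANSITION_NAMES:
                raise ValidationError(f"unknown transition {name!r} in config")
            if not chans:
                raise ValidationError(f"transition {name!r} has no channels")
            for ch in chans:
                self._check_band(self.w1_hz, ch.w2_hz, nyq)
        missing = set(TRANSITION_NAMES) - set(self.combinations)
        if missing:
            raise ValidationError(f"config missing transitions: {sorted(missing)}")

    @staticmethod
    def _check_band(w1: float, w2: float, nyquist: float) -> None:
        if not (0 <= w1 < w2):
            raise ValidationError(f"need w1 < w2, got w1={w1}, w2={w2}")
        if w2 > nyquist:
            raise ValidationError(f"w2={w2} Hz above Nyquist {nyquist} Hz")

    def with_channel(self, transition: str, channels: list[ChannelSpec]) -> "SegmentationConfig":
        """A copy of this config with one transition's channel list replaced."""
        combos = dict(self.combinations)
        combos[transition] = list(channels)
        return replace(self, combinations=combos)


def default_config() -> SegmentationConfig:
    return SegmentationConfig()


def _channel_from_dict(d: dict) -> ChannelSpec:
    return ChannelSpec(
        site=str(d["site"]),
        quantity=str(d["quantity"]),
        axis=str(d.get("axis", "")),
        w2_hz=float(d["w2_hz"]),
    )


def load_config(path_or_defaults: str) -> SegmentationConfig:
    """Load a YAML config, or return the built-in defaults for "defaults".

    The YAML mirrors the dataclass fields; ``combinations`` maps transition
    names to lists of {site, quantity, axis, w2_hz} entries and
    ``detection_bands`` is a list of the same entries. Omitted fields keep
    their defaults.
    """
    if path_or_defaults == "defaults":
        return default_config()
    with open(path_or_defaults) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    for key in (
        "rate_hz",
        "w1_hz",
        "walking_w2_hz",
        "threshold_fraction",
        "walking_window_s",
        "min_separation_s",
        "turn_verify_window_s",
        "walking_axis",
        "stand_sit_derivative_site",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    if "detection_bands" in raw:
        kwargs["detection_bands"] = {
            (str(d["site"]), str(d["quantity"]), str(d.get("axis", ""))): float(d["w2_hz"])
            for d in raw["detection_bands"]
        }
    if "combinations" in raw:
        combos = _default_combinations()
        for name, entries in raw["combinations"].items():
            combos[name] = [_channel_from_dict(d) for d in entries]
        kwargs["combinations"] = combos
    return SegmentationConfig(**kwargs)


def save_config(config: SegmentationConfig, path: str) -> None:
    """Write a config as YAML readable by load_config."""
    data = {
        "rate_hz": config.rate_hz,
        "w1_hz": config.w1_hz,
        "walking_w2_hz": config.walking_w2_hz,
        "threshold_fraction": config.threshold_fraction,
        "walking_window_s": config.walking_window_s,
        "min_separation_s": config.min_separation_s,
        "turn_verify_window_s": config.turn_verify_window_s,
        "walking_axis": config.walking_axis,
        "stand_sit_derivative_site": config.stand_sit_derivative_site,
        "detection_bands": [
            {"site": s, "quantity": q, "axis": a, "w2_hz": w}
            for (s, q, a), w in config.detection_bands.items()
        ],
        "combinations": {
            name: [
                {"site": c.site, "quantity": c.quantity, "axis": c.axis, "w2_hz": c.w2_hz}
                for c in chans
            ]
            for name, chans in config.combinations.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
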