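"""Domain types, the on-disk trial format, and configuration defaults."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tugseg import (
    ActivityEvent,
    MissingChannelError,
    SegmentationConfig,
    SensorTrace,
    TABLE1_FREQUENCIES,
    TransitionSet,
    TrialRecording,
    ValidationError,
    classify_trial,
    default_config,
    load_config,
    read_trial,
    save_config,
    write_trial,
)
from tugseg.config import ChannelSpec
from tugseg.io import read_ground_truth, write_ground_truth
from tugseg.simulate import SimulationParams, simulate_tug


def make_trial(rng, sites=(("trunk", "acceleration"), ("hip", "angular_velocity")),
               n=120, rate=60.0, with_quat=False):
    traces = {}
    for site, quantity in sites:
        traces[(site, quantity)] = SensorTrace(
            site=site, quantity=quantity, samples=rng.normal(size=(n, 3)), rate_hz=rate
        )
    if with_quat:
        q = rng.normal(size=(n, 4))
        q /= np.linalg.norm(q, axis=1, keepdims=True)
        traces[("thigh_left", "orientation")] = SensorTrace(
            site="thigh_left", quantity="orientation", samples=q, rate_hz=rate
        )
    return TrialRecording(traces=traces, distance_m=10.0, subject_id="S01", trial_id="T0")


class TestTypes:
    def test_orientation_traces_are_renormalized(self, rng):
        q = rng.normal(size=(50, 4))
        q = q / np.linalg.norm(q, axis=1, keepdims=True) * 1.0005
        trace = SensorTrace(site="hip", quantity="orientation", samples=q, rate_hz=60.0)
        assert np.allclose(np.linalg.norm(trace.samples, axis=1), 1.0, atol=1e-12)

    def test_far_from_unit_quaternions_rejected(self):
        q = np.tile([2.0, 0.0, 0.0, 0.0], (10, 1))
        with pytest.raises(ValidationError, match="unit norm"):
            SensorTrace(site="hip", quantity="orientation", samples=q, rate_hz=60.0)

    def test_mixed_rates_rejected(self, rng):
        traces = {
            ("trunk", "acceleration"): SensorTrace(
                "trunk", "acceleration", rng.normal(size=(10, 3)), 60.0
            ),
            ("hip", "acceleration"): SensorTrace(
                "hip", "acceleration", rng.normal(size=(10, 3)), 50.0
            ),
        }
        with pytest.raises(ValidationError, match="mixed sampling rates"):
            TrialRecording(traces=traces, distance_m=10.0)

    def test_empty_trial_rejected(self):
        with pytest.raises(ValidationError, match="no channels"):
            TrialRecording(traces={}, distance_m=10.0)

    def test_duration_consistency(self, rng):
        trial = make_trial(rng, n=150)
        assert trial.duration_s == pytest.approx(2.5)

    def test_turning_event_needs_direction(self):
        with pytest.raises(ValidationError):
            ActivityEvent(label="Turning", peak_time_s=1.0, peak_value=1.0)
        with pytest.raises(ValidationError):
            ActivityEvent(label="Standing", peak_time_s=1.0, peak_value=1.0,
                          direction="left")

    def test_transitions_must_increase(self):
        with pytest.raises(ValidationError, match="strictly increasing"):
            TransitionSet(1.0, 2.0, 3.0, 2.5, 4.0, 5.0, 6.0)

    def test_segments_tile_the_transitions(self):
        ts = TransitionSet(*np.arange(1.0, 8.0))
        segs = ts.to_segments()
        assert len(segs) == 6
        assert segs[0].start_s == 1.0 and segs[-1].end_s == 7.0
        for a, b in zip(segs[:-1], segs[1:]):
            assert a.end_s == b.start_s


class TestTrialIO:
    def test_round_trip_identity(self, tmp_path, rng):
        trial = make_trial(rng, with_quat=True)
        path = tmp_path / "trial.csv"
        write_trial(trial, path)
        back = read_trial(path)
        assert back.subject_id == trial.subject_id
        assert back.trial_id == trial.trial_id
        assert back.distance_m == trial.distance_m
        assert set(back.traces) == set(trial.traces)
        for key in trial.traces:
            assert np.allclose(
                back.traces[key].samples, trial.traces[key].samples, atol=1e-9
            )

    @settings(max_examples=15, deadline=None)
    @given(
        n=st.integers(min_value=2, max_value=40),
        rate=st.sampled_from([30.0, 60.0, 100.0]),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    def test_round_trip_property(self, tmp_path_factory, n, rate, seed):
        rng = np.random.default_rng(seed)
        trial = make_trial(rng, n=n, rate=rate, with_quat=True)
        path = tmp_path_factory.mktemp("io") / "t.csv"
        write_trial(trial, path)
        back = read_trial(path)
        for key in trial.traces:
            assert np.allclose(
                back.traces[key].samples, trial.traces[key].samples, atol=1e-9
            )

    def test_row_count_follows_schema_arithmetic(self, tmp_path):
        trial, _ = simulate_tug(SimulationParams(seed=0))
        path = tmp_path / "t.csv"
        write_trial(trial, path)
        expected_rows = sum(
            tr.n_samples * tr.samples.shape[1] for tr in trial.traces.values()
        )
        with open(path) as fh:
            n_lines = sum(1 for _ in fh)
        assert n_lines == expected_rows + 2  # header line + column names

    def test_partial_trial_loads_but_turning_detection_names_missing_channel(
        self, tmp_path, rng, config
    ):
        trial = make_trial(rng, sites=(("trunk", "acceleration"),), n=400)
        path = tmp_path / "partial.csv"
        write_trial(trial, path)
        back = read_trial(path)
        with pytest.raises(MissingChannelError) as err:
            classify_trial(back, config)
        assert "angular_velocity" in str(err.value)

    def test_non_trial_file_rejected(self, tmp_path):
        path = tmp_path / "bogus.csv"
        path.write_text("a,b,c\n1,2,3\n")
        with pytest.raises(ValidationError):
            read_trial(path)

    def test_ground_truth_sidecar_round_trip(self, tmp_path, sim_trial):
        _, truth = sim_trial
        path = tmp_path / "gt.json"
        write_ground_truth(truth, path)
        back = read_ground_truth(path)
        assert np.allclose(
            back.transitions.as_array(), truth.transitions.as_array()
        )
        assert list(back.labels) == list(truth.labels)


class TestConfig:
    # The published per-(transition, sensor) high-cut table, frozen.
    EXPECTED_TABLE = {
        "sit_to_stand": {("trunk", "acceleration", "z"): 1.57,
                         ("hip", "angular_velocity", "x"): 0.69},
        "stand_to_walk_out": {("trunk", "acceleration", "z"): 2.44,
                              ("knee_left", "rom", ""): 8.30},
        "walk_out_to_turn": {("trunk", "angular_velocity", "y"): 1.32,
                             ("head", "angular_velocity", "x"): 0.79,
                             ("hip", "angular_velocity", "y"): 0.98},
        "turn_to_walk_in": {("hip", "angular_velocity", "y"): 0.53,
                            ("head", "angular_velocity", "x"): 0.41},
        "walk_in_to_turn": {("trunk", "angular_velocity", "y"): 1.00,
                            ("hip", "angular_velocity", "y"): 0.59},
        "turn_to_stand": {("trunk", "angular_velocity", "y"): 1.00,
                          ("hip", "angular_velocity", "y"): 0.81},
        "stand_to_sit": {("hip", "acceleration", "z"): 1.07},
    }

    def test_defaults_match_every_published_frequency_cell(self):
        assert TABLE1_FREQUENCIES == self.EXPECTED_TABLE

    def test_default_combination_values(self):
        cfg = load_config("defaults")
        stand_walk = cfg.combinations["stand_to_walk_out"]
        assert [(c.site, c.axis, c.w2_hz) for c in stand_walk] == [("trunk", "z", 2.44)]
        assert cfg.w1_hz == 0.0025
        sit_stand = cfg.combinations["sit_to_stand"]
        assert {(c.site, c.quantity) for c in sit_stand} == {
            ("trunk", "acceleration"), ("knee_left", "rom")
        }
        turn_walk = cfg.combinations["turn_to_walk_in"]
        assert len(turn_walk) == 1 and turn_walk[0].site == "hip"

    def test_threshold_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            SegmentationConfig(threshold_fraction=1.5)

    def test_inverted_band_rejected(self):
        with pytest.raises(ValidationError):
            SegmentationConfig(w1_hz=5.0, walking_w2_hz=2.0)

    def test_yaml_round_trip(self, tmp_path):
        cfg = default_config()
        path = tmp_path / "cfg.yaml"
        save_config(cfg, path)
        back = load_config(str(path))
        assert back.combinations == cfg.combinations
        assert back.detection_bands == cfg.detection_bands
        assert back.w1_hz == cfg.w1_hz

    def test_with_channel_replaces_one_transition(self):
        cfg = default_config()
        new = cfg.with_channel(
            "stand_to_sit", [ChannelSpec("hip", "acceleration", "z", 1.07)]
        )
        assert new.combinations["stand_to_sit"][0].site == "hip"
        assert cfg.combinations["stand_to_sit"][0].site == "trunk"  # original intact
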