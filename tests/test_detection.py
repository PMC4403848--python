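"""Activity detection: major extrema, stand/sit, turning, walking, squares."""

import numpy as np
import pytest

from tugseg import (
    ActivityEvent,
    SimulationParams,
    ValidationError,
    classify_trial,
    detect_stand_sit,
    detect_turning,
    detect_walking,
    find_major_extrema,
    simulate_tug,
    square_signal,
)
from tugseg.conditioning import ConditionedTrace, condition_samples
from tugseg.detection import local_extrema

RATE = 60.0


def as_conditioned(samples, rate=RATE, w1=0.0, w2=30.0, source=("trunk", "acceleration", "z")):
    return ConditionedTrace(
        source=source, samples=np.asarray(samples, float), rate_hz=rate, w1_hz=w1, w2_hz=w2
    )


def gaussian_pulse(t, center, width, amplitude=1.0):
    return amplitude * np.exp(-0.5 * ((t - center) / width) ** 2)


class TestLocalExtrema:
    def test_plateau_takes_earliest_sample(self):
        x = np.array([0.0, 1.0, 2.0, 2.0, 2.0, 1.0, 0.0])
        assert local_extrema(x, "max") == [2]
        assert local_extrema(-x, "min") == [2]

    def test_strictness(self):
        x = np.array([0.0, 1.0, 1.0, 2.0, 0.0])
        assert local_extrema(x, "max") == [3]

    def test_endpoints_never_qualify(self):
        x = np.array([3.0, 1.0, 2.0])
        assert local_extrema(x, "max") == []
        assert local_extrema(x, "min") == [1]


class TestFindMajorExtrema:
    def test_zero_signal_yields_nothing(self):
        assert find_major_extrema(as_conditioned(np.zeros(200))) == []

    def test_two_separated_pulses_found(self):
        t = np.arange(30 * RATE) / RATE
        x = gaussian_pulse(t, 10.0, 0.5) + gaussian_pulse(t, 20.0, 0.5)
        found = find_major_extrema(as_conditioned(x), "max", min_separation_s=1.0)
        assert len(found) == 2
        assert found[0][0] == pytest.approx(10.0, abs=0.05)
        assert found[1][0] == pytest.approx(20.0, abs=0.05)

    def test_sub_threshold_pulse_excluded(self):
        t = np.arange(30 * RATE) / RATE
        x = gaussian_pulse(t, 10.0, 0.5, 1.0) + gaussian_pulse(t, 20.0, 0.5, 0.2)
        found = find_major_extrema(as_conditioned(x), "max", threshold_fraction=0.30)
        assert [round(f[0]) for f in found] == [10]

    def test_thinning_keeps_the_larger_peak(self):
        t = np.arange(10 * RATE) / RATE
        x = gaussian_pulse(t, 5.0, 0.2, 1.0) + gaussian_pulse(t, 5.5, 0.2, 0.8)
        found = find_major_extrema(as_conditioned(x), "max", min_separation_s=1.0)
        assert len(found) == 1
        assert found[0][0] == pytest.approx(5.0, abs=0.1)


class TestStandSit:
    def test_clean_trial_yields_stand_then_sit(self, noise_free_trial, config):
        trial, _ = noise_free_trial
        trunk = condition_samples(
            trial.channel("trunk", "acceleration", "z"), RATE, config.w1_hz, 1.57
        )
        hip = condition_samples(
            trial.channel("hip", "acceleration", "y"), RATE, config.w1_hz, 1.57
        )
        events = detect_stand_sit(trunk, hip)
        assert [e.label for e in events] == ["Standing", "Sitting"]
        assert events[0].peak_time_s < events[1].peak_time_s

    def test_negating_derivative_channel_swaps_labels(self, noise_free_trial, config):
        trial, _ = noise_free_trial
        trunk = condition_samples(
            trial.channel("trunk", "acceleration", "z"), RATE, config.w1_hz, 1.57
        )
        hip = condition_samples(
            trial.channel("hip", "acceleration", "y"), RATE, config.w1_hz, 1.57
        )
        flipped = ConditionedTrace(
            source=hip.source, samples=-hip.samples, rate_hz=RATE,
            w1_hz=hip.w1_hz, w2_hz=hip.w2_hz,
        )
        events = detect_stand_sit(trunk, flipped)
        assert [e.label for e in events] == ["Sitting", "Standing"]

    def test_noisy_trial_peaks_near_truth(self, sim_trial, config):
        trial, truth = sim_trial
        events = classify_trial(trial, config).events
        stand = next(e for e in events if e.label == "Standing")
        sit = next(e for e in events if e.label == "Sitting")
        stand_mid = (truth.transitions.sit_to_stand
                     + truth.transitions.stand_to_walk_out) / 2
        sit_mid = (truth.transitions.turn_to_stand
                   + truth.transitions.stand_to_sit) / 2
        assert stand.peak_time_s == pytest.approx(stand_mid, abs=0.25)
        assert sit.peak_time_s == pytest.approx(sit_mid, abs=0.25)


class TestTurning:
    def make_pair(self, head_scale=0.8, head_shift_s=0.0):
        t = np.arange(30 * RATE) / RATE
        trunk = gaussian_pulse(t, 10.0, 0.6) - gaussian_pulse(t, 20.0, 0.6)
        head = head_scale * (
            gaussian_pulse(t, 10.0 + head_shift_s, 0.6)
            - gaussian_pulse(t, 20.0 + head_shift_s, 0.6)
        )
        return as_conditioned(trunk), as_conditioned(head)

    def test_verified_turns_with_direction(self):
        trunk, head = self.make_pair()
        events = detect_turning(trunk, head)
        assert [e.label for e in events] == ["Turning", "Turning"]
        assert [e.direction for e in events] == ["left", "right"]

    def test_flat_head_channel_drops_events(self):
        trunk, _ = self.make_pair()
        flat = as_conditioned(np.zeros(trunk.n_samples))
        assert detect_turning(trunk, flat) == []

    def test_opposite_sign_head_peak_drops_event(self):
        trunk, head = self.make_pair(head_scale=-0.8)
        assert detect_turning(trunk, head) == []

    def test_head_peak_outside_window_drops_event(self):
        trunk, head = self.make_pair(head_shift_s=1.0)
        assert detect_turning(trunk, head, verify_window_s=0.5) == []

    def test_simulated_trial_has_two_turns(self, sim_trial, config):
        trial, _ = sim_trial
        events = classify_trial(trial, config).events
        assert sum(e.label == "Turning" for e in events) == 2


class TestWalking:
    def test_zero_channel_gives_empty_mask(self):
        mask = detect_walking(as_conditioned(np.zeros(600)))
        assert not mask.any()

    def test_oscillation_support_recovered(self):
        t = np.arange(20 * RATE) / RATE
        x = np.where((t >= 5.0) & (t <= 15.0), np.sin(2 * np.pi * 1.8 * t), 0.0)
        mask = detect_walking(as_conditioned(x), window_s=0.5)
        times = t[mask]
        assert times.min() == pytest.approx(5.0, abs=0.6)
        assert times.max() == pytest.approx(15.0, abs=0.6)
        assert np.mean(mask[(t > 5.5) & (t < 14.5)]) > 0.99

    def test_simulated_walk_segments_covered(self, sim_trial, config):
        trial, truth = sim_trial
        result = classify_trial(trial, config)
        truth_walk = truth.labels == "Walking"
        jaccard = (result.walking_mask & truth_walk).sum() / (
            result.walking_mask | truth_walk
        ).sum()
        assert jaccard >= 0.8

    def test_window_longer_than_trial_rejected(self):
        with pytest.raises(ValidationError):
            detect_walking(as_conditioned(np.zeros(10)), window_s=1.0)


class TestSquareSignal:
    def test_triangle_threshold_region_is_exact(self):
        n = 121
        x = 1.0 - np.abs(np.arange(n) - 60) / 60.0  # unit triangle, peak at 60
        cond = as_conditioned(x)
        event = ActivityEvent(label="Standing", peak_time_s=1.0, peak_value=1.0)
        sq = square_signal(cond, event, fraction=0.30)
        expected = (x > 0.30).astype(int)
        assert np.array_equal(sq.samples, expected)

    def test_fraction_near_one_collapses_to_peak(self):
        n = 121
        x = 1.0 - np.abs(np.arange(n) - 60) / 60.0
        event = ActivityEvent(label="Standing", peak_time_s=1.0, peak_value=1.0)
        sq = square_signal(as_conditioned(x), event, fraction=0.999)
        assert sq.samples.sum() == 1
        assert sq.samples[60] == 1

    @pytest.mark.parametrize("fraction", [0.0, 1.0, 1.5, -0.2])
    def test_invalid_fractions_rejected(self, sim_trial, fraction):
        event = ActivityEvent(label="Standing", peak_time_s=1.0, peak_value=1.0)
        with pytest.raises(ValidationError):
            square_signal(as_conditioned(np.ones(100)), event, fraction=fraction)

    def test_turn_square_duration_tracks_turn_duration(self, sim_trial, config):
        trial, _ = sim_trial
        result = classify_trial(trial, config)
        turn_squares = [s for s in result.squares if s.event.label == "Turning"]
        assert len(turn_squares) == 2
        for sq in turn_squares:
            width_s = sq.samples.sum() / trial.rate_hz
            assert abs(width_s - 2.0) / 2.0 <= 0.30  # default turn_duration_s = 2.0


class TestClassifyTrial:
    def test_event_sequence_ten_metres(self, sim_trial, config):
        trial, _ = sim_trial
        events = classify_trial(trial, config).events
        assert [e.label for e in events] == ["Standing", "Turning", "Turning", "Sitting"]

    def test_event_sequence_five_metres_same_config(self, config):
        trial, _ = simulate_tug(SimulationParams(seed=42, distance_m=5))
        events = classify_trial(trial, config).events
        assert [e.label for e in events] == ["Standing", "Turning", "Turning", "Sitting"]

    def test_turning_precedence_over_walking(self, sim_trial, config):
        trial, _ = sim_trial
        result = classify_trial(trial, config)
        for sq in result.squares:
            if sq.event.label == "Turning":
                labels_in_square = result.labels[sq.samples == 1]
                assert not np.any(labels_in_square == "Walking")

    def test_scale_invariance_of_events(self, sim_trial, config):
        trial, _ = sim_trial
        events_a = classify_trial(trial, config).events
        scaled = {}
        for key, tr in trial.traces.items():
            samples = tr.samples * (4.0 if tr.quantity != "orientation" else 1.0)
            scaled[key] = type(tr)(
                site=tr.site, quantity=tr.quantity, samples=samples, rate_hz=tr.rate_hz
            )
        trial_b = type(trial)(
            traces=scaled, distance_m=trial.distance_m,
            subject_id=trial.subject_id, trial_id=trial.trial_id,
        )
        events_b = classify_trial(trial_b, config).events
        assert [(e.label, e.peak_time_s) for e in events_a] == [
            (e.label, e.peak_time_s) for e in events_b
        ]
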