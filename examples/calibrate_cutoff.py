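"""Exhaustive-search calibration of a high-cut frequency on a small cohort.

Re-derives the optimal band-pass high cut for the hip yaw channel at the
walk-in-to-turn transition by minimizing the summed squared difference
between estimated and reference transition times over an exhaustive
frequency grid, and shows how the optimum stabilizes as subjects accrue
(the grid here is coarsened from the full 2000 points to keep the example
quick; pass grid=(0.5, 10.0, 2000) for the full search).
"""

from tugseg import optimize_w2, references_from_truth, simulate_cohort
from tugseg.config import ChannelSpec

GRID = (0.5, 10.0, 200)

cohort = simulate_cohort(n_subjects=8, trials_per_subject=1, distance_m=10.0, seed=1)
trials = [trial for trial, _ in cohort]
refs = references_from_truth([truth for _, truth in cohort], "walk_in_to_turn")
channel = ChannelSpec("hip", "angular_velocity", "y", 0.59)

result = optimize_w2(trials, refs, channel, "walk_in_to_turn", grid=GRID)
print(f"channel: hip angular velocity (y), transition: walk_in_to_turn")
print(f"optimal high cut: {result.optimal_w2_hz:.2f} Hz "
      f"(cost {result.optimal_cost:.4f} s^2 over {len(trials)} trials)")

print("\nconvergence as subjects accrue:")
for k in range(4, len(trials) + 1):
    partial = optimize_w2(trials[:k], refs[:k], channel, "walk_in_to_turn", grid=GRID)
    print(f"  {k} subjects -> w2 = {partial.optimal_w2_hz:.2f} Hz")
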