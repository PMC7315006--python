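"""Generate one ground-truthed synthetic hunting trial and write it to disk.

The scenario emulates the prey rig: a shrimp on a 250 mm rail moving
leftward at 25 mm/s, reversing instantly into a 75 mm/s rightward leg,
while a simulated cuttlefish tracks it and fires one predictive
tentacular strike.
"""

from cuttlekin import SimScenario, StrikeCommand, make_dataset

scenario = SimScenario(
    seed=7,
    duration_s=30.0,
    attention_schedule=((0.0, 30.0),),
    strikes=(StrikeCommand(time_s=8.0, predictive=True),),
)
pose_path, truth_path, scenario_path = make_dataset(scenario, "scratch/example_trial")

print(f"pose track:   {pose_path}")
print(f"ground truth: {truth_path}")
print(f"scenario:     {scenario_path}")

import pandas as pd

truth = pd.read_csv(truth_path)
print(f"\n{len(truth)} frames at {scenario.fps:g} fps "
      f"({scenario.duration_s:g} s session)")
print(truth["prey_phase"].value_counts().to_string())
# slow frames dominate: the slow leg covers the rail in 10 s, the fast leg in 3.3 s
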