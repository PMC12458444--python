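"""Score the six behavioral traits for one simulated fly.

Shows the phenotyping chain: per-minute activity flags -> sleep bouts (>= 5
inactive minutes) -> sleep min/h; baseline speed in the pre-stimulus hour;
startle duration (return of smoothed speed to baseline) and magnitude
(speed excess in the post-stimulus minute); and 8-zone occupancy.
"""

from invbehave import FlyMetadata, phenotype_fly
from invbehave.phenotype import binarize_activity, detect_sleep_bouts
from invbehave.simulate import SimulationConfig, simulate_fly_trajectory

config = SimulationConfig(
    seed=4,
    stimulus_times_s=(3600.0, 5400.0),
    recording_duration_s=7200.0,
)
fly = FlyMetadata("demo", "INV", "F", 25.0, "1")
traj = simulate_fly_trajectory(config, fly, config.fly_rng(0))

pre = traj.window(0.0, 3600.0)
flags = binarize_activity(pre, epsilon_mm=1.0)
bouts = detect_sleep_bouts(flags)
print(f"pre-stimulus hour: {int((~flags).sum())} inactive minutes in "
      f"{len(bouts)} sleep bout(s) of >= 5 min")

record = phenotype_fly(traj, config.design())
for key, value in record.as_dict().items():
    print(f"  {key:24s} {value}")
# sleep_min_per_hour is time in sleep bouts per scored hour; startle values
# are means over the two stimuli; the two proportions are the shares of
# baseline-hour samples in the food-adjacent and food-distal tube eighths.
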