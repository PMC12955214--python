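"""Score an optomotor response from a walking trajectory.

Generates a 68 s walking bout (onset latency 1.76 s, circling at
120 deg/s, 0.2 mm tracking noise), applies the exclusion filters,
detects full-rotation periods from the y-position peaks, and reports the
signed turning-velocity response and the detected onset latency.
"""

import numpy as np

from optomotor import (
    StimulusCondition,
    SyntheticWalkSpec,
    detect_rotation_periods,
    generate_walk_trajectory,
    onset_latency,
    score_trajectory,
)

spec = SyntheticWalkSpec(
    turning_velocity=120.0,
    onset_latency_mean=1.76,
    onset_latency_sd=0.0,
    position_noise_sd=0.2,
    seed=7,
)
traj = generate_walk_trajectory(spec)
condition = StimulusCondition(wavelength=60.0, angular_velocity=210.0)

segments = detect_rotation_periods(traj)
measurement = score_trajectory(traj, condition=condition, drum_start_time=0.0)

print(f"frames                  : {traj.t.size} at {traj.frame_rate:.0f} Hz")
print(f"full rotations detected : {segments.periods.size}")
print(f"mean rotation period dt : {np.mean(segments.periods):.3f} s")
print(
    f"response R = 360/dt     : {measurement.response:+.1f} deg/s "
    f"(ground truth {spec.turning_velocity:+.1f})"
)
print(f"onset latency           : {onset_latency(traj, 0.0):.2f} s (true {spec.onset_latency_mean})")
print(f"mean distance to center : {measurement.mean_distance_from_center:.1f} mm")
# R recovers the generating turning velocity within a few percent; the
# positive sign marks circling in the pattern direction.
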