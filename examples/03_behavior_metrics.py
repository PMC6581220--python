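"""Behavioural readouts: speed, distance traveled and position heat map.

Samples the two behavioural regimes of the challenge protocol — the
test-retest condition (2 cm/s, frequent rest bouts) and the memantine
condition (4 cm/s, almost no rest) — and derives the head-centroid
metrics.  The challenge roughly doubles speed and distance.
"""
from awakepet import (default_marker_model, head_track, position_heatmap,
                      sample_trajectory, speed_and_distance)

model = default_marker_model()
for name, speed, rest in (("test-retest", 2.0, 0.35), ("memantine", 4.0, 0.05)):
    trajectory = sample_trajectory(120_000, speed, rest_fraction=rest, seed=3)
    track = head_track(trajectory, model)
    sd = speed_and_distance(track)
    hm = position_heatmap(track)
    occupied = (hm.dwell_s > 0).mean()
    print(f"{name:12s}: {sd.avg_speed_cm_s:.2f} cm/s, "
          f"{sd.distance_m:.2f} m in {sd.tracked_s:.0f} s, "
          f"{occupied:.0%} of platform bins visited")
# The printed speeds recover the requested regime speeds; distance scales
# with speed x tracked time.  hm.plot() renders the log-scale heat map.
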