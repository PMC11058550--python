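"""Score a tongue pressure-tracking task from a raw trace.

Builds a synthetic 110 s trace (10 cycles of 8 s rest + 3 s target), scores
it against a maximal tongue pressure of 40 kPa, and prints the per-cycle
in-band fractions.  The target band is 3-5% of Pmax and only the last
1.5 s of each target phase counts toward the score.
"""

import numpy as np

from myotrain import Channel, PressureTrace, TrackingTaskConfig, score_tracking_task

PMAX = 40.0  # kPa, from the session's maximal-pressure calibration
FS = 50.0

cfg = TrackingTaskConfig()
n = round(cfg.total_s * FS)
t = np.arange(n) / FS

# a participant who hits the band centre with some noise, but only after
# a sluggish start in the first three cycles
rng = np.random.default_rng(0)
target_phase = (t % cfg.cycle_s) >= cfg.rest_s
level = np.where(t < 3 * cfg.cycle_s, 0.025 * PMAX, 0.04 * PMAX)
values = np.where(target_phase, level + rng.normal(0, 0.004 * PMAX, n), 0.0)

trace = PressureTrace(Channel.TONGUE, values, fs=FS)
result = score_tracking_task(trace, cfg, PMAX)

print(f"task score: {result.score_pct:.1f}%")
for c in result.cycles:
    print(f"  cycle {c.cycle_index}: in-band fraction {c.in_band_fraction:.2f}")
print("The score is the mean percentage of scored time spent inside 3-5% of Pmax;")
print("the first cycles are low because the simulated participant undershot the band.")
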