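"""Rewarming after wrap removal: analgesia threshold and baseline return.

Skin analgesia is produced below 13.6 degC. This script generates the
default rewarming trace (exponential return toward the 32.1 degC
baseline with a 50-min time constant from an 11.5 degC minimum) and
reports how long the analgesic window lasts after cessation and when
the skin regains baseline.
"""

import dataclasses

import numpy as np

from cryodepth import GeneratorParams, generate_trace, threshold_crossing_times

params = dataclasses.replace(GeneratorParams(), rewarm_min_C=11.5)

noiseless = dataclasses.replace(params, noise_sd=0.0)
trace = generate_trace(noiseless, seed=1, baseline_C=32.1, end_temp_C=11.5)
c = threshold_crossing_times(trace, threshold_C=13.6, baseline_tolerance_C=0.5)
print("noiseless trace:")
print(f"  treatment time below 13.6 degC: {c.time_below_min:6.1f} min")
print(f"  re-exceeds 13.6 degC after:     {c.reexceed_min:6.1f} min")
print(f"  regains baseline (+/-0.5) after:{c.baseline_return_min:6.1f} min")

reexceed, ret = [], []
for i in range(200):
    tr = generate_trace(params, seed=1000 + i, baseline_C=32.1, end_temp_C=11.5)
    ci = threshold_crossing_times(tr, 13.6, 0.5)
    reexceed.append(ci.reexceed_min)
    ret.append(ci.baseline_return_min)
print("\n200 noisy traces (0.2 degC sensor noise):")
print(f"  mean re-exceed time: {np.mean(reexceed):5.1f} min")
print(f"  mean baseline return: {np.mean(ret):5.1f} min")
print("\nSkin analgesia therefore persists only ~5 min beyond the treatment,"
      "\nwhile full thermal recovery takes about three hours.")
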