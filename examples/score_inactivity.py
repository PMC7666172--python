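"""Score sleep-like inactivity from 12-s movement-count epochs.

Simulates one stressed mouse's day of epoch counts, applies the
two-consecutive-zero-epoch rule, and prints the hourly activity profile
around the post-stress window.
"""

import numpy as np

from stresssleep import hourly_profile, inactivity_mask, window_mean_active
from stresssleep.synthetic import CohortConfig, gen_actigraphy

cfg = CohortConfig()
rng = np.random.default_rng(1)
series, _, truth = gen_actigraphy(cfg, rng, group="stress")

mask = inactivity_mask(series)
profile = hourly_profile(series, mask)

print("ZT hour  % active")
for _, row in profile.bins.iloc[10:20].iterrows():
    print(f"  {row['zt_hour_start']:5.0f}   {row['percent_active']:6.1f}")

active = window_mean_active(profile, 13, 16)
print(f"\nZT 13-15 mean active: {active:.1f}% "
      f"(generator planted {100 * truth['window_active_frac']:.1f}%)")
print("A stressed mouse spends far less of the early dark phase active"
      " than the ~69% typical of unstressed controls: that deficit is the"
      " sleep-like inactivity readout.")
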