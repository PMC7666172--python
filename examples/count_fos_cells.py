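"""Count c-Fos-positive cells with local-background thresholding.

Generates one control and one stressed fluorescence image of a
stress-responsive region (DMH), detects somata brighter than the local
median background with the 9-30 um equivalent-diameter filter, and
compares the counts.
"""

import numpy as np

from stresssleep import detect_spots, hemisphere_average
from stresssleep.synthetic import CohortConfig, gen_fos_images

cfg = CohortConfig()
cfg.imaging.count_jitter = False  # plant the exact per-condition counts
rng = np.random.default_rng(5)

for group in ("control", "stress"):
    left, truth_l = gen_fos_images(cfg, rng, "DMH", group)
    right, truth_r = gen_fos_images(cfg, rng, "DMH", group)
    spots_l, spots_r = detect_spots(left), detect_spots(right)
    rc = hemisphere_average("DMH", f"{group}_mouse", left=spots_l, right=spots_r)
    print(f"{group:8s} DMH: left {spots_l.count} (planted {truth_l['n_in_range']}),"
          f" right {spots_r.count} (planted {truth_r['n_in_range']}),"
          f" hemisphere mean {rc.mean_count:.1f} cells,"
          f" density {rc.mean_density:.1f} /mm^2")

print("Counts double in the stressed condition: the DMH is one of the"
      " sleep-regulatory regions activated by social defeat stress."
      " Undersized (6 um) and oversized (40 um) planted distractors are"
      " rejected by the 9-30 um diameter filter.")
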