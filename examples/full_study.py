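"""Run the complete study pipeline on a synthetic cohort.

Generates the three-group cohort (6 control / 13 stress / 9 stress +
sleep deprivation), runs every analysis stage, and prints the group
summary and the key statistical comparisons.
"""

from stresssleep import generate_cohort, run_full_analysis
from stresssleep.synthetic import CohortConfig

cfg = CohortConfig(seed=7)
cohort = generate_cohort(cfg)
bundle = run_full_analysis(cohort)

df = bundle.group_summary
print("group means +/- SEM")
for metric in ("window_active_pct", "window_temp_c", "pct_interaction",
               "pct_avoidance", "sniff_n_bouts", "sniff_mean_bout_s"):
    parts = []
    for g in ("control", "stress", "stress_sleepdep"):
        row = df[(df["group"] == g) & (df["metric"] == metric)].iloc[0]
        parts.append(f"{g}: {row['mean']:7.2f} +/- {row['sem']:.2f}")
    print(f"  {metric:<20s} " + "   ".join(parts))

print(f"\nsusceptible: {bundle.classification['n_susceptible']}"
      f"/{bundle.classification['n_stressed']} of stressed mice")
print(f"hypothermia outlier: {bundle.extras['hypothermia']}")

print("\nselected comparisons")
wanted = (
    "window_active_pct",
    "window_temp_c (hypothermic excluded)",
    "high_social_interest: control vs stress_sleepdep",
    "sniff_n_bouts: control vs stress",
    "valence (interaction time vs intensity): high_social_interest",
)
for r in bundle.stats_records:
    if r["comparison"] in wanted:
        p = r["adjusted_p"] if r["adjusted_p"] is not None else r["p"]
        print(f"  {r['method']:<14s} {r['comparison']:<55s} p = {p:.4g}")

print("\nThe stressed group shows the post-stress activity and temperature"
      " drop, a ~46% susceptible fraction, fewer sniffing bouts, and the"
      " positive sniffing-intensity/interaction-time coupling confined to"
      " high-social-interest mice.")
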