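"""End-to-end orchestration: stages, per-mouse outcome table, statistics.

``run_full_analysis`` executes the whole analysis chain on a cohort
(generated in memory or loaded from files):

1. actigraphy: inactivity scoring, hourly profiles, ZT-window active %;
2. thermometry: window temperature, activity-temperature regression,
   the leave-one-out prediction-band hypothermia flag, control-vs-stress
   ANCOVA;
3. arena: zone occupancy for habituation and test sessions, travel
   distance, mixed-design (repeated-measures) ANOVA with Sidak follow-ups,
   KS comparisons of the zone-time distributions;
4. susceptibility classification and the high-social-interest set, with
   Fisher exact tests of the high-interest proportions against control;
5. sniffing: bout detection, summaries, manual-annotation validation,
   one-way ANOVA + Tukey on intensity, and the intensity-interaction
   correlation / ANCOVA split by phenotype set;
6. optional c-Fos stage: spot counting, hemisphere averaging, per-region
   unpaired t tests.

Every reported statistic is a stats-module record reproducible by calling
the corresponding operation on the cached outcome table.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .actigraphy import hourly_profile, inactivity_mask, window_mean_active
from .arena import (
    ZoneOccupancy,
    classify_susceptibility,
    compute_zone_occupancy,
    high_social_interest_set,
)
from .sniffing import (
    annotation_totals,
    detect_sniff_bouts,
    nose_mesh_distance,
    summarize_sniffing,
    validate_against_manual,
)
from .stats import (
    ContingencyTable2x2,
    ancova_compare,
    fisher_exact_two_sided,
    ks_two_sample,
    oneway_anova_tukey,
    pearson_test,
    twoway_rm_anova_sidak,
    unpaired_t,
)
from .synthetic import Cohort
from .thermometry import (
    ActivityTempPoint,
    fit_activity_temperature,
    flag_hypothermia_outlier,
    window_mean_temp,
)


@dataclass
class ReportBundle:
    """Joined per-mouse outcomes, group summaries and statistics records."""

    outcomes: pd.DataFrame
    group_summary: pd.DataFrame
    stats_records: list[dict]
    classification: dict
    manifest: dict
    fos_counts: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)

    def content_hash(self) -> str:
        payload = json.dumps(
            {
                "outcomes": self.outcomes.round(9).to_dict("records"),
                "stats": self.stats_records,
                "classification": self.classification,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()


def build_outcomes(cohort: Cohort) -> pd.DataFrame:
    """Per-mouse merged phenotypes: one row per mouse, explicit NaN markers
    for fields that are absent by design (e.g. intensity with zero bouts)."""
    cfg = cohort.config
    arena = cfg.arena()
    mesh = cfg.mesh()
    zt_from, zt_to = cfg.analysis_window
    rows = []
    for m in cohort.mice:
        mask = inactivity_mask(m.activity)
        profile = hourly_profile(m.activity, mask)
        active_pct = window_mean_active(profile, zt_from, zt_to)
        temp_c = window_mean_temp(m.temperature, zt_from, zt_to)

        occ_hab = compute_zone_occupancy(m.habituation, arena, m.mouse_id, m.group)
        occ_test = compute_zone_occupancy(m.test, arena, m.mouse_id, m.group)

        dist = nose_mesh_distance(m.test, mesh, arena)
        bouts = detect_sniff_bouts(dist, m.test.fps)
        summary = summarize_sniffing(bouts)
        manual_total = float(sum(e - s for s, e in m.manual_annotations))

        rows.append(
            {
                "mouse_id": m.mouse_id,
                "group": m.group,
                "window_active_pct": active_pct,
                "window_temp_c": temp_c,
                "hab_pct_interaction": occ_hab.pct_interaction,
                "hab_pct_avoidance": occ_hab.pct_avoidance,
                "hab_distance_cm": occ_hab.distance_cm,
                "pct_interaction": occ_test.pct_interaction,
                "pct_avoidance": occ_test.pct_avoidance,
                "time_interaction_s": occ_test.time_interaction_s,
                "time_avoidance_s": occ_test.time_avoidance_s,
                "distance_cm": occ_test.distance_cm,
                "sniff_total_s": summary.total_time_s,
                "sniff_n_bouts": summary.n_bouts,
                "sniff_mean_bout_s": (
                    summary.mean_bout_duration_s
                    if summary.mean_bout_duration_s is not None
                    else np.nan
                ),
                "manual_sniff_total_s": manual_total,
            }
        )
    return pd.DataFrame(rows)


def _occ_from_row(row: pd.Series, which: str = "test") -> ZoneOccupancy:
    pre = "" if which == "test" else "hab_"
    dur = 1.0  # percentages already computed; times rescaled to a unit session
    return ZoneOccupancy(
        mouse_id=row["mouse_id"],
        group=row["group"],
        time_interaction_s=row[f"{pre}pct_interaction"] / 100.0,
        time_avoidance_s=row[f"{pre}pct_avoidance"] / 100.0,
        distance_cm=row.get(f"{pre}distance_cm", 0.0),
        duration_s=dur,
        session_kind=which,
    )


def run_full_analysis(
    cohort: Cohort, include_fos: bool = True, alpha: float = 0.05
) -> ReportBundle:
    cfg = cohort.config
    outcomes = build_outcomes(cohort)
    records: list[dict] = []
    extras: dict = {}
    groups_present = [g for g in ("control", "stress", "stress_sleepdep")
                      if (outcomes["group"] == g).any()]

    def vals(col: str, group: str) -> np.ndarray:
        v = outcomes.loc[outcomes["group"] == group, col].to_numpy(dtype=float)
        return v[~np.isnan(v)]

    # --- 1. sleep-like inactivity in the ZT window -------------------------
    omni, pairs = oneway_anova_tukey(
        [vals("window_active_pct", g) for g in groups_present], groups_present
    )
    omni.comparison = "window_active_pct"
    records.append(omni.to_record())
    for p in pairs:
        p.comparison = "window_active_pct: " + p.comparison
        records.append(p.to_record())

    # --- 2. temperature: outlier flag, regression, ANCOVA ------------------
    points = [
        ActivityTempPoint(
            mouse_id=r["mouse_id"],
            mean_active_pct=r["window_active_pct"],
            mean_temp_c=r["window_temp_c"],
            group=r["group"],
        )
        for _, r in outcomes.iterrows()
        if r["group"] in ("control", "stress")
    ]
    stress_points = [p for p in points if p.group == "stress"]
    flagged_id = None
    if len(stress_points) >= 2 and len(points) >= 5:
        candidate = min(stress_points, key=lambda p: p.mean_temp_c)
        flagged, diag = flag_hypothermia_outlier(points, candidate.mouse_id)
        if flagged:
            flagged_id = candidate.mouse_id
        extras["hypothermia"] = {
            "candidate": candidate.mouse_id,
            "flagged": flagged,
            "candidate_temp_c": diag["candidate_temp_c"],
            "pi95_lower": diag["pi95"][0],
        }
    outcomes["hypothermia_flag"] = outcomes["mouse_id"] == flagged_id
    kept = outcomes[~outcomes["hypothermia_flag"]]

    omni, pairs = oneway_anova_tukey(
        [
            kept.loc[kept["group"] == g, "window_temp_c"].to_numpy(dtype=float)
            for g in groups_present
        ],
        groups_present,
    )
    omni.comparison = "window_temp_c (hypothermic excluded)"
    records.append(omni.to_record())
    for p in pairs:
        p.comparison = "window_temp_c: " + p.comparison
        records.append(p.to_record())

    ancova_groups = []
    for g in ("control", "stress"):
        sub = kept[kept["group"] == g]
        if len(sub) >= 3:
            x = sub["window_active_pct"].to_numpy(dtype=float)
            y = sub["window_temp_c"].to_numpy(dtype=float)
            fit = fit_activity_temperature(
                [
                    ActivityTempPoint(m, a, t, g)
                    for m, a, t in zip(sub["mouse_id"], x, y)
                ]
            )
            records.append(
                {
                    "method": "pearson_regression",
                    "comparison": f"activity_vs_temp: {g}",
                    "statistic": fit.r,
                    "df": fit.n - 2,
                    "p": fit.p_r,
                    "adjusted_p": None,
                    "n": [fit.n],
                    "degenerate": False,
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                }
            )
            ancova_groups.append((x, y))
    if len(ancova_groups) == 2:
        anc = ancova_compare(ancova_groups, alpha=alpha)
        records.append(
            {
                "method": "ancova",
                "comparison": "activity_vs_temp: control vs stress",
                "statistic": anc.f_slope,
                "df": None,
                "p": anc.p_slope_equal,
                "adjusted_p": None,
                "n": [len(x) for x, _ in ancova_groups],
                "degenerate": anc.degenerate,
                "p_intercept": anc.p_intercept_equal,
                "common_slope": anc.common_slope,
            }
        )

    # --- 3. zone occupancy: RM ANOVA + Sidak, KS ---------------------------
    for metric, hab_col, test_col in (
        ("pct_avoidance", "hab_pct_avoidance", "pct_avoidance"),
        ("pct_interaction", "hab_pct_interaction", "pct_interaction"),
        ("distance_cm", "hab_distance_cm", "distance_cm"),
    ):
        values = outcomes[[hab_col, test_col]].to_numpy(dtype=float)
        glabels = outcomes["group"].tolist()
        for comparisons in ("within", "between"):
            omnibus, follow = twoway_rm_anova_sidak(
                values, glabels, ("target_absent", "target_present"), comparisons
            )
            if comparisons == "within":
                for o in omnibus:
                    o.comparison = f"{metric}: {o.comparison}"
                    records.append(o.to_record())
            for f in follow:
                f.comparison = f"{metric}: {f.comparison}"
                records.append(f.to_record())

    for col in ("pct_avoidance", "pct_interaction"):
        for g in groups_present[1:]:
            res = ks_two_sample(vals(col, "control"), vals(col, g))
            res.comparison = f"{col} ECDF: control vs {g}"
            records.append(res.to_record())

    # --- 4. susceptibility and high-social-interest ------------------------
    controls = [
        _occ_from_row(r) for _, r in outcomes[outcomes["group"] == "control"].iterrows()
    ]
    stressed = [
        _occ_from_row(r) for _, r in outcomes[outcomes["group"] == "stress"].iterrows()
    ]
    all_occ = [_occ_from_row(r) for _, r in outcomes.iterrows()]
    labels = classify_susceptibility(stressed, controls)
    label_map = {l.mouse_id: l.label for l in labels}
    outcomes["susceptibility"] = [
        label_map.get(m, "control" if g == "control" else "")
        for m, g in zip(outcomes["mouse_id"], outcomes["group"])
    ]
    n_susceptible = sum(1 for l in labels if l.label == "susceptible")
    membership, proportions = high_social_interest_set(all_occ, controls)
    outcomes["high_social_interest"] = outcomes["mouse_id"].map(membership)
    classification = {
        "labels": label_map,
        "n_susceptible": n_susceptible,
        "n_stressed": len(stressed),
        "susceptible_fraction": n_susceptible / len(stressed) if stressed else np.nan,
        "high_interest_proportion": proportions,
    }
    by_group_counts = {
        g: (
            int(outcomes.loc[outcomes["group"] == g, "high_social_interest"].sum()),
            int((outcomes["group"] == g).sum()),
        )
        for g in groups_present
    }
    for g in groups_present[1:]:
        hi_c, n_c = by_group_counts["control"]
        hi_g, n_g = by_group_counts[g]
        res = fisher_exact_two_sided(
            ContingencyTable2x2(hi_c, n_c - hi_c, hi_g, n_g - hi_g)
        )
        res.comparison = f"high_social_interest: control vs {g}"
        records.append(res.to_record())

    # --- 5. sniffing --------------------------------------------------------
    with_bouts = outcomes[outcomes["sniff_n_bouts"] > 0]
    intensity_groups = [
        with_bouts.loc[with_bouts["group"] == g, "sniff_mean_bout_s"].to_numpy(dtype=float)
        for g in groups_present
    ]
    if all(len(g) >= 2 for g in intensity_groups):
        omni, pairs = oneway_anova_tukey(intensity_groups, groups_present)
        omni.comparison = "sniff_mean_bout_s"
        records.append(omni.to_record())
        for p in pairs:
            p.comparison = "sniff_mean_bout_s: " + p.comparison
            records.append(p.to_record())
    omni, pairs = oneway_anova_tukey(
        [vals("manual_sniff_total_s", g) for g in groups_present], groups_present
    )
    omni.comparison = "manual_sniff_total_s"
    records.append(omni.to_record())
    for p in pairs:
        p.comparison = "manual_sniff_total_s: " + p.comparison
        records.append(p.to_record())
    if "stress" in groups_present:
        res = unpaired_t(vals("sniff_n_bouts", "control"), vals("sniff_n_bouts", "stress"))
        res.comparison = "sniff_n_bouts: control vs stress"
        records.append(res.to_record())

    for g in groups_present:
        sub = outcomes[outcomes["group"] == g]
        if len(sub) >= 3:
            fit = validate_against_manual(
                dict(zip(sub["mouse_id"], sub["sniff_total_s"])),
                dict(zip(sub["mouse_id"], sub["manual_sniff_total_s"])),
            )
            records.append(
                {
                    "method": "pearson_regression",
                    "comparison": f"auto_vs_manual_sniffing: {g}",
                    "statistic": fit.r,
                    "df": fit.n - 2,
                    "p": fit.p_r,
                    "adjusted_p": None,
                    "n": [fit.n],
                    "degenerate": False,
                    "slope": fit.slope,
                }
            )

    # valence: intensity vs interaction time in the high-interest set
    hi_set = outcomes[
        outcomes["high_social_interest"]
        & outcomes["group"].isin(["control", "stress"])
        & (outcomes["sniff_n_bouts"] > 0)
    ]
    susceptible = outcomes[
        (outcomes["susceptibility"] == "susceptible") & (outcomes["sniff_n_bouts"] > 0)
    ]
    valence_sets = {"high_social_interest": hi_set}
    if "stress_sleepdep" in groups_present:
        valence_sets["stress_sleepdep"] = outcomes[
            (outcomes["group"] == "stress_sleepdep") & (outcomes["sniff_n_bouts"] > 0)
        ]
    for name, sub in valence_sets.items():
        if len(sub) >= 3:
            res = pearson_test(
                sub["time_interaction_s"].to_numpy(dtype=float),
                sub["sniff_mean_bout_s"].to_numpy(dtype=float),
            )
            res.comparison = f"valence (interaction time vs intensity): {name}"
            records.append(res.to_record())
    if len(hi_set) >= 3 and len(susceptible) >= 3:
        anc = ancova_compare(
            [
                (
                    hi_set["time_interaction_s"].to_numpy(dtype=float),
                    hi_set["sniff_mean_bout_s"].to_numpy(dtype=float),
                ),
                (
                    susceptible["time_interaction_s"].to_numpy(dtype=float),
                    susceptible["sniff_mean_bout_s"].to_numpy(dtype=float),
                ),
            ],
            alpha=alpha,
        )
        records.append(
            {
                "method": "ancova",
                "comparison": "valence: high_social_interest vs susceptible",
                "statistic": anc.f_slope,
                "df": None,
                "p": anc.p_slope_equal,
                "adjusted_p": None,
                "n": [len(hi_set), len(susceptible)],
                "degenerate": anc.degenerate,
                "p_intercept": anc.p_intercept_equal,
            }
        )

    # --- 6. c-Fos ------------------------------------------------------------
    fos_df = None
    if include_fos and cohort.fos_images:
        from .fos import compare_groups, detect_spots, hemisphere_average

        per_mouse: dict = {}
        for (group, mid, region, hemi), img in cohort.fos_images.items():
            spots = detect_spots(img)
            per_mouse.setdefault((group, mid, region), {})[hemi] = spots
        fos_rows = []
        counts_by_group: dict = {}
        for (group, mid, region), hemis in per_mouse.items():
            rc = hemisphere_average(
                region, mid, left=hemis.get("left"), right=hemis.get("right")
            )
            fos_rows.append(
                {
                    "group": group,
                    "mouse_id": mid,
                    "region": region,
                    "mean_count": rc.mean_count,
                    "mean_density_mm2": rc.mean_density,
                    "single_hemisphere": rc.single_hemisphere,
                }
            )
            counts_by_group.setdefault(group, {}).setdefault(region, []).append(
                rc.mean_count
            )
        fos_df = pd.DataFrame(fos_rows)
        if len(counts_by_group) == 2:
            for res in compare_groups(counts_by_group):
                res.comparison = "fos " + res.comparison
                records.append(res.to_record())

    # --- summary -------------------------------------------------------------
    metric_cols = [
        c
        for c in outcomes.columns
        if c
        not in ("mouse_id", "group", "susceptibility", "high_social_interest", "hypothermia_flag")
    ]
    summary_rows = []
    for g in groups_present:
        sub = outcomes[outcomes["group"] == g]
        for c in metric_cols:
            v = sub[c].to_numpy(dtype=float)
            v = v[~np.isnan(v)]
            summary_rows.append(
                {
                    "group": g,
                    "metric": c,
                    "mean": float(np.mean(v)) if len(v) else np.nan,
                    "sem": float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan,
                    "sd": float(np.std(v, ddof=1)) if len(v) > 1 else np.nan,
                    "n": int(len(v)),
                }
            )
    group_summary = pd.DataFrame(summary_rows)
    manifest = {
        "package": "stresssleep",
        "version": __version__,
        "seed": cfg.seed,
        "analysis_window_zt": list(cfg.analysis_window),
        "config_hash": hashlib.sha256(
            json.dumps(str(cfg), sort_keys=True).encode()
        ).hexdigest()[:16],
    }
    return ReportBundle(
        outcomes=outcomes,
        group_summary=group_summary,
        stats_records=records,
        classification=classification,
        manifest=manifest,
        fos_counts=fos_df,
        extras=extras,
    )


def export_report(
    bundle: ReportBundle, outdir: str | Path, plots: bool = False
) -> list[Path]:
    """Write the report as CSV tables + JSON stats records (+ plots)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in (
        ("outcomes.csv", bundle.outcomes),
        ("group_summary.csv", bundle.group_summary),
    ):
        df.to_csv(out / name, index=False)
        written.append(out / name)
    (out / "stats.json").write_text(
        json.dumps(bundle.stats_records, indent=1, default=str)
    )
    written.append(out / "stats.json")
    (out / "classification.json").write_text(
        json.dumps(bundle.classification, indent=1, default=str)
    )
    written.append(out / "classification.json")
    (out / "manifest.json").write_text(json.dumps(bundle.manifest, indent=1))
    written.append(out / "manifest.json")
    if bundle.fos_counts is not None:
        bundle.fos_counts.to_csv(out / "fos_counts.csv", index=False)
        written.append(out / "fos_counts.csv")
    if plots:
        written += _write_plots(bundle, out)
    return written


def _write_plots(bundle: ReportBundle, out: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .thermometry import fit_xy

    written = []
    df = bundle.outcomes
    fig, ax = plt.subplots(figsize=(5, 4))
    for g, color in (("control", "tab:blue"), ("stress", "tab:red")):
        sub = df[(df["group"] == g) & ~df["hypothermia_flag"]]
        if len(sub) < 3:
            continue
        x = sub["window_active_pct"].to_numpy(dtype=float)
        y = sub["window_temp_c"].to_numpy(dtype=float)
        ax.scatter(x, y, s=18, color=color, label=g)
        fit = fit_xy(x, y)
        xs = np.linspace(x.min(), x.max(), 50)
        lo, hi = fit.ci95_band(xs)
        ax.plot(xs, fit.predict(xs), color=color)
        ax.plot(xs, lo, ls=":", color=color)
        ax.plot(xs, hi, ls=":", color=color)
    flagged = df[df["hypothermia_flag"]]
    if len(flagged):
        ax.scatter(
            flagged["window_active_pct"],
            flagged["window_temp_c"],
            marker="v",
            color="k",
            label="hypothermic",
        )
    ax.set_xlabel("active periods in window (%)")
    ax.set_ylabel("core body temperature (degC)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    p = out / "activity_temperature.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    fig, ax = plt.subplots(1, 2, figsize=(8, 3.5))
    for i, col in enumerate(("pct_avoidance", "pct_interaction")):
        for g in df["group"].unique():
            v = np.sort(df.loc[df["group"] == g, col].to_numpy(dtype=float))
            ax[i].step(v, np.arange(1, len(v) + 1) / len(v), where="post", label=g)
        ax[i].set_xlabel(col)
        ax[i].set_ylabel("cumulative fraction")
    ax[0].legend(fontsize=7)
    fig.tight_layout()
    p = out / "zone_ecdf.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)
    return written
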