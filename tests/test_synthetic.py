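"""The cohort generator: determinism, planted-truth consistency, and
agreement between generated data and the consuming modules."""

import numpy as np
import pytest

from stresssleep.actigraphy import (
    hourly_profile,
    inactivity_mask,
    window_mean_active,
)
from stresssleep.arena import compute_zone_occupancy
from stresssleep.sniffing import detect_sniff_bouts, nose_mesh_distance
from stresssleep.synthetic import (
    CohortConfig,
    _simulate_states,
    gen_actigraphy,
    gen_fos_images,
    gen_social_session,
    generate_cohort,
)


class TestDeterminism:
    def test_identical_seed_identical_cohort(self):
        cfg = CohortConfig(seed=7)
        a = generate_cohort(cfg, include_imaging=False)
        b = generate_cohort(cfg, include_imaging=False)
        for ma, mb in zip(a.mice, b.mice):
            assert np.array_equal(ma.activity.counts, mb.activity.counts)
            assert np.array_equal(ma.temperature.temps_c, mb.temperature.temps_c)
            for part in ma.test.parts:
                assert np.array_equal(ma.test.parts[part], mb.test.parts[part])
            assert ma.truth == mb.truth

    def test_different_seed_differs(self):
        a = generate_cohort(CohortConfig(seed=1), include_imaging=False)
        b = generate_cohort(CohortConfig(seed=2), include_imaging=False)
        assert not np.array_equal(a.mice[0].activity.counts, b.mice[0].activity.counts)


class TestActigraphyGeneration:
    def test_fully_active_has_no_inactive_epochs(self, rng):
        states = _simulate_states(rng, 1200, 1.0)
        assert states.all()

    def test_fully_inactive_all_zero(self, rng):
        states = _simulate_states(rng, 1200, 0.0)
        assert not states.any()

    def test_planted_inactive_runs_always_scorable(self, rng):
        # every inactive run must be >= 2 epochs so the scoring rule sees it
        states = _simulate_states(rng, 5000, 0.5)
        flips = np.flatnonzero(np.diff(states.astype(int)))
        bounds = np.concatenate([[0], flips + 1, [len(states)]])
        for s, e in zip(bounds[:-1], bounds[1:]):
            if not states[s]:
                if s == 0 or e == len(states):
                    continue  # runs cut by the segment edge may be shorter
                assert e - s >= 2

    def test_window_mean_centred_on_planted_fraction(self):
        cfg = CohortConfig()
        rng = np.random.default_rng(3)
        errs = []
        for _ in range(60):
            series, _, truth = gen_actigraphy(cfg, rng, "stress")
            mask = inactivity_mask(series)
            prof = hourly_profile(series, mask)
            got = window_mean_active(prof, *cfg.analysis_window)
            errs.append(got - 100 * truth["window_active_frac"])
        errs = np.array(errs)
        sem = errs.std(ddof=1) / np.sqrt(len(errs))
        assert abs(errs.mean()) < 2 * sem + 0.3

    def test_nocturnal_structure(self):
        cfg = CohortConfig()
        rng = np.random.default_rng(4)
        series, _, _ = gen_actigraphy(cfg, rng, "control")
        mask = inactivity_mask(series)
        prof = hourly_profile(series, mask)
        light = window_mean_active(prof, 0, 12)
        dark = window_mean_active(prof, 12, 24)
        assert dark > light

    def test_hypothermic_trajectory_reaches_trough(self):
        cfg = CohortConfig()
        rng = np.random.default_rng(5)
        _, temps, truth = gen_actigraphy(cfg, rng, "stress", hypothermic=True)
        trough_region = temps.temps_c[(temps.sample_zt > 16) & (temps.sample_zt < 18)]
        assert trough_region.min() == pytest.approx(cfg.hypothermia.trough_c, abs=0.6)
        # recovery: end of day near normal
        assert temps.temps_c[-30:].mean() > 35.5


class TestSocialSessions:
    def test_occupancy_matches_planted_targets(self, cfg):
        rng = np.random.default_rng(6)
        arena = cfg.arena()
        for phenotype in ("control", "resilient", "susceptible"):
            session, _, truth = gen_social_session(cfg, rng, phenotype, "test")
            occ = compute_zone_occupancy(session, arena)
            n = truth["n_frames"]
            assert occ.time_interaction_s * session.fps == pytest.approx(
                truth["realized_frames_interaction"], abs=1.0
            )
            assert occ.time_avoidance_s * session.fps == pytest.approx(
                truth["realized_frames_avoidance"], abs=1.0
            )

    def test_detector_recovers_planted_bouts(self, cfg):
        rng = np.random.default_rng(8)
        arena, mesh = cfg.arena(), cfg.mesh()
        for _ in range(5):
            session, _, truth = gen_social_session(cfg, rng, "control", "test")
            d = nose_mesh_distance(session, mesh, arena)
            bouts = detect_sniff_bouts(d, session.fps)
            assert len(bouts) == len(truth["bouts"])
            for got, planted in zip(bouts, truth["bouts"]):
                assert got.start_s == pytest.approx(planted["start_s"], abs=1e-6)
                assert got.duration_s == pytest.approx(planted["duration_s"], abs=1e-6)

    def test_short_approaches_rejected_by_detector(self, cfg):
        import dataclasses

        rng = np.random.default_rng(9)
        ph = dataclasses.replace(cfg.social.phenotypes["control"], bout_rate=0.0)
        cfg.social.phenotypes["control"] = ph
        arena, mesh = cfg.arena(), cfg.mesh()
        session, _, truth = gen_social_session(cfg, rng, "control", "test")
        assert truth["bouts"] == []
        assert truth["n_short_approaches"] > 0
        d = nose_mesh_distance(session, mesh, arena)
        assert detect_sniff_bouts(d, session.fps) == []

    def test_habituation_has_no_bouts_and_neutral_zones(self, cfg):
        rng = np.random.default_rng(10)
        session, ann, truth = gen_social_session(cfg, rng, "susceptible", "habituation")
        assert truth["bouts"] == []
        assert ann["intervals"] == []
        assert abs(truth["target_pct_interaction"] - truth["target_pct_avoidance"]) < 40

    def test_annotations_track_true_bouts(self, cfg):
        rng = np.random.default_rng(11)
        session, ann, truth = gen_social_session(cfg, rng, "control", "test")
        total_true = sum(b["duration_s"] for b in truth["bouts"])
        total_ann = sum(e - s for s, e in ann["intervals"])
        assert total_ann == pytest.approx(total_true, abs=0.15 * max(total_true, 1.0))

    def test_unknown_phenotype_raises(self, cfg):
        with pytest.raises(ValueError):
            gen_social_session(cfg, np.random.default_rng(0), "ghost")


class TestFosGeneration:
    def test_zero_spots_blank_image(self, cfg, rng):
        img, truth = gen_fos_images(cfg, rng, "DMH", "control", n_spots=0)
        assert truth["n_in_range"] == 0
        in_range = [s for s in truth["spots"] if s["in_range"]]
        assert in_range == []

    def test_requested_count_planted_exactly(self, cfg, rng):
        img, truth = gen_fos_images(cfg, rng, "DMH", "control", n_spots=25)
        in_range = [s for s in truth["spots"] if s["in_range"]]
        assert len(in_range) == 25
        img2, truth2 = gen_fos_images(cfg, rng, "DMH", "control", n_spots=50)
        assert len([s for s in truth2["spots"] if s["in_range"]]) == 50

    def test_stress_regions_scaled(self, cfg):
        base = cfg.imaging.region_base_counts["DMH"]
        cfg.imaging.count_jitter = False
        rng = np.random.default_rng(12)
        _, t_ctrl = gen_fos_images(cfg, rng, "DMH", "control")
        _, t_str = gen_fos_images(cfg, rng, "DMH", "stress")
        assert t_ctrl["n_in_range"] == base
        assert t_str["n_in_range"] == int(base * cfg.imaging.stress_multiplier)

    def test_impossible_placement_raises(self, cfg, rng):
        with pytest.raises(RuntimeError):
            gen_fos_images(cfg, rng, "DMH", "control", n_spots=5000)


class TestCohortAssembly:
    def test_group_sizes_and_phenotype_split(self, small_cohort):
        cfg = small_cohort.config
        groups = [m.group for m in small_cohort.mice]
        assert groups.count("control") == cfg.n_control
        assert groups.count("stress") == cfg.n_stress
        assert groups.count("stress_sleepdep") == cfg.n_stress_sleepdep
        stress_ph = [m.phenotype for m in small_cohort.mice if m.group == "stress"]
        assert stress_ph.count("susceptible") == cfg.n_susceptible
        assert stress_ph.count("resilient") == cfg.n_stress - cfg.n_susceptible

    def test_exactly_one_hypothermic_stress_mouse(self, small_cohort):
        hid = small_cohort.truth["hypothermic_mouse"]
        assert hid is not None
        mouse = next(m for m in small_cohort.mice if m.mouse_id == hid)
        assert mouse.group == "stress"
        flags = [
            m.truth["actigraphy"]["hypothermic"] for m in small_cohort.mice
        ]
        assert sum(flags) == 1

    def test_truth_serializes(self, small_cohort, tmp_path):
        import json

        p = tmp_path / "truth.json"
        small_cohort.save_truth(p)
        loaded = json.loads(p.read_text())
        assert set(loaded["mice"]) == {m.mouse_id for m in small_cohort.mice}
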