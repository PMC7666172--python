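"""Synthetic cohort generator with recorded ground truth.

Emulates every input modality the pipeline consumes — 12-s epoch activity
counts, per-minute body temperature, pose-tracked social-interaction
sessions with manual sniffing annotations, and fluorescence images with
planted somata — for a three-group study design (control / stress /
stress + sleep deprivation, default sizes 6/13/9).

The defaults are calibrated to the study conditions this pipeline targets:

* dark-phase active fraction 0.694 and a stressed ZT 13-15 active fraction
  of 0.401, with a between-mouse SD of 0.12 (back-computed from the group
  SEMs at n = 6 and n = 13);
* temperature coupling Tb = 35.86 + 2.32 x (active fraction) degC, which
  places the two group means at 37.47 and 36.79 degC, with 0.25 degC
  between-mouse residual SD and AR(1) minute noise;
* an optional severely hypothermic stressed mouse whose temperature dips
  to 31.1 degC at ZT 17 and recovers within the day;
* a susceptible : resilient split of 6 : 7 among stressed mice and a
  2 : 7 high- : low-social-interest split after sleep deprivation, with
  zone-occupancy phenotypes separated by many control-SDs (the phenotype
  distributions in the target study did not overlap);
* sniffing-bout rates of about 15 (control) vs 8 (stress) bouts per
  session, with mean bout duration positively coupled to interaction time
  (r ~ 0.7) in high-social-interest phenotypes and uncoupled in
  susceptible mice.

Activity is a two-state semi-Markov chain over 12-s epochs.  Inactive
dwell times are 2 + geometric epochs, so every planted inactive run is
long enough for the >= 2-epoch scoring rule and the planted active
fraction equals the expected scored active fraction.  Social trajectories
are built from a zone-visit schedule that realises the drawn occupancy
targets exactly (up to frame quantisation), so ground truth and pipeline
output are directly comparable.

Every generated cohort carries its ground truth; recovery tests read
truth only from there.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .actigraphy import EPOCHS_PER_HOUR, EpochActivitySeries
from .arena import ArenaGeometry, TrackedSession
from .fos import FluorescenceImage
from .sniffing import MeshSegment
from .thermometry import TemperatureSeries

GROUPS = ("control", "stress", "stress_sleepdep")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class ActigraphyParams:
    """Two-state semi-Markov epoch model, per ZT phase."""

    light_active_frac: float = 0.30
    dark_active_frac: float = 0.694
    stress_window_active_frac: float = 0.401
    between_mouse_sd: float = 0.12
    light_between_mouse_sd: float = 0.03
    mean_inactive_epochs: float = 4.0  # dwell mean; minimum run is 2 epochs
    count_rate: float = 8.0  # mean movement count in an active epoch
    stress_effect_window: tuple[float, float] = (12.0, 16.0)
    sleepdep_window: tuple[float, float] = (12.0, 18.0)
    sleepdep_active_frac: float = 0.95


@dataclass
class TemperatureParams:
    """Linear activity coupling plus AR(1) minute noise."""

    beta0_c: float = 35.86
    beta1_c_per_frac: float = 2.32  # degC per unit active fraction
    mouse_offset_sd_c: float = 0.25
    ar1_sigma_c: float = 0.08
    ar1_rho: float = 0.8
    stress_bump_c: float = 1.0  # transient rise during the ZT 11-12 session
    bump_zt: float = 11.75
    bump_sigma_h: float = 0.15


@dataclass
class HypothermiaParams:
    enabled: bool = True
    trough_c: float = 31.1
    trough_zt: float = 17.0
    trough_sigma_h: float = 2.0


@dataclass
class SocialPhenotype:
    """Zone-occupancy targets (percent of session) and sniffing structure."""

    inter_mean_pct: float
    inter_sd_pct: float
    avoid_mean_pct: float
    avoid_sd_pct: float
    bout_rate: float  # Poisson mean bouts per session
    bout_base_s: float  # d0 in mean duration = d0 + coupling * t_inter
    bout_coupling_s_per_s: float
    bout_mouse_sd_s: float = 0.15
    bout_lognorm_sigma: float = 0.25
    speed_scale: float = 1.0


def _default_phenotypes() -> dict[str, SocialPhenotype]:
    return {
        "control": SocialPhenotype(45, 3, 26, 3, 15.33, 0.2, 0.03),
        "resilient": SocialPhenotype(55, 2, 18, 2, 11.0, 0.2, 0.03),
        "susceptible": SocialPhenotype(8, 2, 62, 3, 5.5, 2.0, 0.0, 0.25),
        "sleepdep_social": SocialPhenotype(50, 3, 22, 3, 13.0, 0.0, 0.02, 0.15, 0.25, 1.5),
        "sleepdep_avoidant": SocialPhenotype(28, 4, 40, 5, 12.0, 0.0, 0.02, 0.15, 0.25, 1.5),
    }


@dataclass
class SocialParams:
    fps: float = 30.0
    session_s: float = 150.0
    px_per_cm: float = 10.0
    mesh_span_cm: tuple[float, float] = (10.0, 20.0)  # x extent of the mesh face
    habituation_zone_pct: float = 33.0  # neutral occupancy, target absent
    annotation_jitter_sd_s: float = 0.05
    n_short_approaches: int = 2  # sub-500 ms approaches the detector must reject
    phenotypes: dict[str, SocialPhenotype] = field(default_factory=_default_phenotypes)


def _default_region_counts() -> dict[str, int]:
    return {
        "VLPO": 20, "MnPO": 20, "MS": 15, "LH": 15,
        "LDT": 12, "DMH": 18, "VLPAG": 14,
    }


@dataclass
class ImagingParams:
    image_shape: tuple[int, int] = (256, 256)
    um_per_px: float = 2.0
    background_level: float = 100.0
    noise_sd: float = 4.0
    gradient_amplitude: float = 10.0
    contrast: float = 10.0  # spot amplitude in units of noise_sd
    diameter_range_um: tuple[float, float] = (12.0, 24.0)
    n_undersize: int = 2  # planted 6 um distractors (below the 9 um bound)
    n_oversize: int = 2  # planted 40 um distractors (above the 30 um bound)
    region_base_counts: dict[str, int] = field(default_factory=_default_region_counts)
    stress_multiplier: float = 2.0
    stress_regions: tuple[str, ...] = ("DMH", "VLPAG")
    count_jitter: bool = True  # Poisson-draw the planted count per image
    mice_per_group: int = 4


@dataclass
class CohortConfig:
    """Everything the generator needs; defaults are the study conditions."""

    seed: int = 0
    n_control: int = 6
    n_stress: int = 13
    n_stress_sleepdep: int = 9
    n_susceptible: int = 6  # of n_stress
    n_sleepdep_social: int = 2  # of n_stress_sleepdep
    analysis_window: tuple[float, float] = (13.0, 16.0)  # ZT bins 13, 14, 15
    actigraphy: ActigraphyParams = field(default_factory=ActigraphyParams)
    temperature: TemperatureParams = field(default_factory=TemperatureParams)
    hypothermia: HypothermiaParams = field(default_factory=HypothermiaParams)
    social: SocialParams = field(default_factory=SocialParams)
    imaging: ImagingParams = field(default_factory=ImagingParams)

    def arena(self) -> ArenaGeometry:
        return ArenaGeometry(px_per_cm=self.social.px_per_cm)

    def mesh(self) -> MeshSegment:
        (x1, x2) = self.social.mesh_span_cm
        return MeshSegment((x1, 0.0), (x2, 0.0))


# ---------------------------------------------------------------------------
# actigraphy + temperature
# ---------------------------------------------------------------------------


def _simulate_states(
    rng: np.random.Generator, n_epochs: int, f: float, mean_inactive: float = 4.0
) -> np.ndarray:
    """Alternating active/inactive runs targeting active fraction f.

    Inactive runs are 2 + geometric with overall mean ``mean_inactive``
    epochs (so every run is scorable by the >= 2-epoch rule); the active
    dwell mean is set so the stationary active fraction equals f.  A
    burn-in is discarded so segments start near stationarity.
    """
    if f >= 0.995:
        return np.ones(n_epochs, dtype=bool)
    if f <= 0.005:
        return np.zeros(n_epochs, dtype=bool)
    li = max(mean_inactive, 2.0)
    la = f * li / (1.0 - f)
    if la < 1.0:
        la = 1.0
        li = (1.0 - f) / f
    burn = 100
    total = n_epochs + burn
    active_first = bool(rng.random() < f)
    p_active = min(1.0, 1.0 / la)
    # extra = geometric(p) - 1 on {0, 1, ...} has mean 1/p - 1 = li - 2
    p_extra_i = 1.0 / (li - 1.0) if li > 2.0 else None
    chunks: list[np.ndarray] = []
    length = 0
    batch = max(16, int(total / ((la + li) / 2.0)) + 16)
    while length < total:
        a_runs = rng.geometric(p_active, size=batch)
        if p_extra_i is not None:
            i_runs = 1 + rng.geometric(p_extra_i, size=batch)  # = 2 + (geom - 1)
        else:
            i_runs = np.full(batch, 2)
        runs = np.empty(2 * batch, dtype=np.int64)
        states = np.empty(2 * batch, dtype=bool)
        first, second = (a_runs, i_runs) if active_first else (i_runs, a_runs)
        runs[0::2], runs[1::2] = first, second
        states[0::2], states[1::2] = active_first, not active_first
        chunk = np.repeat(states, runs)  # pairs keep the alternation phase
        chunks.append(chunk)
        length += len(chunk)
    out = np.concatenate(chunks)[:total]
    return out[burn:]


def _segments_for_group(
    cfg: CohortConfig, rng: np.random.Generator, group: str
) -> tuple[list[tuple[float, float, float]], float]:
    """(zt_from, zt_to, active_frac) segments for one mouse's stress day.

    Returns the segment list and the planted active fraction of the
    analysis window.
    """
    a = cfg.actigraphy
    f_light = float(np.clip(rng.normal(a.light_active_frac, a.light_between_mouse_sd), 0.02, 0.98))
    f_dark = float(np.clip(rng.normal(a.dark_active_frac, a.between_mouse_sd), 0.02, 0.98))
    if group == "control":
        segs = [(0.0, 12.0, f_light), (12.0, 24.0, f_dark)]
        window_f = f_dark
    elif group == "stress":
        w0, w1 = a.stress_effect_window
        f_win = float(np.clip(rng.normal(a.stress_window_active_frac, a.between_mouse_sd), 0.02, 0.98))
        segs = [(0.0, 12.0, f_light), (w0, w1, f_win), (w1, 24.0, f_dark)]
        window_f = f_win
    elif group == "stress_sleepdep":
        s0, s1 = a.sleepdep_window
        segs = [(0.0, 12.0, f_light), (s0, s1, a.sleepdep_active_frac), (s1, 24.0, f_dark)]
        window_f = a.sleepdep_active_frac
    else:
        raise ValueError(f"unknown group {group!r}")
    return segs, window_f


def gen_actigraphy(
    cfg: CohortConfig,
    rng: np.random.Generator,
    group: str,
    hypothermic: bool = False,
) -> tuple[EpochActivitySeries, TemperatureSeries, dict]:
    """One stress-day of epoch counts and minute temperatures for one mouse.

    Temperature couples to the *realised* hourly active fraction, so the
    per-mouse (window active %, window Tb) pair scatters around the
    configured line with the configured residual SD.
    """
    a, tp = cfg.actigraphy, cfg.temperature
    segs, window_f = _segments_for_group(cfg, rng, group)
    states = np.zeros(24 * EPOCHS_PER_HOUR, dtype=bool)
    for z0, z1, f in segs:
        i0, i1 = int(z0 * EPOCHS_PER_HOUR), int(z1 * EPOCHS_PER_HOUR)
        states[i0:i1] = _simulate_states(rng, i1 - i0, f, a.mean_inactive_epochs)
    counts = np.zeros(len(states), dtype=int)
    n_active = int(states.sum())
    counts[states] = 1 + rng.poisson(max(a.count_rate - 1.0, 0.0), size=n_active)
    series = EpochActivitySeries(counts=counts, start_zt=0.0)

    hourly_frac = states.reshape(24, EPOCHS_PER_HOUR).mean(axis=1)
    minutes = np.arange(24 * 60)
    zt_min = minutes / 60.0
    hour_idx = np.minimum((minutes // 60), 23).astype(int)
    offset = rng.normal(0.0, tp.mouse_offset_sd_c)
    eps = rng.normal(0.0, tp.ar1_sigma_c, size=len(minutes))
    eps[0] = rng.normal(0.0, tp.ar1_sigma_c / np.sqrt(1 - tp.ar1_rho**2))
    from scipy.signal import lfilter

    ar = lfilter([1.0], [1.0, -tp.ar1_rho], eps)  # ar[t] = rho ar[t-1] + eps[t]
    temps = tp.beta0_c + tp.beta1_c_per_frac * hourly_frac[hour_idx] + offset + ar
    # handling (defeat or cage transfer) raises Tb transiently in all groups
    temps += tp.stress_bump_c * np.exp(
        -0.5 * ((zt_min - tp.bump_zt) / tp.bump_sigma_h) ** 2
    )
    truth: dict = {
        "group": group,
        "window_active_frac": window_f,
        "temp_offset_c": float(offset),
        "hypothermic": bool(hypothermic),
    }
    if hypothermic:
        h = cfg.hypothermia
        baseline_at_trough = (
            tp.beta0_c + tp.beta1_c_per_frac * hourly_frac[int(h.trough_zt)] + offset
        )
        amp = baseline_at_trough - h.trough_c
        temps -= amp * np.exp(-0.5 * ((zt_min - h.trough_zt) / h.trough_sigma_h) ** 2)
        truth["trough_c"] = h.trough_c
        truth["trough_zt"] = h.trough_zt
    temp_series = TemperatureSeries(temps_c=temps, start_zt=0.0)
    return series, temp_series, truth


# ---------------------------------------------------------------------------
# social sessions
# ---------------------------------------------------------------------------


def _zone_bands(arena: ArenaGeometry, margin: float = 0.8) -> dict[str, tuple[float, float]]:
    """y-ranges (cm) strictly inside each zone, mesh at y = 0."""
    zi = arena.interaction_depth_cm
    za = arena.length_cm - arena.avoidance_depth_cm
    return {
        "interaction": (margin, zi - margin),
        "middle": (zi + margin, za - margin),
        "avoidance": (za + margin, arena.length_cm - margin),
    }


def _walk_in_box(
    rng: np.random.Generator,
    n: int,
    start: np.ndarray,
    xlim: tuple[float, float],
    ylim: tuple[float, float],
    step_sd: float,
) -> np.ndarray:
    """Reflected Gaussian random walk confined to a box (fold reflection)."""
    pos = start + np.cumsum(rng.normal(0.0, step_sd, size=(n, 2)), axis=0)
    for dim, (lo, hi) in enumerate((xlim, ylim)):
        span = hi - lo
        if span <= 0:
            pos[:, dim] = lo
            continue
        folded = np.mod(pos[:, dim] - lo, 2 * span)
        pos[:, dim] = lo + np.where(folded > span, 2 * span - folded, folded)
    return pos


def _visit_schedule(
    rng: np.random.Generator, frames: dict[str, int]
) -> list[tuple[str, int]]:
    """Split zone frame budgets into chunks and interleave middle corridors."""
    def split(total: int, n_chunks: int) -> list[int]:
        if total <= 0:
            return []
        n_chunks = max(1, min(n_chunks, total))
        cuts = np.sort(rng.choice(np.arange(1, total), size=n_chunks - 1, replace=False)) if n_chunks > 1 else np.array([], dtype=int)
        sizes = np.diff(np.concatenate(([0], cuts, [total])))
        return [int(s) for s in sizes]

    zone_chunks = [("interaction", c) for c in split(frames["interaction"], 4)] + [
        ("avoidance", c) for c in split(frames["avoidance"], 4)
    ]
    rng.shuffle(zone_chunks)
    n_corridors = len(zone_chunks) + 1
    mid_sizes = split(frames["middle"], n_corridors)
    while len(mid_sizes) < n_corridors:
        mid_sizes.append(0)
    schedule: list[tuple[str, int]] = []
    for i, zc in enumerate(zone_chunks):
        if mid_sizes[i] > 0:
            schedule.append(("middle", mid_sizes[i]))
        schedule.append(zc)
    if mid_sizes[len(zone_chunks)] > 0:
        schedule.append(("middle", mid_sizes[len(zone_chunks)]))
    return schedule


def gen_social_session(
    cfg: CohortConfig,
    rng: np.random.Generator,
    phenotype: str,
    session_kind: str = "test",
) -> tuple[TrackedSession, dict, dict]:
    """A pose-tracked arena session for one mouse.

    Returns (session, manual-annotation intervals, truth).  The centroid
    follows a zone-visit schedule realising the phenotype's occupancy
    targets exactly up to frame quantisation; sniffing bouts are injected
    near the mesh during interaction visits.  Habituation sessions (target
    absent) use neutral occupancy and contain no sniffing bouts.
    """
    sp = cfg.social
    if phenotype not in sp.phenotypes:
        raise ValueError(f"unknown phenotype {phenotype!r}")
    ph = sp.phenotypes[phenotype]
    arena = cfg.arena()
    mesh = cfg.mesh()
    n_frames = int(round(sp.session_s * sp.fps))

    if session_kind == "habituation":
        pct_inter = float(np.clip(rng.normal(sp.habituation_zone_pct, 5.0), 2, 60))
        pct_avoid = float(np.clip(rng.normal(sp.habituation_zone_pct, 5.0), 2, 95 - pct_inter))
    elif session_kind == "test":
        pct_inter = float(np.clip(rng.normal(ph.inter_mean_pct, ph.inter_sd_pct), 1, 90))
        pct_avoid = float(np.clip(rng.normal(ph.avoid_mean_pct, ph.avoid_sd_pct), 1, 95 - pct_inter))
    else:
        raise ValueError("session_kind must be 'habituation' or 'test'")

    fi = int(round(pct_inter / 100.0 * n_frames))
    fa = int(round(pct_avoid / 100.0 * n_frames))
    fm = n_frames - fi - fa
    schedule = _visit_schedule(rng, {"interaction": fi, "avoidance": fa, "middle": fm})

    bands = _zone_bands(arena)
    xlim = (1.0, arena.width_cm - 1.0)
    step_sd = 0.45 * ph.speed_scale  # cm per frame inside a zone
    centroid = np.empty((n_frames, 2))
    pos = np.array([arena.width_cm / 2.0, arena.length_cm / 2.0])
    i = 0
    inter_spans: list[tuple[int, int]] = []
    for zone, length in schedule:
        if length == 0:
            continue
        ylim = bands[zone]
        if zone == "middle":
            # corridor: drift across the middle band toward a random anchor
            target_y = rng.uniform(*ylim)
            ys = np.linspace(np.clip(pos[1], *ylim), target_y, length)
            xs = np.clip(
                pos[0] + np.cumsum(rng.normal(0, step_sd, length)), *xlim
            )
            seg = np.column_stack([xs, ys + rng.normal(0, 0.1, length)])
            seg[:, 1] = np.clip(seg[:, 1], *ylim)
        else:
            entry = np.array([pos[0], np.clip(pos[1], *ylim)])
            seg = _walk_in_box(rng, length, entry, xlim, ylim, step_sd)
            if zone == "interaction":
                inter_spans.append((i, i + length))
        centroid[i : i + length] = seg
        pos = seg[-1]
        i += length

    # --- sniffing bouts ----------------------------------------------------
    true_bouts: list[tuple[int, int]] = []
    short_approaches: list[tuple[int, int]] = []
    if session_kind == "test":
        t_inter_s = fi / sp.fps
        mean_dur = ph.bout_base_s + ph.bout_coupling_s_per_s * t_inter_s
        mean_dur = max(0.7, mean_dur + rng.normal(0.0, ph.bout_mouse_sd_s))
        n_bouts = int(rng.poisson(ph.bout_rate))
        durations = np.clip(
            rng.lognormal(np.log(mean_dur), ph.bout_lognorm_sigma, size=n_bouts),
            0.55,
            6.0,
        )
        short = rng.uniform(0.15, 0.45, size=sp.n_short_approaches)
        all_events = [(float(d), True) for d in durations] + [
            (float(d), False) for d in short
        ]
        rng.shuffle(all_events)
        gap = max(2, int(round(0.2 * sp.fps)))
        span_iter = iter(sorted(inter_spans, key=lambda s: -(s[1] - s[0])))
        cursor, span_end = None, None
        for dur_s, is_bout in all_events:
            # short approaches use floor so they stay below the frame threshold
            dur_f = max(1, int(np.ceil(dur_s * sp.fps)) if is_bout else int(dur_s * sp.fps))
            placed = False
            while not placed:
                if cursor is None:
                    try:
                        s0, s1 = next(span_iter)
                    except StopIteration:
                        break  # interaction time exhausted: drop remaining events
                    cursor, span_end = s0 + gap, s1 - gap
                if cursor + dur_f <= span_end:
                    (true_bouts if is_bout else short_approaches).append(
                        (cursor, cursor + dur_f)
                    )
                    cursor += dur_f + gap
                    placed = True
                else:
                    cursor = None

    # --- nose track ---------------------------------------------------------
    nose = centroid + rng.normal(0.0, 0.3, size=centroid.shape)
    nose[:, 1] += 1.0  # body-length offset between nose and body centroid
    x1, x2 = sp.mesh_span_cm
    for s, e in true_bouts + short_approaches:
        nx = rng.uniform(x1 + 0.5, x2 - 0.5, size=e - s)
        ny = rng.uniform(0.3, 1.7, size=e - s)
        nose[s:e, 0] = nx
        nose[s:e, 1] = ny
    # keep all non-bout frames strictly out of sniffing range
    in_bout = np.zeros(n_frames, dtype=bool)
    for s, e in true_bouts + short_approaches:
        in_bout[s:e] = True
    too_close = (~in_bout) & (nose[:, 1] < 2.3) & (nose[:, 0] > x1 - 2.3) & (nose[:, 0] < x2 + 2.3)
    nose[too_close, 1] = rng.uniform(2.5, 4.0, size=int(too_close.sum()))

    px = sp.px_per_cm
    likelihood = np.clip(rng.beta(40, 1.2, size=n_frames), 0.0, 1.0)
    # tracking confidence dips must not break planted bouts
    likelihood[in_bout] = 1.0
    parts = {
        "centroid": np.column_stack([centroid * px, np.ones(n_frames)]),
        "nose": np.column_stack([nose * px, likelihood]),
    }
    session = TrackedSession(parts=parts, fps=sp.fps, session_kind=session_kind)

    fps = sp.fps
    truth_bouts = [
        {"start_s": s / fps, "end_s": e / fps, "duration_s": (e - s) / fps}
        for s, e in sorted(true_bouts)
    ]
    annotations = []
    for b in truth_bouts:
        j1 = rng.normal(0.0, sp.annotation_jitter_sd_s)
        j2 = rng.normal(0.0, sp.annotation_jitter_sd_s)
        s, e = b["start_s"] + j1, b["end_s"] + j2
        e = max(e, s + 0.1)
        annotations.append((max(0.0, s), min(e, sp.session_s)))
    annotations.sort()
    merged: list[tuple[float, float]] = []
    for s, e in annotations:  # jitter may create tiny overlaps; merge them
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(e, merged[-1][1]))
        else:
            merged.append((s, e))

    truth = {
        "phenotype": phenotype,
        "session_kind": session_kind,
        "target_pct_interaction": pct_inter,
        "target_pct_avoidance": pct_avoid,
        "realized_frames_interaction": fi,
        "realized_frames_avoidance": fa,
        "n_frames": n_frames,
        "bouts": truth_bouts,
        "n_short_approaches": len(short_approaches),
    }
    return session, {"intervals": merged}, truth


# ---------------------------------------------------------------------------
# fluorescence images
# ---------------------------------------------------------------------------


def gen_fos_images(
    cfg: CohortConfig,
    rng: np.random.Generator,
    region: str,
    group: str,
    n_spots: int | None = None,
) -> tuple[FluorescenceImage, dict]:
    """One calibrated fluorescence image with planted, well-separated somata.

    The planted count is the region's base count, doubled in the
    stress-responsive regions for stressed mice (Poisson-jittered unless
    ``count_jitter`` is off); undersized and oversized distractor disks
    exercise the 9-30 um filter.  Raises if the requested spots cannot be
    placed without overlap.
    """
    im = cfg.imaging
    if n_spots is None:
        base = im.region_base_counts.get(region, 15)
        if group != "control" and region in im.stress_regions:
            base = base * im.stress_multiplier
        n_spots = int(rng.poisson(base)) if im.count_jitter else int(round(base))

    h, w = im.image_shape
    yy, xx = np.mgrid[0:h, 0:w]
    gx, gy = rng.uniform(-1, 1, 2) * im.gradient_amplitude
    img = (
        im.background_level
        + gx * (xx / w - 0.5)
        + gy * (yy / h - 0.5)
        + rng.normal(0.0, im.noise_sd, size=(h, w))
    )
    roi = np.zeros((h, w), dtype=bool)
    roi[8:-8, 8:-8] = True

    d_lo, d_hi = im.diameter_range_um
    diam_um = np.concatenate(
        [
            rng.uniform(d_lo, d_hi, size=n_spots),
            np.full(im.n_undersize, 6.0),
            np.full(im.n_oversize, 40.0),
        ]
    )
    in_range_flag = np.concatenate(
        [np.ones(n_spots, bool), np.zeros(im.n_undersize + im.n_oversize, bool)]
    )
    radii_px = diam_um / 2.0 / im.um_per_px
    centers: list[tuple[float, float]] = []
    order = rng.permutation(len(diam_um))
    placed_idx = []
    for idx in order:
        r = radii_px[idx]
        ok = False
        for _ in range(4000):
            cy = rng.uniform(10 + r, h - 10 - r)
            cx = rng.uniform(10 + r, w - 10 - r)
            if all(
                (cy - oy) ** 2 + (cx - ox) ** 2
                >= (r + radii_px[j] + 4.0) ** 2
                for (oy, ox), j in zip(centers, placed_idx)
            ):
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"cannot place {len(diam_um)} non-overlapping spots in the image"
            )
        centers.append((cy, cx))
        placed_idx.append(idx)

    amplitude = im.contrast * im.noise_sd
    for (cy, cx), idx in zip(centers, placed_idx):
        r = radii_px[idx]
        y0, y1 = int(np.floor(cy - r - 1)), int(np.ceil(cy + r + 2))
        x0, x1 = int(np.floor(cx - r - 1)), int(np.ceil(cx + r + 2))
        sub_y, sub_x = np.mgrid[y0:y1, x0:x1]
        mask = (sub_y - cy) ** 2 + (sub_x - cx) ** 2 <= r**2
        img[y0:y1, x0:x1][mask] += amplitude

    img = np.clip(img, 0, None)
    fl = FluorescenceImage(
        data=img, um_per_px=im.um_per_px, roi_mask=roi, region=region
    )
    truth = {
        "region": region,
        "group": group,
        "n_in_range": int(n_spots),
        "spots": [
            {
                "y_px": float(cy),
                "x_px": float(cx),
                "diameter_um": float(diam_um[idx]),
                "in_range": bool(in_range_flag[idx]),
            }
            for (cy, cx), idx in zip(centers, placed_idx)
        ],
    }
    return fl, truth


# ---------------------------------------------------------------------------
# whole cohort
# ---------------------------------------------------------------------------


@dataclass
class MouseData:
    mouse_id: str
    group: str
    phenotype: str
    activity: EpochActivitySeries
    temperature: TemperatureSeries
    habituation: TrackedSession
    test: TrackedSession
    manual_annotations: list[tuple[float, float]]
    truth: dict


@dataclass
class Cohort:
    config: CohortConfig
    mice: list[MouseData]
    fos_images: dict  # (group, mouse_id, region, hemisphere) -> FluorescenceImage
    fos_truth: dict
    truth: dict

    def mice_in(self, group: str) -> list[MouseData]:
        return [m for m in self.mice if m.group == group]

    def save_truth(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.truth, indent=1, default=float))


def _assign_phenotypes(cfg: CohortConfig, rng: np.random.Generator) -> list[tuple[str, str]]:
    mice = [("control", "control")] * cfg.n_control
    stress = ["susceptible"] * cfg.n_susceptible + ["resilient"] * (
        cfg.n_stress - cfg.n_susceptible
    )
    sleepdep = ["sleepdep_social"] * cfg.n_sleepdep_social + ["sleepdep_avoidant"] * (
        cfg.n_stress_sleepdep - cfg.n_sleepdep_social
    )
    rng.shuffle(stress)
    rng.shuffle(sleepdep)
    mice += [("stress", ph) for ph in stress]
    mice += [("stress_sleepdep", ph) for ph in sleepdep]
    return mice


def generate_cohort(
    cfg: CohortConfig,
    seed: int | None = None,
    include_imaging: bool = True,
) -> Cohort:
    """Generate the full synthetic study: one stress-day recording and one
    habituation + one test session per mouse, plus (optionally) the
    two-group imaging arm.  Identical seed and config give identical output.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    assignments = _assign_phenotypes(cfg, rng)
    stress_ids = [i for i, (g, _) in enumerate(assignments) if g == "stress"]
    outlier_idx = (
        int(rng.choice(stress_ids)) if (cfg.hypothermia.enabled and stress_ids) else -1
    )
    mice = []
    truth_all: dict = {"mice": {}, "hypothermic_mouse": None}
    for i, (group, phenotype) in enumerate(assignments):
        mid = f"m{i:03d}"
        act, temp, t_act = gen_actigraphy(cfg, rng, group, hypothermic=(i == outlier_idx))
        hab, _, t_hab = gen_social_session(cfg, rng, phenotype, "habituation")
        test, ann, t_test = gen_social_session(cfg, rng, phenotype, "test")
        truth = {
            "group": group,
            "phenotype": phenotype,
            "actigraphy": t_act,
            "habituation": t_hab,
            "test": t_test,
        }
        truth_all["mice"][mid] = truth
        if i == outlier_idx:
            truth_all["hypothermic_mouse"] = mid
        mice.append(
            MouseData(
                mouse_id=mid,
                group=group,
                phenotype=phenotype,
                activity=act,
                temperature=temp,
                habituation=hab,
                test=test,
                manual_annotations=ann["intervals"],
                truth=truth,
            )
        )

    fos_images: dict = {}
    fos_truth: dict = {}
    if include_imaging:
        for group in ("control", "stress"):
            for j in range(cfg.imaging.mice_per_group):
                mid = f"fos_{group}_{j}"
                for region in cfg.imaging.region_base_counts:
                    for hemi in ("left", "right"):
                        img, t = gen_fos_images(cfg, rng, region, group)
                        img.hemisphere = hemi
                        fos_images[(group, mid, region, hemi)] = img
                        fos_truth[(group, mid, region, hemi)] = t
    truth_all["fos"] = {
        "|".join(k): v for k, v in fos_truth.items()
    }
    return Cohort(
        config=cfg, mice=mice, fos_images=fos_images, fos_truth=fos_truth, truth=truth_all
    )
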