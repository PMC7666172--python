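"""Social-interaction arena analysis: zones, distance, susceptibility.

The test arena is a 30 cm x 40 cm chamber with a metal-mesh enclosure at
one short wall holding a target mouse.  The *interaction zone* is the strip
of the arena adjacent to the mesh wall and the *avoidance zone* the strip
at the opposite wall; social interest is quantified by time spent in each,
from the tracked body centroid.  Stressed mice whose zone occupancy departs
from the control group by more than one control standard deviation are
classified susceptible (social avoidance) or resilient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LIKELIHOOD_THRESHOLD = 0.9


@dataclass
class ArenaGeometry:
    """Arena dimensions, zone depths and pixel calibration.

    x spans the width, y the length; the mesh wall sits at ``y = 0`` when
    ``mesh_end == "y0"`` and at ``y = length_cm`` when ``mesh_end == "ymax"``.
    Zone depths default to one third of the arena length each (the strips
    nearest and farthest from the mesh), the standard layout for this assay.
    """

    width_cm: float = 30.0
    length_cm: float = 40.0
    mesh_end: str = "y0"
    interaction_depth_cm: float = 40.0 / 3.0
    avoidance_depth_cm: float = 40.0 / 3.0
    px_per_cm: float = 1.0

    def __post_init__(self) -> None:
        if self.interaction_depth_cm <= 0 or self.avoidance_depth_cm <= 0:
            raise ValueError("zone depths must be positive")
        if self.interaction_depth_cm + self.avoidance_depth_cm > self.length_cm:
            raise ValueError("zones may not overlap: depths exceed arena length")
        if self.mesh_end not in ("y0", "ymax"):
            raise ValueError("mesh_end must be 'y0' or 'ymax'")
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm calibration must be positive")

    def to_cm(self, xy_px: np.ndarray) -> np.ndarray:
        return np.asarray(xy_px, dtype=float) / self.px_per_cm

    def mesh_distance_along_length(self, y_cm: np.ndarray) -> np.ndarray:
        """Distance from the mesh wall along the arena length."""
        y_cm = np.asarray(y_cm, dtype=float)
        return y_cm if self.mesh_end == "y0" else self.length_cm - y_cm

    def zone_of(self, y_cm: np.ndarray) -> np.ndarray:
        """Zone label per frame: 'interaction', 'avoidance' or 'middle'."""
        d = self.mesh_distance_along_length(y_cm)
        out = np.full(d.shape, "middle", dtype=object)
        out[d <= self.interaction_depth_cm] = "interaction"
        out[d >= self.length_cm - self.avoidance_depth_cm] = "avoidance"
        return out


@dataclass
class TrackedSession:
    """Per-frame body-part coordinates from a markerless pose estimator.

    ``parts`` maps a body-part name (at least ``centroid``; ``nose`` for
    sniffing analysis) to an (n_frames, 3) array of (x_px, y_px, likelihood).
    """

    parts: dict[str, np.ndarray]
    fps: float
    session_kind: str = "test"  # "habituation" (target absent) or "test"

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if "centroid" not in self.parts:
            raise ValueError("session requires a 'centroid' part")
        n = None
        for name, arr in self.parts.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"part {name!r} must be (n, 3): x, y, likelihood")
            if n is None:
                n = len(arr)
            elif len(arr) != n:
                raise ValueError("all parts must have the same frame count")
            self.parts[name] = arr
        if n == 0:
            raise ValueError("session has no frames")

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.parts.values())))

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def part_xy_cm(
        self,
        part: str,
        arena: ArenaGeometry,
        likelihood_threshold: float = LIKELIHOOD_THRESHOLD,
        interpolate: bool = True,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Calibrated (n, 2) cm coordinates and a per-frame reliability mask.

        Frames with likelihood below threshold are bridged by linear
        interpolation when ``interpolate`` (standard pose-estimator hygiene);
        the returned mask reports which frames were measured directly.
        """
        if part not in self.parts:
            raise KeyError(f"session has no part {part!r}")
        arr = self.parts[part]
        ok = arr[:, 2] >= likelihood_threshold
        xy = arena.to_cm(arr[:, :2])
        if interpolate and not ok.all():
            if not ok.any():
                raise ValueError(f"no reliable frames for part {part!r}")
            idx = np.arange(len(xy))
            for col in range(2):
                xy[~ok, col] = np.interp(idx[~ok], idx[ok], xy[ok, col])
        return xy, ok


@dataclass
class ZoneOccupancy:
    """Zone times, percentages, and travel distance for one session."""

    mouse_id: str
    time_interaction_s: float
    time_avoidance_s: float
    distance_cm: float
    duration_s: float
    group: str = ""
    session_kind: str = "test"

    @property
    def pct_interaction(self) -> float:
        return 100.0 * self.time_interaction_s / self.duration_s

    @property
    def pct_avoidance(self) -> float:
        return 100.0 * self.time_avoidance_s / self.duration_s


@dataclass
class SusceptibilityLabel:
    """Classification of a stressed mouse against control-group thresholds."""

    mouse_id: str
    label: str  # susceptible | resilient | intermediate | control
    avoid_threshold: float
    interact_threshold: float
    avoid_criterion_met: bool = False
    interact_criterion_met: bool = False


def compute_zone_occupancy(
    session: TrackedSession,
    arena: ArenaGeometry,
    mouse_id: str = "",
    group: str = "",
    likelihood_threshold: float = LIKELIHOOD_THRESHOLD,
) -> ZoneOccupancy:
    """Score zone membership per frame from the centroid and sum travel.

    time_in_zone = frames_in_zone / fps; distance is the summed centroid
    displacement in cm with low-likelihood frames bridged by interpolation.
    """
    xy, _ = session.part_xy_cm("centroid", arena, likelihood_threshold)
    zones = arena.zone_of(xy[:, 1])
    n_inter = int(np.sum(zones == "interaction"))
    n_avoid = int(np.sum(zones == "avoidance"))
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    return ZoneOccupancy(
        mouse_id=mouse_id,
        group=group,
        session_kind=session.session_kind,
        time_interaction_s=n_inter / session.fps,
        time_avoidance_s=n_avoid / session.fps,
        distance_cm=float(steps.sum()),
        duration_s=session.duration_s,
    )


def _control_thresholds(controls: list[ZoneOccupancy]) -> tuple[float, float]:
    if len(controls) < 2:
        raise ValueError("need >= 2 control mice to define an SD")
    avoid = np.array([c.pct_avoidance for c in controls])
    inter = np.array([c.pct_interaction for c in controls])
    return (
        float(avoid.mean() + avoid.std(ddof=1)),
        float(inter.mean() - inter.std(ddof=1)),
    )


def classify_susceptibility(
    stressed: list[ZoneOccupancy],
    controls: list[ZoneOccupancy],
    intermediate_policy: str = "intermediate",
) -> list[SusceptibilityLabel]:
    """Label stressed mice against control mean +/- 1 SD zone thresholds.

    A stressed mouse meets the avoidance criterion when its avoidance-zone
    percentage strictly exceeds control mean + 1 SD, and the interaction
    criterion when its interaction-zone percentage falls strictly below
    control mean - 1 SD.  Both met -> susceptible; neither -> resilient;
    exactly one -> intermediate, or the nearer of the two labels when
    ``intermediate_policy == "nearest"`` (avoidance criterion decides).
    """
    if intermediate_policy not in ("intermediate", "nearest"):
        raise ValueError("intermediate_policy must be 'intermediate' or 'nearest'")
    avoid_thr, inter_thr = _control_thresholds(controls)
    labels = []
    for m in stressed:
        a = m.pct_avoidance > avoid_thr
        i = m.pct_interaction < inter_thr
        if a and i:
            lab = "susceptible"
        elif not a and not i:
            lab = "resilient"
        elif intermediate_policy == "nearest":
            lab = "susceptible" if a else "resilient"
        else:
            lab = "intermediate"
        labels.append(
            SusceptibilityLabel(
                mouse_id=m.mouse_id,
                label=lab,
                avoid_threshold=avoid_thr,
                interact_threshold=inter_thr,
                avoid_criterion_met=bool(a),
                interact_criterion_met=bool(i),
            )
        )
    return labels


def high_social_interest_set(
    all_mice: list[ZoneOccupancy], controls: list[ZoneOccupancy]
) -> tuple[dict[str, bool], dict[str, float]]:
    """Apply the control-derived criteria to every mouse, controls included.

    High social interest = neither the avoidance nor the interaction
    criterion met.  Returns per-mouse membership and per-group proportions.
    A control that exceeds its own cohort's thresholds is excluded too.
    """
    avoid_thr, inter_thr = _control_thresholds(controls)
    membership: dict[str, bool] = {}
    by_group: dict[str, list[bool]] = {}
    for m in all_mice:
        high = not (m.pct_avoidance > avoid_thr) and not (m.pct_interaction < inter_thr)
        membership[m.mouse_id] = high
        by_group.setdefault(m.group, []).append(high)
    proportions = {g: float(np.mean(v)) for g, v in by_group.items()}
    return membership, proportions
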