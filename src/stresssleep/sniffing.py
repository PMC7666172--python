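"""Social-sniffing bout detection from nose trajectories.

A sniffing bout is scored when the experimental mouse's nose stays within
2 cm of the mesh enclosure holding the target mouse for at least 500 ms.
Mean bout duration ("sniffing intensity") is a motivation proxy; in control
and stress-resilient mice it correlates positively with interaction-zone
time, the signature of positive valence of social sniffing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .arena import ArenaGeometry, TrackedSession
from .thermometry import RegressionFit, fit_xy

MAX_SNIFF_DIST_CM = 2.0
MIN_BOUT_DURATION_S = 0.5


@dataclass
class MeshSegment:
    """The mesh enclosure's front face, as a segment in arena cm coordinates."""

    p1: tuple[float, float]
    p2: tuple[float, float]

    def __post_init__(self) -> None:
        if math.dist(self.p1, self.p2) == 0:
            raise ValueError("mesh segment must have nonzero length")


@dataclass
class SniffBout:
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class SniffSummary:
    """Totals over a session; mean duration is undefined (None) at 0 bouts."""

    total_time_s: float
    n_bouts: int
    durations_s: list[float]
    mean_bout_duration_s: float | None


def point_segment_distance(points: np.ndarray, seg: MeshSegment) -> np.ndarray:
    """Euclidean distance from each (n, 2) point to the nearest segment point."""
    p = np.asarray(points, dtype=float)
    a = np.asarray(seg.p1, dtype=float)
    b = np.asarray(seg.p2, dtype=float)
    ab = b - a
    t = np.clip(((p - a) @ ab) / (ab @ ab), 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(p - proj, axis=1)


def nose_mesh_distance(
    session: TrackedSession,
    mesh: MeshSegment,
    arena: ArenaGeometry,
    likelihood_threshold: float = 0.9,
) -> np.ndarray:
    """Per-frame nose-to-mesh distance in cm; NaN where the nose is unreliable.

    Low-likelihood nose frames carry NaN (undefined) rather than an
    interpolated position: a fabricated nose point must not create a bout.
    """
    if "nose" not in session.parts:
        raise ValueError("session has no 'nose' part")
    xy, ok = session.part_xy_cm(
        "nose", arena, likelihood_threshold, interpolate=False
    )
    d = point_segment_distance(xy, mesh)
    d[~ok] = np.nan
    return d


def detect_sniff_bouts(
    distances_cm: np.ndarray,
    fps: float,
    max_dist_cm: float = MAX_SNIFF_DIST_CM,
    min_dur_s: float = MIN_BOUT_DURATION_S,
    max_gap_frames: int = 0,
) -> list[SniffBout]:
    """Find maximal in-range runs of at least ceil(min_dur_s * fps) frames.

    A frame is in range when its distance is <= ``max_dist_cm``; NaN
    (undefined) and out-of-range frames break a run unless the gap is at
    most ``max_gap_frames`` (default 0: the continuous-stay rule).  The
    ceiling makes the duration threshold inclusive: at 30 fps, 15 frames
    (exactly 500 ms) already qualify.  Bout duration = frame count / fps.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    d = np.asarray(distances_cm, dtype=float)
    if len(d) == 0:
        raise ValueError("empty distance track")
    inr = np.zeros(len(d), dtype=bool)
    finite = np.isfinite(d)
    inr[finite] = d[finite] <= max_dist_cm

    # merge runs separated by short gaps
    runs: list[list[int]] = []  # [start, stop) frame index pairs
    i = 0
    n = len(inr)
    while i < n:
        if inr[i]:
            j = i
            while j < n and inr[j]:
                j += 1
            if runs and i - runs[-1][1] <= max_gap_frames:
                runs[-1][1] = j
            else:
                runs.append([i, j])
            i = j
        else:
            i += 1

    min_frames = math.ceil(min_dur_s * fps)
    bouts = []
    for start, stop in runs:
        if stop - start >= min_frames:
            bouts.append(SniffBout(start_s=start / fps, end_s=stop / fps))
    return bouts


def summarize_sniffing(bouts: list[SniffBout]) -> SniffSummary:
    durations = [b.duration_s for b in bouts]
    total = float(sum(durations))
    mean = total / len(durations) if durations else None
    return SniffSummary(
        total_time_s=total,
        n_bouts=len(durations),
        durations_s=durations,
        mean_bout_duration_s=mean,
    )


def validate_against_manual(
    auto_totals_s: dict[str, float], manual_totals_s: dict[str, float]
) -> RegressionFit:
    """Regress automatic on manual sniffing totals over paired sessions.

    High Pearson r validates the pose-based detector against manual scoring.
    """
    common = sorted(set(auto_totals_s) & set(manual_totals_s))
    if len(common) < 3:
        raise ValueError("need >= 3 paired sessions")
    manual = [manual_totals_s[k] for k in common]
    auto = [auto_totals_s[k] for k in common]
    return fit_xy(manual, auto)


def annotation_totals(intervals: dict[str, list[tuple[float, float]]]) -> dict[str, float]:
    """Total annotated time per session from manual (start_s, end_s) intervals."""
    out = {}
    for k, iv in intervals.items():
        iv = sorted(iv)
        for (s1, e1), (s2, _) in zip(iv, iv[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping manual intervals in session {k!r}")
        out[k] = float(sum(e - s for s, e in iv))
    return out
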