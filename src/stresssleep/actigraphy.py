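"""Accelerometer-based scoring of sleep-like inactivity.

Voluntary movement is recorded by an implanted 3-axis accelerometer that
reports, for every 12-s epoch, the number of times the movement waveform
exceeded a threshold.  An epoch belongs to a *sleep-like inactive* period
when it sits inside a run of at least two consecutive zero-count epochs
(>= 24 s without movement); all other epochs are *active*.  Hourly profiles
express the active fraction in percent on Zeitgeber time (ZT 0 = lights-on).

The epoch-count path is canonical; deriving counts from a raw acceleration
trace (:func:`count_threshold_crossings`) approximates the sensor's on-board
counter, whose exact waveform synthesis is not documented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EPOCH_LENGTH_S = 12.0
EPOCHS_PER_HOUR = 300  # 3600 / 12


@dataclass
class AccelerationTrace:
    """Raw 3-axis acceleration, in g, sampled at a fixed rate.

    Parameters
    ----------
    samples : (n, 3) array
        Acceleration vectors in g.
    sample_rate : float
        Samples per second (sensor default 25 Hz).
    start_zt : float
        Zeitgeber time of the first sample, hours in [0, 24).
    """

    samples: np.ndarray
    sample_rate: float = 25.0
    start_zt: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an (n, 3) array")
        if len(self.samples) < 1:
            raise ValueError("empty acceleration trace")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("acceleration samples must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")


@dataclass
class EpochActivitySeries:
    """Movement counts per 12-s epoch on Zeitgeber time.

    ``missing_mask`` marks epochs with no usable sensor data; they are
    excluded from denominators rather than imputed.
    """

    counts: np.ndarray
    start_zt: float = 0.0
    epoch_length_s: float = EPOCH_LENGTH_S
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or len(self.counts) == 0:
            raise ValueError("counts must be a non-empty 1-D sequence")
        if np.any(self.counts < 0):
            raise ValueError("movement counts must be non-negative")
        if self.missing_mask is not None:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.counts.shape:
                raise ValueError("missing_mask must align with counts")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def epoch_zt(self) -> np.ndarray:
        """ZT of each epoch start, in hours, increasing without wrap."""
        return self.start_zt + np.arange(len(self)) * self.epoch_length_s / 3600.0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"zt_hours": self.epoch_zt, "count": self.counts})
        if self.missing_mask is not None:
            df["valid"] = ~self.missing_mask
        return df


@dataclass
class InactivityMask:
    """Per-epoch sleep-like-inactivity flags aligned to an EpochActivitySeries."""

    flags: np.ndarray
    series: EpochActivitySeries = field(repr=False)

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.flags.shape != self.series.counts.shape:
            raise ValueError("mask must align 1:1 with its series")

    def __len__(self) -> int:
        return len(self.flags)


@dataclass
class HourlyActivityProfile:
    """Active percentage per 1-h ZT bin.

    ``bins`` has columns ``zt_hour_start`` (bin start, hours from ZT 0 of the
    first day, monotone across days), ``percent_active``, ``n_epochs_present``
    and ``valid`` (False when fewer than 90% of the 300 epochs are present).
    """

    bins: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"zt_hour_start", "percent_active", "n_epochs_present", "valid"}
        if not required.issubset(self.bins.columns):
            raise ValueError(f"profile requires columns {sorted(required)}")


def count_threshold_crossings(
    trace: AccelerationTrace,
    threshold: float = 0.05,
    epoch_length_s: float = EPOCH_LENGTH_S,
) -> EpochActivitySeries:
    """Bin an acceleration trace into per-epoch movement counts.

    The movement waveform is the norm of the sample-to-sample change of
    the acceleration vector (insensitive to the static gravity offset).
    An event is scored whenever the waveform crosses from <= ``threshold``
    to > ``threshold``; events are assigned to the epoch containing the
    sample at which the crossing completes.  A trailing partial epoch is
    dropped.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    wave = np.linalg.norm(np.diff(trace.samples, axis=0), axis=1)  # wave[j] -> sample j + 1
    above = wave > threshold
    # crossing where above turns on; the first waveform point counts if above
    onset = above & ~np.concatenate(([False], above[:-1]))
    event_sample = np.flatnonzero(onset) + 1
    samples_per_epoch = int(round(epoch_length_s * trace.sample_rate))
    if samples_per_epoch < 1 or len(trace.samples) < samples_per_epoch:
        raise ValueError("trace shorter than one epoch")
    n_epochs = len(trace.samples) // samples_per_epoch
    epochs = event_sample // samples_per_epoch
    counts = np.bincount(epochs[epochs < n_epochs], minlength=n_epochs)
    return EpochActivitySeries(
        counts=counts, start_zt=trace.start_zt, epoch_length_s=epoch_length_s
    )


def inactivity_mask(series: EpochActivitySeries) -> InactivityMask:
    """Flag epochs that lie inside a zero-count run of length >= 2.

    Epoch ``i`` is inactive iff ``counts[i] == 0`` and at least one of its
    neighbours is also zero.  Neighbours outside the recording are treated
    as nonzero (an inactive run cannot be asserted without context), so an
    isolated zero epoch is active.  Missing epochs are treated as nonzero
    for run formation and are never themselves flagged.
    """
    counts = series.counts
    zero = counts == 0
    if series.missing_mask is not None:
        zero = zero & ~series.missing_mask
    prev_zero = np.concatenate(([False], zero[:-1]))
    next_zero = np.concatenate((zero[1:], [False]))
    flags = zero & (prev_zero | next_zero)
    return InactivityMask(flags=flags, series=series)


def hourly_profile(
    series: EpochActivitySeries,
    mask: InactivityMask,
    min_coverage: float = 0.9,
) -> HourlyActivityProfile:
    """Aggregate the inactivity mask into 1-h ZT bins.

    percent_active = 100 x (present epochs not flagged inactive) / present.
    Bins with fewer than ``min_coverage`` x 300 epochs present are emitted
    with ``valid = False`` and excluded from downstream window means.
    """
    if mask.series is not series and not np.array_equal(
        mask.series.counts, series.counts
    ):
        raise ValueError("mask is not aligned to this series")
    hours = np.floor(series.epoch_zt + 1e-9).astype(int)
    present = (
        ~series.missing_mask
        if series.missing_mask is not None
        else np.ones(len(series), dtype=bool)
    )
    rows = []
    for h in np.unique(hours):
        in_bin = hours == h
        n_present = int(np.sum(in_bin & present))
        if n_present == 0:
            pct_active = np.nan
        else:
            n_inactive = int(np.sum(in_bin & present & mask.flags))
            pct_active = 100.0 * (n_present - n_inactive) / n_present
        rows.append(
            {
                "zt_hour_start": float(h),
                "percent_active": pct_active,
                "n_epochs_present": n_present,
                "valid": n_present >= min_coverage * EPOCHS_PER_HOUR,
            }
        )
    return HourlyActivityProfile(bins=pd.DataFrame(rows))


def window_mean_active(
    profile: HourlyActivityProfile, zt_from: float, zt_to: float
) -> float:
    """Epoch-weighted mean percent-active over a ZT window.

    Bins are selected by bin start in ``[zt_from, zt_to)`` on the 24-h clock,
    so windows crossing ZT midnight (``zt_from > zt_to``) are supported.
    Only valid bins contribute; an empty window raises.
    """
    bins = profile.bins[profile.bins["valid"]]
    clock = np.mod(bins["zt_hour_start"].to_numpy(), 24.0)
    lo, hi = zt_from % 24.0, zt_to % 24.0
    if lo < hi:
        sel = (clock >= lo) & (clock < hi)
    else:  # window wraps past ZT 24
        sel = (clock >= lo) | (clock < hi)
    chosen = bins[sel]
    weights = chosen["n_epochs_present"].to_numpy(dtype=float)
    if len(chosen) == 0 or weights.sum() == 0:
        raise ValueError("no valid bins in the requested ZT window")
    return float(
        np.average(chosen["percent_active"].to_numpy(dtype=float), weights=weights)
    )
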