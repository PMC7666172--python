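"""Core body-temperature analysis and the severe-hypothermia outlier rule.

The implanted sensor logs core body temperature once per minute.  Group
analyses use window means over a Zeitgeber-time window (ZT 13-15 after a
stress session at ZT 11-12); the coupling between sleep-like inactivity and
temperature is quantified by an ordinary least-squares regression of each
mouse's window-mean temperature on its window-mean active percentage.

A stressed mouse that develops severe hypothermia (the study's example
reached 31.1 degC) is detected by a leave-one-out rule: refit the regression
on all other mice and flag the candidate when its temperature falls strictly
below the lower 95% prediction band evaluated at its activity level.  The
prediction band (for a single new observation) rather than the confidence
band (for the mean response) is the statistically appropriate envelope for
one animal's value; both bands are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

TEMP_PLAUSIBLE_RANGE_C = (25.0, 45.0)


@dataclass
class TemperatureSeries:
    """Per-minute core body temperature in degC on Zeitgeber time."""

    temps_c: np.ndarray
    start_zt: float = 0.0
    sample_interval_s: float = 60.0

    def __post_init__(self) -> None:
        self.temps_c = np.asarray(self.temps_c, dtype=float)
        if self.temps_c.ndim != 1 or len(self.temps_c) == 0:
            raise ValueError("temps_c must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.temps_c)):
            raise ValueError("temperatures must be finite")

    def __len__(self) -> int:
        return len(self.temps_c)

    @property
    def sample_zt(self) -> np.ndarray:
        return self.start_zt + np.arange(len(self)) * self.sample_interval_s / 3600.0

    @property
    def implausible_mask(self) -> np.ndarray:
        """Samples outside the physiological screen [25, 45] degC.

        Flagged, never dropped: severe hypothermia is real data.
        """
        lo, hi = TEMP_PLAUSIBLE_RANGE_C
        return (self.temps_c < lo) | (self.temps_c > hi)


@dataclass
class ActivityTempPoint:
    """One mouse's (window-mean active %, window-mean temperature) pair."""

    mouse_id: str
    mean_active_pct: float
    mean_temp_c: float
    group: str = ""


@dataclass
class RegressionFit:
    """OLS fit of y on x with Pearson test and 95% point-wise bands."""

    slope: float
    intercept: float
    r: float
    p_r: float
    residual_se: float
    n: int
    x_mean: float = field(repr=False, default=0.0)
    sxx: float = field(repr=False, default=0.0)

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def _half_width(self, x, extra: float) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        tcrit = stats.t.ppf(0.975, self.n - 2)
        return tcrit * self.residual_se * np.sqrt(
            extra + 1.0 / self.n + (x - self.x_mean) ** 2 / self.sxx
        )

    def ci95_band(self, x) -> tuple[np.ndarray, np.ndarray]:
        """95% confidence band for the mean response at x (lower, upper)."""
        hw = self._half_width(x, extra=0.0)
        yhat = self.predict(x)
        return yhat - hw, yhat + hw

    def pi95_band(self, x) -> tuple[np.ndarray, np.ndarray]:
        """95% prediction band for a single new observation at x."""
        hw = self._half_width(x, extra=1.0)
        yhat = self.predict(x)
        return yhat - hw, yhat + hw


def window_mean_temp(series: TemperatureSeries, zt_from: float, zt_to: float) -> float:
    """Arithmetic mean of the samples whose ZT lies in [zt_from, zt_to).

    Supports windows wrapping past ZT 24 on the 24-h clock.
    """
    clock = np.mod(series.sample_zt, 24.0)
    lo, hi = zt_from % 24.0, zt_to % 24.0
    sel = (clock >= lo) & (clock < hi) if lo < hi else (clock >= lo) | (clock < hi)
    if not np.any(sel):
        raise ValueError("no temperature samples in the requested window")
    return float(series.temps_c[sel].mean())


def fit_xy(x, y) -> RegressionFit:
    """OLS fit with Pearson r and its two-sided p (t with n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x: all values equal")
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    residual_se = float(np.sqrt(np.sum(resid**2) / (n - 2)))
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p_r=float(res.pvalue),
        residual_se=residual_se,
        n=n,
        x_mean=float(x.mean()),
        sxx=float(np.sum((x - x.mean()) ** 2)),
    )


def fit_activity_temperature(points: list[ActivityTempPoint]) -> RegressionFit:
    """Regress window-mean temperature on window-mean active percentage."""
    x = [p.mean_active_pct for p in points]
    y = [p.mean_temp_c for p in points]
    return fit_xy(x, y)


def flag_hypothermia_outlier(
    points: list[ActivityTempPoint], candidate: str
) -> tuple[bool, dict]:
    """Leave-one-out prediction-band test for severe hypothermia.

    Refits the activity-temperature regression on every mouse except the
    candidate and flags the candidate iff its temperature lies strictly
    below the lower 95% prediction band at its activity level.  Returns the
    flag and a diagnostics dict (fit, band edges, candidate values).
    """
    cand = [p for p in points if p.mouse_id == candidate]
    if len(cand) != 1:
        raise ValueError(f"candidate {candidate!r} must appear exactly once")
    rest = [p for p in points if p.mouse_id != candidate]
    if len(rest) < 4:
        raise ValueError("need >= 4 non-candidate points to refit")
    fit = fit_activity_temperature(rest)
    c = cand[0]
    lo, hi = fit.pi95_band(c.mean_active_pct)
    ci_lo, ci_hi = fit.ci95_band(c.mean_active_pct)
    flagged = bool(c.mean_temp_c < float(lo))
    diagnostics = {
        "fit": fit,
        "candidate_active_pct": c.mean_active_pct,
        "candidate_temp_c": c.mean_temp_c,
        "pi95": (float(lo), float(hi)),
        "ci95": (float(ci_lo), float(ci_hi)),
        "predicted_temp_c": float(fit.predict(c.mean_active_pct)),
    }
    return flagged, diagnostics
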