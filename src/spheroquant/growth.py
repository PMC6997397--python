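"""Growth-curve assembly, peak-PI analysis, regime classification, statistics.

Replicate experiments scan spheroids at irregular times; each repeat is
linearly interpolated onto a daily grid (days 0–21) and the repeats are
pooled into mean ± SEM curves.  Downstream analyses quantify the treatment
response: the peak PI intensity within an early window regressed against
biological effect, growth delay against a diameter threshold, a qualitative
growth-regime label, and Welch t-tests between treatment groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "RepeatSeries",
    "GrowthCurve",
    "RegressionResult",
    "GroupComparison",
    "RegimeConfig",
    "assemble_growth_curve",
    "peak_pi",
    "regress_effect",
    "growth_delay",
    "classify_regime",
    "compare_groups",
    "NOT_REACHED",
]

N_DAYS = 22  # daily grid, days 0..21 inclusive
DAY_GRID = np.arange(N_DAYS, dtype=float)

#: Sentinel returned by :func:`growth_delay` when the treated curve never
#: reaches the threshold within the observation window (growth control).
NOT_REACHED = float("inf")


@dataclass
class RepeatSeries:
    """Per-repeat scan series: mean over the 4–6 spheroids of one repeat."""

    repeat_id: str
    scan_times: np.ndarray  # days post-treatment, strictly increasing
    values: np.ndarray  # mean diameter (µm) or mean PI
    scan_sd: np.ndarray | None = None  # within-repeat SD per scan

    def __post_init__(self):
        self.scan_times = np.asarray(self.scan_times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.scan_times.shape != self.values.shape:
            raise ValueError("scan_times and values must match in length")
        if self.scan_times.size < 2:
            raise ValueError(
                f"repeat {self.repeat_id!r} has fewer than two scans; "
                "interpolation needs at least two"
            )
        if np.any(np.diff(self.scan_times) <= 0):
            raise ValueError("scan_times must be strictly increasing")
        if self.scan_times[0] < 0 or self.scan_times[-1] > 21:
            raise ValueError("scan_times must lie within [0, 21] days")
        if self.scan_sd is not None:
            self.scan_sd = np.asarray(self.scan_sd, dtype=float)


@dataclass
class GrowthCurve:
    """Daily-grid pooled curve: mean ± SEM over repeats, days 0–21."""

    day: np.ndarray
    mean: np.ndarray  # NaN where no repeat has data
    sem: np.ndarray  # NaN where n_repeats < 2
    n_repeats: np.ndarray
    label: str = ""

    def __post_init__(self):
        for name in ("day", "mean", "sem"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.n_repeats = np.asarray(self.n_repeats, dtype=int)
        if self.day.shape != (N_DAYS,):
            raise ValueError(f"curve must cover the {N_DAYS}-day grid")

    @property
    def publication_grade(self) -> bool:
        """True when every day with data pools at least three repeats."""
        has = self.n_repeats > 0
        return bool(has.any() and (self.n_repeats[has] >= 3).all())


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    day: int
    t_statistic: float
    p_value: float


def assemble_growth_curve(
    series: list[RepeatSeries], label: str = ""
) -> GrowthCurve:
    """Pool repeat series onto the daily grid.

    Each repeat is linearly interpolated at integer days between its first
    and last scan; days outside that span are missing for that repeat (no
    extrapolation).  The pooled mean and SEM (sd/√n) are taken per day over
    the repeats with data there.
    """
    if not series:
        raise ValueError("at least one repeat series is required")
    grid = np.full((len(series), N_DAYS), np.nan)
    for i, s in enumerate(series):
        inside = (DAY_GRID >= s.scan_times[0]) & (DAY_GRID <= s.scan_times[-1])
        grid[i, inside] = np.interp(DAY_GRID[inside], s.scan_times, s.values)
    n = np.sum(~np.isnan(grid), axis=0)
    mean = np.where(n > 0, np.nansum(grid, axis=0) / np.maximum(n, 1), np.nan)
    dev2 = np.nansum((grid - mean) ** 2, axis=0)
    sd = np.sqrt(np.where(n >= 2, dev2 / np.maximum(n - 1, 1), np.nan))
    sem = np.where(n >= 2, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    return GrowthCurve(day=DAY_GRID.copy(), mean=mean, sem=sem, n_repeats=n,
                       label=label)


def peak_pi(
    curve: GrowthCurve, window: tuple[float, float] = (0.0, 7.0)
) -> tuple[float, int]:
    """Maximum of a PI curve within a day window; ties break to the
    earliest day.  Returns (peak value, peak day)."""
    lo, hi = window
    sel = (curve.day >= lo) & (curve.day <= hi) & ~np.isnan(curve.mean)
    if not sel.any():
        raise ValueError("no data within the requested window")
    days = curve.day[sel]
    vals = curve.mean[sel]
    i = int(np.argmax(vals))  # argmax takes the first maximum: earliest day
    return float(vals[i]), int(days[i])


def regress_effect(
    peaks: "np.ndarray | list[float]", effects: "np.ndarray | list[float]"
) -> RegressionResult:
    """Ordinary least squares of peak response on biological effect E.

    R² = 1 − SS_res/SS_tot; a constant response has R² = 0 by convention.
    Requires ≥3 points and non-constant E.
    """
    y = np.asarray(peaks, dtype=float)
    x = np.asarray(effects, dtype=float)
    if y.shape != x.shape:
        raise ValueError("peaks and effects must match in length")
    if y.size < 3:
        raise ValueError("regression requires at least three points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in biological effect")
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    intercept = float(ym - slope * xm)
    ss_res = float(np.sum((y - (slope * x + intercept)) ** 2))
    ss_tot = float(np.sum((y - ym) ** 2))
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return RegressionResult(slope=slope, intercept=intercept,
                            r_squared=max(0.0, min(1.0, r2)))


def _first_crossing(curve: GrowthCurve, threshold: float) -> float:
    """First (fractional) day at which the mean curve reaches ``threshold``,
    linear between grid days; NOT_REACHED when it never does."""
    m = curve.mean
    valid = ~np.isnan(m)
    days = curve.day[valid]
    vals = m[valid]
    if vals.size == 0:
        return NOT_REACHED
    if vals[0] >= threshold:
        return float(days[0])
    above = np.nonzero(vals >= threshold)[0]
    if above.size == 0:
        return NOT_REACHED
    j = int(above[0])
    d0, d1 = days[j - 1], days[j]
    v0, v1 = vals[j - 1], vals[j]
    return float(d0 + (threshold - v0) / (v1 - v0) * (d1 - d0))


def growth_delay(
    curve: GrowthCurve, control: GrowthCurve, threshold_um: float
) -> float:
    """Extra time (days) for the treated curve to reach a diameter threshold
    relative to control.  Returns :data:`NOT_REACHED` (inf) when the treated
    spheroid never crosses — growth control within the observation window.

    Raises ``ValueError`` when the control itself never crosses.
    """
    t_control = _first_crossing(control, threshold_um)
    if not math.isfinite(t_control):
        raise ValueError("control never reaches the threshold")
    t_treated = _first_crossing(curve, threshold_um)
    if not math.isfinite(t_treated):
        return NOT_REACHED
    return t_treated - t_control


@dataclass
class RegimeConfig:
    """Thresholds of the qualitative growth-regime rules.

    ``swell_drop_frac``: fractional fall from a post-day-0 local maximum that
    counts as significant shrinkage after transient swelling.
    ``regrowth_days``: consecutive rising days after the minimum that count
    as sustained regrowth.  ``rise_frac``: minimum per-day relative rise for
    those days (filters out numerically flat tails).
    """

    swell_drop_frac: float = 0.15
    regrowth_days: int = 3
    rise_frac: float = 0.005


REGIME_CONTROL = "control-like growth"
REGIME_SWELL = "transient-swelling-then-shrinkage"
REGIME_MONOTONE = "monotone-shrinkage"
REGIME_REGROWTH = "shrinkage-then-regrowth"
REGIME_GROWTH_CONTROL = "growth-control"


def _has_sustained_rise(vals: np.ndarray, start: int, cfg: RegimeConfig) -> bool:
    run = 0
    for i in range(start + 1, len(vals)):
        if vals[i] > vals[i - 1] * (1 + cfg.rise_frac):
            run += 1
            if run >= cfg.regrowth_days:
                return True
        else:
            run = 0
    return False


def classify_regime(
    curve: GrowthCurve,
    pi_curve: GrowthCurve | None = None,
    config: RegimeConfig | None = None,
) -> str:
    """Label the growth response of a diameter curve.

    One of: control-like growth / transient-swelling-then-shrinkage /
    monotone-shrinkage / shrinkage-then-regrowth / growth-control.
    Swelling = a local maximum above the day-0 value followed by a
    ≥15% drop; regrowth = a sustained post-minimum rise over ≥3 consecutive
    days; growth control = final diameter at or below day 0 with no
    regrowth.  The PI curve is accepted for signature compatibility with
    pooled reporting but the rules operate on diameter alone.
    """
    cfg = config or RegimeConfig()
    m = curve.mean
    valid = ~np.isnan(m)
    vals = m[valid]
    if vals.size < 2:
        raise ValueError("curve too short to classify")
    d0 = vals[0]
    final = vals[-1]
    # deepest relative drawdown from the running maximum locates the
    # shrinkage phase; the preceding running-max index is its peak
    runmax = np.maximum.accumulate(vals)
    with np.errstate(divide="ignore", invalid="ignore"):
        drawdown = np.where(runmax > 0, (runmax - vals) / runmax, 0.0)
    i_min = int(np.argmax(drawdown))
    i_peak = int(np.argmax(vals[: i_min + 1]))
    peak = vals[i_peak]
    drop = float(drawdown[i_min])

    if drop < cfg.swell_drop_frac:
        return REGIME_CONTROL if final > d0 else REGIME_GROWTH_CONTROL

    swelled = i_peak > 0 and peak > d0
    regrew = _has_sustained_rise(vals, i_min, cfg)
    if swelled:
        return REGIME_SWELL
    if regrew:
        return REGIME_REGROWTH
    if final <= d0:
        # distinguish steadily shrinking curves from shrink-then-flat ones
        diffs = np.diff(vals)
        if np.all(diffs <= np.maximum(np.abs(vals[:-1]) * cfg.rise_frac, 1e-9)):
            return REGIME_MONOTONE
        return REGIME_GROWTH_CONTROL
    return REGIME_MONOTONE


def compare_groups(
    a: "np.ndarray | list[float]",
    b: "np.ndarray | list[float]",
    label_a: str = "a",
    label_b: str = "b",
    day: int = 21,
) -> GroupComparison:
    """Two-sided unpaired Welch t-test between per-repeat endpoint values."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two repeats")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        group_a=label_a, group_b=label_b, day=day,
        t_statistic=float(t), p_value=float(p),
    )
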