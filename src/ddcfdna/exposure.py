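"""Immunosuppressive-exposure metrics from tacrolimus trough series.

Covers the first post-transplant month: Rosendaal time-in-therapeutic-range
(piecewise-linear interpolation between troughs with exact range-crossing
times), intra-patient coefficient of variation, concentration/dose ratio
with the fast-metabolizer flag, and below-threshold exposure flags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: institutional tacrolimus target range for the first months, ng/mL
TARGET_LOW = 8.0
TARGET_HIGH = 12.0

#: C/D ratio below which a patient is called a fast metabolizer (strict)
FAST_METABOLIZER_CUTOFF = 1.05


@dataclass(frozen=True)
class TacrolimusSeries:
    """Trough levels (ng/mL) and daily doses (mg) on days 0-30."""

    days: np.ndarray
    levels: np.ndarray
    doses: np.ndarray

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=float)
        levels = np.asarray(self.levels, dtype=float)
        doses = np.asarray(self.doses, dtype=float)
        if days.size < 1:
            raise ValueError("series must contain at least one observation")
        if not (days.size == levels.size == doses.size):
            raise ValueError("days, levels and doses must be equally long")
        if np.any(np.diff(days) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any(levels <= 0):
            raise ValueError("trough levels must be positive")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "doses", doses)

    def __len__(self) -> int:
        return int(self.days.size)


@dataclass(frozen=True)
class ExposureMetrics:
    ttr_8_12: float          # % time in [8, 12] ng/mL
    ttr_above_12: float      # % time > 12 ng/mL
    mean_level: float
    sd_level: float
    cv_percent: float
    trough_month1: float
    cd_ratio: float
    fast_metabolizer: bool
    any_below_5: bool
    any_below_6: bool
    mpa_trough: float | None = None


def _band_occupancy(series: TacrolimusSeries, low: float, high: float):
    """Time fractions (below, in [low, high], above) of the piecewise-linear
    trough trajectory over [first day, last day]."""
    t, l = series.days, series.levels
    span = t[-1] - t[0]
    below = inside = above = 0.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        l0, l1 = l[i], l[i + 1]
        if l0 == l1:
            if l0 < low:
                below += dt
            elif l0 <= high:
                inside += dt
            else:
                above += dt
            continue
        # fraction of the segment with level <= threshold x
        def frac_le(x: float) -> float:
            s = (x - l0) / (l1 - l0)
            if l1 > l0:
                return float(np.clip(s, 0.0, 1.0))
            return 1.0 - float(np.clip(s, 0.0, 1.0))

        f_low = frac_le(low)
        f_high = frac_le(high)
        below += dt * f_low
        inside += dt * (f_high - f_low)
        above += dt * (1.0 - f_high)
    return below / span, inside / span, above / span


def rosendaal_ttr(
    series: TacrolimusSeries, low: float = TARGET_LOW, high: float = TARGET_HIGH
) -> tuple[float, float]:
    """Percent time in [low, high] and strictly above ``high``.

    The level is assumed piecewise linear between consecutive troughs;
    range-crossing times are solved exactly on each segment and the
    denominator is the observed span [first day, last day] (no
    extrapolation). Boundary levels count as in range.
    """
    if len(series) < 2:
        raise ValueError("Rosendaal TTR needs at least 2 observations")
    if not low < high:
        raise ValueError("need low < high")
    _, inside, above = _band_occupancy(series, low, high)
    return 100.0 * inside, 100.0 * above


def cv_percent(series: TacrolimusSeries, ddof: int = 1) -> float:
    """Intra-patient variability, CV(%) = (sigma/mu) x 100.

    Sample (n-1) standard deviation by default; ``ddof=0`` switches to the
    population convention.
    """
    if len(series) < 2:
        raise ValueError("CV needs at least 2 observations")
    levels = series.levels
    return float(levels.std(ddof=ddof) / levels.mean() * 100.0)


def cd_ratio(trough_level: float, daily_dose: float) -> tuple[float, bool]:
    """Concentration/dose ratio and the fast-metabolizer flag (< 1.05 strict)."""
    if daily_dose <= 0:
        raise ValueError("daily dose must be positive")
    ratio = trough_level / daily_dose
    return ratio, ratio < FAST_METABOLIZER_CUTOFF


def below_threshold_flags(
    series: TacrolimusSeries, thresholds: tuple[float, float] = (5.0, 6.0)
) -> tuple[bool, ...]:
    """Whether any trough is strictly below each threshold."""
    return tuple(bool(np.any(series.levels < t)) for t in thresholds)


def summarize_exposure(
    series: TacrolimusSeries, mpa_trough: float | None = None
) -> ExposureMetrics:
    """Assemble the month-1 exposure metrics for one patient.

    The month-1 trough is the observation nearest day 30 (the last one under
    the usual schedule); the C/D ratio pairs it with that day's daily dose.
    """
    ttr, above = rosendaal_ttr(series)
    cv = cv_percent(series)
    i_last = int(np.argmin(np.abs(series.days - 30.0)))
    trough = float(series.levels[i_last])
    ratio, fast = cd_ratio(trough, float(series.doses[i_last]))
    b5, b6 = below_threshold_flags(series)
    return ExposureMetrics(
        ttr_8_12=ttr,
        ttr_above_12=above,
        mean_level=float(series.levels.mean()),
        sd_level=float(series.levels.std(ddof=1)),
        cv_percent=cv,
        trough_month1=trough,
        cd_ratio=ratio,
        fast_metabolizer=fast,
        any_below_5=b5,
        any_below_6=b6,
        mpa_trough=mpa_trough,
    )
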