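"""Stage-wise production statistics for a 48-hour deposition experiment.

The lighting program splits a 48-h test (lights on at hour 1) into four
stages — first daytime, first nighttime, second daytime, second nighttime —
and the hourly increments of manure mass or coverage are summarised per
stage.  Also here: the weekly feed-to-manure ratio reconstruction, Pearson
correlation with its t-test p-value, and cage stocking density.

Weekly production parameters (feed, day/night manure rates, pH, moisture
content) and the photoperiod schedule for hen ages 10-30 weeks ship as
packaged CSVs.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LightingSchedule",
    "WeekProfile",
    "StageSummary",
    "load_lighting_schedule",
    "load_week_profiles",
    "get_week_profile",
    "get_lighting",
    "segment_stages",
    "stage_mean_increment",
    "feed_to_manure_ratio",
    "mean_ratio_across_weeks",
    "pearson_r",
    "stocking_density",
]

STAGE_LABELS = ("day1", "night1", "day2", "night2")


@dataclass(frozen=True)
class LightingSchedule:
    """Photoperiod for one hen age: lights on at experiment hour 1 for
    ``daylength_h`` hours (local lights-on clock time 5 am in the field
    protocol)."""

    daylength_h: int
    lights_on_clock_hour: int = 5

    def __post_init__(self) -> None:
        if not 1 <= self.daylength_h <= 23:
            raise ValueError("daylength_h must be in [1, 23]")


@dataclass(frozen=True)
class WeekProfile:
    """Weekly production parameters for one hen age (grams per hen)."""

    age_week: int
    feed_g: float
    day_rate_g: float
    night_rate_g: float
    ratio: float | None = None
    ph_mean: float | None = None
    ph_sd: float | None = None
    mc_mean_pct: float | None = None
    mc_sd_pct: float | None = None

    def __post_init__(self) -> None:
        if self.feed_g <= 0:
            raise ValueError("feed_g must be positive")
        if self.day_rate_g < 0 or self.night_rate_g < 0:
            raise ValueError("manure rates must be non-negative")
        if self.mc_mean_pct is not None and not 0 <= self.mc_mean_pct <= 100:
            raise ValueError("moisture content must be in [0, 100] %")


@dataclass(frozen=True)
class StageSummary:
    """Hour range and increment statistics for one lighting stage."""

    stage_label: str
    hour_start: int  # inclusive, 1-based
    hour_end: int  # inclusive
    mean_increment: float | None = None
    sd_increment: float | None = None

    @property
    def hours(self) -> range:
        return range(self.hour_start, self.hour_end + 1)


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("beltcover.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_lighting_schedule() -> pd.DataFrame:
    """Packaged photoperiod table: age_week, daylength_h, target_weight_g."""
    return _read_packaged("lighting_schedule.csv")


def load_week_profiles() -> pd.DataFrame:
    """Packaged weekly production table (feed, rates, ratio, pH, MC)."""
    return _read_packaged("week_profiles.csv")


def get_week_profile(age_week: int) -> WeekProfile:
    df = load_week_profiles()
    row = df[df["age_week"] == age_week]
    if row.empty:
        raise KeyError(f"no packaged profile for week {age_week}")
    r = row.iloc[0]
    return WeekProfile(
        age_week=int(r["age_week"]),
        feed_g=float(r["feed_g"]),
        day_rate_g=float(r["day_rate"]),
        night_rate_g=float(r["night_rate"]),
        ratio=float(r["ratio"]),
        ph_mean=float(r["ph_mean"]),
        ph_sd=float(r["ph_sd"]),
        mc_mean_pct=float(r["mc_mean"]),
        mc_sd_pct=float(r["mc_sd"]),
    )


def get_lighting(age_week: int) -> LightingSchedule:
    df = load_lighting_schedule()
    row = df[df["age_week"] == age_week]
    if row.empty:
        raise KeyError(f"no packaged lighting schedule for week {age_week}")
    return LightingSchedule(daylength_h=int(row.iloc[0]["daylength_h"]))


def segment_stages(schedule: LightingSchedule, duration_h: int = 48) -> list[StageSummary]:
    """Partition a 48-h experiment into the four lighting stages.

    With daylength L: day1 = [1, L], night1 = [L+1, 24], day2 = [25, 24+L],
    night2 = [24+L+1, 48].  The stages partition hours 1..48 exactly.
    """
    if duration_h != 48:
        raise ValueError("stage segmentation is defined for a 48-hour experiment")
    L = schedule.daylength_h
    if L >= 24:
        raise ValueError("daylength must be < 24 h: no night stage would exist")
    return [
        StageSummary("day1", 1, L),
        StageSummary("night1", L + 1, 24),
        StageSummary("day2", 25, 24 + L),
        StageSummary("night2", 24 + L + 1, 48),
    ]


def stage_mean_increment(increments: pd.Series | dict, stage: StageSummary) -> StageSummary:
    """Mean and sample (n-1) sd of hourly increments over one stage's hours.

    ``increments`` maps hour -> hourly increment (%/h or g/h).
    """
    series = pd.Series(increments)
    missing = [h for h in stage.hours if h not in series.index]
    if missing:
        raise ValueError(f"stage {stage.stage_label} missing hours: {missing}")
    vals = series.loc[list(stage.hours)].astype(float)
    return StageSummary(
        stage.stage_label,
        stage.hour_start,
        stage.hour_end,
        mean_increment=float(vals.mean()),
        sd_increment=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
    )


def feed_to_manure_ratio(profile: WeekProfile, schedule: LightingSchedule) -> float:
    """Daily manure mass divided by daily feed mass, per hen.

    ``(day_rate * L + night_rate * (24 - L)) / feed``.  Note the field
    convention: despite the name "feed-to-manure ratio", the recorded
    quantity is manure output over feed intake (it comes out near 2 because
    fresh manure is ~75 % water while feed is dry).
    """
    if profile.feed_g <= 0:
        raise ValueError("feed_g must be positive")
    L = schedule.daylength_h
    daily_manure = profile.day_rate_g * L + profile.night_rate_g * (24 - L)
    return daily_manure / profile.feed_g


def mean_ratio_across_weeks(ratios) -> float:
    """Arithmetic mean of per-week feed-to-manure ratios."""
    arr = np.asarray(list(ratios), dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one weekly ratio")
    return float(arr.mean())


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with its two-sided t-test p-value.

    The p-value uses ``t = r sqrt((n-2)/(1-r^2))`` on n-2 degrees of
    freedom, the standard test for a Pearson coefficient.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in input series")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def stocking_density(birds_per_cage: int, cage_w_m: float, cage_l_m: float) -> float:
    """Birds per square metre of cage floor."""
    if cage_w_m <= 0 or cage_l_m <= 0:
        raise ValueError("cage dimensions must be positive")
    if birds_per_cage < 0:
        raise ValueError("birds_per_cage must be non-negative")
    return birds_per_cage / (cage_w_m * cage_l_m)
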