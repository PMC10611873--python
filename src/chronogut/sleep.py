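"""Sleep-questionnaire derivations: mid-sleep, social jetlag, chronotype.

Social jetlag (SJL) is the discrepancy between the mid-sleep point on
free days and work days — a behavioural proxy for circadian misalignment.
This module derives, per participant, weekday/weekend mid-sleep points,
the SJL magnitude in hours, a categorical SJL flag (>= 1.5 h), chronotype
(weekend mid-sleep, later = later type) and habitual sleep duration with
its short/average/long category, applying the cohort exclusion rules
(daytime sleep onset, afternoon offset, implausible duration, negative
SJL) in a fixed order with a per-rule log.

Clock times are handled as integer minutes from midnight; all differences
are computed on an unwrapped axis and reduced afterwards, which avoids
both float drift and wrap-around bugs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "parse_clock",
    "format_clock",
    "mid_sleep",
    "sleep_duration",
    "social_jetlag",
    "habitual_duration",
    "chronotype",
    "apply_sleep_exclusions",
    "derive_sleep",
    "ExclusionLog",
    "SJL_THRESHOLD_H",
]

MINUTES_PER_DAY = 1440
#: SJL category cut-off in hours; a difference of exactly 1.5 h counts as SJL.
SJL_THRESHOLD_H = 1.5

# duration plausibility bounds (minutes): < 2 h or > 15 h is excluded
_MIN_DURATION_MIN = 120
_MAX_DURATION_MIN = 900
# daytime onset window [08:00, 17:00)
_ONSET_LO, _ONSET_HI = 8 * 60, 17 * 60
_NOON = 12 * 60


class ClockParseError(ValueError):
    """A clock-time string could not be parsed as HH:MM."""


def parse_clock(value) -> int:
    """Parse ``HH:MM`` (24 h) into integer minutes from midnight.

    Accepts ints/floats already in minutes (passed through after range
    reduction) so tabular round-trips are cheap.
    """
    if isinstance(value, (int, np.integer)):
        return int(value) % MINUTES_PER_DAY
    if isinstance(value, float) and not np.isnan(value):
        return int(round(value)) % MINUTES_PER_DAY
    if not isinstance(value, str):
        raise ClockParseError(f"cannot parse clock time from {value!r}")
    parts = value.strip().split(":")
    if len(parts) not in (2, 3):
        raise ClockParseError(f"expected HH:MM, got {value!r}")
    try:
        hh, mm = int(parts[0]), int(parts[1])
    except ValueError as exc:
        raise ClockParseError(f"expected HH:MM, got {value!r}") from exc
    if not (0 <= hh < 24 and 0 <= mm < 60):
        raise ClockParseError(f"clock time out of range: {value!r}")
    return hh * 60 + mm


def format_clock(minutes: float) -> str:
    """Render minutes-from-midnight as an ``HH:MM`` string."""
    m = int(round(minutes)) % MINUTES_PER_DAY
    return f"{m // 60:02d}:{m % 60:02d}"


def _unwrap_wake(bed: int, wake: int) -> int:
    """Advance wake by 24 h when it does not fall strictly after bed."""
    return wake + MINUTES_PER_DAY if wake <= bed else wake


def sleep_duration(bed, wake) -> float:
    """Time in bed in hours; wake <= bed is read as crossing midnight."""
    b, w = parse_clock(bed), parse_clock(wake)
    return (_unwrap_wake(b, w) - b) / 60.0


def mid_sleep(bed, wake) -> int:
    """Mid-sleep point in minutes from midnight.

    The midpoint of the bed→wake interval on the unwrapped axis, reduced
    modulo 24 h.  ``mid_sleep("23:00", "07:00")`` is 03:00.
    """
    b, w = parse_clock(bed), parse_clock(wake)
    w = _unwrap_wake(b, w)
    return int(round((b + w) / 2)) % MINUTES_PER_DAY


def social_jetlag(week_mid, weekend_mid) -> float:
    """Signed SJL in hours: weekend mid-sleep minus weekday mid-sleep.

    The difference is taken on the circle and reported as the
    representative in (-12, +12] hours.  Negative values (weekday
    mid-sleep later than weekend) are returned as-is; the exclusion
    stage removes them rather than truncating.
    """
    wk, we = parse_clock(week_mid), parse_clock(weekend_mid)
    diff = (we - wk) % MINUTES_PER_DAY
    if diff > MINUTES_PER_DAY // 2:
        diff -= MINUTES_PER_DAY
    return diff / 60.0


def habitual_duration(week_h: float, weekend_h: float) -> tuple[float, str]:
    """Habitual sleep duration (unweighted mean of the two day types) and
    its category: short < 7 h, average 7–9 h, long > 9 h."""
    if week_h <= 0 or weekend_h <= 0:
        raise ValueError("sleep durations must be positive")
    h = (week_h + weekend_h) / 2.0
    if h < 7:
        cat = "short"
    elif h > 9:
        cat = "long"
    else:
        cat = "average"
    return h, cat


def chronotype(weekend_bed, weekend_wake) -> int:
    """Chronotype as weekend mid-sleep (minutes); later = later type."""
    return mid_sleep(weekend_bed, weekend_wake)


@dataclass
class ExclusionLog:
    """Ordered counts of records removed per exclusion rule."""

    rules: list[str] = field(default_factory=list)
    removed: list[int] = field(default_factory=list)
    remaining: list[int] = field(default_factory=list)

    def record(self, rule: str, n_removed: int, n_remaining: int) -> None:
        self.rules.append(rule)
        self.removed.append(int(n_removed))
        self.remaining.append(int(n_remaining))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rule": self.rules, "removed": self.removed, "remaining": self.remaining}
        )


_REQUIRED = ["weekday_bed", "weekday_wake", "weekend_bed", "weekend_wake"]


def apply_sleep_exclusions(
    records: pd.DataFrame,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the cohort sleep exclusions in order, returning the derived
    table (all input rows, excluded ones carrying a reason) and a log.

    Rules, applied sequentially to the still-retained set:

    1. ``missing`` — any of the four bed/wake times absent;
    2. ``daytime_onset`` — a bed time in [08:00, 17:00) on either day type;
    3. ``late_offset`` — a wake time after 12:00 noon on either day type;
    4. ``implausible_duration`` — time in bed < 2 h or > 15 h;
    5. ``negative_sjl`` — weekday mid-sleep later than weekend mid-sleep.

    Input columns: ``participant_id``, ``weekday_bed``, ``weekday_wake``,
    ``weekend_bed``, ``weekend_wake`` (HH:MM), optional ``psqi``.
    """
    df = records.copy()
    n = len(df)
    reason = pd.Series(pd.NA, index=df.index, dtype="object")

    missing = df[_REQUIRED].isna().any(axis=1)
    for col in _REQUIRED:
        if df[col].dtype == object:
            missing |= df[col].astype(str).str.strip().isin(["", "nan", "None"])
    reason[missing] = "missing"

    def _minutes(col):
        return df[col].where(~missing).map(
            lambda v: parse_clock(v) if not pd.isna(v) else np.nan
        )

    wd_bed, wd_wake = _minutes("weekday_bed"), _minutes("weekday_wake")
    we_bed, we_wake = _minutes("weekend_bed"), _minutes("weekend_wake")

    alive = reason.isna()
    daytime = (
        ((wd_bed >= _ONSET_LO) & (wd_bed < _ONSET_HI))
        | ((we_bed >= _ONSET_LO) & (we_bed < _ONSET_HI))
    ) & alive
    reason[daytime] = "daytime_onset"

    alive = reason.isna()
    late = ((wd_wake > _NOON) | (we_wake > _NOON)) & alive
    reason[late] = "late_offset"

    def _dur(bed, wake):
        w = wake.where(wake > bed, wake + MINUTES_PER_DAY)
        return w - bed

    wd_dur, we_dur = _dur(wd_bed, wd_wake), _dur(we_bed, we_wake)
    alive = reason.isna()
    bad_dur = (
        (wd_dur < _MIN_DURATION_MIN)
        | (wd_dur > _MAX_DURATION_MIN)
        | (we_dur < _MIN_DURATION_MIN)
        | (we_dur > _MAX_DURATION_MIN)
    ) & alive
    reason[bad_dur] = "implausible_duration"

    wd_mid = ((wd_bed + _dur(wd_bed, wd_wake) / 2) % MINUTES_PER_DAY).round()
    we_mid = ((we_bed + _dur(we_bed, we_wake) / 2) % MINUTES_PER_DAY).round()
    sjl_h = (we_mid - wd_mid) % MINUTES_PER_DAY
    sjl_h = sjl_h.where(sjl_h <= MINUTES_PER_DAY // 2, sjl_h - MINUTES_PER_DAY) / 60.0
    alive = reason.isna()
    neg = (sjl_h < 0) & alive
    reason[neg] = "negative_sjl"

    log = ExclusionLog()
    running = n
    for rule, mask in [
        ("missing", missing),
        ("daytime_onset", daytime),
        ("late_offset", late),
        ("implausible_duration", bad_dur),
        ("negative_sjl", neg),
    ]:
        k = int(mask.sum())
        running -= k
        log.record(rule, k, running)

    out = df.copy()
    out["exclusion_reason"] = reason
    out["_wd_mid"] = wd_mid
    out["_we_mid"] = we_mid
    out["_wd_dur_h"] = wd_dur / 60.0
    out["_we_dur_h"] = we_dur / 60.0
    out["_sjl_h"] = sjl_h
    return out, log


def derive_sleep(records: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionLog]:
    """Full sleep derivation for a questionnaire table.

    Returns one row per input participant with mid-sleep points (HH:MM),
    durations (h), SJL hours and flag, chronotype, habitual duration and
    category; rows failing an exclusion rule carry ``exclusion_reason``
    and NA derived values.
    """
    flagged, log = apply_sleep_exclusions(records)
    keep = flagged["exclusion_reason"].isna()

    out = pd.DataFrame(index=flagged.index)
    out["participant_id"] = flagged["participant_id"]
    out["mid_sleep_weekday"] = flagged["_wd_mid"].where(keep).map(
        lambda m: format_clock(m) if not pd.isna(m) else pd.NA
    )
    out["mid_sleep_weekend"] = flagged["_we_mid"].where(keep).map(
        lambda m: format_clock(m) if not pd.isna(m) else pd.NA
    )
    out["sleep_duration_weekday_h"] = flagged["_wd_dur_h"].where(keep)
    out["sleep_duration_weekend_h"] = flagged["_we_dur_h"].where(keep)
    out["sjl_h"] = flagged["_sjl_h"].where(keep)
    out["sjl_flag"] = (flagged["_sjl_h"] >= SJL_THRESHOLD_H).where(keep)
    out["chronotype"] = out["mid_sleep_weekend"]
    hab = (flagged["_wd_dur_h"] + flagged["_we_dur_h"]) / 2.0
    out["habitual_sleep_h"] = hab.where(keep)
    cat = pd.Series(pd.NA, index=flagged.index, dtype="object")
    cat[hab < 7] = "short"
    cat[(hab >= 7) & (hab <= 9)] = "average"
    cat[hab > 9] = "long"
    out["duration_category"] = cat.where(keep)
    if "psqi" in flagged.columns:
        out["psqi"] = flagged["psqi"]
    out["exclusion_reason"] = flagged["exclusion_reason"]
    return out, log
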