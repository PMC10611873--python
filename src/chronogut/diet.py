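"""Chrononutrition features and diet-quality indices.

Two sources of dietary data are handled:

* time-stamped meal-log events from free-living study days, segmented
  into eating occasions (EO) and summarised into daily timing features
  (counts, eating/fasting windows, eating midpoint);
* food-frequency-questionnaire (FFQ) food-group intakes (g/day), scored
  into the plant-based diet indices PDI, hPDI and uPDI by cohort
  quintiles, with the energy-plausibility exclusions (Harris–Benedict
  basal metabolic rate ratio, unanswered-item count).

An eating occasion is a chain of logged events in which consecutive
events are separated by less than 30 minutes; a chain whose summed
energy is below 50 kcal is discarded after chaining.  Occasions are
classified as main meals or snacks by sex-specific energy thresholds
(>= 400 kcal female / >= 500 kcal male).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sleep import format_clock

__all__ = [
    "EatingOccasion",
    "segment_eating_occasions",
    "day_features",
    "filter_free_living_days",
    "mean_over_valid_days",
    "harris_benedict_bmr",
    "ffq_exclusion",
    "score_pdi_family",
    "circular_mean_minutes",
    "DEFAULT_GROUP_CLASSES",
    "EO_MIN_KCAL",
    "EO_GAP_MIN",
    "MAIN_MEAL_KCAL",
]

EO_MIN_KCAL = 50.0
EO_GAP_MIN = 30.0
#: main-meal energy thresholds by sex
MAIN_MEAL_KCAL = {"F": 400.0, "M": 500.0}
#: valid free-living day energy range (kcal) by sex
DAY_ENERGY_RANGE = {"F": (500.0, 5000.0), "M": (500.0, 8000.0)}
#: FFQ energy-intake / BMR plausibility band
EI_BMR_RANGE = (0.52, 2.58)
MAX_UNANSWERED = 10


@dataclass(frozen=True)
class EatingOccasion:
    start_min: float  # clock minutes of first event
    end_min: float  # clock minutes of last event
    energy_kcal: float
    kind: str  # "main_meal" | "snack"


def _norm_sex(sex: str) -> str:
    s = str(sex).strip().upper()[:1]
    if s not in ("F", "M"):
        raise ValueError(f"unknown sex code: {sex!r}")
    return s


def segment_eating_occasions(
    times_min, energies_kcal, sex: str,
    gap_min: float = EO_GAP_MIN, min_kcal: float = EO_MIN_KCAL,
) -> list[EatingOccasion]:
    """Segment one day's meal-log events into eating occasions.

    ``times_min`` are event clock times in minutes within the day (sorted
    ascending); ``energies_kcal`` the event energies.  Consecutive events
    closer than ``gap_min`` are chained into one occasion; the occasion's
    energy is the chain sum (sub-threshold events inside a chain still
    contribute).  Chains totalling less than ``min_kcal`` are dropped
    after merging.  Surviving occasions are classified main meal vs snack
    by the sex-specific threshold.
    """
    s = _norm_sex(sex)
    t = np.asarray(times_min, dtype=float)
    e = np.asarray(energies_kcal, dtype=float)
    if t.size != e.size:
        raise ValueError("times and energies must have equal length")
    if np.any(e < 0):
        raise ValueError("event energies must be non-negative")
    if t.size == 0:
        return []
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]

    occasions: list[EatingOccasion] = []
    start = 0
    for i in range(1, t.size + 1):
        if i == t.size or t[i] - t[i - 1] >= gap_min:
            total = float(e[start:i].sum())
            if total >= min_kcal:
                kind = "main_meal" if total >= MAIN_MEAL_KCAL[s] else "snack"
                occasions.append(
                    EatingOccasion(float(t[start]), float(t[i - 1]), total, kind)
                )
            start = i
    return occasions


def day_features(occasions: list[EatingOccasion]) -> dict | None:
    """Daily timing features from one day's eating occasions.

    First/last EO times are occasion *start* times; eating window is
    their difference, the fasting window its 24 h complement, the eating
    midpoint the window's middle.  Returns ``None`` for a day with zero
    occasions (the day is invalid and contributes no features).
    """
    if not occasions:
        return None
    starts = [o.start_min for o in occasions]
    first, last = min(starts), max(starts)
    window_h = (last - first) / 60.0
    return {
        "n_eating_occasions": len(occasions),
        "n_main_meals": sum(o.kind == "main_meal" for o in occasions),
        "n_snacks": sum(o.kind == "snack" for o in occasions),
        "first_eo_min": first,
        "last_eo_min": last,
        "eating_window_h": window_h,
        "fasting_window_h": 24.0 - window_h,
        "eating_midpoint_min": first + (last - first) / 2.0,
        "total_energy_kcal": sum(o.energy_kcal for o in occasions),
    }


def filter_free_living_days(day_energy_kcal: float, sex: str) -> bool:
    """A free-living day is valid iff its energy lies in the sex-specific
    closed interval (500–5000 kcal female, 500–8000 kcal male)."""
    lo, hi = DAY_ENERGY_RANGE[_norm_sex(sex)]
    return bool(lo <= day_energy_kcal <= hi)


def circular_mean_minutes(minutes) -> float:
    """Wrap-aware mean of clock times (minutes), in [0, 1440).

    Times are unwrapped onto a common axis before averaging — each value
    is shifted by whole days to sit within +/-12 h of a reference
    direction — so that 23:30 and 00:30 average to 00:00 rather than
    12:00 (late-night times past midnight are effectively treated as
    > 24 h), while the result for same-evening times is the plain
    arithmetic mean.
    """
    m = np.asarray(minutes, dtype=float)
    ang = m / 1440.0 * 2 * np.pi
    ref = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean()) / (2 * np.pi) * 1440.0
    unwrapped = m + 1440.0 * np.round((ref - m) / 1440.0)
    out = float(np.mean(unwrapped) % 1440.0)
    return 0.0 if out >= 1440.0 - 1e-9 else out


_CLOCK_FEATURES = ("first_eo_min", "last_eo_min", "eating_midpoint_min")


def mean_over_valid_days(day_rows: pd.DataFrame) -> pd.Series | None:
    """Participant-level means over valid free-living days.

    Clock-time features are averaged circularly; everything else
    arithmetically.  Returns ``None`` when no valid day remains.
    """
    if len(day_rows) == 0:
        return None
    out = {}
    for col in day_rows.columns:
        vals = day_rows[col].dropna()
        if len(vals) == 0:
            out[col] = np.nan
        elif col in _CLOCK_FEATURES:
            out[col] = circular_mean_minutes(vals.to_numpy())
        else:
            out[col] = float(vals.mean())
    return pd.Series(out)


def harris_benedict_bmr(sex: str, weight_kg: float, height_cm: float, age_y: float) -> float:
    """Basal metabolic rate (kcal/day) by the original Harris–Benedict
    coefficients; used for FFQ energy-plausibility screening."""
    if weight_kg <= 0 or height_cm <= 0 or age_y <= 0:
        raise ValueError("anthropometrics must be positive")
    if _norm_sex(sex) == "M":
        return 66.4730 + 13.7516 * weight_kg + 5.0033 * height_cm - 6.7550 * age_y
    return 655.0955 + 9.5634 * weight_kg + 1.8496 * height_cm - 4.6756 * age_y


def ffq_exclusion(
    energy_kcal: float, bmr_kcal: float, n_unanswered: int = 0
) -> tuple[bool, float]:
    """FFQ plausibility: valid iff energy/BMR in [0.52, 2.58] and at most
    ten unanswered items.  Returns (valid, ratio)."""
    if bmr_kcal <= 0:
        raise ValueError("BMR must be positive")
    ratio = energy_kcal / bmr_kcal
    valid = (EI_BMR_RANGE[0] <= ratio <= EI_BMR_RANGE[1]) and n_unanswered <= MAX_UNANSWERED
    return bool(valid), float(ratio)


#: default food-group classification for the plant-based diet indices
DEFAULT_GROUP_CLASSES = {
    "whole_grains": "healthy_plant",
    "fruits": "healthy_plant",
    "vegetables": "healthy_plant",
    "nuts": "healthy_plant",
    "legumes": "healthy_plant",
    "vegetable_oils": "healthy_plant",
    "tea_coffee": "healthy_plant",
    "fruit_juices": "less_healthy_plant",
    "refined_grains": "less_healthy_plant",
    "potatoes": "less_healthy_plant",
    "sugar_sweetened_beverages": "less_healthy_plant",
    "sweets_desserts": "less_healthy_plant",
    "animal_fat": "animal",
    "dairy": "animal",
    "eggs": "animal",
    "fish_seafood": "animal",
    "meat": "animal",
    "misc_animal": "animal",
}

_CLASSES = ("healthy_plant", "less_healthy_plant", "animal")


def quintile_scores(values) -> np.ndarray:
    """Cohort quintile score 1–5 per value: average ranks, floored into
    five equal bins.  Deterministic and order-independent under ties."""
    from scipy.stats import rankdata

    v = np.asarray(values, dtype=float)
    ranks = rankdata(v, method="average")
    q = np.floor((ranks - 1) * 5.0 / v.size).astype(int) + 1
    return np.clip(q, 1, 5)


def score_pdi_family(
    ffq: pd.DataFrame, group_classes: dict[str, str] | None = None
) -> pd.DataFrame:
    """Score PDI, hPDI and uPDI from cohort FFQ food-group intakes.

    Each configured food group is split into cohort quintiles (scores
    1–5).  PDI scores every plant group ascending and animal groups
    reversed (6 - q); hPDI scores healthy-plant ascending and everything
    else reversed; uPDI scores less-healthy-plant ascending and
    everything else reversed.  Each index is the sum of its per-group
    scores; per-group scores are returned as ``score_<group>`` columns
    (the ascending quintile, before any reversal).
    """
    classes = DEFAULT_GROUP_CLASSES if group_classes is None else group_classes
    for g, c in classes.items():
        if c not in _CLASSES:
            raise KeyError(f"food group {g!r} has unknown class {c!r}")
        if g not in ffq.columns:
            raise KeyError(f"FFQ table lacks configured food group {g!r}")

    out = pd.DataFrame(index=ffq.index)
    pdi = np.zeros(len(ffq), dtype=int)
    hpdi = np.zeros(len(ffq), dtype=int)
    updi = np.zeros(len(ffq), dtype=int)
    for g, c in classes.items():
        q = quintile_scores(ffq[g].to_numpy())
        rev = 6 - q
        out[f"score_{g}"] = q
        pdi += q if c in ("healthy_plant", "less_healthy_plant") else rev
        hpdi += q if c == "healthy_plant" else rev
        updi += q if c == "less_healthy_plant" else rev
    out.insert(0, "uPDI", updi)
    out.insert(0, "hPDI", hpdi)
    out.insert(0, "PDI", pdi)
    return out


def derive_diet_days(
    meal_events: pd.DataFrame, demographics: pd.DataFrame
) -> pd.DataFrame:
    """Per-participant-day diet-timing features from a meal-event log.

    ``meal_events`` columns: ``participant_id``, ``timestamp`` (ISO 8601
    or datetime) and ``energy_kcal``; sex is looked up in
    ``demographics``.  Days are calendar dates; events are segmented per
    day, features computed, and each day flagged valid by the
    sex-specific energy range.
    """
    ev = meal_events.copy()
    ev["timestamp"] = pd.to_datetime(ev["timestamp"])
    sex_by_id = demographics.set_index("participant_id")["sex"]
    rows = []
    for (pid, date), grp in ev.groupby(
        ["participant_id", ev["timestamp"].dt.date], sort=True
    ):
        sex = sex_by_id.loc[pid]
        mins = grp["timestamp"].dt.hour * 60 + grp["timestamp"].dt.minute
        occ = segment_eating_occasions(mins.to_numpy(), grp["energy_kcal"].to_numpy(), sex)
        feats = day_features(occ)
        if feats is None:
            continue
        feats["participant_id"] = pid
        feats["date"] = str(date)
        feats["valid_day"] = filter_free_living_days(feats["total_energy_kcal"], sex)
        rows.append(feats)
    return pd.DataFrame(rows)


def derive_diet_features(
    meal_events: pd.DataFrame, demographics: pd.DataFrame
) -> pd.DataFrame:
    """Participant-level mean diet-timing features over valid days,
    with clock-time features also rendered as HH:MM strings."""
    days = derive_diet_days(meal_events, demographics)
    if days.empty:
        return pd.DataFrame()
    feature_cols = [
        "n_eating_occasions", "n_main_meals", "n_snacks",
        "first_eo_min", "last_eo_min", "eating_window_h",
        "fasting_window_h", "eating_midpoint_min", "total_energy_kcal",
    ]
    out_rows = []
    for pid, grp in days[days["valid_day"]].groupby("participant_id", sort=True):
        means = mean_over_valid_days(grp[feature_cols])
        if means is None:
            continue
        means["n_valid_days"] = len(grp)
        means["participant_id"] = pid
        out_rows.append(means)
    out = pd.DataFrame(out_rows)
    if out.empty:
        return out
    for col in ("first_eo_min", "last_eo_min", "eating_midpoint_min"):
        out[col.replace("_min", "_clock")] = out[col].map(format_clock)
    return out.reset_index(drop=True)
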