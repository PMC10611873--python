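"""Synthetic PREDICT-like cohort with planted, recoverable effects.

Generates every table the analysis pipeline consumes — demographics,
sleep questionnaire, meal-event log, FFQ food-group intakes, CGM traces,
postprandial series and a compositional species-abundance matrix — for a
cohort in which social-jetlag (SJL) status, its demographic skew
(younger, more male), its diet shifts (less fruit/nuts, more
sugar-sweetened beverages/potatoes) and its direct plus diet-mediated
effects on species abundance are all planted with known coefficients, so
each downstream stage can be tested against ground truth.

Design of the abundance table: null species are log-normal intensities
with per-species Bernoulli detection (creating the >=20% / <20%
prevalence structure the screen filters on); planted species are
generated directly on the arcsine-square-root scale — where the screen's
effect size and the mediation models operate — then mapped back through
sin^2.  Compositional closure is achieved by a single filler taxon
absorbing the remainder of each sample, so rows sum to one exactly while
the planted transformed-scale coefficients survive closure untouched.

Food-group intakes use mean-zero shifted-gamma noise, which keeps
intakes non-negative at the paper-scale standard deviations while
leaving the group shift exactly additive (the mediator model stays
correctly specified).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sleep import format_clock

__all__ = [
    "SyntheticConfig",
    "CohortBundle",
    "generate_cohort",
    "generate_cgm_trace",
    "generate_postprandial_series",
    "write_bundle",
    "read_bundle",
    "POSTPRANDIAL_ANALYTES",
]

#: venous sampling grid (minutes) of the standardised-meal protocol
PROTOCOL_MINUTES = np.array([0, 15, 30, 60, 120, 180, 240, 270, 300, 360], float)
POSTPRANDIAL_ANALYTES = ("glucose", "insulin", "triglyceride", "glyca")

_BASE_DATE = pd.Timestamp("2018-07-02 09:00")  # nominal clinic-visit anchor

#: food-group baseline means and SDs (g/day); the five groups with
#: group-difference data carry observed cohort-scale values, the rest are
#: generator choices at plausible UK-adult magnitudes
FOOD_GROUPS: dict[str, tuple[float, float]] = {
    "whole_grains": (120.0, 60.0),
    "fruits": (211.0, 147.0),
    "vegetables": (250.0, 120.0),
    "nuts": (18.0, 20.4),
    "legumes": (30.0, 25.0),
    "vegetable_oils": (15.0, 10.0),
    "tea_coffee": (500.0, 250.0),
    "fruit_juices": (80.0, 70.0),
    "refined_grains": (150.0, 70.0),
    "potatoes": (71.0, 48.8),
    "sugar_sweetened_beverages": (62.5, 119.0),
    "sweets_desserts": (60.0, 45.0),
    "animal_fat": (10.0, 8.0),
    "dairy": (250.0, 130.0),
    "eggs": (25.0, 20.0),
    "fish_seafood": (45.0, 35.8),
    "meat": (90.0, 55.0),
    "misc_animal": (20.0, 15.0),
}

#: SJL-group additive intake shifts (g/day), signs and sizes following
#: the observed group contrasts (less fruit and nuts, more
#: sugar-sweetened beverages, potatoes and fish)
DEFAULT_DIET_EFFECTS: dict[str, float] = {
    "fruits": -36.0,
    "nuts": -3.5,
    "sugar_sweetened_beverages": 25.2,
    "potatoes": 5.3,
    "fish_seafood": 7.2,
}


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions."""

    n_participants: int = 934
    sjl_prevalence: float = 0.16
    age_shift_sjl: float = -8.4  # years; SJL group younger
    male_frac_by_group: dict = field(
        default_factory=lambda: {"no_sjl": 0.25, "sjl": 0.39}
    )
    diet_effects: dict = field(default_factory=lambda: dict(DEFAULT_DIET_EFFECTS))
    n_species: int = 100
    n_direct_species: int = 6
    n_mediated_species: int = 2
    effect_size_d: float = 0.8
    mediated_fraction: float = 0.15
    mediator_group: str = "nuts"
    family_sd: float = 0.02  # transformed-abundance scale
    twin_frac: float = 0.5  # fraction of participants in twin pairs
    n_negative_sjl: int = 0  # planted records with weekday mid-sleep later
    n_meal_days: int = 3
    cgm_days: int = 14
    seed: int = 0

    def validate(self) -> None:
        fracs = {
            "sjl_prevalence": self.sjl_prevalence,
            "twin_frac": self.twin_frac,
            **{f"male_frac[{k}]": v for k, v in self.male_frac_by_group.items()},
        }
        for name, v in fracs.items():
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_participants", "n_species", "cgm_days", "n_meal_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_direct_species", "n_mediated_species", "n_negative_sjl"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_direct_species + self.n_mediated_species > self.n_species:
            raise ValueError("planted species outnumber n_species")
        if self.n_mediated_species > 0 and not 0 < self.mediated_fraction < 1:
            raise ValueError("mediated_fraction must lie in (0, 1)")
        if self.n_mediated_species == 0 and self.mediated_fraction not in (0, 0.15):
            raise ValueError("mediated_fraction set without mediated species")
        if self.mediator_group not in FOOD_GROUPS:
            raise ValueError(f"unknown mediator food group {self.mediator_group!r}")
        if self.n_mediated_species > 0 and self.diet_effects.get(
            self.mediator_group, 0
        ) == 0:
            raise ValueError(
                "mediated species require a non-zero diet effect on the mediator"
            )

    @classmethod
    def from_file(cls, path) -> "SyntheticConfig":
        """Load a config from YAML or JSON."""
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)


@dataclass
class CohortBundle:
    """All generated tables plus the planted ground truth."""

    demographics: pd.DataFrame
    sleep: pd.DataFrame
    meals: pd.DataFrame
    ffq: pd.DataFrame
    cgm: pd.DataFrame
    postprandial: pd.DataFrame
    abundance: pd.DataFrame  # samples x species, rows sum to 1
    ground_truth: dict

    _TABLES = (
        "demographics", "sleep", "meals", "ffq", "cgm", "postprandial", "abundance"
    )


def _rng_child(seed: int, label: str) -> np.random.Generator:
    import zlib

    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode())])
    )


def _shifted_gamma(rng, mean_zero_floor: float, sd: float, size: int) -> np.ndarray:
    """Mean-zero noise with support [-floor, inf): Gamma(k, theta) - floor
    with k*theta = floor and sqrt(k)*theta = sd."""
    if mean_zero_floor <= 0:
        return np.zeros(size)
    theta = sd**2 / mean_zero_floor
    k = (mean_zero_floor / sd) ** 2
    return rng.gamma(k, theta, size=size) - mean_zero_floor


def _make_sleep(cfg: SyntheticConfig, rng, sjl: np.ndarray, neg_idx: np.ndarray):
    n = cfg.n_participants
    wd_mid = np.clip(rng.normal(3.4, 0.7, n), 2.0, 4.5)  # hours past midnight
    wd_dur = np.clip(rng.normal(8.1, 0.9, n), 6.5, 10.0)
    delta = np.where(
        sjl,
        np.clip(1.55 + np.abs(rng.normal(0.0, 0.5, n)), 1.55, 3.5),
        np.clip(np.abs(rng.normal(0.65, 0.4, n)), 0.0, 1.45),
    )
    if neg_idx.size:
        delta[neg_idx] = rng.uniform(-1.4, -0.3, neg_idx.size)
    we_mid = wd_mid + delta
    we_dur = np.where(sjl, rng.normal(9.0, 1.0, n), rng.normal(8.6, 0.9, n))
    we_dur = np.clip(we_dur, 6.5, 10.5)
    # keep weekend wake before noon so the late-offset rule stays quiet
    we_dur = np.minimum(we_dur, 2 * (11.5 - we_mid))

    def hhmm(hours):
        return [format_clock(round(h * 60)) for h in np.mod(hours, 24)]

    psqi = np.clip(np.round(rng.normal(4.5, 2.5, n)), 0, 21).astype(int)
    return pd.DataFrame(
        {
            "weekday_bed": hhmm(wd_mid - wd_dur / 2),
            "weekday_wake": hhmm(wd_mid + wd_dur / 2),
            "weekend_bed": hhmm(we_mid - we_dur / 2),
            "weekend_wake": hhmm(we_mid + we_dur / 2),
            "psqi": psqi,
        }
    )


_ETHNICITY = (
    ["white", "asian", "black", "mixed", "other", "unknown"],
    [0.896, 0.014, 0.016, 0.025, 0.010, 0.039],
)
_EDUCATION = (["below_university", "university_or_higher", "unknown"], [0.37, 0.59, 0.04])
_MENOPAUSE = (["pre", "post", "peri", "unknown"], [0.50, 0.28, 0.07, 0.15])


def _make_demographics(cfg: SyntheticConfig, rng, sjl: np.ndarray) -> pd.DataFrame:
    n = cfg.n_participants
    male_p = np.where(
        sjl, cfg.male_frac_by_group["sjl"], cfg.male_frac_by_group["no_sjl"]
    )
    sex = np.where(rng.random(n) < male_p, "M", "F")
    age = np.where(
        sjl,
        rng.normal(46.8 + cfg.age_shift_sjl, 11.3, n),
        rng.normal(46.8, 11.7, n),
    )
    age = np.clip(age, 18, 65)
    bmi = np.clip(rng.normal(25.6, 5.0, n), 16, 45)
    height = np.where(sex == "M", rng.normal(176, 7, n), rng.normal(163, 6.5, n))
    weight = bmi * (height / 100) ** 2
    eth = rng.choice(_ETHNICITY[0], size=n, p=np.array(_ETHNICITY[1]) / sum(_ETHNICITY[1]))
    edu = rng.choice(_EDUCATION[0], size=n, p=_EDUCATION[1])
    meno = np.where(
        sex == "F",
        rng.choice(_MENOPAUSE[0], size=n, p=_MENOPAUSE[1]),
        "not_applicable",
    )
    # twin structure: a configurable fraction of participants sit in
    # 2-person families sharing a random intercept
    n_pairs = int(round(cfg.twin_frac * n / 2))
    family = np.arange(n)
    perm = rng.permutation(n)
    for k in range(n_pairs):
        a, b = perm[2 * k], perm[2 * k + 1]
        family[b] = family[a]
    fam_codes, fam_idx = np.unique(family, return_inverse=True)
    return pd.DataFrame(
        {
            "participant_id": [f"P{i:04d}" for i in range(n)],
            "family_id": [f"F{j:04d}" for j in fam_idx],
            "sex": sex,
            "age": np.round(age, 1),
            "bmi": np.round(bmi, 1),
            "height_cm": np.round(height, 1),
            "weight_kg": np.round(weight, 1),
            "ethnicity": eth,
            "education": edu,
            "menopause": meno,
        }
    )


def _make_ffq(cfg: SyntheticConfig, rng, sjl: np.ndarray, demo: pd.DataFrame):
    n = cfg.n_participants
    out = {"participant_id": demo["participant_id"]}
    for group, (mean, sd) in FOOD_GROUPS.items():
        shift = cfg.diet_effects.get(group, 0.0)
        floor = mean + min(shift, 0.0)
        noise = _shifted_gamma(rng, floor, sd, n)
        out[group] = np.round(mean + shift * sjl + noise, 2)
    out["total_energy_kcal"] = np.round(np.clip(rng.normal(2000, 400, n), 900, 4200), 0)
    out["n_unanswered"] = rng.poisson(0.8, n)
    out["alcohol_g"] = np.round(rng.gamma(1.2, 9.0, n), 1)
    return pd.DataFrame(out)


def _make_abundance(cfg: SyntheticConfig, rng, sjl: np.ndarray, demo, ffq):
    n, S = cfg.n_participants, cfg.n_species
    names = [f"SGB{5000 + j:05d}" for j in range(S)]
    direct = list(range(cfg.n_direct_species))
    mediated = list(
        range(cfg.n_direct_species, cfg.n_direct_species + cfg.n_mediated_species)
    )
    planted = set(direct) | set(mediated)

    fam_u = {}
    u_map = rng.normal(0.0, cfg.family_sd, demo["family_id"].nunique())
    for j, fam in enumerate(sorted(demo["family_id"].unique())):
        fam_u[fam] = u_map[j]
    u = demo["family_id"].map(fam_u).to_numpy()

    X = sjl.astype(float)
    mediator = ffq[cfg.mediator_group].to_numpy(float)
    m_center = mediator - FOOD_GROUPS[cfg.mediator_group][0]

    ab = np.zeros((n, S))
    truth_species = []
    sigma = 0.04
    for rank, j in enumerate(direct):
        mu = rng.uniform(0.12, 0.20)
        sign = 1.0 if rank % 2 == 0 else -1.0
        beta = sign * cfg.effect_size_d * np.sqrt(sigma**2 + cfg.family_sd**2)
        z = mu + beta * X + u + rng.normal(0, sigma, n)
        ab[:, j] = np.sin(np.clip(z, 0.0, np.pi / 2 - 1e-6)) ** 2
        truth_species.append(
            {
                "species": names[j],
                "kind": "direct",
                "mu": mu,
                "effect": beta,
                "target_d": sign * cfg.effect_size_d,
            }
        )
    a_path = cfg.diet_effects.get(cfg.mediator_group, 0.0)
    for j in mediated:
        mu = rng.uniform(0.12, 0.20)
        total = -cfg.effect_size_d * sigma  # mediated species lower in SJL
        b = cfg.mediated_fraction * total / a_path if a_path else 0.0
        c_prime = (1 - cfg.mediated_fraction) * total
        z = mu + c_prime * X + b * m_center + u + rng.normal(0, sigma, n)
        ab[:, j] = np.sin(np.clip(z, 0.0, np.pi / 2 - 1e-6)) ** 2
        truth_species.append(
            {
                "species": names[j],
                "kind": "mediated",
                "mu": mu,
                "a": a_path,
                "b": b,
                "c_prime": c_prime,
                "total": total,
                "prop_mediated": cfg.mediated_fraction,
                "mediator": cfg.mediator_group,
            }
        )
    # null species: log-normal intensities, per-species Bernoulli detection
    for j in range(S):
        if j in planted:
            continue
        mean_ab = 10 ** rng.uniform(-4, -2)
        vals = np.exp(rng.normal(np.log(mean_ab), 1.0, n))
        detect_p = rng.uniform(0.10, 0.95)
        vals *= rng.random(n) < detect_p
        ab[:, j] = np.minimum(vals, 0.02)

    # closure: a filler taxon absorbs each sample's remainder; rows whose
    # species already exceed 0.9 are rescaled (rare) so the filler stays
    # positive
    row_sum = ab.sum(axis=1)
    over = row_sum > 0.9
    if over.any():
        ab[over] *= (0.9 / row_sum[over])[:, None]
        row_sum = ab.sum(axis=1)
    filler = 1.0 - row_sum
    table = pd.DataFrame(ab, columns=names, index=demo["participant_id"])
    table.insert(0, "FILLER_remainder", filler)
    table.index.name = "participant_id"

    truth = {
        "direct_species": [names[j] for j in direct],
        "mediated_species": [names[j] for j in mediated],
        "null_species": [names[j] for j in range(S) if j not in planted],
        "filler_species": "FILLER_remainder",
        "species_effects": truth_species,
        "residual_sd_transformed": sigma,
    }
    return table, truth


def _make_meals(cfg: SyntheticConfig, rng, sjl: np.ndarray, demo) -> pd.DataFrame:
    rows_pid, rows_ts, rows_kcal = [], [], []
    base = _BASE_DATE.normalize() + pd.Timedelta(days=7)
    for i, pid in enumerate(demo["participant_id"]):
        late = 30.0 if sjl[i] else 0.0  # SJL: delayed first meal
        n_snacks_mean = 1.0 if sjl[i] else 1.6  # SJL: fewer eating occasions
        for d in range(cfg.n_meal_days):
            day = base + pd.Timedelta(days=int(d))
            times, kcals = [], []
            for anchor, mu_kcal in ((8 * 60 + late, 550), (13 * 60, 650), (19 * 60, 750)):
                t0 = anchor + rng.normal(0, 35)
                total = max(rng.normal(mu_kcal, 140), 280)
                if rng.random() < 0.3:  # meal logged as two close events
                    split = rng.uniform(0.3, 0.7)
                    times += [t0, t0 + rng.uniform(5, 20)]
                    kcals += [total * split, total * (1 - split)]
                else:
                    times.append(t0)
                    kcals.append(total)
            for _ in range(rng.poisson(n_snacks_mean)):
                times.append(rng.uniform(9.5 * 60, 22 * 60))
                kcals.append(max(rng.normal(150, 60), 55))
            if rng.random() < 0.25:  # a sub-50 kcal isolated nibble
                times.append(rng.uniform(10 * 60, 21.5 * 60))
                kcals.append(rng.uniform(15, 45))
            order = np.argsort(times)
            for k in order:
                rows_pid.append(pid)
                rows_ts.append(day + pd.Timedelta(minutes=float(times[k])))
                rows_kcal.append(round(float(kcals[k]), 1))
    return pd.DataFrame(
        {"participant_id": rows_pid, "timestamp": rows_ts, "energy_kcal": rows_kcal}
    )


def generate_cgm_trace(
    participant_id: str,
    days: int = 14,
    seed: int | None = None,
    start=None,
    constant: float | None = None,
) -> pd.DataFrame:
    """One participant's CGM trace: one reading per 15-minute slot for
    ``days`` days, starting at the device-fit timestamp (first row).

    ``constant`` replaces the profile by a flat trace (CV = 0
    downstream).  The profile is a personal baseline plus a diurnal
    oscillation, post-meal excursions at typical meal hours, and
    smoothed sensor noise.
    """
    if days <= 0:
        raise ValueError("days must be >= 1")
    rng = np.random.default_rng(seed)
    n = 96 * int(days)
    fit = pd.Timestamp(start) if start is not None else _BASE_DATE
    ts = fit + pd.to_timedelta(np.arange(n) * 15, unit="m")
    if constant is not None:
        glucose = np.full(n, float(constant))
    else:
        hours = (ts - ts[0].normalize()) / pd.Timedelta(hours=1)
        hod = np.mod(hours, 24.0)
        baseline = rng.normal(5.0, 0.35)
        diurnal = 0.2 * np.sin(2 * np.pi * (hod - 10) / 24)
        bumps = np.zeros(n)
        for meal_h in (8, 13, 19):
            amp = rng.normal(1.3, 0.35, int(days))
            day_idx = (hours // 24).astype(int)
            bumps += np.maximum(amp[np.clip(day_idx, 0, days - 1)], 0.2) * np.exp(
                -0.5 * ((hod - meal_h - 0.75) / 0.8) ** 2
            )
        noise = rng.normal(0, 0.22, n)
        noise = np.convolve(noise, np.ones(3) / 3, mode="same")  # sensor smoothing
        glucose = np.maximum(baseline + diurnal + bumps + noise, 2.5)
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "timestamp": ts,
            "glucose_mmol": np.round(glucose, 2),
        }
    )


_PP_TEMPLATES = {
    # analyte: (baseline mean, baseline sd, peak amplitude mean, sd, peak minute)
    "glucose": (5.0, 0.4, 2.2, 0.6, 45.0),
    "insulin": (6.0, 2.0, 45.0, 15.0, 45.0),
    "triglyceride": (1.05, 0.35, 0.8, 0.3, 240.0),
}


def generate_postprandial_series(
    participant_id: str,
    analyte: str,
    seed: int | None = None,
    flat: bool = False,
) -> pd.DataFrame:
    """Postprandial concentration series on the 10-point protocol grid
    (0–360 min).  ``flat`` pins every value at baseline (zero iAUC)."""
    if analyte not in POSTPRANDIAL_ANALYTES:
        raise ValueError(f"unknown analyte {analyte!r}")
    rng = np.random.default_rng(seed)
    t = PROTOCOL_MINUTES
    if analyte == "glyca":
        base = rng.normal(1.32, 0.18)
        rise = rng.normal(-0.03, 0.05)
        vals = base + rise * t / 360.0
        if not flat:
            vals = vals + np.where(t > 0, rng.normal(0, 0.004, t.size), 0.0)
        else:
            vals = np.full(t.size, base)
    else:
        b_mu, b_sd, a_mu, a_sd, tp = _PP_TEMPLATES[analyte]
        base = max(rng.normal(b_mu, b_sd), 0.1 * b_mu)
        if flat:
            vals = np.full(t.size, base)
        else:
            amp = max(rng.normal(a_mu, a_sd), 0.15 * a_mu)
            shape = (t / tp) * np.exp(1 - t / tp)
            vals = base + amp * shape + np.where(
                t > 0, rng.normal(0, 0.02 * (base + amp), t.size), 0.0
            )
            vals = np.maximum(vals, 0.05 * base)
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "analyte": analyte,
            "minute": t.astype(int),
            "value": np.round(vals, 4),
            "baseline": round(float(vals[0]), 4),
        }
    )


def _make_cgm(cfg, rng, demo) -> pd.DataFrame:
    traces = []
    for pid in demo["participant_id"]:
        traces.append(
            generate_cgm_trace(
                pid,
                days=cfg.cgm_days,
                seed=int(rng.integers(0, 2**31 - 1)),
                start=_BASE_DATE,
            )
        )
    return pd.concat(traces, ignore_index=True)


def _make_postprandial(cfg, rng, demo) -> pd.DataFrame:
    frames = []
    for pid in demo["participant_id"]:
        for analyte in POSTPRANDIAL_ANALYTES:
            frames.append(
                generate_postprandial_series(
                    pid, analyte, seed=int(rng.integers(0, 2**31 - 1))
                )
            )
    return pd.concat(frames, ignore_index=True)


def generate_cohort(
    config: SyntheticConfig | None = None,
    include: tuple = ("meals", "cgm", "postprandial"),
) -> CohortBundle:
    """Generate the full synthetic cohort.

    SJL status is assigned first; sleep times are then sampled so that
    re-deriving SJL from the generated bed/wake times reproduces the
    assigned status, diet intakes are baseline + group shift + noise, and
    mediated species depend on SJL through the mediator food group plus a
    direct path sized to the target proportion mediated.  ``include``
    selects the expensive tables (meal log, CGM, postprandial); the core
    tables (demographics, sleep, FFQ, abundance) are always produced.
    """
    cfg = config or SyntheticConfig()
    cfg.validate()
    seed = cfg.seed

    rng_status = _rng_child(seed, "status")
    n = cfg.n_participants
    sjl = rng_status.random(n) < cfg.sjl_prevalence
    non_sjl_idx = np.flatnonzero(~sjl)
    if cfg.n_negative_sjl > cfg.n_participants - int(sjl.sum()):
        raise ValueError("n_negative_sjl exceeds available non-SJL participants")
    neg_idx = rng_status.choice(non_sjl_idx, size=cfg.n_negative_sjl, replace=False)

    demo = _make_demographics(cfg, _rng_child(seed, "demographics"), sjl)
    sleep = _make_sleep(cfg, _rng_child(seed, "sleep"), sjl, neg_idx)
    sleep.insert(0, "participant_id", demo["participant_id"])
    ffq = _make_ffq(cfg, _rng_child(seed, "ffq"), sjl, demo)
    abundance, truth = _make_abundance(
        cfg, _rng_child(seed, "abundance"), sjl, demo, ffq
    )

    meals = (
        _make_meals(cfg, _rng_child(seed, "meals"), sjl, demo)
        if "meals" in include
        else pd.DataFrame(columns=["participant_id", "timestamp", "energy_kcal"])
    )
    cgm = (
        _make_cgm(cfg, _rng_child(seed, "cgm"), demo)
        if "cgm" in include
        else pd.DataFrame(columns=["participant_id", "timestamp", "glucose_mmol"])
    )
    pp = (
        _make_postprandial(cfg, _rng_child(seed, "postprandial"), demo)
        if "postprandial" in include
        else pd.DataFrame(
            columns=["participant_id", "analyte", "minute", "value", "baseline"]
        )
    )

    truth.update(
        {
            "sjl_status": {
                pid: bool(s) for pid, s in zip(demo["participant_id"], sjl)
            },
            "n_sjl": int(sjl.sum()),
            "negative_sjl_ids": [demo["participant_id"].iloc[i] for i in neg_idx],
            "config": asdict(cfg),
        }
    )
    return CohortBundle(
        demographics=demo,
        sleep=sleep,
        meals=meals,
        ffq=ffq,
        cgm=cgm,
        postprandial=pp,
        abundance=abundance,
        ground_truth=truth,
    )


def write_bundle(bundle: CohortBundle, out_dir) -> Path:
    """Write the bundle as a directory of CSVs plus ground_truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in CohortBundle._TABLES:
        df: pd.DataFrame = getattr(bundle, name)
        df.to_csv(out / f"{name}.csv", index=(name == "abundance"))
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(bundle.ground_truth, fh, indent=1, default=str)
    return out


def read_bundle(in_dir) -> CohortBundle:
    """Read a bundle written by :func:`write_bundle`."""
    p = Path(in_dir)
    tables = {}
    for name in CohortBundle._TABLES:
        kwargs = {"index_col": 0} if name == "abundance" else {}
        tables[name] = pd.read_csv(p / f"{name}.csv", **kwargs)
    with open(p / "ground_truth.json") as fh:
        truth = json.load(fh)
    return CohortBundle(ground_truth=truth, **tables)
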