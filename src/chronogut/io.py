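"""Pipeline orchestration, configuration and table I/O.

Binds the stages — sleep derivation with exclusions, diet-timing and
diet-index features, metabolic markers, covariate-adjusted comparisons,
the microbiome screen and diet mediation — into one reproducible run
over a directory of CSV inputs (as written by the synthetic generator
or assembled from real exports), with per-stage CSV outputs, a
CONSORT-style exclusion-flow table, and a run manifest carrying the
config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diet, mediation, metabolic, screen, sleep

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "read_abundance",
    "exclusion_flow",
    "log_event",
]


def log_event(event: str, **payload) -> None:
    """Machine-readable JSON event line on stderr."""
    print(json.dumps({"event": event, **payload}, default=str), file=sys.stderr)


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run; defaults mirror the analysis
    constants (SJL cut-off 1.5 h, EO floor 50 kcal / 30 min gap, CGM
    range 3.9–5.6 mmol/L with 12 h discard, screen thresholds 20%
    prevalence / q < 0.2 / |d| > 0.2)."""

    input_dir: str = "."
    output_dir: str = "chronogut_out"
    sjl_threshold_h: float = 1.5
    eo_min_kcal: float = 50.0
    eo_gap_min: float = 30.0
    cgm_range: tuple = (3.9, 5.6)
    cgm_discard_h: float = 12.0
    prevalence_threshold: float = 0.20
    q_threshold: float = 0.20
    d_threshold: float = 0.20
    mediators: list = field(default_factory=lambda: ["nuts", "hPDI"])
    covariates: list = field(
        default_factory=lambda: ["sex", "age", "bmi", "ethnicity", "education"]
    )
    outcome_family: list = field(default_factory=list)  # ANCOVA outcomes
    n_sims: int = 1000
    run_discrimination: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "sjl_threshold_h", "eo_min_kcal", "eo_gap_min", "cgm_discard_h",
            "prevalence_threshold", "q_threshold", "d_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def analysis_config(self) -> dict:
        """Config without filesystem paths — what the analysis depends on."""
        d = asdict(self)
        d.pop("input_dir", None)
        d.pop("output_dir", None)
        return d

    def content_hash(self) -> str:
        payload = json.dumps(self.analysis_config(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


def read_abundance(path, dialect: str = "tidy_csv") -> pd.DataFrame:
    """Read a relative-abundance matrix into samples x species form.

    ``tidy_csv``: long table with sample, species, abundance columns (or
    a wide samples x species CSV with the sample ID as first column —
    detected automatically).  ``species_by_sample_tsv``: MetaPhlAn-style
    wide TSV, species rows x sample columns.  Rows whose sum is within
    1% of 1 are renormalised to exactly 1 (logged); rows further off
    raise.
    """
    if dialect == "species_by_sample_tsv":
        wide = pd.read_csv(path, sep="\t", index_col=0)
        table = wide.T
    elif dialect == "tidy_csv":
        df = pd.read_csv(path)
        lower = [c.lower() for c in df.columns]
        # long form is recognised by an explicit species column; anything
        # else is read as a wide samples x species matrix
        if "species" in lower:
            s_col, sp_col, a_col = df.columns[:3]
            table = df.pivot(index=s_col, columns=sp_col, values=a_col).fillna(0.0)
        else:
            table = pd.read_csv(path, index_col=0)
    else:
        raise ValueError(f"unknown abundance dialect {dialect!r}")
    if (table.to_numpy() < 0).any():
        raise ValueError("negative abundances in input")
    sums = table.sum(axis=1)
    off = (sums - 1.0).abs()
    bad = off > 0.01
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} sample row(s) do not sum to 1 within 1% "
            f"(worst: {sums[bad].iloc[0]:.4g})"
        )
    needs = off > 1e-9
    if needs.any():
        log_event("abundance_renormalised", n_rows=int(needs.sum()))
        table = table.div(sums, axis=0)
    return table


def exclusion_flow(logs: dict[str, "sleep.ExclusionLog"]) -> pd.DataFrame:
    """CONSORT-style counts: per stage and rule, removed and remaining."""
    frames = []
    for stage, lg in logs.items():
        f = lg.to_frame()
        f.insert(0, "stage", stage)
        frames.append(f)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["stage", "rule", "removed", "remaining"]
    )


def _require(path: Path, what: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"{what} table required but missing: {path}")
    return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute derive → compare → screen → mediate over an input directory.

    Expects ``demographics.csv``, ``sleep.csv`` and ``abundance.csv`` in
    ``config.input_dir`` (``meals.csv``, ``ffq.csv``, ``cgm.csv``,
    ``postprandial.csv`` optional).  Writes per-stage CSVs, an
    exclusion-flow table and ``manifest.json`` into ``config.output_dir``
    and returns the tables in memory.
    """
    config.validate()
    in_dir, out_dir = Path(config.input_dir), Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {}
    logs: dict = {}

    demo = pd.read_csv(_require(in_dir / "demographics.csv", "demographics"))
    sleep_q = pd.read_csv(_require(in_dir / "sleep.csv", "sleep questionnaire"))

    derived, sleep_log = sleep.derive_sleep(sleep_q)
    logs["sleep"] = sleep_log
    for rule, removed in zip(sleep_log.rules, sleep_log.removed):
        log_event("sleep_exclusion", rule=rule, removed=removed)
    derived.to_csv(out_dir / "sleep_derived.csv", index=False)
    report["sleep"] = derived
    kept = derived[derived["exclusion_reason"].isna()]

    features = demo.merge(
        kept[["participant_id", "sjl_h", "sjl_flag", "habitual_sleep_h",
              "duration_category", "chronotype"]],
        on="participant_id",
        how="inner",
    )

    ffq_path = in_dir / "ffq.csv"
    if ffq_path.exists():
        ffq = pd.read_csv(ffq_path)
        groups = [g for g in diet.DEFAULT_GROUP_CLASSES if g in ffq.columns]
        classes = {g: diet.DEFAULT_GROUP_CLASSES[g] for g in groups}
        bmr = demo.apply(
            lambda r: diet.harris_benedict_bmr(
                r["sex"], r["weight_kg"], r["height_cm"], r["age"]
            ),
            axis=1,
        )
        bmr.index = demo["participant_id"]
        ffq = ffq.set_index("participant_id")
        valid, ratios = [], []
        for pid, row in ffq.iterrows():
            ok, ratio = diet.ffq_exclusion(
                row["total_energy_kcal"], bmr[pid], int(row.get("n_unanswered", 0))
            )
            valid.append(ok)
            ratios.append(ratio)
        ffq["ei_bmr_ratio"] = ratios
        ffq["ffq_valid"] = valid
        ffq_lg = sleep.ExclusionLog()
        ffq_lg.record("ffq_implausible", int(len(ffq) - sum(valid)), int(sum(valid)))
        logs["ffq"] = ffq_lg
        scored = diet.score_pdi_family(ffq.loc[valid, groups], classes)
        ffq = ffq.join(scored)
        ffq.reset_index().to_csv(out_dir / "ffq_scored.csv", index=False)
        report["ffq"] = ffq.reset_index()
        features = features.merge(
            ffq.reset_index()[
                ["participant_id", "PDI", "hPDI", "uPDI", "alcohol_g"] + groups
            ],
            on="participant_id",
            how="left",
        )

    meals_path = in_dir / "meals.csv"
    if meals_path.exists():
        meals = pd.read_csv(meals_path)
        if len(meals):
            diet_feats = diet.derive_diet_features(meals, demo)
            diet_feats.to_csv(out_dir / "diet_features.csv", index=False)
            report["diet"] = diet_feats
            features = features.merge(diet_feats, on="participant_id", how="left")

    pp_path, cgm_path = in_dir / "postprandial.csv", in_dir / "cgm.csv"
    pp = pd.read_csv(pp_path) if pp_path.exists() else None
    cgm = pd.read_csv(cgm_path) if cgm_path.exists() else None
    if (pp is not None and len(pp)) or (cgm is not None and len(cgm)):
        metab = metabolic.derive_metabolic(pp, cgm)
        metab.to_csv(out_dir / "metabolic_markers.csv", index=False)
        report["metabolic"] = metab
        features = features.merge(metab, on="participant_id", how="left")

    features.to_csv(out_dir / "participant_features.csv", index=False)
    report["features"] = features

    # covariate-adjusted comparisons across the configured outcome family
    from .stats import compare_outcomes

    outcomes = config.outcome_family or [
        c
        for c in (
            "hPDI", "uPDI", "PDI", "nuts", "fruits", "potatoes",
            "sugar_sweetened_beverages", "n_eating_occasions", "eating_window_h",
            "glucose_iauc", "insulin_iauc", "triglyceride_iauc",
            "glyca_rise_6h", "cgm_cv_pct", "cgm_tir_pct",
        )
        if c in features.columns
    ]
    if outcomes:
        comparisons = compare_outcomes(
            features, outcomes, group="sjl_flag", covariates=config.covariates
        )
        comparisons.to_csv(out_dir / "comparisons.csv", index=False)
        report["comparisons"] = comparisons

    ab_path = in_dir / "abundance.csv"
    if ab_path.exists():
        ab = read_abundance(ab_path)
        labels = kept.set_index("participant_id")["sjl_flag"]
        shared = ab.index.intersection(labels.index)
        table = screen.AbundanceTable(
            abundances=ab.loc[shared], groups=labels.loc[shared].astype(bool)
        )
        scr = screen.screen_species(
            table,
            prevalence_threshold=config.prevalence_threshold,
            q_threshold=config.q_threshold,
            d_threshold=config.d_threshold,
        )
        scr.table.to_csv(out_dir / "screen.csv", index=False)
        report["screen"] = scr
        prev_diff = screen.prevalence_difference_screen(
            table, config.prevalence_threshold
        )
        prev_diff.to_csv(out_dir / "prevalence_difference.csv", index=False)
        report["prevalence_difference"] = prev_diff
        if config.run_discrimination:
            disc = screen.bootstrap_discrimination(table, seed=config.seed)
            report["discrimination"] = disc
            with open(out_dir / "discrimination.json", "w") as fh:
                json.dump(
                    {"median_auc": disc["median_auc"], "aucs": disc["aucs"]}, fh
                )

        # mediation over significant species x configured mediators
        sig_species = list(scr.significant["species"])
        mediators = [m for m in config.mediators if m in features.columns]
        if sig_species and mediators:
            med_data = features.merge(
                ab.loc[shared, sig_species],
                left_on="participant_id",
                right_index=True,
            )
            med_data["sjl_flag"] = med_data["sjl_flag"].astype(int)
            med_table = mediation.batch_mediate(
                med_data,
                mediators=mediators,
                outcomes=sig_species,
                exposure="sjl_flag",
                covariates=config.covariates,
                cluster="family_id" if "family_id" in med_data.columns else None,
                n_sims=config.n_sims,
                seed=config.seed,
            )
            med_table.to_csv(out_dir / "mediation.csv", index=False)
            report["mediation"] = med_table

    flow = exclusion_flow(logs)
    flow.to_csv(out_dir / "exclusion_flow.csv", index=False)
    report["exclusion_flow"] = flow

    manifest = {
        "config": config.analysis_config(),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "n_input": int(len(sleep_q)),
        "n_after_sleep_exclusions": int(len(kept)),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    report["manifest"] = manifest
    return report
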