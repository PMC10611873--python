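"""Covariate-adjusted cohort comparisons and supporting statistics.

Group differences between the social-jetlag (SJL) and no-SJL groups are
estimated ANCOVA-style: the outcome (Shapiro–Wilk-guided log/sqrt
transform when non-normal) is regressed on the group indicator plus
covariates (sex, age, BMI, ethnicity, education by default) and the
group coefficient reported, with optional cluster-robust standard
errors on family ID and BH-FDR across an outcome family.  Also here:
moderation (group x sex/age/menopause interaction models with
simple-effects contrasts), Pearson partial correlation by double
residualisation, greedy nearest-neighbour age matching, and the
chi-square test for categorical characteristics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps

from .screen import bh_fdr

__all__ = [
    "AdjustedComparison",
    "ancova_compare",
    "compare_outcomes",
    "interaction_model",
    "partial_correlation",
    "match_by_age",
    "MatchedCohort",
    "categorical_group_test",
    "kruskal_group_test",
    "select_transform",
]

DEFAULT_COVARIATES = ["sex", "age", "bmi", "ethnicity", "education"]


def select_transform(values: np.ndarray, alpha: float = 0.05) -> tuple[str, np.ndarray]:
    """Choose none/log/sqrt for an outcome by Shapiro–Wilk on raw data.

    When the raw outcome rejects normality (p < alpha), log (positive
    data only) and sqrt (non-negative only) candidates are evaluated and
    the transform maximising Shapiro–Wilk W is applied; otherwise the
    data are left untouched.
    """
    v = np.asarray(values, dtype=float)
    if np.unique(v).size < 3:
        raise ValueError("outcome is (near-)constant; nothing to compare")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p_raw = sps.shapiro(v)
    if p_raw >= alpha:
        return "none", v
    candidates: dict[str, np.ndarray] = {"none": v}
    if np.all(v > 0):
        candidates["log"] = np.log(v)
    if np.all(v >= 0):
        candidates["sqrt"] = np.sqrt(v)
    best_name, best_w = "none", -np.inf
    for name, tv in candidates.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w, _ = sps.shapiro(tv)
        if w > best_w:
            best_name, best_w = name, w
    return best_name, candidates[best_name]


@dataclass
class AdjustedComparison:
    """Covariate-adjusted group difference for one outcome."""

    outcome: str
    estimate: float  # adjusted difference, SJL minus no-SJL
    se: float
    p: float
    q: float | None
    transform: str
    covariates: list[str]
    n: int
    group_means: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {
            "outcome": self.outcome,
            "estimate": self.estimate,
            "se": self.se,
            "p": self.p,
            "q": self.q,
            "transform": self.transform,
            "n": self.n,
            "mean_sjl": self.group_means.get("sjl"),
            "mean_no_sjl": self.group_means.get("no_sjl"),
        }


def _rhs(terms: list[str], data: pd.DataFrame) -> str:
    out = []
    for t in terms:
        if data[t].dtype == object or isinstance(
            data[t].dtype, pd.CategoricalDtype
        ) or data[t].dtype == bool:
            out.append(f"C(Q('{t}'))")
        else:
            out.append(f"Q('{t}')")
    return " + ".join(out)


def ancova_compare(
    data: pd.DataFrame,
    outcome: str,
    group: str = "sjl_flag",
    covariates: list[str] | None = None,
    family_cluster: str | None = None,
    transform: str | None = None,
) -> AdjustedComparison:
    """ANCOVA-style adjusted comparison of one outcome between groups.

    ``transform=None`` selects none/log/sqrt by Shapiro–Wilk; pass an
    explicit name to force it.  ``family_cluster`` switches the group
    test to cluster-robust standard errors on that column.
    """
    covariates = DEFAULT_COVARIATES if covariates is None else covariates
    cols = [outcome, group] + covariates + ([family_cluster] if family_cluster else [])
    df = data[cols].dropna().copy()
    df[group] = df[group].astype(int)
    if transform is None:
        tname, tvals = select_transform(df[outcome].to_numpy())
    else:
        tname = transform
        v = df[outcome].to_numpy(float)
        tvals = {"none": v, "log": np.log, "sqrt": np.sqrt}[tname](v) if tname != "none" else v
    df["_y"] = tvals

    formula = f"_y ~ Q('{group}')"
    if covariates:
        formula += " + " + _rhs(covariates, df)
    model = smf.ols(formula, data=df)
    if family_cluster:
        res = model.fit(
            cov_type="cluster", cov_kwds={"groups": df[family_cluster]}
        )
    else:
        res = model.fit()
    term = f"Q('{group}')"
    return AdjustedComparison(
        outcome=outcome,
        estimate=float(res.params[term]),
        se=float(res.bse[term]),
        p=float(res.pvalues[term]),
        q=None,
        transform=tname,
        covariates=list(covariates),
        n=int(res.nobs),
        group_means={
            "sjl": float(df.loc[df[group] == 1, outcome].mean()),
            "no_sjl": float(df.loc[df[group] == 0, outcome].mean()),
        },
    )


def compare_outcomes(
    data: pd.DataFrame,
    outcomes: list[str],
    group: str = "sjl_flag",
    covariates: list[str] | None = None,
    family_cluster: str | None = None,
    fdr: bool = True,
) -> pd.DataFrame:
    """Adjusted comparisons for a family of outcomes, BH-corrected
    across the family (one q per outcome) when ``fdr``."""
    results = []
    for out in outcomes:
        try:
            results.append(
                ancova_compare(data, out, group, covariates, family_cluster)
            )
        except ValueError:
            continue
    table = pd.DataFrame([r.to_row() for r in results])
    if fdr and len(table):
        table["q"] = bh_fdr(table["p"].to_numpy())
    return table


def interaction_model(
    data: pd.DataFrame,
    outcome: str,
    moderator: str,
    group: str = "sjl_flag",
    covariates: list[str] | None = None,
) -> dict:
    """Moderation: does the group effect depend on the moderator?

    Fits ``outcome ~ group * moderator + covariates``; returns the
    interaction term(s) with p-values, an overall interaction F-test,
    and — for categorical moderators — the simple group effect within
    each moderator level.
    """
    covariates = DEFAULT_COVARIATES if covariates is None else covariates
    covariates = [c for c in covariates if c != moderator]
    cols = [outcome, group, moderator] + covariates
    df = data[cols].dropna().copy()
    df[group] = df[group].astype(int)
    categorical = (
        df[moderator].dtype == object
        or isinstance(df[moderator].dtype, pd.CategoricalDtype)
        or df[moderator].dtype == bool
    )
    if categorical:
        levels = df[moderator].astype(str).unique()
        if len(levels) < 2:
            raise ValueError(f"moderator {moderator!r} has a single level")
        counts = df.groupby([group, df[moderator].astype(str)]).size()
        full = pd.MultiIndex.from_product([[0, 1], levels])
        empty = [idx for idx in full if idx not in counts.index]
        if empty:
            raise ValueError(f"empty group x moderator cell(s): {empty}")
        mod_term = f"C(Q('{moderator}'))"
    else:
        mod_term = f"Q('{moderator}')"
    formula = f"Q('{outcome}') ~ Q('{group}') * {mod_term}"
    if covariates:
        formula += " + " + _rhs(covariates, df)
    res = smf.ols(formula, data=df).fit()
    inter_terms = [t for t in res.params.index if ":" in t]
    ftest = res.f_test([f"{t} = 0" for t in inter_terms])
    out = {
        "interaction_terms": {
            t: {"estimate": float(res.params[t]), "p": float(res.pvalues[t])}
            for t in inter_terms
        },
        "interaction_f_p": float(ftest.pvalue),
        "n": int(res.nobs),
    }
    if categorical:
        simple = {}
        for lev in sorted(df[moderator].astype(str).unique()):
            sub = df[df[moderator].astype(str) == lev]
            f2 = f"Q('{outcome}') ~ Q('{group}')"
            if covariates:
                f2 += " + " + _rhs(covariates, sub)
            try:
                r2 = smf.ols(f2, data=sub).fit()
                simple[lev] = {
                    "estimate": float(r2.params[f"Q('{group}')"]),
                    "p": float(r2.pvalues[f"Q('{group}')"]),
                    "n": int(r2.nobs),
                }
            except Exception:  # noqa: BLE001 - level too sparse to fit
                simple[lev] = {"estimate": np.nan, "p": np.nan, "n": len(sub)}
        out["simple_effects"] = simple
    return out


def partial_correlation(x, y, covariates) -> tuple[float, float]:
    """Pearson partial correlation of x and y given covariates.

    Both variables are residualised on the covariates (with intercept)
    and the residuals correlated; p from the t distribution with
    n - k - 2 degrees of freedom (k covariates).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = np.column_stack([np.ones(x.size), np.asarray(covariates, dtype=float)])
    k = Z.shape[1] - 1
    if x.size <= k + 2:
        raise ValueError("need n > n_covariates + 2")
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("collinear covariates")
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    r = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    df_resid = x.size - k - 2
    r_clamped = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_clamped * np.sqrt(df_resid / (1 - r_clamped**2))
    p = float(2 * sps.t.sf(abs(t), df_resid))
    return r, p


@dataclass
class MatchedCohort:
    """1:1 age-matched pairs of SJL participants and controls."""

    pairs: list[tuple]  # (sjl_id, control_id)
    pre_mean_diff: float  # mean(SJL ages) - mean(control ages), before
    post_mean_diff: float  # same, over matched pairs
    unmatched_sjl: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["sjl_id", "control_id"])


def match_by_age(
    data: pd.DataFrame,
    group: str = "sjl_flag",
    age: str = "age",
    id_col: str = "participant_id",
    caliper: float = 2.0,
    seed: int | None = None,
) -> MatchedCohort:
    """Greedy nearest-neighbour 1:1 age matching without replacement.

    Controls are first restricted to the SJL group's age range widened
    by the caliper; SJL participants are then processed in seeded random
    order, each taking the nearest remaining control by age (ties to the
    younger control).  SJL participants with no control within the
    caliper are dropped and listed in ``unmatched_sjl``.
    """
    df = data[[id_col, group, age]].dropna()
    sjl = df[df[group].astype(bool)]
    ctrl = df[~df[group].astype(bool)]
    if len(sjl) == 0 or len(ctrl) == 0:
        raise ValueError("both groups must be non-empty")
    lo, hi = sjl[age].min() - caliper, sjl[age].max() + caliper
    ctrl = ctrl[(ctrl[age] >= lo) & (ctrl[age] <= hi)]
    if len(ctrl) == 0:
        raise ValueError("no controls within the overlapping age range")

    pre = float(sjl[age].mean() - df.loc[~df[group].astype(bool), age].mean())
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sjl))
    avail = ctrl.sort_values([age, id_col]).reset_index(drop=True)
    taken = np.zeros(len(avail), dtype=bool)
    pairs, unmatched = [], []
    sjl_rows = sjl.reset_index(drop=True)
    for i in order:
        row = sjl_rows.iloc[i]
        free = np.where(~taken)[0]
        if free.size == 0:
            unmatched.append(row[id_col])
            continue
        dists = np.abs(avail[age].to_numpy()[free] - row[age])
        j = free[int(np.argmin(dists))]  # argmin ties -> youngest (sorted)
        if abs(avail[age].iloc[j] - row[age]) > caliper:
            unmatched.append(row[id_col])
            continue
        taken[j] = True
        pairs.append((row[id_col], avail[id_col].iloc[j]))
    if pairs:
        sjl_ages = {r[id_col]: r[age] for _, r in sjl_rows.iterrows()}
        ctrl_ages = {r[id_col]: r[age] for _, r in avail.iterrows()}
        post = float(
            np.mean([sjl_ages[a] for a, _ in pairs])
            - np.mean([ctrl_ages[b] for _, b in pairs])
        )
    else:
        post = float("nan")
    return MatchedCohort(
        pairs=pairs, pre_mean_diff=pre, post_mean_diff=post, unmatched_sjl=unmatched
    )


def categorical_group_test(counts, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a contingency table of counts by group x
    level (Yates continuity correction off by default)."""
    table = np.asarray(counts, dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero-margin row or column")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=correction)
    return float(chi2), float(p)


def kruskal_group_test(*samples) -> tuple[float, float]:
    """Kruskal–Wallis test for continuous characteristics across groups."""
    stat, p = sps.kruskal(*samples)
    return float(stat), float(p)
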