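"""Differential-abundance screening of gut microbial species between
social-jetlag groups.

The screen mirrors a prevalence-filter-then-rank-test design: species
must be present (relative abundance > 0) in at least 20% of samples in
*both* groups; retained species are compared with a two-sided
Mann–Whitney U test, Benjamini–Hochberg corrected across the retained
family only, and flagged significant under the dual criterion q < 0.2
AND |Cohen's d| > 0.2, with d computed on arcsine-square-root
transformed abundances (pooled-SD standardisation).  A complementary
prevalence-difference screen lists species prevalent in exactly one
group, and a bootstrap random-forest protocol measures whether the whole
composition discriminates the groups (median test AUC over stratified
80/20 resplits).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AbundanceTable",
    "ScreenResults",
    "prevalence",
    "cohens_d",
    "bh_fdr",
    "screen_species",
    "prevalence_difference_screen",
    "bootstrap_discrimination",
    "PREVALENCE_THRESHOLD",
    "Q_THRESHOLD",
    "D_THRESHOLD",
]

PREVALENCE_THRESHOLD = 0.20
Q_THRESHOLD = 0.20
D_THRESHOLD = 0.20


@dataclass
class AbundanceTable:
    """Samples x species relative-abundance matrix with binary group labels.

    ``abundances`` is a DataFrame (rows = samples, columns = species) of
    fractions in [0, 1]; ``groups`` a boolean Series aligned on the same
    index, True for the social-jetlag group.
    """

    abundances: pd.DataFrame
    groups: pd.Series

    def __post_init__(self):
        ab = self.abundances
        if (ab.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")
        sums = ab.sum(axis=1)
        if (sums > 1 + 1e-6).any():
            raise ValueError("sample abundances must sum to at most 1")
        self.groups = self.groups.reindex(ab.index).astype(bool)
        if self.groups.isna().any():
            raise ValueError("every sample needs a group label")

    @property
    def species(self) -> list[str]:
        return list(self.abundances.columns)

    def split(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(SJL samples, non-SJL samples)."""
        return (
            self.abundances.loc[self.groups],
            self.abundances.loc[~self.groups],
        )


def prevalence(table: AbundanceTable, group: bool) -> pd.Series:
    """Per-species prevalence within one group: the fraction of that
    group's samples with strictly positive abundance."""
    sub = table.abundances.loc[table.groups == group]
    if len(sub) == 0:
        raise ValueError("group is empty")
    return (sub > 0).mean(axis=0)


def cohens_d(x, y) -> float:
    """Cohen's d = (mean(x) - mean(y)) / pooled SD, with the pooled SD
    weighted by (n - 1).  NaN when the pooled SD is zero."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >= 2 values")
    nx, ny = x.size, y.size
    pooled_var = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if pooled_var <= 0:
        return float("nan")
    return float((x.mean() - y.mean()) / np.sqrt(pooled_var))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (q-values).

    q_(i) = min over j >= i of p_(j) * m / j for the sorted p-values,
    capped at 1; ties and original order are preserved on return.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


_EXACT_MAX_N = 20


def _mwu(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann–Whitney U: exact null when the combined sample is
    small and tie-free, otherwise the tie-corrected normal approximation
    with continuity correction."""
    combined = np.concatenate([x, y])
    exact = combined.size <= _EXACT_MAX_N and np.unique(combined).size == combined.size
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


@dataclass
class ScreenResults:
    """Result of a differential-abundance screen.

    ``table`` has one row per species passing the prevalence filter with
    prevalence per group, U, p, BH q, Cohen's d (arcsine-sqrt scale by
    default), the dual-criterion significance flag, and direction.
    """

    table: pd.DataFrame
    n_tested: int
    n_significant: int
    thresholds: dict = field(default_factory=dict)

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def summary(self) -> str:
        lines = [
            "Differential-abundance screen",
            f"  species tested (prevalence >= {self.thresholds['prevalence']:.0%}"
            f" in both groups): {self.n_tested}",
            f"  significant (q < {self.thresholds['q']} and |d| > "
            f"{self.thresholds['d']}): {self.n_significant}",
            f"    up in SJL:   {int((self.significant['direction'] == 'up_in_SJL').sum())}",
            f"    down in SJL: {int((self.significant['direction'] == 'down_in_SJL').sum())}",
        ]
        return "\n".join(lines)


def screen_species(
    table: AbundanceTable,
    prevalence_threshold: float = PREVALENCE_THRESHOLD,
    q_threshold: float = Q_THRESHOLD,
    d_threshold: float = D_THRESHOLD,
    d_scale: str = "arcsine_sqrt",
) -> ScreenResults:
    """Screen every species for differential abundance between groups.

    Species prevalent in >= ``prevalence_threshold`` of BOTH groups are
    tested (Mann–Whitney U on raw relative abundances, two-sided); BH
    correction runs across the retained family only; d is computed on
    arcsine-sqrt transformed abundances unless ``d_scale="raw"``.
    """
    sjl, ctrl = table.split()
    if len(sjl) < 2 or len(ctrl) < 2:
        raise ValueError("both groups need >= 2 samples")
    prev_sjl = (sjl > 0).mean(axis=0)
    prev_ctrl = (ctrl > 0).mean(axis=0)
    keep = (prev_sjl >= prevalence_threshold) & (prev_ctrl >= prevalence_threshold)
    kept = [s for s in table.species if keep[s]]

    rows = []
    for sp in kept:
        x = sjl[sp].to_numpy(float)
        y = ctrl[sp].to_numpy(float)
        u, p = _mwu(x, y)
        if d_scale == "arcsine_sqrt":
            d = cohens_d(np.arcsin(np.sqrt(x)), np.arcsin(np.sqrt(y)))
        elif d_scale == "raw":
            d = cohens_d(x, y)
        else:
            raise ValueError(f"unknown d scale {d_scale!r}")
        rows.append(
            {
                "species": sp,
                "prevalence_sjl": float(prev_sjl[sp]),
                "prevalence_no_sjl": float(prev_ctrl[sp]),
                "U": u,
                "p": p,
                "d": d,
            }
        )
    out = pd.DataFrame(
        rows, columns=["species", "prevalence_sjl", "prevalence_no_sjl", "U", "p", "d"]
    )
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
        out["significant"] = (out["q"] < q_threshold) & (out["d"].abs() > d_threshold)
        out["direction"] = np.where(out["d"] >= 0, "up_in_SJL", "down_in_SJL")
    else:
        out["q"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
        out["direction"] = pd.Series(dtype=object)
    return ScreenResults(
        table=out,
        n_tested=len(out),
        n_significant=int(out["significant"].sum()) if len(out) else 0,
        thresholds={"prevalence": prevalence_threshold, "q": q_threshold, "d": d_threshold},
    )


def prevalence_difference_screen(
    table: AbundanceTable, threshold: float = PREVALENCE_THRESHOLD
) -> pd.DataFrame:
    """Species prevalent (>= threshold) in exactly one group, with the
    absolute prevalence difference, sorted descending."""
    prev_sjl = prevalence(table, True)
    prev_ctrl = prevalence(table, False)
    one_sided = (prev_sjl >= threshold) ^ (prev_ctrl >= threshold)
    out = pd.DataFrame(
        {
            "species": prev_sjl.index[one_sided],
            "prevalence_sjl": prev_sjl[one_sided].to_numpy(),
            "prevalence_no_sjl": prev_ctrl[one_sided].to_numpy(),
        }
    )
    out["abs_prevalence_diff"] = (
        out["prevalence_sjl"] - out["prevalence_no_sjl"]
    ).abs()
    out["prevalent_in"] = np.where(
        out["prevalence_sjl"] >= threshold, "SJL_only", "no_SJL_only"
    )
    return out.sort_values(
        "abs_prevalence_diff", ascending=False, kind="stable"
    ).reset_index(drop=True)


def bootstrap_discrimination(
    table: AbundanceTable,
    n_iter: int = 100,
    train_frac: float = 0.8,
    seed: int | None = None,
    n_estimators: int = 100,
) -> dict:
    """Whole-composition discrimination of the groups by random forest.

    Per iteration a stratified ``train_frac`` / (1 - train_frac) split is
    drawn, a random forest trained on all species features, and the test
    ROC AUC recorded; the summary statistic is the median AUC across
    iterations.  Splits whose test half lacks a class are redrawn (and
    counted).
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import train_test_split

    rng = np.random.default_rng(seed)
    X = table.abundances.to_numpy(float)
    y = table.groups.to_numpy(bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    aucs = []
    n_resampled = 0
    for _ in range(n_iter):
        for _attempt in range(20):
            split_seed = int(rng.integers(0, 2**31 - 1))
            X_tr, X_te, y_tr, y_te = train_test_split(
                X, y, train_size=train_frac, stratify=y, random_state=split_seed
            )
            if y_te.any() and not y_te.all():
                break
            n_resampled += 1
        clf = RandomForestClassifier(
            n_estimators=n_estimators,
            random_state=int(rng.integers(0, 2**31 - 1)),
            n_jobs=1,
        )
        clf.fit(X_tr, y_tr)
        scores = clf.predict_proba(X_te)[:, 1]
        aucs.append(float(roc_auc_score(y_te, scores)))
    return {
        "median_auc": float(np.median(aucs)),
        "aucs": aucs,
        "n_resampled_splits": n_resampled,
    }
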