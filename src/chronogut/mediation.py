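"""Causal mediation of social-jetlag effects on species abundance
through diet.

The estimand follows the classic linear product-of-coefficients
decomposition with simulation-based inference:

* mediator model:  M = a*X + covariates (+ family random intercept)
* outcome model:   Y = c'*X + b*M + covariates (+ family random intercept)

with X the binary SJL exposure, M a diet variable (e.g. hPDI or nut
intake) and Y the arcsine-square-root transformed relative abundance of
one species.  Point estimates are ACME = a*b (average causal mediation
effect, the indirect path), ADE = c' (average direct effect) and total
effect = c' + a*b; with no exposure–mediator interaction these satisfy
ACME + ADE = total exactly.  Inference is quasi-Bayesian: coefficient
vectors are drawn from the asymptotic normal of each fitted model,
ACME/ADE/total recomputed per draw, and two-sided p-values and 95%
intervals read off the simulation distribution.  The proportion
mediated is summarised by the median of ACME/total over draws.

Family relatedness (twin pairs) enters as a random intercept on the
family ID in both models (``statsmodels`` MixedLM); without a cluster
column plain OLS is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "transform_abundance",
    "MediationSpec",
    "MediationModel",
    "MediationResults",
    "fit_mediation",
    "batch_mediate",
]


def transform_abundance(p):
    """Arcsine-square-root transform arcsin(sqrt(p)), radians, for
    relative abundances p in [0, 1]; variance-stabilising for
    proportions."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("relative abundances must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


@dataclass
class MediationSpec:
    """One mediation question: exposure -> mediator -> outcome.

    ``outcome_is_abundance`` applies the arcsine-sqrt transform to the
    outcome column before modelling.
    """

    exposure: str
    mediator: str
    outcome: str
    covariates: list[str] = field(default_factory=list)
    cluster: str | None = None
    n_sims: int = 1000
    seed: int | None = None
    outcome_is_abundance: bool = True

    def __post_init__(self):
        if self.n_sims < 100:
            raise ValueError("n_sims must be >= 100 for stable tail estimates")


def _formula(lhs: str, rhs_terms: list[str], data: pd.DataFrame) -> str:
    terms = []
    for t in rhs_terms:
        if data[t].dtype == object or isinstance(
            data[t].dtype, pd.CategoricalDtype
        ) or data[t].dtype == bool:
            terms.append(f"C(Q('{t}'))")
        else:
            terms.append(f"Q('{t}')")
    return f"Q('{lhs}') ~ " + " + ".join(terms)


def _fit_linear(formula: str, data: pd.DataFrame, cluster: str | None):
    """Fit OLS, or MixedLM with a random intercept when clustered.
    Returns (params, cov) for the fixed effects."""
    if cluster is None:
        res = smf.ols(formula, data=data).fit()
        return res.params, res.cov_params(), res
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=data, groups=data[cluster])
        try:
            res = model.fit(reml=True)
        except np.linalg.LinAlgError:
            res = model.fit(reml=True, method="powell")
    params = res.fe_params
    cov = res.cov_params().loc[params.index, params.index]
    return params, cov, res


@dataclass
class MediationResults:
    """Estimates and simulation-based inference for one mediation fit."""

    acme: float
    ade: float
    total: float
    prop_mediated: float
    acme_ci: tuple[float, float]
    ade_ci: tuple[float, float]
    total_ci: tuple[float, float]
    prop_mediated_ci: tuple[float, float]
    acme_p: float
    ade_p: float
    total_p: float
    n_obs: int
    n_sims: int
    spec: MediationSpec
    paths: dict = field(default_factory=dict)  # fitted a, b, c'
    flags: list[str] = field(default_factory=list)

    def summary(self) -> str:
        s = self.spec
        rows = [
            ("ACME (a*b)", self.acme, self.acme_ci, self.acme_p),
            ("ADE (c')", self.ade, self.ade_ci, self.ade_p),
            ("Total effect", self.total, self.total_ci, self.total_p),
            ("Prop. mediated", self.prop_mediated, self.prop_mediated_ci, None),
        ]
        lines = [
            "Causal mediation (quasi-Bayesian, "
            f"{self.n_sims} draws, n = {self.n_obs})",
            f"  exposure: {s.exposure}   mediator: {s.mediator}   "
            f"outcome: {s.outcome}",
            f"  {'':16s} {'estimate':>10s} {'95% CI':>22s} {'p':>8s}",
        ]
        for name, est, ci, p in rows:
            pstr = f"{p:8.4f}" if p is not None else "        "
            lines.append(
                f"  {name:16s} {est:10.4f} [{ci[0]:9.4f}, {ci[1]:9.4f}] {pstr}"
            )
        if self.flags:
            lines.append("  flags: " + ", ".join(self.flags))
        return "\n".join(lines)

    def to_row(self) -> dict:
        return {
            "exposure": self.spec.exposure,
            "mediator": self.spec.mediator,
            "outcome": self.spec.outcome,
            "acme": self.acme,
            "acme_lo": self.acme_ci[0],
            "acme_hi": self.acme_ci[1],
            "acme_p": self.acme_p,
            "ade": self.ade,
            "ade_lo": self.ade_ci[0],
            "ade_hi": self.ade_ci[1],
            "ade_p": self.ade_p,
            "total": self.total,
            "total_lo": self.total_ci[0],
            "total_hi": self.total_ci[1],
            "total_p": self.total_p,
            "prop_mediated": self.prop_mediated,
            "prop_mediated_lo": self.prop_mediated_ci[0],
            "prop_mediated_hi": self.prop_mediated_ci[1],
            "n_obs": self.n_obs,
            "flags": ";".join(self.flags),
        }


def _sim_p(draws: np.ndarray) -> float:
    """Two-sided simulation p-value: twice the smaller tail mass."""
    pos = float(np.mean(draws > 0))
    neg = float(np.mean(draws < 0))
    return min(1.0, 2.0 * min(pos, neg) + float(np.mean(draws == 0)))


class MediationModel:
    """Linear mediation model for one exposure–mediator–outcome triple.

    Built from a tidy participant-level DataFrame; ``fit()`` returns a
    :class:`MediationResults`.
    """

    def __init__(self, data: pd.DataFrame, spec: MediationSpec):
        cols = [spec.exposure, spec.mediator, spec.outcome] + list(spec.covariates)
        if spec.cluster:
            cols.append(spec.cluster)
        missing_cols = [c for c in cols if c not in data.columns]
        if missing_cols:
            raise KeyError(f"data lacks columns {missing_cols}")
        df = data[cols].dropna().copy()
        x = df[spec.exposure]
        uniq = set(pd.unique(x.dropna()))
        if not uniq <= {0, 1, True, False}:
            raise ValueError("exposure must be binary (0/1)")
        df[spec.exposure] = x.astype(int)
        if spec.outcome_is_abundance:
            df[spec.outcome] = transform_abundance(df[spec.outcome].to_numpy())
        self.data = df
        self.spec = spec

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **spec_kwargs) -> "MediationModel":
        return cls(data, MediationSpec(**spec_kwargs))

    def fit(self, method: str = "quasi_bayesian") -> MediationResults:
        spec = self.spec
        df = self.data
        rng = np.random.default_rng(spec.seed)

        med_formula = _formula(spec.mediator, [spec.exposure] + spec.covariates, df)
        out_formula = _formula(
            spec.outcome, [spec.exposure, spec.mediator] + spec.covariates, df
        )
        x_term = f"Q('{spec.exposure}')"
        m_term = f"Q('{spec.mediator}')"
        try:
            med_params, med_cov, _ = _fit_linear(med_formula, df, spec.cluster)
        except Exception as exc:  # noqa: BLE001 - re-raise with context
            raise RuntimeError(f"mediator model failed: {spec.mediator}: {exc}") from exc
        try:
            out_params, out_cov, _ = _fit_linear(out_formula, df, spec.cluster)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"outcome model failed: {spec.outcome}: {exc}") from exc
        for term, params, what in (
            (x_term, med_params, "mediator model"),
            (x_term, out_params, "outcome model"),
            (m_term, out_params, "outcome model"),
        ):
            if term not in params.index:
                raise RuntimeError(f"{what} is singular in term {term}")

        a_hat = float(med_params[x_term])
        b_hat = float(out_params[m_term])
        c_hat = float(out_params[x_term])

        if method == "quasi_bayesian":
            a_draws = rng.multivariate_normal(
                med_params.to_numpy(), med_cov.to_numpy(), size=spec.n_sims,
                method="cholesky",
            )[:, list(med_params.index).index(x_term)]
            out_draw = rng.multivariate_normal(
                out_params.to_numpy(), out_cov.to_numpy(), size=spec.n_sims,
                method="cholesky",
            )
            b_draws = out_draw[:, list(out_params.index).index(m_term)]
            c_draws = out_draw[:, list(out_params.index).index(x_term)]
        elif method == "bootstrap":
            a_draws, b_draws, c_draws = self._bootstrap_draws(
                df, med_formula, out_formula, x_term, m_term, rng
            )
        else:
            raise ValueError(f"unknown inference method {method!r}")

        acme_draws = a_draws * b_draws
        ade_draws = c_draws
        total_draws = acme_draws + ade_draws

        flags = []
        total_hat = c_hat + a_hat * b_hat
        with np.errstate(divide="ignore", invalid="ignore"):
            prop_draws = np.where(total_draws != 0, acme_draws / total_draws, np.nan)
        prop_hat = float(np.nanmedian(prop_draws))
        # unstable when the total effect is indistinguishable from zero
        if _sim_p(total_draws) > 0.2:
            flags.append("total_effect_near_zero")
        if prop_hat < 0 or prop_hat > 1:
            flags.append("prop_mediated_outside_unit_interval")

        def ci(d):
            lo, hi = np.nanpercentile(d, [2.5, 97.5])
            return (float(lo), float(hi))

        return MediationResults(
            acme=a_hat * b_hat,
            ade=c_hat,
            total=total_hat,
            prop_mediated=prop_hat,
            acme_ci=ci(acme_draws),
            ade_ci=ci(ade_draws),
            total_ci=ci(total_draws),
            prop_mediated_ci=ci(prop_draws),
            acme_p=_sim_p(acme_draws),
            ade_p=_sim_p(ade_draws),
            total_p=_sim_p(total_draws),
            n_obs=len(df),
            n_sims=spec.n_sims,
            spec=spec,
            paths={"a": a_hat, "b": b_hat, "c_prime": c_hat},
            flags=flags,
        )

    def _bootstrap_draws(self, df, med_formula, out_formula, x_term, m_term, rng):
        """Nonparametric bootstrap over participants (over whole families
        when a cluster column is present)."""
        spec = self.spec
        a, b, c = [], [], []
        if spec.cluster:
            fams = df[spec.cluster].unique()
            groups = {f: df[df[spec.cluster] == f] for f in fams}
        for _ in range(spec.n_sims):
            if spec.cluster:
                pick = rng.choice(len(fams), size=len(fams), replace=True)
                boot = pd.concat(
                    [groups[fams[i]] for i in pick], ignore_index=True
                )
                # resampled families are duplicated: relabel to keep
                # random intercepts per resampled cluster
                sizes = [len(groups[fams[i]]) for i in pick]
                boot[spec.cluster] = np.repeat(np.arange(len(pick)), sizes)
            else:
                boot = df.sample(n=len(df), replace=True, random_state=rng)
            try:
                mp, _, _ = _fit_linear(med_formula, boot, spec.cluster)
                op, _, _ = _fit_linear(out_formula, boot, spec.cluster)
            except Exception:  # noqa: BLE001 - skip degenerate resamples
                continue
            a.append(mp[x_term])
            b.append(op[m_term])
            c.append(op[x_term])
        return np.asarray(a), np.asarray(b), np.asarray(c)


def fit_mediation(data: pd.DataFrame, spec: MediationSpec) -> MediationResults:
    """Convenience wrapper: build and fit a :class:`MediationModel`."""
    return MediationModel(data, spec).fit()


def batch_mediate(
    data: pd.DataFrame,
    mediators: list[str],
    outcomes: list[str],
    exposure: str,
    covariates: list[str] | None = None,
    cluster: str | None = None,
    n_sims: int = 1000,
    seed: int | None = None,
    outcome_is_abundance: bool = True,
) -> pd.DataFrame:
    """Run every (mediator, outcome) pair, one result row each.

    Seeds are spawned deterministically from ``seed`` per pair so the
    table is reproducible and independent of evaluation order; per-pair
    failures are recorded in an ``error`` column and do not stop the
    batch.
    """
    import zlib

    covariates = covariates or []
    pairs = [(m, o) for m in mediators for o in outcomes]
    rows = []
    for m, o in pairs:
        # per-pair seed keyed on the pair's names, not its position, so a
        # duplicated spec reproduces the identical row
        pair_key = zlib.crc32(f"{exposure}|{m}|{o}".encode())
        ss = np.random.SeedSequence([0 if seed is None else int(seed), pair_key])
        spec = MediationSpec(
            exposure=exposure,
            mediator=m,
            outcome=o,
            covariates=covariates,
            cluster=cluster,
            n_sims=n_sims,
            seed=int(ss.generate_state(1)[0] % (2**31 - 1)),
            outcome_is_abundance=outcome_is_abundance,
        )
        try:
            res = fit_mediation(data, spec)
            rows.append({**res.to_row(), "error": ""})
        except Exception as exc:  # noqa: BLE001 - per-pair isolation
            rows.append(
                {"exposure": exposure, "mediator": m, "outcome": o, "error": str(exc)}
            )
    return pd.DataFrame(rows)
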