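"""Mediation estimands: transform, decomposition, planted-coefficient
recovery, and agreement with an independent mediation implementation."""

import numpy as np
import pandas as pd
import pytest

from chronogut.mediation import (
    MediationModel,
    MediationSpec,
    batch_mediate,
    fit_mediation,
    transform_abundance,
)


def test_transform_closed_forms():
    assert transform_abundance(0.0) == 0.0
    assert transform_abundance(1.0) == pytest.approx(np.pi / 2)
    assert transform_abundance(0.25) == pytest.approx(np.pi / 6)
    arr = transform_abundance(np.array([0.0, 0.25, 1.0]))
    assert arr == pytest.approx([0.0, np.pi / 6, np.pi / 2])
    with pytest.raises(ValueError):
        transform_abundance(1.2)
    with pytest.raises(ValueError):
        transform_abundance(-0.1)


def _planted(n, a=0.5, b=0.4, c=0.8, seed=0):
    rng = np.random.default_rng(seed)
    x = (rng.random(n) < 0.5).astype(int)
    m = a * x + rng.normal(0, 1, n)
    y = c * x + b * m + rng.normal(0, 1, n)
    return pd.DataFrame({"x": x, "m": m, "y": y})


def test_planted_coefficients_recovered_no_clustering():
    data = _planted(2000)
    spec = MediationSpec(
        exposure="x", mediator="m", outcome="y", n_sims=2000, seed=1,
        outcome_is_abundance=False,
    )
    res = fit_mediation(data, spec)
    assert res.acme_ci[0] <= 0.20 <= res.acme_ci[1]
    assert res.total_ci[0] <= 1.00 <= res.total_ci[1]
    assert res.prop_mediated_ci[0] <= 0.20 <= res.prop_mediated_ci[1]
    assert res.acme == pytest.approx(0.20, abs=0.08)
    assert res.total == pytest.approx(1.00, abs=0.15)
    assert res.prop_mediated == pytest.approx(0.20, abs=0.08)
    # linear decomposition is exact at the point estimates
    assert res.acme + res.ade - res.total == pytest.approx(0.0, abs=1e-10)


def test_matches_statsmodels_mediation_oracle():
    """Independent route: statsmodels' Mediation on the same OLS models
    must agree on ACME/ADE within simulation error."""
    import statsmodels.api as sm
    from statsmodels.stats.mediation import Mediation

    data = _planted(1200, seed=3)
    spec = MediationSpec(
        exposure="x", mediator="m", outcome="y", n_sims=2000, seed=4,
        outcome_is_abundance=False,
    )
    mine = fit_mediation(data, spec)
    out_mod = sm.OLS.from_formula("y ~ x + m", data)
    med_mod = sm.OLS.from_formula("m ~ x", data)
    np.random.seed(7)
    other = Mediation(out_mod, med_mod, "x", "m").fit(
        method="parametric", n_rep=1000
    ).summary()
    acme_sm = float(other.loc["ACME (average)", "Estimate"])
    ade_sm = float(other.loc["ADE (average)", "Estimate"])
    assert mine.acme == pytest.approx(acme_sm, abs=0.03)
    assert mine.ade == pytest.approx(ade_sm, abs=0.03)


def test_no_mediator_path_gives_null_acme():
    data = _planted(1500, b=0.0, seed=5)
    res = fit_mediation(
        data,
        MediationSpec(
            exposure="x", mediator="m", outcome="y", n_sims=1000, seed=6,
            outcome_is_abundance=False,
        ),
    )
    assert res.acme_ci[0] <= 0 <= res.acme_ci[1]
    assert abs(res.prop_mediated) < 0.1


def test_exposure_flip_sign_symmetry():
    data = _planted(1500, seed=8)
    flipped = data.assign(x=1 - data["x"])
    k = dict(mediator="m", outcome="y", n_sims=1000, seed=9, outcome_is_abundance=False)
    r1 = fit_mediation(data, MediationSpec(exposure="x", **k))
    r2 = fit_mediation(flipped, MediationSpec(exposure="x", **k))
    assert r1.acme == pytest.approx(-r2.acme, abs=1e-10)
    assert r1.ade == pytest.approx(-r2.ade, abs=1e-10)
    assert r1.total == pytest.approx(-r2.total, abs=1e-10)
    assert r1.prop_mediated == pytest.approx(r2.prop_mediated, abs=0.05)


def test_mixed_and_plain_agree_when_family_sd_zero():
    rng = np.random.default_rng(10)
    n = 800
    data = _planted(n, seed=10)
    data["family"] = [f"f{i}" for i in rng.integers(0, n // 2, n)]
    k = dict(
        exposure="x", mediator="m", outcome="y", n_sims=1000, seed=11,
        outcome_is_abundance=False,
    )
    plain = fit_mediation(data, MediationSpec(**k))
    mixed = fit_mediation(data, MediationSpec(cluster="family", **k))
    assert mixed.acme == pytest.approx(plain.acme, abs=0.03)
    assert mixed.ade == pytest.approx(plain.ade, abs=0.05)


def test_validation_errors():
    data = _planted(100)
    with pytest.raises(ValueError):
        MediationSpec(exposure="x", mediator="m", outcome="y", n_sims=10)
    bad = data.assign(x=data["x"] + 0.5)
    with pytest.raises(ValueError):
        MediationModel(
            bad,
            MediationSpec(exposure="x", mediator="m", outcome="y",
                          outcome_is_abundance=False),
        )
    with pytest.raises(KeyError):
        MediationModel(
            data,
            MediationSpec(exposure="x", mediator="m", outcome="absent",
                          outcome_is_abundance=False),
        )


def test_batch_cardinality_and_determinism():
    data = _planted(400, seed=12)
    data["m2"] = data["m"] + np.random.default_rng(13).normal(0, 1, len(data))
    data["y2"] = data["y"] * 0.5
    t = batch_mediate(
        data, mediators=["m", "m2"], outcomes=["y", "y2"], exposure="x",
        n_sims=200, seed=14, outcome_is_abundance=False,
    )
    assert len(t) == 4
    assert (t["error"] == "").all()
    t2 = batch_mediate(
        data, mediators=["m"], outcomes=["y"], exposure="x",
        n_sims=200, seed=14, outcome_is_abundance=False,
    )
    row_a = t[(t.mediator == "m") & (t.outcome == "y")].iloc[0]
    row_b = t2.iloc[0]
    assert row_a["acme"] == row_b["acme"]
    assert row_a["prop_mediated"] == row_b["prop_mediated"]


def test_batch_isolates_failures():
    data = _planted(200, seed=15)
    data["dead"] = 1.0  # constant outcome cannot be fit meaningfully
    t = batch_mediate(
        data, mediators=["m"], outcomes=["y", "dead"], exposure="x",
        n_sims=200, seed=16, outcome_is_abundance=False,
    )
    assert len(t) == 2
    ok = t[t.outcome == "y"].iloc[0]
    assert ok["error"] == ""


def test_summary_renders(core_bundle):
    truth = core_bundle.ground_truth
    data = core_bundle.demographics.merge(
        core_bundle.ffq[["participant_id", "nuts"]], on="participant_id"
    )
    data["sjl_flag"] = data["participant_id"].map(truth["sjl_status"]).astype(int)
    sp = truth["mediated_species"][0]
    data[sp] = core_bundle.abundance[sp].reindex(data["participant_id"]).to_numpy()
    res = fit_mediation(
        data,
        MediationSpec(
            exposure="sjl_flag", mediator="nuts", outcome=sp,
            covariates=["sex", "age"], cluster="family_id", seed=17,
        ),
    )
    text = res.summary()
    assert "ACME" in text and "Prop. mediated" in text
    assert res.n_obs == len(data)
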