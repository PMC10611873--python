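"""Adjusted group comparisons, interactions, partial correlation,
age matching and categorical tests."""

import numpy as np
import pandas as pd
import pytest

from chronogut.stats import (
    ancova_compare,
    categorical_group_test,
    compare_outcomes,
    interaction_model,
    kruskal_group_test,
    match_by_age,
    partial_correlation,
    select_transform,
)


def _cohort(n=400, delta=0.0, seed=0, lognormal=False):
    rng = np.random.default_rng(seed)
    g = (rng.random(n) < 0.3).astype(int)
    age = rng.normal(45, 10, n)
    sex = rng.choice(["F", "M"], n)
    y = 0.02 * age + (sex == "M") * 0.5 + delta * g + rng.normal(0, 1, n)
    if lognormal:
        y = np.exp(y * 0.5)
    return pd.DataFrame({"sjl_flag": g, "age": age, "sex": sex, "y": y})


def test_ancova_recovers_planted_difference():
    df = _cohort(n=900, delta=0.5, seed=1)
    res = ancova_compare(df, "y", covariates=["age", "sex"])
    assert res.estimate == pytest.approx(0.5, abs=2.5 * res.se)
    assert res.p < 0.01
    assert res.transform == "none"
    assert res.n == 900


def test_ancova_matches_normal_equations_oracle():
    """The group coefficient equals the direct least-squares solve on a
    small instance."""
    df = _cohort(n=50, delta=0.8, seed=2)
    res = ancova_compare(df, "y", covariates=["age", "sex"], transform="none")
    X = np.column_stack(
        [
            np.ones(len(df)),
            df["sjl_flag"],
            df["age"],
            (df["sex"] == "M").astype(float),
        ]
    )
    beta = np.linalg.solve(X.T @ X, X.T @ df["y"].to_numpy())
    assert res.estimate == pytest.approx(beta[1], abs=1e-8)


def test_ancova_transform_selection_lognormal():
    df = _cohort(n=500, delta=0.0, seed=3, lognormal=True)
    res = ancova_compare(df, "y", covariates=["age", "sex"])
    assert res.transform == "log"
    name, vals = select_transform(np.exp(np.random.default_rng(4).normal(size=400)))
    assert name == "log"


def test_ancova_null_calibration():
    """Permuted labels: the group p-value is uniform, so ~5% of 200
    permutations land below 0.05."""
    rng = np.random.default_rng(5)
    df = _cohort(n=300, delta=0.0, seed=6)
    hits = 0
    for _ in range(200):
        df2 = df.assign(sjl_flag=rng.permutation(df["sjl_flag"].to_numpy()))
        hits += ancova_compare(df2, "y", covariates=["age", "sex"],
                               transform="none").p < 0.05
    assert 0.02 <= hits / 200 <= 0.09


def test_ancova_irrelevant_covariate_no_effect():
    df = _cohort(n=300, delta=0.4, seed=7)
    df["constant_ish"] = 3.14  # identical across groups
    r1 = ancova_compare(df, "y", covariates=["age", "sex"], transform="none")
    df["noise_cov"] = np.random.default_rng(8).normal(size=len(df))
    # a covariate orthogonal to the group changes the estimate only
    # within numerical noise
    r2 = ancova_compare(df, "y", covariates=["age", "sex", "noise_cov"],
                        transform="none")
    assert r2.estimate == pytest.approx(r1.estimate, abs=0.05)
    with pytest.raises(ValueError):
        ancova_compare(df.assign(y=1.0), "y", covariates=["age"])


def test_compare_outcomes_family_fdr():
    df = _cohort(n=400, delta=0.6, seed=9)
    df["y2"] = np.random.default_rng(10).normal(size=len(df))
    table = compare_outcomes(df, ["y", "y2"], covariates=["age", "sex"])
    assert len(table) == 2
    assert (table["q"] >= table["p"] - 1e-12).all()


def test_interaction_detected_when_planted():
    rng = np.random.default_rng(11)
    hits = 0
    for rep in range(10):
        n = 900
        g = (rng.random(n) < 0.3).astype(int)
        sex = rng.choice(["F", "M"], n)
        y = np.where(sex == "M", 0.5 * g, 0.0) + rng.normal(0, 1, n)
        df = pd.DataFrame({"sjl_flag": g, "sex": sex, "y": y,
                           "age": rng.normal(45, 10, n)})
        res = interaction_model(df, "y", "sex", covariates=["age"])
        hits += res["interaction_f_p"] < 0.05
        if rep == 0:
            assert res["simple_effects"]["M"]["estimate"] > res["simple_effects"]["F"]["estimate"]
    assert hits >= 8


def test_interaction_null_and_errors():
    df = _cohort(n=500, delta=0.3, seed=12)
    res = interaction_model(df, "y", "sex", covariates=["age"])
    term = next(iter(res["interaction_terms"].values()))
    assert abs(term["estimate"]) < 0.5
    with pytest.raises(ValueError):
        interaction_model(df.assign(sex="F"), "y", "sex", covariates=["age"])
    df_empty = df.copy()
    df_empty.loc[(df_empty.sjl_flag == 1) & (df_empty.sex == "M"), "sex"] = "F"
    with pytest.raises(ValueError):
        interaction_model(df_empty, "y", "sex", covariates=["age"])


def test_partial_correlation_identity_and_planted():
    rng = np.random.default_rng(13)
    z = rng.normal(size=4000)
    x = 0.6 * z + rng.normal(size=4000)
    r, p = partial_correlation(x, x.copy(), np.column_stack([z]))
    assert r == pytest.approx(1.0)
    # trivariate normal with known partial correlation
    rho = 0.30
    e1 = rng.normal(size=5000)
    e2 = rho * e1 + np.sqrt(1 - rho**2) * rng.normal(size=5000)
    zz = rng.normal(size=5000)
    xx = 0.7 * zz + e1
    yy = -0.4 * zz + e2
    r2, p2 = partial_correlation(xx, yy, np.column_stack([zz]))
    assert r2 == pytest.approx(rho, abs=0.03)
    assert p2 < 1e-10
    # independent null
    r3, _ = partial_correlation(
        rng.normal(size=5000), rng.normal(size=5000),
        np.column_stack([rng.normal(size=5000)]),
    )
    assert abs(r3) < 0.05


def test_partial_correlation_matches_ppcor_style_reference():
    import pingouin as pg

    rng = np.random.default_rng(14)
    df = pd.DataFrame(
        {
            "x": rng.normal(size=300),
            "y": rng.normal(size=300),
            "z1": rng.normal(size=300),
            "z2": rng.normal(size=300),
        }
    )
    df["y"] += 0.4 * df["x"] + 0.3 * df["z1"]
    r, p = partial_correlation(
        df["x"], df["y"], df[["z1", "z2"]].to_numpy()
    )
    ref = pg.partial_corr(df, x="x", y="y", covar=["z1", "z2"])
    assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
    assert p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)
    with pytest.raises(ValueError):
        partial_correlation(df["x"][:5], df["y"][:5], df[["z1", "z2", "z1"]][:5].to_numpy())


def _match_frame(sjl_ages, ctrl_ages):
    return pd.DataFrame(
        {
            "participant_id": [f"s{i}" for i in range(len(sjl_ages))]
            + [f"c{i}" for i in range(len(ctrl_ages))],
            "sjl_flag": [1] * len(sjl_ages) + [0] * len(ctrl_ages),
            "age": list(sjl_ages) + list(ctrl_ages),
        }
    )


def test_match_identical_lists_zero_difference():
    mc = match_by_age(_match_frame([30, 40, 50], [30, 40, 50]), seed=0)
    assert mc.post_mean_diff == pytest.approx(0.0)
    assert len(mc.pairs) == 3


def test_match_hand_oracle_small():
    # hand enumeration of greedy outcomes over both processing orders:
    # s0 (30) takes 29 or 31; s1 (40) takes 31 (dist 9) or, if 31 is
    # gone, 50 (dist 10) — never 29 while 31/50 remain
    mc = match_by_age(_match_frame([30, 40], [29, 31, 50]), caliper=15, seed=0)
    got = dict(mc.pairs)
    assert len(got) == 2
    assert got["s0"] in ("c0", "c1")
    assert got["s1"] in ("c1", "c2") and got["s1"] != got["s0"]
    tight = match_by_age(_match_frame([30, 40], [29, 31, 50]), caliper=2, seed=0)
    assert "s1" in tight.unmatched_sjl  # every control > 2 y from 40


def test_match_shifted_distributions_reduce_difference(rng):
    sjl_ages = rng.normal(38, 8, 60)
    ctrl_ages = rng.normal(47, 10, 300)
    mc = match_by_age(_match_frame(sjl_ages, ctrl_ages), caliper=5.0, seed=1)
    assert abs(mc.post_mean_diff) < abs(mc.pre_mean_diff)
    # controls used at most once
    used = [b for _, b in mc.pairs]
    assert len(used) == len(set(used))
    with pytest.raises(ValueError):
        match_by_age(_match_frame([30], [90]), caliper=2)


def test_chi_square_hand_values():
    chi2, p = categorical_group_test([[10, 10], [10, 10]])
    assert chi2 == 0.0 and p == 1.0
    chi2, _ = categorical_group_test([[30, 10], [10, 30]])
    assert chi2 == pytest.approx(20.0)
    with pytest.raises(ValueError):
        categorical_group_test([[0, 0], [5, 5]])
    stat, p = kruskal_group_test([1, 2, 3, 4], [2, 3, 4, 5])
    assert p > 0.05


def test_chi_square_null_uniform(rng):
    """Independence-generated tables give approximately uniform p."""
    ps = []
    for _ in range(300):
        a = rng.multinomial(200, [0.25] * 4).reshape(2, 2)
        if (a.sum(axis=0) == 0).any() or (a.sum(axis=1) == 0).any():
            continue
        ps.append(categorical_group_test(a)[1])
    assert 0.02 <= np.mean(np.array(ps) < 0.05) <= 0.10
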