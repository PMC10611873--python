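"""Eating-occasion segmentation, daily timing features, and the
plant-based diet indices."""

import numpy as np
import pandas as pd
import pytest

from oracles import oracle_segment

from chronogut.diet import (
    DEFAULT_GROUP_CLASSES,
    circular_mean_minutes,
    day_features,
    ffq_exclusion,
    filter_free_living_days,
    harris_benedict_bmr,
    mean_over_valid_days,
    quintile_scores,
    score_pdi_family,
    segment_eating_occasions,
)


def test_segmentation_worked_example():
    occ = segment_eating_occasions([480, 500, 780], [300, 150, 600], "F")
    assert [(o.start_min, o.end_min, o.energy_kcal, o.kind) for o in occ] == [
        (480.0, 500.0, 450.0, "main_meal"),
        (780.0, 780.0, 600.0, "main_meal"),
    ]


def test_segmentation_floor_and_sex_thresholds():
    assert segment_eating_occasions([600], [40], "M") == []
    male = segment_eating_occasions([600], [450], "M")[0]
    female = segment_eating_occasions([600], [450], "F")[0]
    assert male.kind == "snack" and female.kind == "main_meal"
    with pytest.raises(ValueError):
        segment_eating_occasions([600], [450], "X")


def test_segmentation_matches_partition_oracle_randomised(rng):
    for _ in range(300):
        n = int(rng.integers(1, 13))
        times = np.sort(rng.uniform(6 * 60, 23 * 60, n))
        # force interesting gap structure around the 30-min boundary
        times += rng.choice([0.0, 29.0, 31.0], size=n)
        times = np.sort(times)
        kcals = rng.uniform(10, 700, n)
        sex = rng.choice(["F", "M"])
        got = [
            (o.start_min, o.end_min, o.energy_kcal, o.kind)
            for o in segment_eating_occasions(times, kcals, sex)
        ]
        want = oracle_segment(times, kcals, sex)
        assert len(got) == len(want)
        for g, w in zip(got, want):
            assert g[0] == w[0] and g[1] == w[1]
            assert g[2] == pytest.approx(w[2])
            assert g[3] == w[3]


def test_day_features_windows_and_midpoint():
    occ = segment_eating_occasions([480, 1200], [600, 700], "F")
    f = day_features(occ)
    assert f["eating_window_h"] == 12.0
    assert f["fasting_window_h"] == 12.0
    assert f["eating_midpoint_min"] == 14 * 60
    # degenerate single occasion
    f1 = day_features(segment_eating_occasions([720], [600], "F"))
    assert f1["eating_window_h"] == 0.0
    assert f1["fasting_window_h"] == 24.0
    assert f1["eating_midpoint_min"] == 720
    # three occasions: midpoint between first and last starts
    f3 = day_features(segment_eating_occasions([420, 750, 1140], [500, 500, 500], "F"))
    assert f3["first_eo_min"] == 420 and f3["last_eo_min"] == 1140
    assert f3["eating_midpoint_min"] == 780  # 13:00
    assert day_features([]) is None


def test_window_complement_invariant(rng):
    for _ in range(50):
        n = int(rng.integers(1, 8))
        occ = segment_eating_occasions(
            np.sort(rng.uniform(0, 1439, n)), rng.uniform(60, 500, n), "M"
        )
        f = day_features(occ)
        if f is not None:
            assert f["eating_window_h"] + f["fasting_window_h"] == pytest.approx(24.0)


@pytest.mark.parametrize(
    "sex,kcal,ok",
    [("F", 450, False), ("M", 7500, True), ("F", 5200, False),
     ("F", 500, True), ("M", 8000, True), ("M", 8001, False)],
)
def test_free_living_day_energy_bounds(sex, kcal, ok):
    assert filter_free_living_days(kcal, sex) is ok


def test_mean_over_valid_days_circular_midnight():
    days = pd.DataFrame(
        {"eating_midpoint_min": [23.5 * 60, 0.5 * 60], "eating_window_h": [10.0, 12.0]}
    )
    m = mean_over_valid_days(days)
    assert m["eating_midpoint_min"] == pytest.approx(0.0, abs=1e-9)
    assert m["eating_window_h"] == 11.0
    assert mean_over_valid_days(days.iloc[:0]) is None


def test_circular_mean_agrees_with_unwrapped_axis(rng):
    # when all times sit within one 12 h half-circle, the circular mean
    # equals the arithmetic mean after unwrapping past midnight
    for _ in range(50):
        base = rng.uniform(0, 1440)
        offs = rng.uniform(0, 300, size=5)
        got = circular_mean_minutes((base + offs) % 1440)
        want = (base + offs.mean()) % 1440
        assert got == pytest.approx(want, abs=1e-6) or abs(got - want) == pytest.approx(1440, abs=1e-6)


def test_harris_benedict_hand_values():
    assert harris_benedict_bmr("M", 70, 175, 30) == pytest.approx(1702.0125)
    assert harris_benedict_bmr("F", 60, 165, 40) == pytest.approx(1347.0595)
    with pytest.raises(ValueError):
        harris_benedict_bmr("M", 0, 175, 30)


@pytest.mark.parametrize(
    "ratio,unanswered,ok",
    [(0.50, 0, False), (1.0, 0, True), (1.0, 11, False),
     (0.52, 0, True), (2.58, 10, True), (2.59, 0, False)],
)
def test_ffq_exclusion_bounds(ratio, unanswered, ok):
    valid, got_ratio = ffq_exclusion(ratio * 1500.0, 1500.0, unanswered)
    assert valid is ok
    assert got_ratio == pytest.approx(ratio)


def test_quintiles_are_permutation_on_five_distinct():
    assert sorted(quintile_scores([3.0, 1.0, 4.0, 1.5, 9.0])) == [1, 2, 3, 4, 5]


def test_quintiles_invariant_to_monotone_rescaling(rng):
    v = rng.normal(size=40)
    assert np.array_equal(quintile_scores(v), quintile_scores(np.exp(v)))
    assert np.array_equal(quintile_scores(v), quintile_scores(3 * v + 7))


def test_pdi_symmetry_and_extremes(rng):
    groups = list(DEFAULT_GROUP_CLASSES)
    n = 25
    ffq = pd.DataFrame(rng.uniform(10, 500, (n, len(groups))), columns=groups)
    # plant one participant maximal in all healthy-plant, minimal elsewhere
    for g in groups:
        if DEFAULT_GROUP_CLASSES[g] == "healthy_plant":
            ffq.loc[0, g] = 1e6
        else:
            ffq.loc[0, g] = 0.0
    scores = score_pdi_family(ffq)
    assert scores.loc[0, "hPDI"] == scores["hPDI"].max()
    assert scores.loc[0, "uPDI"] == scores["uPDI"].min()
    n_healthy = sum(c == "healthy_plant" for c in DEFAULT_GROUP_CLASSES.values())
    n_other = len(groups) - n_healthy
    assert scores.loc[0, "hPDI"] == 5 * n_healthy + 5 * n_other  # all reversed minima score 5
    # index equals the sum of its per-group scores
    per_group = scores[[f"score_{g}" for g in groups]]
    pdi_manual = sum(
        per_group[f"score_{g}"]
        if DEFAULT_GROUP_CLASSES[g] != "animal"
        else 6 - per_group[f"score_{g}"]
        for g in groups
    )
    assert (scores["PDI"] == pdi_manual).all()


def test_hpdi_updi_anticorrelated_on_inverse_cohort(rng):
    groups = list(DEFAULT_GROUP_CLASSES)
    n = 50
    healthy_load = rng.uniform(0, 1, n)
    ffq = pd.DataFrame(index=range(n))
    for g in groups:
        cls = DEFAULT_GROUP_CLASSES[g]
        if cls == "healthy_plant":
            ffq[g] = 100 * healthy_load + rng.normal(0, 1, n)
        elif cls == "less_healthy_plant":
            ffq[g] = 100 * (1 - healthy_load) + rng.normal(0, 1, n)
        else:
            ffq[g] = rng.uniform(10, 100, n)
    scores = score_pdi_family(ffq)
    assert scores["hPDI"].corr(scores["uPDI"]) < -0.5


def test_unmapped_group_raises():
    with pytest.raises(KeyError):
        score_pdi_family(pd.DataFrame({"fruits": [1, 2]}), {"fruits": "weird"})
    with pytest.raises(KeyError):
        score_pdi_family(pd.DataFrame({"fruits": [1, 2]}), {"absent": "animal"})
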