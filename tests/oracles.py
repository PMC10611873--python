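"""Independent reference implementations used to check the package's
primitives: brute-force and enumeration oracles only, never the code
paths under test."""

import itertools

import numpy as np


def oracle_segment(times, kcals, sex, gap=30.0, floor=50.0):
    """Exhaustive-partition oracle for eating-occasion segmentation:
    enumerate every contiguous partition of the sorted event stream,
    keep the (unique) one in which all within-block gaps are < gap and
    all between-block gaps are >= gap, then apply the energy floor and
    the sex-specific main-meal threshold."""
    order = np.argsort(times, kind="stable")
    t = np.asarray(times, float)[order]
    e = np.asarray(kcals, float)[order]
    n = len(t)
    if n == 0:
        return []
    valid = []
    for cuts in itertools.product([0, 1], repeat=n - 1):
        blocks, start = [], 0
        for i, c in enumerate(cuts, start=1):
            if c:
                blocks.append((start, i))
                start = i
        blocks.append((start, n))
        ok = True
        for s, f in blocks:
            if any(t[i + 1] - t[i] >= gap for i in range(s, f - 1)):
                ok = False
        for (s1, f1), (s2, f2) in zip(blocks, blocks[1:]):
            if t[s2] - t[f1 - 1] < gap:
                ok = False
        if ok:
            valid.append(blocks)
    assert len(valid) == 1, "chaining partition must be unique"
    thr = 400.0 if sex == "F" else 500.0
    out = []
    for s, f in valid[0]:
        total = float(e[s:f].sum())
        if total >= floor:
            out.append(
                (float(t[s]), float(t[f - 1]), total,
                 "main_meal" if total >= thr else "snack")
            )
    return out


def mwu_permutation_p(x, y):
    """Exhaustive label-permutation oracle for the two-sided
    Mann–Whitney p-value (group sizes small enough to enumerate)."""
    from scipy.stats import mannwhitneyu

    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = mannwhitneyu(x, y, alternative="two-sided").statistic
    mu = n1 * len(y) / 2
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        mask = np.zeros(len(pooled), bool)
        mask[list(idx)] = True
        u = mannwhitneyu(pooled[mask], pooled[~mask], alternative="two-sided").statistic
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total
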