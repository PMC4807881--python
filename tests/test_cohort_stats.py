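"""Organism-level summaries and hypothesis tests against hand oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hemoquant import synthetic as syn
from hemoquant.cohort_stats import (
    bonferroni_posthoc,
    cfu_per_individual,
    mann_whitney,
    median_lifespan,
    one_way_anova,
    relative_lifespan,
    timecourse_anova,
)
from hemoquant.errors import ConfigError, UndefinedStatisticError


def _cohort(days_by_rep: dict[int, list[int]], group="g") -> pd.DataFrame:
    rows = [
        {"group": group, "replicate": rep, "individual_id": f"{group}-{rep}-{i}",
         "death_day": d}
        for rep, days in days_by_rep.items()
        for i, d in enumerate(days)
    ]
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# survival


def test_median_conventions():
    assert median_lifespan(_cohort({0: [23] * 5}), "g").median_days == 23
    assert median_lifespan(_cohort({0: [10, 20, 30]}), "g").median_days == 20
    assert median_lifespan(_cohort({0: [10, 20, 30, 40]}), "g").median_days == 25


def test_replicate_aggregation_mean_of_medians():
    s = median_lifespan(_cohort({0: [10, 20, 30], 1: [20, 30, 40]}), "g")
    assert s.replicate_medians == [20.0, 30.0]
    assert s.median_days == 25.0
    assert s.sem_days == pytest.approx(5.0)


def test_empty_group_rejected():
    with pytest.raises(ConfigError):
        median_lifespan(_cohort({0: [10]}), "absent")


def test_relative_lifespan_values():
    assert relative_lifespan(23, 49) == pytest.approx(46.94, abs=0.01)
    assert relative_lifespan(38, 49) == pytest.approx(77.55, abs=0.01)
    assert relative_lifespan(12, 12) == 100.0
    with pytest.raises(ConfigError):
        relative_lifespan(10, 0)


def test_survival_recovery_simulated_cohorts():
    # generated medians (23, 49) recover a relative lifespan near 47%
    for seed in range(4):
        spec = syn.CohortSpec(
            groups=[
                syn.CohortGroup("mut", 50, 5, lifespan=syn.LifespanModel(23, 6)),
                syn.CohortGroup("wt", 50, 5, lifespan=syn.LifespanModel(49, 3)),
            ],
            seed=seed,
        )
        t = syn.make_survival_cohort(spec)
        rel = relative_lifespan(
            median_lifespan(t, "mut").median_days,
            median_lifespan(t, "wt").median_days,
        )
        assert abs(rel - 47.0) / 47.0 < 0.15


# --------------------------------------------------------------------------
# CFU


def _counts(rows):
    return pd.DataFrame(rows, columns=["individual_id", "group", "dilution", "count"])


def test_cfu_rules():
    df = _counts(
        [
            ("a", "g", 1.0, 0),  # zero count at 1:1 → 0 CFU
            ("b", "g", 10.0, 30),  # 30 at 1:10 → 300
            ("c", "g", 1.0, 200), ("c", "g", 10.0, 30),  # 1:1 saturated → use 1:10
            ("d", "g", 1.0, 200), ("d", "g", 10.0, 180),  # all saturated → flagged
        ]
    )
    est = cfu_per_individual(df, saturation_limit=150).set_index("individual_id")
    assert est.loc["a", "estimated_cfu"] == 0.0
    assert est.loc["b", "estimated_cfu"] == 300.0
    assert est.loc["c", "estimated_cfu"] == 300.0
    assert est.loc["c", "consistency_ratio"] == pytest.approx(200 / 300)
    assert bool(est.loc["d", "saturated"]) and np.isnan(est.loc["d", "estimated_cfu"])


# --------------------------------------------------------------------------
# ANOVA


def test_anova_hand_oracle():
    res = one_way_anova([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
    # SSB = 6, SSW = 6 → F(2,6) = 3.0
    assert res.statistic == pytest.approx(3.0, rel=1e-12)
    assert res.df == (2, 6)


def test_anova_two_groups_equals_t_squared():
    from scipy import stats as ss

    rng = np.random.default_rng(0)
    a, b = rng.normal(size=12), rng.normal(0.5, 1, size=9)
    res = one_way_anova([a, b])
    t = ss.ttest_ind(a, b).statistic
    assert res.statistic == pytest.approx(t**2, rel=1e-10)


def test_anova_degenerate_cases():
    res = one_way_anova([[1.0, 2.0], [1.0, 2.0]])
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(UndefinedStatisticError):
        one_way_anova([[1.0, 1.0], [2.0, 2.0]])
    with pytest.raises(ConfigError):
        one_way_anova([[1.0, 2.0]])


# --------------------------------------------------------------------------
# Bonferroni


def test_bonferroni_adjustment_rules():
    rng = np.random.default_rng(1)
    groups = {k: rng.normal(i * 0.5, 1, size=8) for i, k in enumerate("abcde")}
    table = bonferroni_posthoc(groups)
    m = len(table)
    assert m == 10
    for _, row in table.iterrows():
        assert row["p_adj"] == pytest.approx(min(1.0, m * row["p_raw"]), rel=1e-12)
        assert row["p_adj"] >= row["p_raw"]
    # matches statsmodels' bonferroni correction on the same raw p-values
    from statsmodels.stats.multitest import multipletests

    adj = multipletests(table["p_raw"], method="bonferroni")[1]
    np.testing.assert_allclose(table["p_adj"], adj, rtol=1e-12)


def test_bonferroni_single_comparison_is_identity():
    rng = np.random.default_rng(2)
    groups = {"a": rng.normal(size=6), "b": rng.normal(size=6)}
    table = bonferroni_posthoc(groups, comparisons=[("a", "b")])
    assert table["p_adj"].iloc[0] == table["p_raw"].iloc[0]
    with pytest.raises(ConfigError):
        bonferroni_posthoc(groups, comparisons=[("a", "zzz")])


def test_bonferroni_familywise_error_under_null():
    rng = np.random.default_rng(3)
    alpha, hits = 0.05, 0
    reps = 400
    for _ in range(reps):
        groups = {k: rng.normal(size=6) for k in "abc"}
        table = bonferroni_posthoc(groups, alpha=alpha)
        hits += int(table["significant"].any())
    assert hits / reps <= alpha + 0.03


# --------------------------------------------------------------------------
# Mann-Whitney


def brute_force_u_and_p(x, y):
    """U by pairwise counting; two-tailed p by full label enumeration."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_of(xs, ys):
        return sum(
            1.0 if xi > yi else (0.5 if xi == yi else 0.0) for xi in xs for yi in ys
        )

    u_obs = u_of(x, y)
    mu = n1 * len(y) / 2.0
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(u_of(xs, ys))
    p = np.mean([abs(u - mu) >= abs(u_obs - mu) - 1e-9 for u in us])
    return u_obs, float(p)


def test_mann_whitney_complete_separation_and_symmetry():
    assert mann_whitney([1, 2, 3], [4, 5, 6]).statistic == 0.0
    res = mann_whitney([1, 2, 3], [1, 2, 3])
    assert res.statistic == 3 * 3 / 2


def test_mann_whitney_enumeration_example():
    res = mann_whitney([1, 3], [2, 4])
    u, p = brute_force_u_and_p([1, 3], [2, 4])
    assert res.statistic == u == 1.0
    assert res.p_value == pytest.approx(p)


@pytest.mark.parametrize("seed", range(4))
def test_mann_whitney_exact_matches_enumeration_with_ties(seed):
    rng = np.random.default_rng(seed)
    x = list(rng.integers(0, 4, size=4))  # small support forces ties
    y = list(rng.integers(0, 4, size=5))
    res = mann_whitney(x, y)
    u, p = brute_force_u_and_p(x, y)
    assert res.statistic == pytest.approx(u)
    assert res.p_value == pytest.approx(p)


def test_mann_whitney_large_sample_matches_scipy():
    from scipy import stats as ss

    rng = np.random.default_rng(5)
    x, y = rng.normal(size=25), rng.normal(0.8, 1, size=30)
    res = mann_whitney(x, y)
    ref = ss.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    assert res.statistic == ref.statistic
    assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)


# --------------------------------------------------------------------------
# time-course ANOVA


def _curves(offsets_by_group, times, n_subj=4, noise=0.5, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for g, offset in offsets_by_group.items():
        for s in range(n_subj):
            for t in times:
                rows.append(
                    {"group": g, "subject": f"{g}{s}", "time": t,
                     "value": offset(t) + rng.normal(0, noise)}
                )
    return pd.DataFrame(rows)


def test_identical_curves_not_significant():
    df = _curves({"a": lambda t: 1.0, "b": lambda t: 1.0}, times=[0, 5, 10])
    res = timecourse_anova(df)
    assert res.extra["earliest_significant_time"] is None


def test_divergence_detected_not_before_changepoint():
    times = list(range(0, 40, 5))
    df = _curves(
        {"a": lambda t: 0.0, "b": lambda t: 0.0 if t < 20 else (t - 20) * 2.0},
        times=times, n_subj=6, noise=0.4, seed=1,
    )
    res = timecourse_anova(df)
    assert res.extra["earliest_significant_time"] is not None
    assert res.extra["earliest_significant_time"] >= 20


def test_single_timepoint_reduces_to_one_way():
    df = _curves({"a": lambda t: 0.0, "b": lambda t: 2.0}, times=[7], n_subj=6, seed=2)
    res = timecourse_anova(df)
    gs = [sub["value"].to_numpy() for _, sub in df.groupby("group")]
    assert res.statistic == pytest.approx(one_way_anova(gs).statistic)


def test_misaligned_grids_rejected():
    df = _curves({"a": lambda t: 0.0, "b": lambda t: 0.0}, times=[0, 5])
    df = df.drop(df[(df["subject"] == "a0") & (df["time"] == 5)].index)
    with pytest.raises(ConfigError):
        timecourse_anova(df)
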