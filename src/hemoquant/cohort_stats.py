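"""Organism-level quantification and the statistical tests of the assays.

Survival is summarized as the median death day per replicate tube and a
group value of mean-of-replicate-medians ± SEM (the "median ± x d"
reporting convention for cohorts split across tubes); relative lifespan
is the group median as a percentage of a reference group. Endogenous
bacterial load is estimated from serial-dilution spot counts as
count × dilution factor at the lowest countable dilution.

Hypothesis tests mirror the original analysis toolchain: one-way ANOVA
with a Bonferroni post hoc (pooled-variance pairwise t, adjusted
p = min(1, m·p)), the two-tailed Mann-Whitney U (exact for small
samples, normal approximation with tie correction otherwise), and a
two-factor group × time ANOVA with Bonferroni-adjusted per-timepoint
comparisons for intensity time courses. All flies are followed to
death — right-censoring is rejected, never silently modelled.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, UndefinedStatisticError

__all__ = [
    "SurvivalSummary",
    "TestResult",
    "median_lifespan",
    "relative_lifespan",
    "cfu_per_individual",
    "one_way_anova",
    "bonferroni_posthoc",
    "mann_whitney",
    "timecourse_anova",
]


@dataclass
class SurvivalSummary:
    group: str
    replicate_medians: list[float]
    median_days: float  # mean of replicate medians
    sem_days: float
    n_individuals: int
    relative_lifespan_pct: float | None = None


@dataclass
class TestResult:
    name: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    posthoc: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# Survival


def median_lifespan(
    cohort: pd.DataFrame,
    group: str,
    by_replicate: bool = True,
    value_col: str = "death_day",
) -> SurvivalSummary:
    """Median death day of one group, aggregated over replicate tubes.

    With ``by_replicate`` the summary is the mean of per-replicate
    medians with its SEM; otherwise a single pooled median (SEM 0).
    Median ties use the midpoint convention.
    """
    sub = cohort[cohort["group"] == group]
    if sub.empty:
        raise ConfigError(f"group {group!r} has no individuals")
    if by_replicate and "replicate" in sub.columns:
        meds = sub.groupby("replicate")[value_col].median().to_numpy(dtype=float)
    else:
        meds = np.array([float(sub[value_col].median())])
    sem = float(meds.std(ddof=1) / math.sqrt(len(meds))) if len(meds) > 1 else 0.0
    return SurvivalSummary(
        group=group,
        replicate_medians=[float(m) for m in meds],
        median_days=float(meds.mean()),
        sem_days=sem,
        n_individuals=int(len(sub)),
    )


def relative_lifespan(group_median_days: float, reference_median_days: float) -> float:
    """Group median lifespan as a percentage of the reference median.

    E.g. medians of 23 d against a 49 d reference give 46.9% — the value
    is never rounded here; rounding belongs to display.
    """
    if reference_median_days <= 0:
        raise ConfigError("reference median must be > 0")
    if group_median_days < 0:
        raise ConfigError("group median must be >= 0")
    return 100.0 * group_median_days / reference_median_days


# --------------------------------------------------------------------------
# CFU


def cfu_per_individual(
    counts: pd.DataFrame, saturation_limit: int = 150
) -> pd.DataFrame:
    """Estimate CFU per individual from serial-dilution spot counts.

    For each individual the estimate is ``count × dilution`` at the
    lowest (least diluted) countable spot — a spot is countable when its
    count is below ``saturation_limit``. Individuals whose spots are all
    saturated are flagged with no estimate. When other dilutions were
    plated, their naive estimates divided by the chosen estimate are
    reported as a consistency ratio (mean over the other dilutions).
    """
    required = {"individual_id", "dilution", "count"}
    missing = required - set(counts.columns)
    if missing:
        raise ConfigError(f"counts table lacks columns {sorted(missing)}")
    rows = []
    for ind, sub in counts.groupby("individual_id", sort=False):
        sub = sub.sort_values("dilution")
        group = sub["group"].iloc[0] if "group" in sub.columns else ""
        countable = sub[sub["count"] < saturation_limit]
        row = {
            "individual_id": ind,
            "group": group,
            "estimated_cfu": np.nan,
            "dilution_used": np.nan,
            "count_used": np.nan,
            "saturated": countable.empty,
            "consistency_ratio": np.nan,
        }
        if not countable.empty:
            best = countable.iloc[0]
            est = float(best["count"] * best["dilution"])
            row.update(
                estimated_cfu=est,
                dilution_used=float(best["dilution"]),
                count_used=int(best["count"]),
            )
            others = sub[sub["dilution"] != best["dilution"]]
            if not others.empty and est > 0:
                naive = others["count"] * others["dilution"]
                row["consistency_ratio"] = float((naive / est).mean())
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "individual_id", "group", "estimated_cfu", "dilution_used",
            "count_used", "saturated", "consistency_ratio",
        ],
    )


# --------------------------------------------------------------------------
# ANOVA and post hoc


def _as_groups(groups) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float) for g in groups]
    if len(out) < 2:
        raise ConfigError("need at least 2 groups")
    if any(len(g) < 2 for g in out):
        raise ConfigError("every group needs n >= 2")
    return out


def one_way_anova(groups) -> TestResult:
    """One-way ANOVA: F = MS_between / MS_within with df (k−1, N−k)."""
    gs = _as_groups(groups)
    k = len(gs)
    n_tot = sum(len(g) for g in gs)
    grand = np.concatenate(gs).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df1, df2 = k - 1, n_tot - k
    if ssw == 0:
        raise UndefinedStatisticError("zero within-group variance; F undefined")
    f = (ssb / df1) / (ssw / df2)
    p = float(stats.f.sf(f, df1, df2))
    return TestResult(name="one-way ANOVA", statistic=float(f), df=(df1, df2), p_value=p)


def bonferroni_posthoc(
    groups: dict[str, np.ndarray],
    comparisons: list[tuple[str, str]] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise pooled-variance t tests with Bonferroni adjustment.

    The pooled within-group variance (MS_within over *all* groups, df
    N−k) is used for every pair; adjusted p = min(1, m × raw p) for m
    requested comparisons, significant at ``alpha``.
    """
    names = list(groups)
    arrs = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    _as_groups(arrs.values())
    if comparisons is None:
        comparisons = list(itertools.combinations(names, 2))
    for a, b in comparisons:
        if a not in arrs or b not in arrs:
            raise ConfigError(f"comparison ({a!r}, {b!r}) names an unknown group")
    n_tot = sum(len(v) for v in arrs.values())
    k = len(arrs)
    ssw = sum(((v - v.mean()) ** 2).sum() for v in arrs.values())
    df = n_tot - k
    if ssw == 0:
        raise UndefinedStatisticError("zero pooled variance; t tests undefined")
    msw = ssw / df
    m = len(comparisons)
    rows = []
    for a, b in comparisons:
        va, vb = arrs[a], arrs[b]
        se = math.sqrt(msw * (1.0 / len(va) + 1.0 / len(vb)))
        t = (va.mean() - vb.mean()) / se
        p_raw = float(2.0 * stats.t.sf(abs(t), df))
        p_adj = min(1.0, m * p_raw)
        rows.append(
            {
                "group_a": a, "group_b": b, "t": float(t), "df": df,
                "p_raw": p_raw, "p_adj": p_adj, "significant": p_adj < alpha,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["group_a", "group_b", "t", "df", "p_raw", "p_adj", "significant"],
    )


# --------------------------------------------------------------------------
# Mann-Whitney


def _u_from_ranks(ranks_x: np.ndarray, n1: int) -> float:
    return float(ranks_x.sum() - n1 * (n1 + 1) / 2.0)


def mann_whitney(x, y, tails: str = "two") -> TestResult:
    """Mann-Whitney U with midrank ties.

    ``tails``: ``"two"`` (default), ``"less"`` (alternative: x tends
    below y) or ``"greater"``. Exact p by enumeration of all label
    assignments for small samples (n ≤ 8 per group, or ≤ 10 pooled);
    otherwise the normal approximation with tie-corrected variance and
    continuity correction. U is reported for the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ConfigError("both samples must be nonempty")
    if tails not in ("two", "less", "greater"):
        raise ConfigError(f"tails must be two|less|greater, got {tails!r}")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    u = _u_from_ranks(ranks[:n1], n1)
    mu = n1 * n2 / 2.0

    if max(n1, n2) <= 8 or n1 + n2 <= 10:
        us = np.array(
            [
                _u_from_ranks(ranks[list(idx)], n1)
                for idx in itertools.combinations(range(n1 + n2), n1)
            ]
        )
        eps = 1e-9
        if tails == "two":
            p = float(np.mean(np.abs(us - mu) >= abs(u - mu) - eps))
        elif tails == "less":
            p = float(np.mean(us <= u + eps))
        else:
            p = float(np.mean(us >= u - eps))
        method = "exact"
    else:
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum()
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var == 0:
            raise UndefinedStatisticError("all values tied; U variance is zero")
        sd = math.sqrt(var)
        if tails == "two":
            z = (abs(u - mu) - 0.5) / sd
            p = float(min(1.0, 2.0 * stats.norm.sf(max(z, 0.0))))
        elif tails == "less":
            z = (u - mu + 0.5) / sd
            p = float(stats.norm.cdf(z))
        else:
            z = (u - mu - 0.5) / sd
            p = float(stats.norm.sf(z))
        method = "normal-approx"
    return TestResult(
        name="Mann-Whitney U",
        statistic=u,
        df=(),
        p_value=p,
        extra={"n1": n1, "n2": n2, "method": method, "tails": tails},
    )


# --------------------------------------------------------------------------
# Time-course ANOVA


def timecourse_anova(
    curves: pd.DataFrame,
    alpha: float = 0.05,
    group_col: str = "group",
    subject_col: str = "subject",
    time_col: str = "time",
    value_col: str = "value",
) -> TestResult:
    """Two-factor (group × time) ANOVA plus per-timepoint comparisons.

    ``curves`` is long-format with one row per subject per timepoint.
    All subjects must share the same time grid — misaligned grids are an
    error, never silently interpolated. Per-timepoint group differences
    are one-way ANOVAs Bonferroni-adjusted over the number of
    timepoints; the earliest adjusted-significant timepoint is reported
    in ``extra["earliest_significant_time"]`` (None if none). A single
    timepoint reduces to the one-way ANOVA at that time.
    """
    for col in (group_col, subject_col, time_col, value_col):
        if col not in curves.columns:
            raise ConfigError(f"curves table lacks column {col!r}")
    times = np.sort(curves[time_col].unique())
    grids = curves.groupby([group_col, subject_col])[time_col].apply(
        lambda s: tuple(np.sort(s.to_numpy()))
    )
    if grids.nunique() != 1:
        raise ConfigError("subjects have misaligned time grids")
    for g, sub in curves.groupby(group_col):
        if sub[subject_col].nunique() < 2:
            raise ConfigError(f"group {g!r} needs >= 2 subjects")

    per_time = []
    for t in times:
        at_t = curves[curves[time_col] == t]
        gs = [sub[value_col].to_numpy() for _, sub in at_t.groupby(group_col)]
        try:
            res = one_way_anova(gs)
            f, p = res.statistic, res.p_value
        except UndefinedStatisticError:
            f, p = np.nan, 1.0
        p_adj = min(1.0, len(times) * p)
        per_time.append(
            {"time": float(t), "F": f, "p_raw": p, "p_adj": p_adj,
             "significant": p_adj < alpha}
        )
    table = pd.DataFrame(per_time, columns=["time", "F", "p_raw", "p_adj", "significant"])
    sig = table[table["significant"]]
    earliest = float(sig["time"].iloc[0]) if not sig.empty else None

    if len(times) == 1:
        gs = [sub[value_col].to_numpy() for _, sub in curves.groupby(group_col)]
        res = one_way_anova(gs)
        return TestResult(
            name="time-course ANOVA (single timepoint)",
            statistic=res.statistic,
            df=res.df,
            p_value=res.p_value,
            posthoc=table,
            extra={"earliest_significant_time": earliest},
        )

    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    data = curves.rename(
        columns={group_col: "group", time_col: "time", value_col: "value"}
    )
    model = ols("value ~ C(group) * C(time)", data=data).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    inter = aov.loc["C(group):C(time)"]
    grp = aov.loc["C(group)"]
    return TestResult(
        name="two-way ANOVA (group x time)",
        statistic=float(grp["F"]),
        df=(float(grp["df"]), float(aov.loc["Residual", "df"])),
        p_value=float(grp["PR(>F)"]),
        posthoc=table,
        extra={
            "earliest_significant_time": earliest,
            "interaction_F": float(inter["F"]),
            "interaction_p": float(inter["PR(>F)"]),
            "anova_table": aov,
        },
    )
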