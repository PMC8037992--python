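"""The group-comparison and correlation battery.

Omnibus group differences use one-way ANOVA for amplitude and thickness
measures and Kruskal–Wallis for mfPERG peak times (the study's fixed
family→test policy; a data-driven Shapiro–Wilk gate is available as an
option).  Post hocs compare each patient group against the controls with
pooled-variance t or Mann–Whitney tests, Holm-adjusted over the two
comparisons.  Structure–function associations use Pearson correlation with
Holm adjustment within each correlation panel.

A summary-statistics path (`anova_from_summary`, `posthoc_from_summary`)
reconstructs the omnibus F values and post hoc p-values directly from group
means, SDs and sizes — the printed tables are sufficient statistics for
these tests, which makes the published results reproducible without
subject-level data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

CONTROL = "Control"
PEAK_TIME_FAMILY = "peak_time"


# --------------------------------------------------------------------------
# summary statistics containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("summary statistics need n >= 2")
        if self.sd < 0:
            raise ValueError("SD must be non-negative")


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float


@dataclass
class PosthocEntry:
    pair: tuple[str, str]
    test: str                 # "pooled-t" or "mann-whitney"
    statistic: float
    df: float | None
    p_raw: float
    p_holm: float | None = None


@dataclass
class GroupComparisonResult:
    measure: str
    test: str                 # "ANOVA" or "Kruskal-Wallis"
    statistic: float
    df1: int
    df2: int | None
    p_raw: float
    p_holm: float | None = None
    posthoc: list[PosthocEntry] = field(default_factory=list)
    normality_p: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_raw: float
    n: int
    p_holm: float | None = None

    @property
    def r2(self) -> float:
        return self.r ** 2


# --------------------------------------------------------------------------
# summary-statistics reconstructions
# --------------------------------------------------------------------------

def _as_summary(g) -> SummaryStats:
    return g if isinstance(g, SummaryStats) else SummaryStats(*g)


def anova_from_summary(groups: Sequence[SummaryStats | tuple]) -> AnovaResult:
    """One-way fixed-effects ANOVA from per-group (mean, SD, n).

    F = [Σ nᵢ(mᵢ − m̄)²/(k−1)] / [Σ (nᵢ−1)sᵢ²/(N−k)] with m̄ the n-weighted
    grand mean — identical to the raw-data ANOVA, since (mean, SD, n) are
    sufficient.  Zero within-group variance with unequal means yields an
    explicit infinite F.
    """
    gs = [_as_summary(g) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    n = np.array([g.n for g in gs], dtype=float)
    m = np.array([g.mean for g in gs])
    s = np.array([g.sd for g in gs])
    k, N = len(gs), n.sum()
    grand = float(np.sum(n * m) / N)
    ss_between = float(np.sum(n * (m - grand) ** 2))
    ss_within = float(np.sum((n - 1) * s ** 2))
    df1, df2 = k - 1, int(N - k)
    ms_between = ss_between / df1
    if ss_within == 0.0:
        if ss_between == 0.0:
            return AnovaResult(F=0.0, df1=df1, df2=df2, p=1.0)
        return AnovaResult(F=np.inf, df1=df1, df2=df2, p=0.0)
    F = ms_between / (ss_within / df2)
    p = float(sps.f.sf(F, df1, df2))
    return AnovaResult(F=float(F), df1=df1, df2=df2, p=p)


def t_from_summary(a: SummaryStats | tuple, b: SummaryStats | tuple) -> tuple[float, int, float]:
    """Two-sided pooled-variance (Student) t test from summary statistics."""
    a, b = _as_summary(a), _as_summary(b)
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd ** 2 + (b.n - 1) * b.sd ** 2) / df
    if sp2 == 0.0:
        if a.mean == b.mean:
            return 0.0, df, 1.0
        return np.inf if a.mean > b.mean else -np.inf, df, 0.0
    t = (a.mean - b.mean) / np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return float(t), df, p


def posthoc_from_summary(
    stats_by_group: Mapping[str, SummaryStats | tuple],
    control: str = CONTROL,
) -> list[PosthocEntry]:
    """Patient-vs-control pooled-t post hocs from printed summary statistics,
    Holm-adjusted over the comparisons."""
    if control not in stats_by_group:
        raise ValueError(f"control group {control!r} absent")
    entries = []
    for grp, st in stats_by_group.items():
        if grp == control:
            continue
        t, df, p = t_from_summary(st, stats_by_group[control])
        entries.append(PosthocEntry(pair=(grp, control), test="pooled-t",
                                    statistic=t, df=df, p_raw=p))
    adj = holm_adjust([e.p_raw for e in entries])
    for e, pa in zip(entries, adj):
        e.p_holm = float(pa)
    return entries


# --------------------------------------------------------------------------
# multiple-testing adjustment
# --------------------------------------------------------------------------

def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm–Bonferroni step-down adjusted p-values.

    Sort ascending, multiply the i-th smallest by (m − i), enforce the
    running maximum, cap at 1, and restore the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = p[order] * (m - np.arange(m))
    adj = np.minimum(np.maximum.accumulate(adj), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


# --------------------------------------------------------------------------
# raw-data battery
# --------------------------------------------------------------------------

def _validate_groups(values_by_group):
    arrays = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for g, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    pooled = np.concatenate(list(arrays.values()))
    if np.ptp(pooled) == 0.0:
        raise ValueError("all values identical: degenerate variance")
    return arrays


def omnibus_test(
    values_by_group: Mapping[str, Sequence[float]],
    family: str = "amplitude",
    measure: str = "",
    policy: str = "paper",
    alpha: float = 0.05,
) -> GroupComparisonResult:
    """Omnibus group comparison with the normality-gated test choice.

    ``policy='paper'`` applies the study's fixed mapping: Kruskal–Wallis for
    the peak-time family, ANOVA otherwise (Shapiro–Wilk p-values are still
    reported).  ``policy='shapiro'`` picks Kruskal–Wallis whenever any group
    rejects normality at ``alpha``.
    """
    arrays = _validate_groups(values_by_group)
    normality = {}
    for g, v in arrays.items():
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")   # tiny groups return NaN
                normality[g] = float(sps.shapiro(v).pvalue)
        except ValueError:
            normality[g] = np.nan

    if policy == "paper":
        use_kw = family == PEAK_TIME_FAMILY
    elif policy == "shapiro":
        use_kw = any(p < alpha for p in normality.values() if not np.isnan(p))
    else:
        raise ValueError(f"unknown policy {policy!r}")

    vals = list(arrays.values())
    k, N = len(vals), sum(len(v) for v in vals)
    if use_kw:
        stat, p = sps.kruskal(*vals)
        return GroupComparisonResult(
            measure=measure, test="Kruskal-Wallis", statistic=float(stat),
            df1=k - 1, df2=None, p_raw=float(p), normality_p=normality,
        )
    stat, p = sps.f_oneway(*vals)
    return GroupComparisonResult(
        measure=measure, test="ANOVA", statistic=float(stat),
        df1=k - 1, df2=N - k, p_raw=float(p), normality_p=normality,
    )


def posthoc_pairwise(
    values_by_group: Mapping[str, Sequence[float]],
    control: str = CONTROL,
    parametric: bool = True,
) -> list[PosthocEntry]:
    """Each patient group vs the control group, Holm-adjusted.

    Pooled-variance two-sided t tests when ``parametric``, Mann–Whitney U
    otherwise.
    """
    arrays = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if control not in arrays:
        raise ValueError(f"control group {control!r} absent")
    for g, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    ctrl = arrays[control]
    entries = []
    for grp, v in arrays.items():
        if grp == control:
            continue
        if parametric:
            res = sps.ttest_ind(v, ctrl, equal_var=True)
            entries.append(PosthocEntry(
                pair=(grp, control), test="pooled-t",
                statistic=float(res.statistic), df=float(len(v) + len(ctrl) - 2),
                p_raw=float(res.pvalue)))
        else:
            res = sps.mannwhitneyu(v, ctrl, alternative="two-sided")
            entries.append(PosthocEntry(
                pair=(grp, control), test="mann-whitney",
                statistic=float(res.statistic), df=None, p_raw=float(res.pvalue)))
    adj = holm_adjust([e.p_raw for e in entries])
    for e, pa in zip(entries, adj):
        e.p_holm = float(pa)
    return entries


def correlate(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with the two-sided t-distribution p (n − 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must pair up")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("zero variance in x or y")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(r=float(r), p_raw=float(p), n=len(x))


def correlation_panel(
    pairs: Mapping[str, tuple[Sequence[float], Sequence[float]]],
) -> dict[str, CorrelationResult]:
    """A family of correlations, Holm-adjusted together."""
    results = {name: correlate(x, y) for name, (x, y) in pairs.items()}
    names = list(results)
    adj = holm_adjust([results[n].p_raw for n in names])
    return {
        n: CorrelationResult(r=results[n].r, p_raw=results[n].p_raw,
                             n=results[n].n, p_holm=float(a))
        for n, a in zip(names, adj)
    }


def adjust_family(results: Sequence[GroupComparisonResult]) -> None:
    """Holm-adjust omnibus p-values across one table family, in place."""
    adj = holm_adjust([r.p_raw for r in results])
    for r, pa in zip(results, adj):
        r.p_holm = float(pa)
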