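"""Delay statistics: DA-CA comparisons, regression, contrasts, power, agreement.

The outcome throughout is the dental-development delay DA - CA (years):
positive values mean dental age runs ahead of chronological age. The module
covers the full downstream analysis of a hypodontia cohort:

* two-group comparisons of DA-CA (pooled-variance Student t by default,
  Welch and Wilcoxon rank-sum as options), from raw data or from published
  summary statistics;
* a marked-delay classification using a -2 SD cutoff from the control-group
  DA-CA distribution, compared between groups by a Yates-corrected
  chi-square;
* a multiple linear regression of DA-CA on agenesis status, sex and CA with
  all interactions, summarised by a marginality-respecting Type II ANOVA;
* severity contrasts (one-way ANOVA + Tukey HSD) and agenesis-pattern
  contrasts (Kruskal-Wallis + Dunn's test, Bonferroni-adjusted);
* the a-priori sample size for a two-sided two-sample t-test (noncentral t);
* Cohen's kappa for intra-rater stage-scoring agreement.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DelayRecord",
    "GroupComparison",
    "CutoffClassification",
    "DelayModelResult",
    "PowerSpec",
    "KappaResult",
    "compute_delays",
    "compare_groups",
    "summary_difference",
    "marked_delay",
    "type2_anova",
    "fit_delay_model",
    "severity_anova",
    "pattern_kruskal",
    "dunn_test",
    "bonferroni",
    "power_two_sample_t",
    "n_per_group",
    "cohens_kappa",
]


@dataclass(frozen=True)
class DelayRecord:
    """Per-individual analysis record: ages, delay and agenesis descriptors."""

    id: str
    group: str
    sex: str
    ca: float
    da: float
    delay: float
    severity: str = "control"
    pattern_key: str = "control"
    da_source: str = "demirjian"

    def __post_init__(self) -> None:
        if not math.isclose(self.delay, self.da - self.ca, abs_tol=1e-9):
            raise ValueError("delay must equal da - ca")


def compute_delays(cohort: pd.DataFrame) -> pd.DataFrame:
    """Build the delay table (one row per individual with a DA) from a scored cohort.

    Individuals with no dental age (pattern could not be imputed) are dropped
    with a count recorded in ``DataFrame.attrs['n_skipped_missing_da']``.
    """
    required = {"id", "group", "sex", "ca", "da"}
    missing_cols = required - set(cohort.columns)
    if missing_cols:
        raise ValueError(f"cohort is missing columns {sorted(missing_cols)}")
    has_da = cohort["da"].notna()
    out = cohort.loc[has_da].copy()
    out["delay"] = out["da"] - out["ca"]
    cols = ["id", "group", "sex", "ca", "da", "delay"]
    for optional in ("severity", "pattern_key", "pattern_label", "da_source"):
        if optional in out.columns:
            cols.append(optional)
    out = out[cols].reset_index(drop=True)
    out.attrs["n_skipped_missing_da"] = int((~has_da).sum())
    return out


@dataclass(frozen=True)
class GroupComparison:
    """Two-group mean comparison with a t-based confidence interval."""

    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    delta: float
    ci95: tuple[float, float]
    t: float
    df: float
    p: float
    method: str

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo <= self.delta <= hi):
            raise ValueError("confidence interval does not contain delta")


def _t_comparison(
    mean_a, sd_a, n_a, mean_b, sd_b, n_b, group_a, group_b, welch: bool
) -> GroupComparison:
    delta = mean_a - mean_b
    va, vb = sd_a**2, sd_b**2
    if welch:
        se = math.sqrt(va / n_a + vb / n_b)
        df = (va / n_a + vb / n_b) ** 2 / (
            (va / n_a) ** 2 / (n_a - 1) + (vb / n_b) ** 2 / (n_b - 1)
        )
        method = "welch"
    else:
        sp2 = ((n_a - 1) * va + (n_b - 1) * vb) / (n_a + n_b - 2)
        se = math.sqrt(sp2 * (1 / n_a + 1 / n_b))
        df = n_a + n_b - 2
        method = "student"
    if se == 0:
        t = 0.0 if delta == 0 else math.copysign(math.inf, delta)
    else:
        t = delta / se
    p = 2 * stats.t.sf(abs(t), df)
    half = stats.t.ppf(0.975, df) * se
    return GroupComparison(
        group_a=group_a, group_b=group_b,
        mean_a=mean_a, mean_b=mean_b, sd_a=sd_a, sd_b=sd_b, n_a=n_a, n_b=n_b,
        delta=delta, ci95=(delta - half, delta + half),
        t=t, df=df, p=min(1.0, p), method=method,
    )


def compare_groups(
    data: pd.DataFrame,
    *,
    value: str = "delay",
    group: str = "group",
    order: tuple[str, str] = ("control", "agenesis"),
    welch: bool = False,
) -> GroupComparison:
    """Two-sample comparison of means, delta = mean(first) - mean(second).

    Pooled-variance Student's t by default; ``welch=True`` for unequal
    variances. The 95% CI comes from the same t distribution.
    """
    a = data.loc[data[group] == order[0], value].to_numpy(float)
    b = data.loc[data[group] == order[1], value].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    return _t_comparison(
        a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b),
        order[0], order[1], welch,
    )


def rank_sum_test(
    data: pd.DataFrame,
    *,
    value: str = "delay",
    group: str = "group",
    order: tuple[str, str] = ("control", "agenesis"),
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) statistic and p for two groups."""
    a = data.loc[data[group] == order[0], value]
    b = data.loc[data[group] == order[1], value]
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def summary_difference(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
    *,
    group_a: str = "control",
    group_b: str = "agenesis",
    welch: bool = False,
) -> GroupComparison:
    """The same comparison as :func:`compare_groups` from summary statistics only.

    Enables reproducing published group contrasts (delta, CI, t, p) when only
    per-group means, SDs and sizes are available.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("group sizes must be at least 2")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be non-negative")
    return _t_comparison(
        float(mean_a), float(sd_a), int(n_a),
        float(mean_b), float(sd_b), int(n_b),
        group_a, group_b, welch,
    )


@dataclass(frozen=True)
class CutoffClassification:
    """Marked-delay classification below control mean - 2 SD, with Yates chi-square."""

    cutoff: float
    counts: Mapping[str, tuple[int, int]]  # group -> (n_below, n_total)
    proportions: Mapping[str, float]
    chi2: float
    p: float

    def __post_init__(self) -> None:
        for g, (below, total) in self.counts.items():
            if not 0 <= below <= total:
                raise ValueError(f"inconsistent counts for group {g}")


def marked_delay(
    delays: pd.DataFrame,
    *,
    value: str = "delay",
    group: str = "group",
    control: str = "control",
) -> CutoffClassification:
    """Classify marked dental delay using a -2 SD cutoff from the control group.

    The cutoff is control mean - 2 x control SD at full precision. Group
    proportions below the cutoff are compared with a 2x2 chi-square with
    Yates' continuity correction.
    """
    ctrl = delays.loc[delays[group] == control, value].to_numpy(float)
    if len(ctrl) < 2:
        raise ValueError("control group empty or too small to define the cutoff")
    cutoff = float(ctrl.mean() - 2.0 * ctrl.std(ddof=1))
    counts, props, table = {}, {}, []
    for g, sub in delays.groupby(group, sort=True):
        vals = sub[value].to_numpy(float)
        below = int((vals < cutoff).sum())
        counts[g] = (below, len(vals))
        props[g] = below / len(vals)
        table.append([below, len(vals) - below])
    if len(table) != 2:
        raise ValueError("marked_delay expects exactly two groups")
    if any(b == 0 for b, _ in counts.values()) and all(b == 0 for b, _ in counts.values()):
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(np.asarray(table), correction=True)
    return CutoffClassification(
        cutoff=cutoff, counts=counts, proportions=props, chi2=float(chi2), p=float(p)
    )


# --- multiple regression with Type II ANOVA -----------------------------------

_TERMS: tuple[tuple[str, ...], ...] = (
    ("agenesis",), ("sex",), ("ca",),
    ("agenesis", "sex"), ("agenesis", "ca"), ("sex", "ca"),
    ("agenesis", "sex", "ca"),
)


def _design(df: pd.DataFrame, terms: Sequence[tuple[str, ...]]) -> np.ndarray:
    cols = [np.ones(len(df))]
    for t in terms:
        cols.append(np.prod([df[f].to_numpy(float) for f in t], axis=0))
    return np.column_stack(cols)


def _rss(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def type2_anova(
    data: pd.DataFrame,
    response: str,
    factors: Sequence[str],
    terms: Sequence[tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Marginality-respecting Type II ANOVA by nested-model RSS differences.

    Each term is tested by adding it to the model containing every term that
    does not include it (its higher-order relatives stay excluded); F uses
    the full model's residual mean square. Equivalent to R's ``car::Anova``
    type II convention.
    """
    if terms is None:
        terms = [
            t for r in range(1, len(factors) + 1)
            for t in itertools.combinations(factors, r)
        ]
    terms = [tuple(t) for t in terms]
    y = data[response].to_numpy(float)
    n = len(y)
    X_full = _design(data, terms)
    rss_full, rank_full = _rss(y, X_full)
    if rank_full < X_full.shape[1]:
        raise ValueError(
            f"rank-deficient design: {X_full.shape[1]} columns, rank {rank_full} "
            f"(terms {terms})"
        )
    df_resid = n - rank_full
    ms_resid = rss_full / df_resid
    rows = []
    for t in terms:
        base = [u for u in terms if not set(t) <= set(u)]
        rss_base, rank_base = _rss(y, _design(data, base))
        rss_with, rank_with = _rss(y, _design(data, base + [t]))
        df_t = rank_with - rank_base
        ss = rss_base - rss_with
        F = (ss / df_t) / ms_resid
        rows.append(
            {
                "term": ":".join(t),
                "sum_sq": ss,
                "df": df_t,
                "F": F,
                "p": float(stats.f.sf(F, df_t, df_resid)),
            }
        )
    rows.append(
        {"term": "Residual", "sum_sq": rss_full, "df": df_resid, "F": np.nan, "p": np.nan}
    )
    return pd.DataFrame(rows)


@dataclass
class DelayModelResult:
    """OLS fit of DA-CA on agenesis, sex and CA with its Type II ANOVA."""

    anova: pd.DataFrame
    coefficients: pd.Series
    residuals: np.ndarray
    fitted: np.ndarray
    shapiro_p: float

    def residual_table(self) -> pd.DataFrame:
        return pd.DataFrame({"fitted": self.fitted, "residual": self.residuals})


def fit_delay_model(delays: pd.DataFrame) -> DelayModelResult:
    """Regress DA-CA on agenesis status, sex, CA and all their interactions.

    Treatment coding with control / female as reference levels; the global
    contribution of each term comes from the marginality-respecting Type II
    ANOVA; residual normality is checked by Shapiro-Wilk.
    """
    df = delays.copy()
    df["agenesis"] = (df["group"] == "agenesis").astype(float)
    df["sex"] = (df["sex"] == "male").astype(float) if df["sex"].dtype == object else df["sex"]
    n_params = len(_TERMS) + 1
    if len(df) <= n_params:
        raise ValueError("not enough observations to fit the full interaction model")
    anova = type2_anova(df, "delay", ["agenesis", "sex", "ca"], terms=_TERMS)
    X = _design(df, _TERMS)
    y = df["delay"].to_numpy(float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    names = ["Intercept"] + [":".join(t) for t in _TERMS]
    shapiro_p = float(stats.shapiro(resid).pvalue) if 3 <= len(resid) <= 5000 else float("nan")
    return DelayModelResult(
        anova=anova,
        coefficients=pd.Series(beta, index=names),
        residuals=resid,
        fitted=fitted,
        shapiro_p=shapiro_p,
    )


# --- severity and pattern contrasts -------------------------------------------

def severity_anova(
    delays: pd.DataFrame,
    *,
    value: str = "delay",
    group: str = "severity",
    order: Sequence[str] = ("control", "mild", "moderate", "oligodontia"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-way ANOVA across severity levels followed by Tukey HSD pairwise tests.

    Levels with fewer than two observations are dropped with a warning.
    Returns (omnibus table, pairwise table with Tukey-adjusted p-values).
    """
    import warnings

    groups, labels = [], []
    for level in order:
        vals = delays.loc[delays[group] == level, value].to_numpy(float)
        if len(vals) < 2:
            if len(vals):
                warnings.warn(f"severity level {level!r} has n={len(vals)} < 2; dropped")
            continue
        groups.append(vals)
        labels.append(level)
    if len(groups) < 2:
        raise ValueError("need at least two severity levels with n >= 2")
    F, p = stats.f_oneway(*groups)
    omnibus = pd.DataFrame(
        {"F": [float(F)], "p": [float(p)], "k": [len(groups)],
         "n": [sum(map(len, groups))]}
    )
    res = stats.tukey_hsd(*groups)
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        ci = res.confidence_interval()
        rows.append(
            {
                "level_a": labels[i],
                "level_b": labels[j],
                "diff": float(np.mean(groups[i]) - np.mean(groups[j])),
                "ci_low": float(ci.low[i, j]),
                "ci_high": float(ci.high[i, j]),
                "p_adj": float(res.pvalue[i, j]),
            }
        )
    return omnibus, pd.DataFrame(rows)


def bonferroni(p_values: Iterable[float], m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, m * p)."""
    p = np.asarray(list(p_values), dtype=float)
    m = len(p) if m is None else m
    return np.minimum(1.0, m * p)


def dunn_test(
    groups: Sequence[np.ndarray], labels: Sequence[str]
) -> pd.DataFrame:
    """Dunn's rank-based post hoc z-tests with tie correction and Bonferroni.

    Uses the pooled-rank statistic z = (Rbar_i - Rbar_j) / SE with
    SE^2 = (N(N+1)/12 - T) (1/n_i + 1/n_j), T = sum(t^3 - t) / (12 (N - 1)).
    """
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1))
    base_var = N * (N + 1) / 12.0 - tie_term
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = math.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2 * stats.norm.sf(abs(z))
        rows.append(
            {
                "group_a": labels[i], "group_b": labels[j],
                "n_a": sizes[i], "n_b": sizes[j],
                "z": z, "p": p,
                "singleton": sizes[i] < 2 or sizes[j] < 2,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = bonferroni(out["p"])
    return out


def pattern_kruskal(
    delays: pd.DataFrame,
    *,
    value: str = "delay",
    group: str = "pattern_label",
) -> tuple[float, float, pd.DataFrame]:
    """Kruskal-Wallis omnibus over agenesis-pattern groups + Dunn post hoc tests.

    Singleton groups participate in the omnibus and are flagged in the
    pairwise table. Returns (H, p, Dunn table with Bonferroni-adjusted p).
    """
    labels = sorted(delays[group].unique())
    groups = [delays.loc[delays[group] == g, value].to_numpy(float) for g in labels]
    if len(groups) < 2:
        raise ValueError("need at least two pattern groups")
    H, p = stats.kruskal(*groups)
    return float(H), float(p), dunn_test(groups, labels)


# --- power / sample size -------------------------------------------------------

@dataclass(frozen=True)
class PowerSpec:
    """Design parameters for a two-sided two-sample t-test."""

    alpha: float = 0.05
    power: float = 0.90
    effect_size: float = 0.413

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must be in (0, 1)")
        if self.effect_size <= 0:
            raise ValueError("effect size d must be positive")


def power_two_sample_t(n_per_group: float, d: float, alpha: float = 0.05) -> float:
    """Exact power of a two-sided two-sample t-test via the noncentral t."""
    df = 2.0 * n_per_group - 2.0
    nc = d * math.sqrt(n_per_group / 2.0)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    upper = stats.nct.sf(tcrit, df, nc)
    lower = stats.nct.cdf(-tcrit, df, nc)
    if np.isnan(lower):  # extreme-tail underflow in scipy's nct
        lower = 0.0
    return float(upper + lower)


@dataclass(frozen=True)
class SampleSizeResult:
    """Integer per-group n plus the continuous solution it was rounded from."""

    n_per_group: int
    n_continuous: float
    achieved_power: float
    spec: PowerSpec


def n_per_group(spec: PowerSpec = PowerSpec()) -> SampleSizeResult:
    """Smallest integer n per group achieving the target power.

    Solves power(n) = target over continuous n (the convention of standard
    power calculators), then rounds up and, because the discrete power curve
    can dip below target at the ceiling, increments until power(n) >= target.
    """
    d, alpha, target = spec.effect_size, spec.alpha, spec.power
    f = lambda n: power_two_sample_t(n, d, alpha) - target
    if f(2.0) >= 0:
        n_cont = 2.0  # minimum admissible group size already reaches the target
    else:
        hi = 4.0
        while f(hi) < 0:
            hi *= 2.0
            if hi > 1e7:
                raise ValueError("power target unreachable for this effect size")
        n_cont = float(optimize.brentq(f, 2.0, hi, xtol=1e-9))
    n = max(2, math.ceil(n_cont - 1e-9))
    while power_two_sample_t(n, d, alpha) < target:
        n += 1
    return SampleSizeResult(
        n_per_group=n,
        n_continuous=n_cont,
        achieved_power=power_two_sample_t(n, d, alpha),
        spec=spec,
    )


# --- rater agreement -----------------------------------------------------------

@dataclass(frozen=True)
class KappaResult:
    """Cohen's kappa with its observed and chance agreement components."""

    kappa: float
    observed_agreement: float
    chance_agreement: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.kappa <= 1.0 + 1e-12:
            raise ValueError("kappa outside [-1, 1]")


def cohens_kappa(ratings1: Sequence, ratings2: Sequence) -> KappaResult:
    """Unweighted Cohen's kappa between two categorical rating vectors.

    Categories are the union of both raters' categories, so ratings that one
    rater never used are still handled. kappa = (po - pe) / (1 - pe).
    """
    r1 = np.asarray(list(ratings1))
    r2 = np.asarray(list(ratings2))
    if r1.shape != r2.shape or r1.ndim != 1 or len(r1) == 0:
        raise ValueError("ratings must be equal-length non-empty 1-D sequences")
    cats = np.union1d(r1, r2)
    n = len(r1)
    po = float(np.mean(r1 == r2))
    pe = float(
        sum((np.mean(r1 == c)) * (np.mean(r2 == c)) for c in cats)
    )
    kappa = 1.0 if pe == 1.0 else (po - pe) / (1.0 - pe)
    return KappaResult(kappa=kappa, observed_agreement=po, chance_agreement=pe, n=n)


def kappa_by_tooth(
    first: pd.DataFrame, second: pd.DataFrame, columns: Sequence[str]
) -> pd.DataFrame:
    """Per-tooth Cohen's kappa between two scoring sessions (same individuals)."""
    rows = []
    for col in columns:
        res = cohens_kappa(first[col], second[col])
        rows.append(
            {"tooth": col, "kappa": res.kappa, "observed": res.observed_agreement,
             "chance": res.chance_agreement, "n": res.n}
        )
    return pd.DataFrame(rows)
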