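"""Normality-routed group comparisons, summaries and correlations.

The framework mirrors how small clinical biomechanics cohorts are
analysed: every comparison first runs distribution diagnostics
(Shapiro-Wilk normality per group, Bartlett homoscedasticity across
groups, both at alpha = 0.05) and the diagnostics then *route* the
comparison to the appropriate test:

two groups, unpaired
    both normal + homoscedastic -> Student t
    both normal, heteroscedastic -> Welch t
    any group non-normal        -> Wilcoxon rank-sum (Mann-Whitney)
two groups, paired
    difference normal           -> paired t
    difference non-normal       -> Wilcoxon signed-rank
three groups
    all normal + homoscedastic  -> one-way ANOVA, SNK-q post hoc
    all normal, heteroscedastic -> Brown-Forsythe, Tamhane T2 post hoc
    any non-normal              -> Kruskal-Wallis, Dunn post hoc

Summaries are "mean +/- SD" for normal samples and "median (range)"
otherwise.  No multiple-testing correction is applied across
properties; post-hoc procedures carry their own adjustment.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, PairingError, ParameterError

__all__ = [
    "ALPHA",
    "Diagnostics",
    "TestResult",
    "route_unpaired",
    "route_paired",
    "route_omnibus",
    "assess_distribution",
    "compare_two_groups",
    "compare_three_groups",
    "t_from_summary",
    "correlation_matrix",
    "summarize_property",
    "significance_stars",
    "compare_groups_table",
    "paired_status_table",
]

ALPHA = 0.05

#: Largest per-group n at which exact rank-test p-values are used
#: (ties force the normal approximation with continuity correction).
EXACT_RANK_N = 25


def significance_stars(p: float) -> str:
    """Tiered annotation: . p<0.10, * p<0.05, ** p<0.01, *** p<0.001."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.10:
        return "."
    return ""


@dataclass(frozen=True)
class Diagnostics:
    """Normality and homoscedasticity diagnostics for >= 1 groups."""

    shapiro_ps: tuple          # one p per group
    bartlett_p: float          # homogeneity of variances across groups
    alpha: float = ALPHA

    @property
    def normal(self) -> tuple:
        return tuple(p >= self.alpha for p in self.shapiro_ps)

    @property
    def all_normal(self) -> bool:
        return all(self.normal)

    @property
    def homoscedastic(self) -> bool:
        return self.bartlett_p >= self.alpha


def route_unpaired(diag: Diagnostics) -> str:
    """Decision table for an unpaired two-group comparison.

    Both groups normal and homoscedastic -> Student t; both normal but
    heteroscedastic -> Welch t; any non-normal group -> rank sum (the
    variance flag is then irrelevant).
    """
    if diag.all_normal and diag.homoscedastic:
        return "student_t"
    if diag.all_normal:
        return "welch_t"
    return "wilcoxon"


def route_paired(diag: Diagnostics) -> str:
    """Paired routing on the normality of the within-pair differences."""
    return "paired_t" if diag.all_normal else "paired_wilcoxon"


def route_omnibus(diag: Diagnostics) -> str:
    """Decision table for a three-group omnibus comparison, with the
    matched post-hoc procedure implied (SNK-q / Tamhane T2 / Dunn)."""
    if diag.all_normal and diag.homoscedastic:
        return "anova"
    if diag.all_normal:
        return "brown_forsythe"
    return "kruskal_wallis"


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p: float
    diagnostics: Diagnostics | None = None
    df: float | None = None
    posthoc: pd.DataFrame | None = None
    alpha: float = ALPHA
    notes: list = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return self.p < self.alpha

    @property
    def stars(self) -> str:
        return significance_stars(self.p)


def _shapiro_p(x: np.ndarray) -> float:
    """Shapiro-Wilk p; a constant sample is treated as maximally
    non-normal (degenerate) rather than crashing."""
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        return 0.0
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        return float(sps.shapiro(x).pvalue)


def assess_distribution(
    *groups, alpha: float = ALPHA, variance_test: str = "bartlett"
) -> Diagnostics:
    """Shapiro-Wilk per group plus Bartlett's test across groups.

    Bartlett's statistic includes the standard small-sample correction
    factor; ``variance_test="levene"`` switches to the Levene
    (mean-centred) alternative.
    """
    if len(groups) < 1:
        raise InsufficientDataError("need at least one group")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    for g in arrs:
        if len(g) < 3:
            raise InsufficientDataError("each group needs n >= 3")
    shapiro_ps = tuple(_shapiro_p(g) for g in arrs)
    if len(arrs) >= 2:
        if any(np.ptp(g) == 0 for g in arrs):
            bartlett_p = 0.0 if any(np.ptp(g) > 0 for g in arrs) else 1.0
        elif variance_test == "bartlett":
            bartlett_p = float(sps.bartlett(*arrs).pvalue)
        elif variance_test == "levene":
            bartlett_p = float(sps.levene(*arrs, center="mean").pvalue)
        else:
            raise ParameterError(f"unknown variance test '{variance_test}'")
    else:
        bartlett_p = float("nan")
    return Diagnostics(shapiro_ps=shapiro_ps, bartlett_p=bartlett_p, alpha=alpha)


def _rank_sum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Wilcoxon rank-sum via the Mann-Whitney U of the first sample.

    Exact p for small tie-free samples, otherwise the normal
    approximation with continuity correction.
    """
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= EXACT_RANK_N and len(b) <= EXACT_RANK_N
                         and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def _signed_rank(diff: np.ndarray) -> tuple[float, float]:
    nz = diff[diff != 0]
    if len(nz) == 0:
        return 0.0, 1.0
    has_ties = len(np.unique(np.abs(nz))) < len(nz)
    method = "exact" if (len(nz) <= EXACT_RANK_N and not has_ties) else "approx"
    res = sps.wilcoxon(diff, alternative="two-sided", method=method,
                       correction=(method == "approx"))
    return float(res.statistic), float(res.pvalue)


def compare_two_groups(
    a,
    b,
    paired: bool = False,
    alpha: float = ALPHA,
    variance_test: str = "bartlett",
) -> TestResult:
    """Diagnostics-routed two-sample comparison, two-sided.

    Unpaired data route to Student t / Welch t / rank-sum as described
    in the module docstring; paired data route on the normality of the
    within-pair differences to the paired t or signed-rank test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise PairingError(f"paired samples differ in length: {len(a)} vs {len(b)}")
        diff = a - b
        if len(diff) < 3:
            raise InsufficientDataError("need n >= 3 pairs")
        if np.ptp(diff) == 0 and diff[0] == 0:
            # identical samples: a null comparison by construction
            diag = Diagnostics(shapiro_ps=(1.0,), bartlett_p=float("nan"), alpha=alpha)
            return TestResult("paired_t", 0.0, 1.0, diag, df=len(diff) - 1, alpha=alpha)
        shapiro_diff = _shapiro_p(diff)
        diag = Diagnostics(shapiro_ps=(shapiro_diff,), bartlett_p=float("nan"),
                           alpha=alpha)
        if route_paired(diag) == "paired_t":
            res = sps.ttest_rel(a, b)
            return TestResult("paired_t", float(res.statistic), float(res.pvalue),
                              diag, df=len(diff) - 1, alpha=alpha)
        stat, p = _signed_rank(diff)
        return TestResult("paired_wilcoxon", stat, p, diag, alpha=alpha)

    diag = assess_distribution(a, b, alpha=alpha, variance_test=variance_test)
    route = route_unpaired(diag)
    if route == "student_t":
        res = sps.ttest_ind(a, b, equal_var=True)
        return TestResult("student_t", float(res.statistic), float(res.pvalue),
                          diag, df=len(a) + len(b) - 2, alpha=alpha)
    if route == "welch_t":
        res = sps.ttest_ind(a, b, equal_var=False)
        return TestResult("welch_t", float(res.statistic), float(res.pvalue),
                          diag, df=float(res.df), alpha=alpha)
    stat, p = _rank_sum(a, b)
    return TestResult("wilcoxon", stat, p, diag, alpha=alpha)


def t_from_summary(
    n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float
) -> tuple[float, float, float]:
    """Pooled-variance two-sample t from summary statistics.

    Returns (t, df, two-sided p) with t signed as mean1 - mean2 on
    n1 + n2 - 2 degrees of freedom.  Useful for re-checking published
    baseline comparisons where only group summaries are printed.
    """
    if n1 < 2 or n2 < 2:
        raise ParameterError("need n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ParameterError("standard deviations must be positive")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (mean1 - mean2) / se
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return t, float(df), p


# ---------------------------------------------------------------------------
# Three-group omnibus tests and post-hoc procedures
# ---------------------------------------------------------------------------

def _brown_forsythe_means(groups: list[np.ndarray]) -> tuple[float, float, float]:
    """Brown-Forsythe F* test for equality of means under unequal
    variances, with Satterthwaite denominator degrees of freedom."""
    k = len(groups)
    ns = np.array([len(g) for g in groups], dtype=float)
    means = np.array([np.mean(g) for g in groups])
    variances = np.array([np.var(g, ddof=1) for g in groups])
    N = ns.sum()
    grand = float(np.sum(ns * means) / N)
    num = float(np.sum(ns * (means - grand) ** 2))
    weights = (1.0 - ns / N) * variances
    den = float(weights.sum())
    fstar = num / den
    c = weights / den
    df2 = 1.0 / float(np.sum(c**2 / (ns - 1.0)))
    p = float(sps.f.sf(fstar, k - 1, df2))
    return fstar, df2, p


def _posthoc_snk(groups: list[np.ndarray], labels: list[str]) -> pd.DataFrame:
    """Student-Newman-Keuls q test on ANOVA residual variance.

    Means are ordered; each pair is tested against the studentized
    range with the span r of the pair in the ordering.  The stepwise
    rule blocks a pair from being declared significant when a wider
    pair containing it already failed.
    """
    k = len(groups)
    ns = np.array([len(g) for g in groups], dtype=float)
    means = np.array([np.mean(g) for g in groups])
    df_w = int(ns.sum()) - k
    mse = float(
        sum(np.sum((g - m) ** 2) for g, m in zip(groups, means)) / df_w
    )
    order = np.argsort(means)
    rank_of = {int(idx): r for r, idx in enumerate(order)}
    rows = []
    nonsig_spans: set[tuple[int, int]] = set()
    # widest spans first so the blocking rule can propagate inwards
    pairs = sorted(
        ((i, j) for i in range(k) for j in range(i + 1, k)),
        key=lambda ij: -abs(rank_of[ij[0]] - rank_of[ij[1]]),
    )
    for i, j in pairs:
        r = abs(rank_of[i] - rank_of[j]) + 1
        # harmonic mean sample size for unequal groups
        nh = 2.0 / (1.0 / ns[i] + 1.0 / ns[j])
        q = abs(means[i] - means[j]) / math.sqrt(mse / nh)
        p = float(sps.studentized_range.sf(q, r, df_w))
        lo = min(rank_of[i], rank_of[j])
        hi = max(rank_of[i], rank_of[j])
        blocked = any(blo <= lo and hi <= bhi for blo, bhi in nonsig_spans)
        sig = (p < ALPHA) and not blocked
        if not sig:
            nonsig_spans.add((lo, hi))
        rows.append({"group1": labels[i], "group2": labels[j],
                     "statistic": q, "p": p, "significant": sig})
    return pd.DataFrame(rows)


def _posthoc_tamhane_t2(groups: list[np.ndarray], labels: list[str]) -> pd.DataFrame:
    """Tamhane's T2: pairwise Welch t tests with Sidak adjustment."""
    k = len(groups)
    m = k * (k - 1) // 2
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            res = sps.ttest_ind(groups[i], groups[j], equal_var=False)
            p_adj = min(1.0, 1.0 - (1.0 - float(res.pvalue)) ** m)
            rows.append({"group1": labels[i], "group2": labels[j],
                         "statistic": float(res.statistic), "p": p_adj,
                         "significant": p_adj < ALPHA})
    return pd.DataFrame(rows)


def _posthoc_dunn(groups: list[np.ndarray], labels: list[str]) -> pd.DataFrame:
    """Dunn's rank-based z tests on the pooled Kruskal-Wallis ranks,
    with the tie correction; unadjusted two-sided p-values."""
    k = len(groups)
    ns = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for n in ns:
        mean_ranks.append(float(np.mean(ranks[start:start + n])))
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1.0))
    base_var = N * (N + 1.0) / 12.0 - tie_term
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            se = math.sqrt(base_var * (1.0 / ns[i] + 1.0 / ns[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * float(sps.norm.sf(abs(z)))
            rows.append({"group1": labels[i], "group2": labels[j],
                         "statistic": z, "p": p, "significant": p < ALPHA})
    return pd.DataFrame(rows)


def compare_three_groups(
    g1,
    g2,
    g3,
    labels: tuple = ("group1", "group2", "group3"),
    alpha: float = ALPHA,
    variance_test: str = "bartlett",
) -> TestResult:
    """Diagnostics-routed three-group omnibus test with matched post hoc.

    Routes to ANOVA (+ SNK-q), Brown-Forsythe (+ Tamhane T2) or
    Kruskal-Wallis (+ Dunn); post-hoc pairwise comparisons are reported
    only when the omnibus test rejects at ``alpha``.
    """
    groups = [np.asarray(g, dtype=float) for g in (g1, g2, g3)]
    if any(len(g) < 3 for g in groups):
        raise InsufficientDataError("each of the three groups needs n >= 3")
    diag = assess_distribution(*groups, alpha=alpha, variance_test=variance_test)
    labels = list(labels)
    route = route_omnibus(diag)
    if route == "anova":
        res = sps.f_oneway(*groups)
        result = TestResult("anova", float(res.statistic), float(res.pvalue),
                            diag, alpha=alpha)
        posthoc = _posthoc_snk
    elif route == "brown_forsythe":
        fstar, df2, p = _brown_forsythe_means(groups)
        result = TestResult("brown_forsythe", fstar, p, diag, df=df2, alpha=alpha)
        posthoc = _posthoc_tamhane_t2
    else:
        res = sps.kruskal(*groups)
        result = TestResult("kruskal_wallis", float(res.statistic),
                            float(res.pvalue), diag, alpha=alpha)
        posthoc = _posthoc_dunn
    if result.significant:
        result.posthoc = posthoc(groups, labels)
    return result


# ---------------------------------------------------------------------------
# Correlations and summaries
# ---------------------------------------------------------------------------

def correlation_matrix(table: pd.DataFrame, columns: list[str] | None = None):
    """Pairwise Pearson R with two-sided p and star annotations.

    Returns a dict with square DataFrames ``r``, ``p``, ``stars``, the
    number of complete rows used per pair in ``n``, and a list of
    constant columns whose correlations are undefined (reported as NaN
    rather than raising).
    """
    if columns is None:
        columns = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    k = len(columns)
    r = pd.DataFrame(np.eye(k), index=columns, columns=columns)
    p = pd.DataFrame(np.zeros((k, k)), index=columns, columns=columns)
    n = pd.DataFrame(np.zeros((k, k), dtype=int), index=columns, columns=columns)
    constant: list[str] = []
    for c in columns:
        vals = table[c].dropna()
        if len(vals) and np.ptp(vals.to_numpy(dtype=float)) == 0:
            constant.append(c)
    for i in range(k):
        for j in range(k):
            sub = table[[columns[i], columns[j]]].dropna()
            n.iloc[i, j] = len(sub)
            if i == j:
                continue
            if len(sub) < 3:
                raise InsufficientDataError(
                    f"need >= 3 complete rows for ({columns[i]}, {columns[j]})"
                )
            x = sub[columns[i]].to_numpy(dtype=float)
            y = sub[columns[j]].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                r.iloc[i, j] = np.nan
                p.iloc[i, j] = np.nan
                continue
            res = sps.pearsonr(x, y)
            r.iloc[i, j] = float(res.statistic)
            p.iloc[i, j] = float(res.pvalue)
    stars = p.map(lambda v: significance_stars(v) if np.isfinite(v) else "")
    np.fill_diagonal(stars.values, "")
    return {"r": r, "p": p, "stars": stars, "n": n, "constant_columns": constant}


@dataclass(frozen=True)
class PropertySummary:
    text: str
    normal: bool
    mean: float
    sd: float
    median: float
    minimum: float
    maximum: float
    n: int


def summarize_property(samples, alpha: float = ALPHA, decimals: int = 2
                       ) -> PropertySummary:
    """Normality-routed summary: "mean +/- SD" or "median (range)".

    A constant sample is degenerate and reported in median/range form.
    """
    x = np.asarray(samples, dtype=float)
    if len(x) < 3:
        raise InsufficientDataError("need n >= 3 to summarize")
    normal = _shapiro_p(x) >= alpha
    mean, sd = float(np.mean(x)), float(np.std(x, ddof=1))
    med = float(np.median(x))
    lo, hi = float(np.min(x)), float(np.max(x))
    if normal:
        text = f"{mean:.{decimals}f}±{sd:.{decimals}f}"
    else:
        text = f"{med:.{decimals}f} (range: {lo:.{decimals}f}~{hi:.{decimals}f})"
    return PropertySummary(text=text, normal=normal, mean=mean, sd=sd,
                           median=med, minimum=lo, maximum=hi, n=len(x))


# ---------------------------------------------------------------------------
# Cohort-table drivers
# ---------------------------------------------------------------------------

PROPERTY_COLUMNS = [
    "h0_mm", "peak_strain_pct", "peak_stress_kPa", "E_kPa", "eta_kPa_s", "edr_pct",
]


def compare_groups_table(
    table: pd.DataFrame,
    group_a: str,
    group_b: str,
    properties: list[str] | None = None,
    statuses: list[str] | None = None,
) -> pd.DataFrame:
    """Two-group comparison of every property at every loading status.

    Legs enter as independent observations, matching the convention of
    per-leg clinical summary tables.  Returns one row per
    (status, property) with group summaries, the routed test, its
    statistic and p, and the star annotation.
    """
    properties = properties or PROPERTY_COLUMNS
    statuses = statuses or sorted(table["status"].unique())
    rows = []
    for status in statuses:
        sub = table[table["status"] == status]
        for prop in properties:
            a = sub.loc[sub["group"] == group_a, prop].to_numpy(dtype=float)
            b = sub.loc[sub["group"] == group_b, prop].to_numpy(dtype=float)
            res = compare_two_groups(a, b)
            rows.append({
                "status": status,
                "property": prop,
                f"summary_{group_a}": summarize_property(a).text,
                f"summary_{group_b}": summarize_property(b).text,
                "test": res.test_name,
                "statistic": res.statistic,
                "p": res.p,
                "stars": res.stars,
            })
    return pd.DataFrame(rows)


def paired_status_table(
    table: pd.DataFrame,
    status_a: str = "time_zero",
    status_b: str = "post_loading",
    properties: list[str] | None = None,
) -> pd.DataFrame:
    """Within-leg paired comparison between the two loading statuses,
    per group and property (loading-history effect)."""
    properties = properties or PROPERTY_COLUMNS
    rows = []
    for group in sorted(table["group"].unique()):
        sub = table[table["group"] == group]
        pivot = sub.pivot_table(index=["subject", "leg"], columns="status",
                                values=properties)
        for prop in properties:
            wide = pivot[prop].dropna(subset=[status_a, status_b])
            a = wide[status_a].to_numpy(dtype=float)
            b = wide[status_b].to_numpy(dtype=float)
            res = compare_two_groups(a, b, paired=True)
            rows.append({
                "group": group,
                "property": prop,
                "mean_diff": float(np.mean(a - b)),
                "test": res.test_name,
                "statistic": res.statistic,
                "p": res.p,
                "stars": res.stars,
            })
    return pd.DataFrame(rows)
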