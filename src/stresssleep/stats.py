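"""The study's statistics layer behind one uniform result type.

Covers every test used in the analyses: Pearson correlation with OLS,
two-sided Fisher exact (probability method), two-sample Kolmogorov-Smirnov,
one-way ANOVA with Tukey's multiple comparisons, mixed-design (two-way
repeated-measures) ANOVA with Sidak's multiple comparisons, ANCOVA
slope/intercept homogeneity, and the unpaired t test.  Multiplicity
handling mirrors the original analyses exactly: Tukey within ANOVA
families, Sidak within the repeated-measures family, no correction
elsewhere.

Engines: scipy.stats for the classical tests, pingouin for the mixed
ANOVA; the ANCOVA nested-model F tests are computed directly from least
squares because no single library call exposes the slope-homogeneity /
intercept-homogeneity pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .thermometry import RegressionFit, fit_xy


@dataclass
class TestResult:
    """One statistical test: method, statistic, df, two-sided p."""

    method: str
    statistic: float
    df: float | tuple
    p: float
    adjusted_p: float | None = None
    n: tuple = ()
    comparison: str = ""
    degenerate: bool = False
    extra: dict = field(default_factory=dict)

    def to_record(self) -> dict:
        return {
            "method": self.method,
            "comparison": self.comparison,
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p,
            "adjusted_p": self.adjusted_p,
            "n": list(self.n),
            "degenerate": self.degenerate,
        }


@dataclass
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(v) != v or v < 0 for v in cells):
            raise ValueError("cells must be non-negative integers")
        if sum(cells) < 1:
            raise ValueError("table must contain at least one observation")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def pearson_test(x, y) -> TestResult:
    """Pearson r with two-sided p from t = r sqrt((n-2)/(1-r^2)), n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return TestResult(
        method="pearson", statistic=float(r), df=n - 2, p=float(p), n=(n,)
    )


def unpaired_t(x, y, welch: bool = False) -> TestResult:
    """Two-sided unpaired t test (pooled variance; Welch optional)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need n >= 2")
    res = stats.ttest_ind(x, y, equal_var=not welch)
    degenerate = not np.isfinite(res.statistic)
    return TestResult(
        method="welch_t" if welch else "unpaired_t",
        statistic=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue) if not degenerate else (1.0 if np.allclose(x.mean(), y.mean()) else np.nan),
        n=(len(x), len(y)),
        degenerate=degenerate,
    )


def fisher_exact_two_sided(table: ContingencyTable2x2) -> TestResult:
    """Two-sided Fisher exact p by the probability method.

    Sums the hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed the observed table's.
    """
    arr = table.as_array()
    odds, p = stats.fisher_exact(arr, alternative="two-sided")
    return TestResult(
        method="fisher_exact",
        statistic=float(odds),
        df=np.nan,
        p=float(p),
        n=(int(arr[0].sum()), int(arr[1].sum())),
    )


def ks_two_sample(x, y) -> TestResult:
    """Two-sample KS: D = sup |ECDF_x - ECDF_y|.

    Exact p when m*n <= 10^4 (lattice-path enumeration), asymptotic above.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if len(x) * len(y) <= 10_000 else "asymp"
    res = stats.ks_2samp(x, y, method=method)
    return TestResult(
        method="ks_2samp",
        statistic=float(res.statistic),
        df=np.nan,
        p=float(res.pvalue),
        n=(len(x), len(y)),
        extra={"p_method": method},
    )


def oneway_anova_tukey(
    groups: list[np.ndarray], names: list[str] | None = None
) -> tuple[TestResult, list[TestResult]]:
    """One-way ANOVA F test plus Tukey HSD pairwise comparisons.

    Tukey p-values come from the studentized-range distribution with the
    Tukey-Kramer correction for unequal group sizes (pooled MS_within).
    Zero within-group variance yields a flagged degenerate result instead
    of raising, so pipelines on pathological data keep running.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with n >= 2 each")
    names = names or [f"g{i}" for i in range(len(groups))]
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    ms_within = sum(np.sum((g - g.mean()) ** 2) for g in groups) / (n_total - k)
    if ms_within == 0:
        omni = TestResult(
            method="oneway_anova",
            statistic=np.nan,
            df=(k - 1, n_total - k),
            p=np.nan,
            n=tuple(len(g) for g in groups),
            degenerate=True,
        )
        return omni, []
    f, p = stats.f_oneway(*groups)
    omni = TestResult(
        method="oneway_anova",
        statistic=float(f),
        df=(k - 1, n_total - k),
        p=float(p),
        n=tuple(len(g) for g in groups),
    )
    hsd = stats.tukey_hsd(*groups)
    pairwise = []
    for i in range(k):
        for j in range(i + 1, k):
            # unadjusted pairwise p from the pooled-variance t statistic
            se = np.sqrt(ms_within * (1 / len(groups[i]) + 1 / len(groups[j])))
            t = (groups[i].mean() - groups[j].mean()) / se
            p_raw = 2 * stats.t.sf(abs(t), n_total - k)
            pairwise.append(
                TestResult(
                    method="tukey_hsd",
                    comparison=f"{names[i]} vs {names[j]}",
                    statistic=float(hsd.statistic[i, j]),
                    df=(k, n_total - k),
                    p=float(p_raw),
                    adjusted_p=float(hsd.pvalue[i, j]),
                    n=(len(groups[i]), len(groups[j])),
                )
            )
    return omni, pairwise


def sidak_adjust(p: float, m: int) -> float:
    """Sidak family-wise adjustment: p_adj = 1 - (1 - p)^m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(1.0 - (1.0 - p) ** m)


def twoway_rm_anova_sidak(
    values: np.ndarray,
    groups: list[str],
    level_names: tuple[str, str] = ("absent", "present"),
    comparisons: str = "within",
) -> tuple[list[TestResult], list[TestResult]]:
    """Mixed-design ANOVA (between-group x two-level within) with Sidak tests.

    ``values`` is (n_subjects, 2): one row per subject, one column per
    within-subject level (e.g. target absent / present).  Returns the three
    omnibus F tests (between, within, interaction; the within-subject error
    term is used for the within and interaction effects) and the Sidak-
    adjusted follow-up comparisons: paired t per group across levels
    (``comparisons="within"``) or unpaired t per group pair at each level
    (``comparisons="between"``).  With a two-level within factor sphericity
    holds trivially, so no correction is applied.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] != 2:
        raise ValueError("values must be (n_subjects, 2)")
    if np.isnan(values).any():
        raise ValueError("missing cells are not allowed in the mixed design")
    groups = list(groups)
    if len(groups) != len(values):
        raise ValueError("one group label per subject required")
    uniq = list(dict.fromkeys(groups))
    if any(groups.count(g) < 2 for g in uniq):
        raise ValueError("every group needs >= 2 subjects")

    import warnings

    import pingouin as pg

    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(len(values)), 2),
            "group": np.repeat(groups, 2),
            "level": np.tile(level_names, len(values)),
            "value": values.ravel(),
        }
    )
    with warnings.catch_warnings():
        # zero-variance designs divide 0/0 inside the engine; handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        aov = pg.mixed_anova(
            data=long, dv="value", within="level", subject="subject", between="group"
        )
    omnibus = []
    for _, row in aov.iterrows():
        f, p = float(row["F"]), float(row["p_unc"])
        degenerate = not np.isfinite(f)
        if degenerate:
            # zero within-subject error: a zero-SS effect has F = 0
            f, p = (0.0, 1.0) if float(row["SS"]) <= 1e-12 else (np.inf, 0.0)
        omnibus.append(
            TestResult(
                method="mixed_anova",
                comparison=str(row["Source"]),
                statistic=f,
                df=(float(row["DF1"]), float(row["DF2"])),
                p=p,
                n=tuple(groups.count(g) for g in uniq),
                degenerate=degenerate,
            )
        )

    followups = []
    if comparisons == "within":
        m = len(uniq)
        for g in uniq:
            sel = np.array([gg == g for gg in groups])
            res = stats.ttest_rel(values[sel, 0], values[sel, 1])
            p = float(res.pvalue) if np.isfinite(res.statistic) else 1.0
            followups.append(
                TestResult(
                    method="sidak_paired_t",
                    comparison=f"{g}: {level_names[0]} vs {level_names[1]}",
                    statistic=float(res.statistic),
                    df=int(sel.sum()) - 1,
                    p=p,
                    adjusted_p=sidak_adjust(p, m),
                    n=(int(sel.sum()),),
                    degenerate=not np.isfinite(res.statistic),
                )
            )
    elif comparisons == "between":
        pairs = [(a, b) for i, a in enumerate(uniq) for b in uniq[i + 1 :]]
        m = len(pairs) * 2
        for lvl_idx, lvl in enumerate(level_names):
            for a, b in pairs:
                xa = values[np.array([g == a for g in groups]), lvl_idx]
                xb = values[np.array([g == b for g in groups]), lvl_idx]
                res = unpaired_t(xa, xb)
                followups.append(
                    TestResult(
                        method="sidak_unpaired_t",
                        comparison=f"{lvl}: {a} vs {b}",
                        statistic=res.statistic,
                        df=res.df,
                        p=res.p,
                        adjusted_p=sidak_adjust(res.p, m),
                        n=res.n,
                        degenerate=res.degenerate,
                    )
                )
    else:
        raise ValueError("comparisons must be 'within' or 'between'")
    return omnibus, followups


@dataclass
class AncovaResult:
    """Slope- and intercept-homogeneity tests across groups.

    The slope test is the F test on the interaction block of the full model
    y ~ x + group + x:group.  When slope equality is not rejected at
    ``alpha``, intercepts are compared under the common-slope model (the
    classical ANCOVA group test); otherwise ``p_intercept_equal`` is None
    because group effects are not comparable at a single intercept.
    """

    group_fits: list[RegressionFit]
    p_slope_equal: float
    p_intercept_equal: float | None
    common_slope: float
    group_intercepts: list[float]
    f_slope: float
    f_intercept: float | None
    alpha: float
    degenerate: bool = False


def _lstsq_rss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def ancova_compare(
    groups: list[tuple[np.ndarray, np.ndarray]], alpha: float = 0.05
) -> AncovaResult:
    """Compare regression slopes, then intercepts, across groups.

    With a single group this degenerates to plain OLS (slope test p = 1).
    Noiseless inputs (zero residual variance in the full model) are
    handled as degenerate: coefficient estimates remain exact and the
    slope test reports p = 1 when the interaction coefficients are all
    zero, 0 otherwise.
    """
    fits = []
    for x, y in groups:
        x = np.asarray(x, dtype=float)
        if len(x) < 3:
            raise ValueError("each group needs n >= 3")
        if np.ptp(x) == 0:
            raise ValueError("degenerate x within a group")
        fits.append(fit_xy(x, y))

    k = len(groups)
    x_all = np.concatenate([np.asarray(x, dtype=float) for x, _ in groups])
    y_all = np.concatenate([np.asarray(y, dtype=float) for _, y in groups])
    gidx = np.concatenate(
        [np.full(len(x), i) for i, (x, _) in enumerate(groups)]
    ).astype(int)
    n = len(x_all)

    ones = np.ones(n)
    dummies = [(gidx == i).astype(float) for i in range(1, k)]
    X_full = np.column_stack(
        [ones, x_all, *dummies, *[d * x_all for d in dummies]]
    )
    X_cs = np.column_stack([ones, x_all, *dummies])  # common slope
    X_1 = np.column_stack([ones, x_all])  # single line

    beta_full, rss_full = _lstsq_rss(X_full, y_all)
    beta_cs, rss_cs = _lstsq_rss(X_cs, y_all)
    _, rss_1 = _lstsq_rss(X_1, y_all)

    df_full = n - 2 * k
    df_cs = n - (k + 1)
    interaction_coefs = beta_full[k + 1 :] if k > 1 else np.array([])
    common_slope = float(beta_cs[1])
    base_int = float(beta_cs[0])
    group_intercepts = [base_int] + [base_int + float(b) for b in beta_cs[2 : k + 1]]

    degenerate = False
    if k == 1:
        p_slope, f_slope = 1.0, 0.0
    elif rss_full <= 1e-12 * max(1.0, float(y_all @ y_all)):
        degenerate = True
        f_slope = np.inf if np.any(np.abs(interaction_coefs) > 1e-9) else 0.0
        p_slope = 0.0 if f_slope == np.inf else 1.0
    else:
        f_slope = ((rss_cs - rss_full) / (k - 1)) / (rss_full / df_full)
        p_slope = float(stats.f.sf(f_slope, k - 1, df_full))

    p_intercept = f_intercept = None
    if k > 1 and p_slope >= alpha:
        if rss_cs <= 1e-12 * max(1.0, float(y_all @ y_all)):
            degenerate = True
            differs = rss_1 - rss_cs > 1e-9 * max(1.0, rss_1)
            f_intercept = np.inf if differs else 0.0
            p_intercept = 0.0 if differs else 1.0
        else:
            f_intercept = ((rss_1 - rss_cs) / (k - 1)) / (rss_cs / df_cs)
            p_intercept = float(stats.f.sf(f_intercept, k - 1, df_cs))

    return AncovaResult(
        group_fits=fits,
        p_slope_equal=float(p_slope),
        p_intercept_equal=p_intercept,
        common_slope=common_slope,
        group_intercepts=group_intercepts,
        f_slope=float(f_slope),
        f_intercept=f_intercept,
        alpha=alpha,
        degenerate=degenerate,
    )
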