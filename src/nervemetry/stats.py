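"""Cohort statistics and the reliability/repeatability battery.

Group comparisons use the Kruskal-Wallis omnibus test followed by pairwise
Wilcoxon rank-sum tests; clinical correlations are Spearman, with a
trendline-residual outlier rule (points more than ``sd_threshold`` residual
SDs from an OLS fit are excluded and the correlation reported both ways);
demographic screening in controls uses rank-based partial correlations (age,
BMI) and rank-sum tests (sex); leg disability is modeled by a multiple linear
regression on standardized predictors with ANOVA-based pruning.

Raw p-values are reported throughout — no multiple-comparison correction —
and all tests are two-sided.

Reliability: ICC is the two-way random-effects, absolute-agreement,
single-measurement coefficient (overridable); CV is the root-mean-square of
per-subject coefficients of variation (a pooled SD-of-differences variant is
available); test-retest agreement uses Bland-Altman limits on the relative
(percent-of-pair-mean) differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.anova import anova_lm

__all__ = [
    "GroupComparisonResult",
    "CorrelationResult",
    "RegressionResult",
    "ReliabilityResult",
    "group_compare",
    "correlate_with_outlier_rule",
    "demographic_screen",
    "fit_disability_model",
    "interrater_reliability",
    "test_retest",
    "rank_sum_test",
    "icc_agreement",
]


@dataclass
class GroupComparisonResult:
    metric: str
    kruskal_stat: float
    kruskal_p: float
    pairwise_p: dict[tuple[str, str], float]
    group_n: dict[str, int]
    group_median: dict[str, float]
    group_iqr: dict[str, float]


@dataclass
class CorrelationResult:
    x_metric: str
    y_metric: str
    rho: float  # outliers excluded
    p: float
    n_used: int
    outlier_ids: list[str]
    rho_with_outliers: float
    p_with_outliers: float


@dataclass
class RegressionResult:
    response: str
    coefficients: dict[str, tuple[float, float, float]]  # term -> (beta, se, p)
    retained: list[str]
    pruned: list[str]
    adjusted_r2: float
    model_p: float
    n: int


@dataclass
class ReliabilityResult:
    metric: str
    icc: float
    cv_percent: float
    bias: float | None = None
    loa_lower: float | None = None
    loa_upper: float | None = None
    paired_t_p: float | None = None
    means: tuple[float, float] | None = None
    sds: tuple[float, float] | None = None
    n: int = 0


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

def rank_sum_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact when both samples have <= 25 observations and there are no ties;
    otherwise the normal approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (len(a) <= 25 and len(b) <= 25 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.pvalue)


def group_compare(cohort: pd.DataFrame, metric: str) -> GroupComparisonResult:
    """Kruskal-Wallis omnibus plus post-hoc pairwise rank-sum tests for one metric."""
    if metric not in cohort.columns:
        raise KeyError(f"metric column {metric!r} not in cohort table")
    groups = {
        g: sub[metric].dropna().to_numpy()
        for g, sub in cohort.groupby("group", sort=False)
    }
    groups = {g: v for g, v in groups.items() if len(v) >= 3}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups with >= 3 subjects each")
    values = list(groups.values())
    if np.unique(np.concatenate(values)).size == 1:
        warnings.warn(f"metric {metric!r} is constant across all groups; p undefined", stacklevel=2)
        stat, omni_p = np.nan, np.nan
        pairwise = {tuple(pair): np.nan for pair in combinations(groups, 2)}
    else:
        stat, omni_p = sps.kruskal(*values)
        pairwise = {
            (g1, g2): rank_sum_test(groups[g1], groups[g2])
            for g1, g2 in combinations(groups, 2)
        }
    return GroupComparisonResult(
        metric=metric,
        kruskal_stat=float(stat),
        kruskal_p=float(omni_p),
        pairwise_p=pairwise,
        group_n={g: len(v) for g, v in groups.items()},
        group_median={g: float(np.median(v)) for g, v in groups.items()},
        group_iqr={
            g: float(np.percentile(v, 75) - np.percentile(v, 25)) for g, v in groups.items()
        },
    )


# ---------------------------------------------------------------------------
# Correlations with the trendline outlier rule
# ---------------------------------------------------------------------------

def correlate_with_outlier_rule(
    cohort: pd.DataFrame,
    x_metric: str,
    y_metric: str,
    sd_threshold: float = 2.5,
    extra_exclusions: tuple[str, ...] = (),
) -> CorrelationResult:
    """Spearman correlation with trendline-residual outlier exclusion.

    An OLS line of ``y_metric`` on ``x_metric`` is fit over all complete
    pairs; points lying more than ``sd_threshold`` standard deviations from
    the trendline are flagged as outliers and the correlation recomputed
    without them.  Both versions are reported.  "Standard deviations from the
    trendline" is measured by the externally studentized (deletion) residual,
    so a gross outlier cannot inflate the very residual scale it is judged
    against.  Outliers identified on one pair propagate to other correlations
    via ``extra_exclusions`` (caller-supplied subject ids), never by
    re-derivation.
    """
    data = cohort.loc[~cohort["subject_id"].isin(extra_exclusions), ["subject_id", x_metric, y_metric]]
    data = data.dropna()
    if len(data) < 5:
        raise ValueError(f"need >= 5 complete ({x_metric}, {y_metric}) pairs, got {len(data)}")
    x = data[x_metric].to_numpy(float)
    y = data[y_metric].to_numpy(float)
    rho_all, p_all = sps.spearmanr(x, y)

    n = len(x)
    X = np.c_[np.ones(n), x]
    h = np.einsum("ij,jk,ik->i", X, np.linalg.pinv(X.T @ X), X)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sse = float((resid**2).sum())
    # relative tolerance: numerically perfect fits leave rounding-level residue
    if sse <= 1e-20 * max(float((y**2).sum()), 1.0) or n <= 3:
        outlier_ids: list[str] = []  # perfect fit: no outlier flaggable
    else:
        # externally studentized residuals: each point judged against the
        # residual scale of the fit that excludes it
        with np.errstate(divide="ignore", invalid="ignore"):
            s2_del = (sse - resid**2 / (1.0 - h)) / (n - 3)
            t = np.abs(resid) / np.sqrt(np.maximum(s2_del, 0.0) * (1.0 - h))
        # s2_del <= 0 means the point carries essentially all residual
        # variance: an unambiguous outlier.
        t = np.where(np.isfinite(t), t, np.inf)
        outlier_ids = data.loc[t > sd_threshold, "subject_id"].tolist()

    keep = ~data["subject_id"].isin(outlier_ids)
    xs, ys = x[keep.to_numpy()], y[keep.to_numpy()]
    rho, p = sps.spearmanr(xs, ys)
    return CorrelationResult(
        x_metric=x_metric,
        y_metric=y_metric,
        rho=float(rho),
        p=float(p),
        n_used=int(keep.sum()),
        outlier_ids=outlier_ids,
        rho_with_outliers=float(rho_all),
        p_with_outliers=float(p_all),
    )


# ---------------------------------------------------------------------------
# Demographic screening in controls
# ---------------------------------------------------------------------------

def demographic_screen(
    controls: pd.DataFrame, biomarkers: tuple[str, ...] = ("mtr", "csa", "circularity")
) -> dict[str, dict[str, object]]:
    """Screen control-cohort biomarkers against age, BMI and sex.

    Age and BMI use rank-based (Spearman-type) partial correlations, each
    conditioned on the other demographic plus sex; sex uses a two-sample
    rank-sum test.  Returns ``{biomarker: {"age": (r, p), "bmi": (r, p),
    "sex_p": p}}``.
    """
    for col in ("age", "bmi", "sex"):
        if col not in controls.columns:
            raise KeyError(f"missing demographic column {col!r}")
    if (controls["group"] != "control").any():
        raise ValueError("demographic screen runs on the control cohort only")
    if len(controls) < 8:
        raise ValueError(f"need >= 8 control subjects, got {len(controls)}")
    df = controls.copy()
    df["sex_num"] = (df["sex"] == "M").astype(float)
    out: dict[str, dict[str, object]] = {}
    for bm in biomarkers:
        entry: dict[str, object] = {}
        if df[bm].nunique() <= 1:
            warnings.warn(f"biomarker {bm!r} is constant in controls; screen degenerate", stacklevel=2)
            out[bm] = {"age": (np.nan, np.nan), "bmi": (np.nan, np.nan), "sex_p": np.nan}
            continue
        for var, covars in (("age", ["bmi", "sex_num"]), ("bmi", ["age", "sex_num"])):
            res = pg.partial_corr(data=df, x=var, y=bm, covar=covars, method="spearman")
            entry[var] = (float(res["r"].iloc[0]), float(res["p_val"].iloc[0]))
        males = df.loc[df["sex"] == "M", bm].to_numpy()
        females = df.loc[df["sex"] == "F", bm].to_numpy()
        entry["sex_p"] = (
            rank_sum_test(males, females) if len(males) >= 1 and len(females) >= 1 else np.nan
        )
        out[bm] = entry
    return out


# ---------------------------------------------------------------------------
# Disability regression with ANOVA pruning
# ---------------------------------------------------------------------------

def fit_disability_model(
    patients: pd.DataFrame,
    candidate_terms: tuple[str, ...] = ("sex", "mtr", "csa"),
    prune_alpha: float = 0.05,
    exclude_ids: tuple[str, ...] = (),
    response: str = "cmtes_l",
) -> RegressionResult:
    """Multiple linear regression of leg disability with ANOVA-based pruning.

    Continuous predictors are z-scored; sex enters as a 0/1 male indicator
    (female reference).  The full model is fit, a term-wise ANOVA (type II)
    computed, and terms whose p-value is >= ``prune_alpha`` — or undefined,
    as happens for a zero-contribution term in a saturated/noise-free fit —
    are dropped before the final refit.  Standardized coefficients, standard
    errors, adjusted R² and the overall model p are reported.
    """
    df = patients.loc[
        (patients["group"] != "control") & ~patients["subject_id"].isin(exclude_ids)
    ].copy()
    cols = [response] + [t for t in candidate_terms if t != "sex"]
    df = df.dropna(subset=[c for c in cols if c in df.columns])
    terms = list(candidate_terms)
    if "sex" in terms and df["sex"].nunique() < 2:
        warnings.warn("single-sex cohort: sex term dropped from the disability model", stacklevel=2)
        terms.remove("sex")
    if len(df) <= len(terms) + 2:
        raise ValueError(f"too few patients (n={len(df)}) for {len(terms)} candidate terms")

    X = pd.DataFrame(index=df.index)
    for t in terms:
        if t == "sex":
            X["sex"] = (df["sex"] == "M").astype(float)
        else:
            v = df[t].astype(float)
            sd = v.std(ddof=1)
            if sd == 0:
                warnings.warn(f"predictor {t!r} is constant; dropped", stacklevel=2)
                continue
            X[t] = (v - v.mean()) / sd
    terms = list(X.columns)
    cond = np.linalg.cond(sm.add_constant(X).to_numpy())
    if cond > 1e6:
        warnings.warn(f"ill-conditioned design matrix (condition number {cond:.2g})", stacklevel=2)
    work = X.copy()
    work["_y"] = df[response].astype(float)

    def _fit(use_terms: list[str]):
        rhs = " + ".join(use_terms) if use_terms else "1"
        return smf.ols(f"_y ~ {rhs}", data=work).fit()

    full = _fit(terms)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        aov = anova_lm(full, typ=2)
    tss = float(((work["_y"] - work["_y"].mean()) ** 2).sum())
    if full.ssr <= 1e-12 * max(tss, 1.0):
        # numerically saturated (noise-free) fit: F statistics are 0/0 noise,
        # so prune by each term's sum-of-squares contribution instead
        retained = [t for t in terms if float(aov.loc[t, "sum_sq"]) > 1e-9 * max(tss, 1.0)]
    else:
        term_p = {t: float(aov.loc[t, "PR(>F)"]) for t in terms}
        retained = [t for t in terms if np.isfinite(term_p[t]) and term_p[t] < prune_alpha]
    pruned = [t for t in terms if t not in retained]
    if not retained:
        warnings.warn("every candidate term was pruned; reporting intercept-only model", stacklevel=2)
    final = _fit(retained)

    coeffs = {
        name.replace("Intercept", "intercept"): (
            float(final.params[name]),
            float(final.bse[name]),
            float(final.pvalues[name]),
        )
        for name in final.params.index
    }
    return RegressionResult(
        response=response,
        coefficients=coeffs,
        retained=retained,
        pruned=pruned,
        adjusted_r2=float(final.rsquared_adj),
        model_p=float(final.f_pvalue) if retained else np.nan,
        n=len(df),
    )


# ---------------------------------------------------------------------------
# Reliability / repeatability
# ---------------------------------------------------------------------------

_ICC_TYPES = {
    "two-way-random-absolute-single": ("ICC2", "ICC(A,1)"),
    "one-way-random-single": ("ICC1", "ICC(1,1)"),
    "two-way-mixed-consistency-single": ("ICC3", "ICC(C,1)"),
}


def icc_agreement(
    measurements: np.ndarray, variant: str = "two-way-random-absolute-single"
) -> float:
    """Intraclass correlation for an (n subjects x k raters) table.

    Default: two-way random effects, absolute agreement, single measurement —
    the standard choice for rater-agreement designs.
    """
    m = np.asarray(measurements, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need an (n >= 2 subjects) x (k >= 2 raters) table")
    if variant not in _ICC_TYPES:
        raise ValueError(f"unknown ICC variant {variant!r}; one of {sorted(_ICC_TYPES)}")
    n, k = m.shape
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": m.ravel(),
        }
    )
    with warnings.catch_warnings(), np.errstate(divide="ignore", invalid="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)
        table = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
    wanted = _ICC_TYPES[variant]
    row = table[table["Type"].isin(wanted)]
    return float(row["ICC"].iloc[0])


def _rms_cv(m: np.ndarray) -> tuple[float, np.ndarray]:
    """RMS over subjects of per-subject CV (%), excluding non-positive means."""
    means = m.mean(axis=1)
    sds = m.std(axis=1, ddof=1)
    valid = means > 0
    if not valid.all():
        warnings.warn(
            f"{int((~valid).sum())} subject(s) with non-positive mean excluded from CV",
            stacklevel=3,
        )
    cvs = sds[valid] / means[valid] * 100.0
    return float(np.sqrt(np.mean(cvs**2))), valid


def _pooled_cv(m: np.ndarray) -> float:
    """Within-subject SD (pooled over subjects) as a percent of the grand mean."""
    within_sd = np.sqrt(np.mean(m.std(axis=1, ddof=1) ** 2))
    return float(within_sd / m.mean() * 100.0)


def _as_pairs(measurements) -> np.ndarray:
    m = np.asarray(measurements, dtype=float)
    if m.ndim != 2 or m.shape[1] != 2:
        raise ValueError("expected an (n subjects x 2 measurements) array")
    if np.isnan(m).any():
        raise ValueError("both measurements must be complete for every subject")
    return m


def interrater_reliability(
    ratings,
    metric: str = "",
    icc_variant: str = "two-way-random-absolute-single",
    cv_method: str = "rms",
) -> ReliabilityResult:
    """Inter-rater agreement: ICC, CV and a paired t-test across two raters.

    ``ratings`` is an (n subjects x 2 raters) array.  If the two raters agree
    exactly, ICC = 1, CV = 0 and the paired-t p is undefined (NaN) because the
    difference variance is zero.
    """
    m = _as_pairs(ratings)
    if m.shape[0] < 5:
        raise ValueError(f"need >= 5 subjects, got {m.shape[0]}")
    icc = icc_agreement(m, icc_variant)
    cv, _ = (_rms_cv(m)[0], None) if cv_method == "rms" else (_pooled_cv(m), None)
    diffs = m[:, 1] - m[:, 0]
    if np.allclose(diffs, diffs[0]) and np.isclose(diffs.std(ddof=1), 0.0):
        t_p = np.nan if np.isclose(diffs[0], 0.0) else 0.0
    else:
        t_p = float(sps.ttest_rel(m[:, 0], m[:, 1]).pvalue)
    return ReliabilityResult(
        metric=metric,
        icc=icc,
        cv_percent=cv,
        bias=float(diffs.mean()),
        paired_t_p=t_p,
        means=(float(m[:, 0].mean()), float(m[:, 1].mean())),
        sds=(float(m[:, 0].std(ddof=1)), float(m[:, 1].std(ddof=1))),
        n=m.shape[0],
    )


def test_retest(
    pairs,
    metric: str = "",
    icc_variant: str = "two-way-random-absolute-single",
    cv_method: str = "rms",
) -> ReliabilityResult:
    """Scan-rescan repeatability with Bland-Altman relative limits of agreement.

    Per subject the relative difference is (scan2 - scan1) / pair mean x 100;
    bias is its mean and the 95% limits of agreement are bias +- 1.96 x its
    SD.  Subjects with non-positive pair means are excluded with a warning.
    ICC and CV are computed as in :func:`interrater_reliability`.
    """
    m = _as_pairs(pairs)
    if m.shape[0] < 5:
        raise ValueError(f"need >= 5 subjects, got {m.shape[0]}")
    means = m.mean(axis=1)
    valid = means > 0
    if not valid.all():
        warnings.warn(
            f"{int((~valid).sum())} subject(s) with non-positive pair mean excluded", stacklevel=2
        )
    mv = m[valid]
    rel = (mv[:, 1] - mv[:, 0]) / mv.mean(axis=1) * 100.0
    bias = float(rel.mean())
    sd = float(rel.std(ddof=1))
    icc = icc_agreement(mv, icc_variant)
    cv = _rms_cv(mv)[0] if cv_method == "rms" else _pooled_cv(mv)
    return ReliabilityResult(
        metric=metric,
        icc=icc,
        cv_percent=cv,
        bias=bias,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        n=mv.shape[0],
    )
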