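"""Sulcal asymmetry indices, covariate-adjusted group contrasts, and
summary-statistic test reconstructions.

The asymmetry index AI = 2(R - L)/(R + L) is dimensionless in [-2, 2]; a
positive AI means a longer or deeper sulcus in the right hemisphere. Group
contrasts on sulcal metrics are ordinary least squares with age, sex,
scanning-site and total-intracranial-volume covariates. The
summary-statistic helpers (one-way ANOVA from per-group mean/SD/n, Pearson
chi-square from a contingency table, intraclass correlation) reconstruct
tests from printed demographic summaries when raw data are unavailable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .data import ValidationError


@dataclass
class StatResult:
    """A single test statistic with its degrees of freedom and p-value."""

    kind: str  # "F" | "t" | "chi2" | "ICC" | "r"
    value: float
    df: tuple[float, ...]
    p: float | None = None
    ci: tuple[float, float] | None = None
    note: str = ""


@dataclass
class RegressionResult:
    """A covariate-adjusted group contrast from an OLS fit.

    ``standardized_beta`` is the contrast coefficient after z-scoring the
    outcome over the analysis sample (group difference in SD units).
    """

    contrast: str
    estimate: float
    standardized_beta: float
    t: float
    df: int
    p: float
    q: float | None = None
    degenerate: bool = False


def asymmetry_index(left: float, right: float) -> float:
    """AI = 2(R - L)/(R + L); NaN when both sides are zero (absent sulcus)."""
    if left < 0 or right < 0:
        raise ValidationError("sulcal measures must be non-negative")
    total = left + right
    if total == 0:
        return math.nan
    return 2.0 * (right - left) / total


def ai_table(sulci: pd.DataFrame) -> pd.DataFrame:
    """Per-subject asymmetry indices for every sulcus × measure.

    Returns a long table with columns subject_id, sulcus, measure
    (``length``/``depth``) and ``ai``; missing when both hemispheres are 0.
    """
    wide = sulci.pivot_table(
        index=["subject_id", "sulcus"],
        columns="hemisphere",
        values=["length_mm", "depth_mm"],
    )
    rows = []
    for (sid, sulcus), row in wide.iterrows():
        for measure, col in (("length", "length_mm"), ("depth", "depth_mm")):
            left, right = row[(col, "L")], row[(col, "R")]
            if pd.isna(left) or pd.isna(right):
                continue
            rows.append(
                {
                    "subject_id": sid,
                    "sulcus": sulcus,
                    "measure": measure,
                    "ai": asymmetry_index(float(left), float(right)),
                }
            )
    return pd.DataFrame(rows, columns=["subject_id", "sulcus", "measure", "ai"])


def ai_group_tests(ai_by_group: dict[str, np.ndarray]) -> dict:
    """One-sample t per group, one-way ANOVA across groups, Tukey HSD post hoc.

    A zero-variance group yields an infinite t (flagged), never an exception.
    Tukey uses the studentized-range distribution with the Tukey–Kramer
    unequal-n adjustment (via scipy).
    """
    per_group: dict[str, StatResult] = {}
    for name, vals in ai_by_group.items():
        vals = np.asarray(vals, dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size < 2:
            raise ValidationError(f"group {name} needs >= 2 observations")
        if np.std(vals, ddof=1) == 0:
            t = math.inf if vals.mean() > 0 else (-math.inf if vals.mean() < 0 else 0.0)
            per_group[name] = StatResult("t", t, (vals.size - 1,), p=0.0 if t else 1.0,
                                         note="zero variance")
        else:
            res = stats.ttest_1samp(vals, 0.0)
            per_group[name] = StatResult("t", float(res.statistic), (vals.size - 1,),
                                         p=float(res.pvalue))

    groups = list(ai_by_group)
    arrays = [np.asarray(ai_by_group[g], dtype=float) for g in groups]
    arrays = [a[~np.isnan(a)] for a in arrays]
    f = stats.f_oneway(*arrays)
    n_total = sum(a.size for a in arrays)
    anova = StatResult("F", float(f.statistic), (len(groups) - 1, n_total - len(groups)),
                       p=float(f.pvalue))

    values = np.concatenate(arrays)
    if np.std(values, ddof=1) == 0:
        tukey = pd.DataFrame(columns=["group1", "group2", "meandiff", "p_adj"])
    else:
        # studentized-range pairwise comparisons; scipy applies the
        # Tukey-Kramer adjustment when group sizes differ
        res = stats.tukey_hsd(*arrays)
        rows = []
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                rows.append(
                    {
                        "group1": groups[i],
                        "group2": groups[j],
                        "meandiff": float(arrays[i].mean() - arrays[j].mean()),
                        "p_adj": float(res.pvalue[i, j]),
                    }
                )
        tukey = pd.DataFrame(rows)
    return {"per_group": per_group, "anova": anova, "tukey": tukey}


def covariate_design(subjects: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Design columns [intercept, age, sex_F, site dummies, tiv].

    Sex is a single 0/1 indicator (F=1); site enters as k-1 dummies with the
    lexicographically first site as reference.
    """
    if subjects[["age", "sex", "site", "tiv"]].isna().any().any():
        bad = subjects.index[subjects[["age", "sex", "site", "tiv"]].isna().any(axis=1)]
        raise ValidationError(f"missing covariates for subjects {list(bad)}; no imputation")
    cols = [np.ones(len(subjects))]
    names = ["intercept"]

    def add(values: np.ndarray, name: str) -> None:
        # constant covariates are absorbed by the intercept
        if np.ptp(values) > 0:
            cols.append(values)
            names.append(name)

    add(subjects["age"].to_numpy(dtype=float), "age")
    add((subjects["sex"] == "F").to_numpy(dtype=float), "sex_F")
    sites = sorted(subjects["site"].unique())
    for site in sites[1:]:
        add((subjects["site"] == site).to_numpy(dtype=float), f"site[{site}]")
    add(subjects["tiv"].to_numpy(dtype=float), "tiv")
    X = np.column_stack(cols)
    _check_full_rank(X, names)
    return X, names


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        kept = np.empty((X.shape[0], 0))
        for j, name in enumerate(names):
            cand = np.column_stack([kept, X[:, j]])
            if np.linalg.matrix_rank(cand) > kept.shape[1]:
                kept = cand
            else:
                bad.append(name)
        raise ValidationError(f"rank-deficient design; collinear columns: {bad}")


def sulcal_regression(
    metric: pd.Series,
    subjects: pd.DataFrame,
    contrast: tuple[str, str],
) -> RegressionResult:
    """OLS of a sulcal metric on group indicators + age + sex + site + TIV.

    ``contrast = (a, b)`` reports the adjusted mean difference a - b with its
    t statistic on n - p residual degrees of freedom, plus the same
    coefficient from a fit of the z-scored outcome (standardized beta).
    """
    y = metric.loc[subjects.index].to_numpy(dtype=float)
    n = len(y)
    groups = sorted(subjects["group"].unique())
    if contrast[0] not in groups or contrast[1] not in groups:
        raise ValidationError(f"contrast {contrast} not among groups {groups}")
    Xc, names = covariate_design(subjects)
    gcols, gnames = [], []
    for g in groups[1:]:  # first group (sorted) is the reference level
        gcols.append((subjects["group"] == g).to_numpy(dtype=float))
        gnames.append(f"group[{g}]")
    X = np.column_stack([Xc[:, :1]] + gcols + [Xc[:, 1:]])
    names = ["intercept"] + gnames + names[1:]
    if n <= X.shape[1] + 2:
        raise ValidationError("too few subjects for the covariate model")
    _check_full_rank(X, names)

    sd_y = float(np.std(y, ddof=1))
    degenerate = sd_y == 0.0

    def _contrast_vec() -> np.ndarray:
        c = np.zeros(X.shape[1])
        for g, sign in ((contrast[0], 1.0), (contrast[1], -1.0)):
            if g == groups[0]:
                continue  # reference level contributes 0
            c[names.index(f"group[{g}]")] = sign
        return c

    c = _contrast_vec()
    df = n - X.shape[1]
    XtX_inv = np.linalg.inv(X.T @ X)

    def _fit(yy: np.ndarray) -> tuple[float, float]:
        beta = XtX_inv @ (X.T @ yy)
        resid = yy - X @ beta
        sigma2 = float(resid @ resid) / df
        est = float(c @ beta)
        se = math.sqrt(max(sigma2 * float(c @ XtX_inv @ c), 0.0))
        return est, se

    est, se = _fit(y)
    if degenerate or se == 0.0:
        return RegressionResult(
            contrast=f"{contrast[0]} - {contrast[1]}", estimate=0.0,
            standardized_beta=0.0, t=0.0, df=df, p=1.0, degenerate=True,
        )
    t = est / se
    p = 2.0 * stats.t.sf(abs(t), df)
    est_z, _ = _fit((y - y.mean()) / sd_y)
    return RegressionResult(
        contrast=f"{contrast[0]} - {contrast[1]}",
        estimate=est, standardized_beta=est_z, t=float(t), df=int(df), p=float(p),
    )


def anova_from_summary(means, sds, ns) -> StatResult:
    """One-way ANOVA F reconstructed from per-group means, SDs and ns.

    SSB = sum n_i (m_i - grand mean)^2, SSW = sum (n_i - 1) s_i^2,
    F = [SSB/(k-1)] / [SSW/(N-k)]. Equals the classical raw-data ANOVA when
    the summaries come from that raw data.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if means.shape != sds.shape or means.shape != ns.shape or means.ndim != 1:
        raise ValidationError("means, sds, ns must be equal-length vectors")
    k = means.size
    if k < 2:
        raise ValidationError("need >= 2 groups")
    if np.any(ns < 2):
        raise ValidationError("every group needs n >= 2")
    N = ns.sum()
    grand = float((ns * means).sum() / N)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    df1, df2 = k - 1, N - k
    if ssw == 0:
        f = math.inf if ssb > 0 else 0.0
        p = 0.0 if ssb > 0 else 1.0
    else:
        f = (ssb / df1) / (ssw / df2)
        p = float(stats.f.sf(f, df1, df2))
    return StatResult("F", float(f), (float(df1), float(df2)), p=p)


def chisq_from_table(counts) -> StatResult:
    """Pearson chi-square on an r×c contingency table, no continuity correction."""
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or np.any(table < 0):
        raise ValidationError("counts must be a non-negative 2-D table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValidationError("zero row or column margin")
    res = stats.chi2_contingency(table, correction=False)
    return StatResult("chi2", float(res.statistic), (float(res.dof),), p=float(res.pvalue))


def icc_agreement(method_a, method_b) -> StatResult:
    """Agreement between two measurement methods.

    Two-way random-effects, absolute-agreement, single-measure intraclass
    correlation — ICC(2,1), labelled ``ICC2`` in the result note — with its
    F-based 95% confidence interval (via pingouin).
    """
    a = np.asarray(method_a, dtype=float)
    b = np.asarray(method_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValidationError("need paired 1-D measurements, n >= 3")
    if np.std(a) == 0 and np.std(b) == 0:
        return StatResult("ICC", math.nan, (math.nan,), note="constant ratings; ICC undefined")
    n = a.size
    long = pd.DataFrame(
        {
            "target": np.tile(np.arange(n), 2),
            "rater": np.repeat(["a", "b"], n),
            "score": np.concatenate([a, b]),
        }
    )
    table = pg.intraclass_corr(long, targets="target", raters="rater", ratings="score")
    table = table.set_index("Type")
    row = table.loc["ICC(A,1)"] if "ICC(A,1)" in table.index else table.loc["ICC2"]
    ci_col = "CI95" if "CI95" in table.columns else "CI95%"
    lo, hi = row[ci_col]
    return StatResult(
        "ICC", float(row["ICC"]), (float(row["df1"]), float(row["df2"])),
        p=float(row["pval"]), ci=(float(lo), float(hi)),
        note="two-way random effects, absolute agreement, single measure (ICC2 / A,1)",
    )


def correlate_lgi_sulcal(region_means: pd.DataFrame, sulcal_metrics: pd.DataFrame) -> pd.DataFrame:
    """Pearson r (+ two-sided p) between region-mean LGI and sulcal metrics.

    Both inputs are subject-indexed; every column pair is tested. Pairs with a
    zero-variance column are flagged missing.
    """
    common = region_means.index.intersection(sulcal_metrics.index)
    if len(common) < 4:
        raise ValidationError("need >= 4 matched subjects")
    rows = []
    for lcol in region_means.columns:
        x = region_means.loc[common, lcol].to_numpy(dtype=float)
        for scol in sulcal_metrics.columns:
            y = sulcal_metrics.loc[common, scol].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append({"lgi_region": lcol, "sulcal_metric": scol,
                             "r": math.nan, "p": math.nan})
                continue
            r, p = stats.pearsonr(x, y)
            rows.append({"lgi_region": lcol, "sulcal_metric": scol,
                         "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)
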