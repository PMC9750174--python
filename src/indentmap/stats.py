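"""Reliability, method-agreement and group-comparison statistics.

The reliability toolkit mirrors standard practice for repeated biomechanical
measurements: per-site coefficients of variation from triplicates, the
intra-assay CV (unweighted mean of site CVs), and the single-measurement
two-way absolute-agreement intraclass correlation coefficient, ICC(A,1),
with exact F-based 95 % confidence limits.  Method agreement between needle
probing and volumetric imaging uses Pearson correlation and Bland-Altman
bias/limits of agreement.  Regional pooling averages available sites per
specimen within each condyle and anteroposterior sub-region, then compares
groups parametrically (t test / one-way ANOVA with Bonferroni post hoc) or
non-parametrically (Mann-Whitney U with Bonferroni-Dunn correction).

Missing or flagged sites are excluded, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "site_cv",
    "intra_assay_cv",
    "ICCResult",
    "icc_absolute_single",
    "BlandAltmanResult",
    "bland_altman",
    "pearson_r",
    "percent_change",
    "RegionSummary",
    "pool_regions",
    "compare_groups",
    "dataset_accounting",
]


def site_cv(values) -> float:
    """Coefficient of variation (%) of one site's repeats: 100 * sd / mean.

    Requires >= 2 non-missing repeats; the sample (ddof=1) SD is used.
    Returns NaN (undefined-CV flag) when the mean is not positive.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 2:
        raise ValueError("site CV needs at least 2 non-missing repeats")
    m = float(np.mean(v))
    if m <= 0:
        return float("nan")
    return 100.0 * float(np.std(v, ddof=1)) / m


def intra_assay_cv(table: pd.DataFrame) -> float:
    """Unweighted mean (%) of all non-missing site CVs across specimens.

    ``table`` holds one row per (specimen, site) cell with repeat columns,
    or a precomputed ``cv`` column; NaN cells are skipped.
    """
    if "cv" in table.columns:
        cvs = table["cv"].to_numpy(dtype=float)
    else:
        repeat_cols = [c for c in table.columns if c not in ("specimen", "site_id")]
        cvs = np.array([
            site_cv(row) if np.isfinite(row).sum() >= 2 else np.nan
            for row in table[repeat_cols].to_numpy(dtype=float)
        ])
    cvs = cvs[np.isfinite(cvs)]
    if len(cvs) == 0:
        raise ValueError("no non-missing site CVs to average")
    return float(np.mean(cvs))


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    n: int
    k: int


def icc_absolute_single(matrix, alpha: float = 0.05) -> ICCResult:
    """ICC(A,1): two-way, absolute agreement, single measurement.

    ``matrix`` is n subjects x k repeats; rows containing missing values are
    dropped listwise.  The estimate comes from the two-way ANOVA
    decomposition,

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)),

    with the exact F-based confidence interval of McGraw & Wong.
    """
    X = np.asarray(matrix, dtype=float)
    X = X[~np.isnan(X).any(axis=1)]
    n, k = X.shape
    if n < 3 or k < 2:
        raise ValueError(f"ICC needs >= 3 complete subjects and >= 2 repeats (got {n}x{k})")
    grand = X.mean()
    row_m = X.mean(axis=1)
    col_m = X.mean(axis=0)
    ss_rows = k * np.sum((row_m - grand) ** 2)
    ss_cols = n * np.sum((col_m - grand) ** 2)
    ss_tot = np.sum((X - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom if denom != 0 else 1.0
    if mse == 0 and msc == 0:
        return ICCResult(1.0, 1.0, 1.0, n, k)
    # McGraw & Wong (1996) exact interval for ICC(A,1)
    a = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isfinite(a):
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_u = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f_l = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lo = (n * (msr - f_u * mse)) / (
            f_u * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi = (n * (f_l * msr - mse)) / (
            k * msc + (k * n - k - n) * mse + n * f_l * msr
        )
    else:
        lo = hi = 1.0
    return ICCResult(float(icc), float(lo), float(hi), n, k)


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    sd: float
    n: int


def bland_altman(a, b) -> BlandAltmanResult:
    """Bland-Altman agreement of paired methods: bias = mean(b - a) and 95 %
    limits of agreement bias +/- 1.96 sd(b - a)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    d = (b - a)[ok]
    if len(d) < 2:
        raise ValueError("Bland-Altman needs at least 2 complete pairs")
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltmanResult(bias, bias - 1.96 * sd, bias + 1.96 * sd, sd, len(d))


def pearson_r(a, b):
    """Sample Pearson correlation with two-sided p (>= 3 complete pairs)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("Pearson correlation needs at least 3 complete pairs")
    r, p = sps.pearsonr(a[ok], b[ok])
    return float(r), float(p)


def percent_change(reference: float, value: float) -> float:
    """Percent change of ``value`` relative to ``reference``, in %."""
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return 100.0 * (value - reference) / reference


@dataclass
class RegionSummary:
    """Per-region pooled statistics and attached comparisons."""

    specimen_means: pd.DataFrame   # specimen x region means over available sites
    group_stats: pd.DataFrame      # region -> mean, sd, n (of specimen means)
    comparisons: pd.DataFrame      # contrast, statistic, p, p_adjusted


def pool_regions(
    site_table: pd.DataFrame,
    grid,
    value: str = "value",
    parametric: bool = True,
) -> RegionSummary:
    """Pool per-site values into condyle and sub-region summaries.

    ``site_table`` needs columns ``specimen``, ``site_id`` and the value
    column; NaN values (missing or flagged sites) are excluded.  Per
    specimen, each region's mean is taken over its available sites; group
    statistics are the mean (SD) of specimen means.  Attached comparisons:
    lateral vs medial (t test or Mann-Whitney U) and all sub-region pairs
    (one-way ANOVA F plus pairwise tests, Bonferroni-adjusted).
    """
    df = site_table.copy()
    df = df[np.isfinite(df[value].to_numpy(dtype=float))]
    if df.empty:
        raise ValueError("no available (non-missing) site values to pool")
    df["condyle"] = [grid.condyle_of(s) for s in df["site_id"]]
    df["subregion"] = [grid.subregion_of(s) for s in df["site_id"]]

    pieces = []
    for level in ("condyle", "subregion"):
        m = df.groupby(["specimen", level])[value].mean().unstack()
        pieces.append(m)
    spec_means = pd.concat(pieces, axis=1)

    group_stats = pd.DataFrame({
        "mean": spec_means.mean(axis=0),
        "sd": spec_means.std(axis=0, ddof=1),
        "n": spec_means.notna().sum(axis=0),
    })

    rows = []

    def _pair(name, x, y):
        x = x[np.isfinite(x)]
        y = y[np.isfinite(y)]
        if len(x) < 2 or len(y) < 2:
            return
        if parametric:
            stat, p = sps.ttest_ind(x, y, equal_var=False)
        else:
            stat, p = sps.mannwhitneyu(x, y, alternative="two-sided")
        rows.append({"contrast": name, "statistic": float(stat), "p": float(p)})

    if "lateral" in spec_means.columns and "medial" in spec_means.columns:
        _pair("lateral vs medial",
              spec_means["lateral"].to_numpy(), spec_means["medial"].to_numpy())
    subs = [c for c in spec_means.columns if "/" in c]
    sub_arrays = [spec_means[c].dropna().to_numpy() for c in subs]
    if len(subs) >= 3 and all(len(a) >= 2 for a in sub_arrays):
        if parametric:
            f, p = sps.f_oneway(*sub_arrays)
            rows.append({"contrast": "sub-regions (ANOVA)", "statistic": float(f),
                         "p": float(p)})
        else:
            h, p = sps.kruskal(*sub_arrays)
            rows.append({"contrast": "sub-regions (Kruskal-Wallis)",
                         "statistic": float(h), "p": float(p)})
    for c1, c2 in combinations(subs, 2):
        _pair(f"{c1} vs {c2}", spec_means[c1].to_numpy(), spec_means[c2].to_numpy())

    comp = pd.DataFrame(rows)
    if not comp.empty:
        pairwise = comp["contrast"].str.contains(" vs ")
        m = int(pairwise.sum())
        comp["p_adjusted"] = comp["p"]
        comp.loc[pairwise, "p_adjusted"] = np.minimum(comp.loc[pairwise, "p"] * m, 1.0)
    return RegionSummary(spec_means, group_stats, comp)


def compare_groups(
    summary_a: RegionSummary,
    summary_b: RegionSummary,
    labels=("control", "knockout"),
    parametric: bool = False,
) -> pd.DataFrame:
    """Region-wise group contrast (genotype comparison).

    Default path is the non-parametric Mann-Whitney U with Bonferroni-Dunn
    correction across the fixed family of regions, matching how degenerated
    and control cartilage are compared.
    """
    rows = []
    regions = [c for c in summary_a.specimen_means.columns
               if c in summary_b.specimen_means.columns]
    for region in regions:
        x = summary_a.specimen_means[region].dropna().to_numpy()
        y = summary_b.specimen_means[region].dropna().to_numpy()
        if len(x) < 2 or len(y) < 2:
            continue
        if parametric:
            stat, p = sps.ttest_ind(x, y, equal_var=False)
        else:
            stat, p = sps.mannwhitneyu(x, y, alternative="two-sided")
        rows.append({
            "region": region,
            f"mean_{labels[0]}": float(np.mean(x)),
            f"mean_{labels[1]}": float(np.mean(y)),
            "difference": float(np.mean(y) - np.mean(x)),
            "statistic": float(stat),
            "p": float(p),
        })
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adjusted"] = np.minimum(out["p"] * len(out), 1.0)
    return out


def dataset_accounting(statuses, flagged=("atypical", "failed")) -> dict:
    """Totals and flagged percentage for a sequence of QC statuses."""
    statuses = list(statuses)
    total = len(statuses)
    n_flagged = sum(s in flagged for s in statuses)
    rate = 100.0 * n_flagged / total if total else 0.0
    return {"total": total, "flagged": n_flagged, "rate_percent": rate}
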