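"""Cohort preprocessing and statistical validation.

Implements the statistical layer of the clinical-validation workflow:
median imputation of missing cells, substitution of physically impossible
outliers, Kolmogorov-Smirnov normality screening (Lilliefors-corrected by
default because the normal parameters are estimated from the sample),
group descriptives with Wilcoxon rank-sum / chi-squared tests, two-way
mixed-model consistency ICC for concurrent validity, and normality-routed
correlation matrices (Pearson for Gaussian pairs, Spearman otherwise).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "CohortTable",
    "IccResult",
    "CorrMatrix",
    "DescriptiveRow",
    "impute_median",
    "substitute_outliers",
    "ks_normality",
    "group_compare",
    "describe_by_group",
    "icc_consistency",
    "correlation_matrix",
    "icc_band",
    "correlation_band",
]

log = logging.getLogger(__name__)


@dataclass
class CohortTable:
    """A cohort data frame plus a provenance log of every edited cell."""

    df: pd.DataFrame
    log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if "id" in self.df.columns and self.df["id"].duplicated().any():
            raise ValueError("subject ids must be unique")

    def copy(self) -> "CohortTable":
        return CohortTable(self.df.copy(), list(self.log))


def _as_table(table) -> CohortTable:
    if isinstance(table, CohortTable):
        return table
    return CohortTable(df=table)


def impute_median(table, variables: list[str]) -> CohortTable:
    """Replace missing cells by the per-variable median of the valid cells.

    Every replacement is appended to the provenance log.  A variable with
    no valid observation raises.
    """
    table = _as_table(table).copy()
    df = table.df
    for var in variables:
        if var not in df.columns:
            raise ValueError(f"unknown variable '{var}'")
        col = pd.to_numeric(df[var], errors="coerce")
        valid = col.dropna()
        missing_idx = df.index[col.isna()]
        if len(missing_idx) == 0:
            continue
        if valid.empty:
            raise ValueError(f"variable '{var}' has no valid observations to impute from")
        med = float(valid.median())
        for idx in missing_idx:
            table.log.append({"op": "impute", "variable": var,
                              "row": idx, "old": None, "new": med})
        df.loc[missing_idx, var] = med
    return table


def substitute_outliers(table, rules: dict | None = None) -> CohortTable:
    """Replace physically impossible values by the median of the valid ones.

    ``rules`` maps variable name to a validity predicate (callable on a
    Series returning a boolean mask of VALID cells).  The default rule
    flags walking speeds above 2 m/s, which is not plausible for an elderly
    walker.
    """
    table = _as_table(table).copy()
    df = table.df
    if rules is None:
        rules = {var: (lambda s: s <= 2.0)
                 for var in ("Speed_4m_walk", "Velocity (m/s)") if var in df.columns}
    for var, predicate in rules.items():
        if var not in df.columns:
            raise ValueError(f"outlier rule references unknown variable '{var}'")
        col = pd.to_numeric(df[var], errors="coerce")
        valid_mask = predicate(col).fillna(False) & col.notna()
        bad_idx = df.index[col.notna() & ~valid_mask]
        if len(bad_idx) == 0:
            continue
        med = float(col[valid_mask].median())
        for idx in bad_idx:
            table.log.append({"op": "substitute", "variable": var, "row": idx,
                              "old": float(col.loc[idx]), "new": med})
        df.loc[bad_idx, var] = med
    return table


def ks_normality(x, alpha: float = 0.05, lilliefors_correction: bool = True
                 ) -> tuple[float, bool]:
    """One-sample KS test against a normal with the sample's mean and SD.

    Returns ``(p, is_normal)``.  By default the Lilliefors correction is
    applied since location and scale are estimated from the data; set
    ``lilliefors_correction=False`` for the classical (anti-conservative)
    KS p-value.  A constant vector is reported non-normal with p = 0.
    """
    x = np.asarray(pd.to_numeric(pd.Series(x), errors="coerce").dropna(), float)
    if x.size < 8:
        raise ValueError("normality screening needs at least 8 observations")
    if np.ptp(x) == 0:
        warnings.warn("constant vector: reporting non-normal by convention")
        return 0.0, False
    if lilliefors_correction:
        _, p = lilliefors(x, dist="norm", pvalmethod="table")
    else:
        _, p = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    return float(p), bool(p > alpha)


def group_compare(table, variable: str, group: str = "FALLS",
                  continuous_test: str = "wilcoxon") -> tuple[str, float, float]:
    """Two-group comparison of one variable.

    Continuous variables use the Wilcoxon rank-sum (Mann-Whitney) test with
    normal approximation and tie correction (``continuous_test="ttest"``
    switches to Student's t); categorical variables use Pearson's
    chi-squared without continuity correction.  Returns
    ``(test name, statistic, p)``.
    """
    df = _as_table(table).df
    if variable not in df.columns:
        raise ValueError(f"unknown variable '{variable}'")
    g = df[group].astype(bool)
    if g.all() or (~g).all():
        raise ValueError("both groups must be non-empty")
    col = df[variable]
    if pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col):
        a = pd.to_numeric(col[~g], errors="coerce").dropna()
        b = pd.to_numeric(col[g], errors="coerce").dropna()
        if continuous_test == "wilcoxon":
            res = sps.mannwhitneyu(a, b, alternative="two-sided",
                                   method="asymptotic", use_continuity=True)
            return "wilcoxon-rank-sum", float(res.statistic), float(res.pvalue)
        if continuous_test == "ttest":
            res = sps.ttest_ind(a, b)
            return "student-t", float(res.statistic), float(res.pvalue)
        raise ValueError(f"unknown continuous test '{continuous_test}'")
    contingency = pd.crosstab(col, g)
    chi2, p, _, _ = sps.chi2_contingency(contingency.to_numpy(), correction=False)
    return "chi-squared", float(chi2), float(p)


@dataclass
class DescriptiveRow:
    """One formatted descriptives row: overall / non-fallers / fallers cells."""

    variable: str
    overall: str | dict[str, str]
    nonfallers: str | dict[str, str]
    fallers: str | dict[str, str]
    test: str
    p: float


def _num_cell(x: pd.Series) -> str:
    x = pd.to_numeric(x, errors="coerce").dropna()
    sd = x.std(ddof=1) if len(x) > 1 else 0.0
    return f"{x.mean():.1f} ({sd:.1f})/[{x.min():.1f}|{x.max():.1f}]"


def _cat_cells(x: pd.Series, n: int) -> dict[str, str]:
    out = {}
    for level, count in x.value_counts().sort_index().items():
        out[str(level)] = f"{count}/{n} ({100.0 * count / n:.0f}%)"
    return out


def describe_by_group(table, variable: str, group: str = "FALLS") -> DescriptiveRow:
    """Descriptive cells ``mean (SD)/[min|max]`` or ``n/N (%)`` by group."""
    df = _as_table(table).df
    test, _, p = group_compare(table, variable, group)
    g = df[group].astype(bool)
    col = df[variable]
    if pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col):
        return DescriptiveRow(variable, _num_cell(col), _num_cell(col[~g]),
                              _num_cell(col[g]), test, p)
    return DescriptiveRow(variable, _cat_cells(col, len(col)),
                          _cat_cells(col[~g], int((~g).sum())),
                          _cat_cells(col[g], int(g.sum())), test, p)


def icc_band(icc: float) -> str:
    """Concurrent-validity band of an ICC value."""
    if icc > 0.90:
        return "very good"
    if icc >= 0.71:
        return "good"
    if icc >= 0.51:
        return "moderate"
    if icc >= 0.31:
        return "mediocre"
    return "bad/null"


@dataclass
class IccResult:
    icc: float
    f_statistic: float
    df1: int
    df2: int
    ci95: tuple[float, float]
    p: float
    band: str


def icc_consistency(pairs: np.ndarray, confidence: float = 0.95) -> IccResult:
    """Single-measure two-way mixed-model consistency ICC, ICC(C,1).

    From the two-way ANOVA decomposition of an n x k paired-measurement
    matrix: ICC = (MSR - MSE) / (MSR + (k-1) MSE) with F = MSR/MSE on
    (n-1, (n-1)(k-1)) degrees of freedom; the confidence interval follows
    the F-distribution bounds.  Consistency ignores fixed rater offsets,
    so ICC(x, x + c) = 1.
    """
    data = np.asarray(pairs, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("pairs must be an n x k matrix with k >= 2")
    if np.isnan(data).any():
        raise ValueError("missing cells are not allowed; impute first")
    n, k = data.shape
    if n < 3:
        raise ValueError("need at least 3 paired measurements")
    grand = data.mean()
    ss_rows = k * np.sum((data.mean(axis=1) - grand) ** 2)
    ss_cols = n * np.sum((data.mean(axis=0) - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    df1, df2 = n - 1, (n - 1) * (k - 1)
    msr = ss_rows / df1
    mse = ss_err / df2
    if mse <= 0:
        warnings.warn("zero residual variance: perfect consistency")
        return IccResult(1.0, np.inf, df1, df2, (1.0, 1.0), 0.0, icc_band(1.0))
    icc = (msr - mse) / (msr + (k - 1) * mse)
    f_stat = msr / mse
    p = float(sps.f.sf(f_stat, df1, df2))
    a = 1.0 - confidence
    fl = f_stat / sps.f.ppf(1 - a / 2, df1, df2)
    fu = f_stat * sps.f.ppf(1 - a / 2, df2, df1)
    lo = (fl - 1.0) / (fl + k - 1.0)
    hi = (fu - 1.0) / (fu + k - 1.0)
    return IccResult(float(icc), float(f_stat), df1, df2,
                     (float(lo), float(hi)), p, icc_band(float(icc)))


def correlation_band(r: float) -> str:
    """Strength band of a correlation coefficient (on its magnitude)."""
    r = abs(r)
    if np.isnan(r):
        return "null"
    if r >= 0.50:
        return "strong"
    if r >= 0.30:
        return "moderate"
    if r >= 0.10:
        return "weak"
    return "null"


@dataclass
class CorrMatrix:
    """Pairwise correlations with per-pair method, p-value and band."""

    r: pd.DataFrame
    p: pd.DataFrame
    method: pd.DataFrame
    band: pd.DataFrame


def correlation_matrix(table, vars_a: list[str], vars_b: list[str] | None = None,
                       alpha: float = 0.05) -> CorrMatrix:
    """Normality-routed correlation matrix.

    Each pair uses Pearson's coefficient if both variables pass the
    normality screen and Spearman's rank coefficient otherwise.  Constant
    variables yield an undefined (NaN) coefficient banded as null.
    """
    df = _as_table(table).df
    vars_b = vars_a if vars_b is None else vars_b
    all_vars = list(dict.fromkeys(vars_a + vars_b))
    normal: dict[str, bool] = {}
    for v in all_vars:
        if v not in df.columns:
            raise ValueError(f"unknown variable '{v}'")
        col = pd.to_numeric(df[v], errors="coerce").dropna()
        if np.ptp(col.to_numpy()) == 0:
            normal[v] = False
            continue
        normal[v] = ks_normality(col, alpha=alpha)[1]
    r = pd.DataFrame(index=vars_a, columns=vars_b, dtype=float)
    p = pd.DataFrame(index=vars_a, columns=vars_b, dtype=float)
    method = pd.DataFrame(index=vars_a, columns=vars_b, dtype=object)
    band = pd.DataFrame(index=vars_a, columns=vars_b, dtype=object)
    for va in vars_a:
        for vb in vars_b:
            sub = df[[va, vb]].apply(pd.to_numeric, errors="coerce").dropna()
            if len(sub) < 8:
                raise ValueError(f"fewer than 8 complete pairs for ({va}, {vb})")
            x, y = sub[va].to_numpy(), sub[vb].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                warnings.warn(f"constant variable in pair ({va}, {vb})")
                r.loc[va, vb], p.loc[va, vb] = np.nan, np.nan
                method.loc[va, vb], band.loc[va, vb] = "undefined", "null"
                continue
            if va == vb:
                r.loc[va, vb], p.loc[va, vb] = 1.0, 0.0
                method.loc[va, vb] = "pearson" if normal[va] else "spearman"
                band.loc[va, vb] = "strong"
                continue
            if normal[va] and normal[vb]:
                cc, pp = sps.pearsonr(x, y)
                method.loc[va, vb] = "pearson"
            else:
                cc, pp = sps.spearmanr(x, y)
                method.loc[va, vb] = "spearman"
            r.loc[va, vb], p.loc[va, vb] = float(cc), float(pp)
            band.loc[va, vb] = correlation_band(float(cc))
    return CorrMatrix(r=r, p=p, method=method, band=band)
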