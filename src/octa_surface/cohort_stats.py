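"""Statistical battery for normative vessel-surface cohorts.

Covers the per-stratum summary table (count, mean, sd, min, quartiles, max),
Pearson correlation with the non-correlation t-test, a Gaussian GLM of
surface area on sex, age, spherical equivalent, axial length and visual
acuity with all ten two-way interactions assessed by type-II (marginality-
respecting) F tests, the paired left/right-eye t-test, and explicit,
rule-based outlier flagging.  Eyes are analysed separately (OD, OS)
throughout; correlation between fellow eyes is sidestepped rather than
modelled.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.anova import anova_lm

from .volume_io import CohortTable

__all__ = [
    "SummaryTable",
    "CorrelationResult",
    "GLMResult",
    "MAIN_EFFECTS",
    "GLM_EFFECTS",
    "summarize",
    "pearson_with_test",
    "fit_glm_type2",
    "paired_t_test",
    "detect_outliers",
    "significance_code",
]

logger = logging.getLogger(__name__)

_SUMMARY_STATS = ["count", "mean", "sd", "min", "25%", "50%", "75%", "max"]

MAIN_EFFECTS = ["age", "sex", "se", "al", "va"]
#: the 15 effects of the full two-way-interaction model, in report order
GLM_EFFECTS = MAIN_EFFECTS + [
    f"{a}:{b}" for a, b in itertools.combinations(MAIN_EFFECTS, 2)
]


@dataclass
class SummaryTable:
    """Tidy per-variable, per-stratum summary: one row per (stratum, variable)."""

    df: pd.DataFrame

    def stat(self, variable: str, statistic: str, stratum: str = "overall") -> float:
        row = self.df[(self.df["variable"] == variable) & (self.df["stratum"] == stratum)]
        if row.empty:
            raise KeyError(f"no summary row for variable={variable!r} stratum={stratum!r}")
        return float(row.iloc[0][statistic])


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


@dataclass
class GLMResult:
    """Type-II ANOVA of the Gaussian GLM: one F test per main effect and interaction."""

    table: pd.DataFrame  # index = GLM_EFFECTS; columns F, p, df_num, df_den, sign
    n_used: int
    rsquared: float
    params: pd.Series
    bse: pd.Series

    def effect(self, name: str) -> pd.Series:
        return self.table.loc[name]


def _summary_row(values: pd.Series) -> dict:
    v = pd.to_numeric(values, errors="coerce").dropna().to_numpy(dtype=float)
    if len(v) == 0:
        return {"count": 0, **{s: np.nan for s in _SUMMARY_STATS[1:]}}
    q25, q50, q75 = np.percentile(v, [25, 50, 75])  # linear interpolation
    return {
        "count": len(v),
        "mean": v.mean(),
        "sd": v.std(ddof=1) if len(v) > 1 else np.nan,
        "min": v.min(),
        "25%": q25,
        "50%": q50,
        "75%": q75,
        "max": v.max(),
    }


def summarize(
    table: CohortTable,
    variables: list[str] | None = None,
    strata: list[str] | None = None,
) -> SummaryTable:
    """Per-variable summary statistics, overall and per stratum.

    ``strata`` names grouping columns (e.g. ``["sex", "eye"]`` for the
    male-right / female-right / male-left / female-left split).  Statistics
    use non-missing values only, sd with the n-1 denominator and quartiles by
    linear interpolation.  An "overall" stratum is always included.
    """
    if len(table) == 0:
        raise ValueError("cannot summarise an empty cohort")
    if variables is None:
        variables = ["age", "se", "al", "va", "surface_mm2"]
    rows = []
    for var in variables:
        rows.append({"stratum": "overall", "variable": var, **_summary_row(table.df[var])})
    if strata:
        for key, group in table.df.groupby(strata, dropna=False):
            if not isinstance(key, tuple):
                key = (key,)
            label = " ".join(str(k) for k in key)
            for var in variables:
                rows.append({"stratum": label, "variable": var, **_summary_row(group[var])})
    return SummaryTable(pd.DataFrame(rows, columns=["stratum", "variable", *_SUMMARY_STATS]))


def pearson_with_test(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with the two-sided non-correlation test.

    Pairs with a missing value in either vector are dropped.  The p-value
    comes from t = r sqrt((n-2)/(1-r^2)) against Student's t with n-2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ValueError("correlation undefined: zero variance in x or y")
    r = float(np.clip((xc @ yc) / denom, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(r=r, p=p, n=n)


def significance_code(p: float) -> str:
    """R-style significance codes: 0 '***' 0.001 '**' 0.01 '*' 0.05 '.' 0.1 ' ' 1."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "."
    return " "


def _model_frame(table: CohortTable, response: str) -> pd.DataFrame:
    df = table.df[[response, *MAIN_EFFECTS]].copy()
    # sex as a 0/1 indicator (reference = female, the larger group); for a
    # two-level factor this is equivalent to treatment contrasts, and the
    # type-II F tests are contrast-invariant anyway
    df["sex"] = df["sex"].map({"female": 0.0, "male": 1.0})
    df = df.dropna()
    return df


def fit_glm_type2(table: CohortTable, response: str = "surface_mm2") -> GLMResult:
    """Gaussian GLM (identity link = OLS) with all two-way interactions, type-II F tests.

    The model is ``response ~ (sex + age + se + al + va)**2`` after listwise
    deletion of incomplete rows.  Each effect's type-II sum of squares
    compares the models with and without that term, conditioning on every
    term that does not contain it (so main effects are tested ignoring their
    own interactions, and interactions are tested against all other terms);
    F uses the full-model residual mean square.
    """
    df = _model_frame(table, response)
    formula = f"{response} ~ (sex + age + se + al + va)**2"
    n_params = 16  # intercept + 5 mains + 10 interactions
    if len(df) <= n_params:
        raise ValueError(
            f"{len(df)} complete rows cannot identify {n_params} parameters; need more data"
        )
    fit = smf.ols(formula, data=df).fit()
    if fit.df_resid <= 0 or np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        u, s, vt = np.linalg.svd(fit.model.exog)
        aliased = [
            fit.model.exog_names[i]
            for i in np.argsort(np.abs(vt[-1]))[::-1][:2]
        ]
        raise ValueError(f"design matrix is rank deficient; near-aliased terms: {aliased}")
    if fit.ssr <= np.finfo(float).eps * fit.centered_tss:
        # perfect fit: residual MS is 0, F is unbounded; report inf/p=0
        logger.warning("fit_glm_type2: residual SS ~ 0 (perfect fit); F reported as inf")
        an = anova_lm(fit, typ=2)
        real = an["sum_sq"] > 1e-9 * fit.centered_tss
        an["F"] = np.where(real, np.inf, 0.0)
        an["PR(>F)"] = np.where(real, 0.0, 1.0)
    else:
        an = anova_lm(fit, typ=2)
    an = an.drop(index="Residual")

    def _canonical(name: str) -> str:
        parts = sorted(name.lower().split(":"), key=MAIN_EFFECTS.index)
        return ":".join(parts)

    an = an.rename(index={name: _canonical(name) for name in an.index})
    out = pd.DataFrame(index=GLM_EFFECTS, columns=["F", "p", "df_num", "df_den"], dtype=float)
    for eff in GLM_EFFECTS:
        out.loc[eff, "F"] = an.loc[eff, "F"]
        out.loc[eff, "p"] = an.loc[eff, "PR(>F)"]
        out.loc[eff, "df_num"] = an.loc[eff, "df"]
        out.loc[eff, "df_den"] = fit.df_resid
    out["sign"] = [significance_code(p) for p in out["p"]]
    return GLMResult(
        table=out,
        n_used=len(df),
        rsquared=float(fit.rsquared),
        params=fit.params,
        bse=fit.bse,
    )


def paired_t_test(table: CohortTable, response: str = "surface_mm2") -> dict:
    """Two-sided paired t-test of right vs left eyes on within-subject differences.

    Pairs are subjects with a non-missing response for both OD and OS.
    """
    df = table.df.pivot_table(index="subject_id", columns="eye", values=response, aggfunc="first")
    if "OD" not in df.columns or "OS" not in df.columns:
        raise ValueError("paired test needs both OD and OS eyes in the cohort")
    pairs = df[["OD", "OS"]].dropna()
    n = len(pairs)
    if n < 2:
        raise ValueError(f"need at least 2 complete OD/OS pairs, got {n}")
    diff = (pairs["OD"] - pairs["OS"]).to_numpy(dtype=float)
    sd = diff.std(ddof=1)
    if sd == 0:
        t, p = 0.0, 1.0
    else:
        t = diff.mean() / (sd / np.sqrt(n))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return {"t": float(t), "p": float(p), "n_pairs": n}


def detect_outliers(values, rule: str = "tukey_3iqr") -> np.ndarray:
    """Indices of values flagged by a declared rule; removal is the caller's call.

    ``tukey_3iqr`` flags values outside [q1 - 3 IQR, q3 + 3 IQR] (far-out
    fences); ``zscore_3sd`` flags |z| > 3.  Both are conservative at small n.
    The flagged indices and values are logged so any removal is auditable.
    """
    v = np.asarray(values, dtype=float)
    if np.sum(np.isfinite(v)) < 4:
        raise ValueError("need at least 4 finite values for outlier detection")
    if rule == "tukey_3iqr":
        q1, q3 = np.nanpercentile(v, [25, 75])
        iqr = q3 - q1
        flagged = (v < q1 - 3 * iqr) | (v > q3 + 3 * iqr)
    elif rule == "zscore_3sd":
        mu, sd = np.nanmean(v), np.nanstd(v, ddof=1)
        flagged = np.abs(v - mu) > 3 * sd if sd > 0 else np.zeros_like(v, dtype=bool)
    else:
        raise ValueError(f"unknown rule {rule!r}; use 'tukey_3iqr' or 'zscore_3sd'")
    flagged &= np.isfinite(v)
    idx = np.flatnonzero(flagged)
    if len(idx):
        logger.info("detect_outliers(%s): flagged indices %s values %s", rule, idx, v[idx])
    return idx
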