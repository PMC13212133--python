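"""Association analyses: 2x2 odds ratios, logistic models, baseline tables.

Implements the descriptive and regression layer of the cohort analysis:
Wald odds ratios from a low-RA x MASLD contingency table, multivariable
logistic regression via in-repo IRLS, a ladder of nested covariate
adjustment models for the RA term, baseline characteristic tables with
one-way ANOVA / chi-square group tests, and median/mode covariate
imputation with audit indicator columns.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._glm import CollinearityError, LogisticFit, SeparationWarning, irls_logistic

__all__ = [
    "ContingencyTable2x2",
    "EffectEstimate",
    "odds_ratio_2x2",
    "fit_logistic",
    "model_ladder",
    "MODEL_LADDER_COVARIATES",
    "baseline_table",
    "impute_covariates",
    "LogisticFit",
    "SeparationWarning",
    "CollinearityError",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for exposure (rows: low RA / high RA) x outcome (MASLD / non)."""

    a: float  # low RA, MASLD
    b: float  # low RA, non-MASLD
    c: float  # high RA, MASLD
    d: float  # high RA, non-MASLD

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be nonnegative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")


@dataclass(frozen=True)
class EffectEstimate:
    or_: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str


def odds_ratio_2x2(t: ContingencyTable2x2) -> EffectEstimate:
    """Wald odds ratio with 95% CI from a 2x2 table.

    OR = (a*d)/(b*c). The Haldane-Anscombe +0.5 correction is applied to
    every cell only when some cell is zero; SE = sqrt(sum of reciprocal
    cells) on the (possibly corrected) counts; p from the Wald z test.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise ValueError("a margin of the table is zero: odds ratio undefined")
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = np.log(or_)
    z = log_or / se
    p = 2.0 * stats.norm.sf(abs(z))
    return EffectEstimate(or_=float(or_),
                          ci_low=float(np.exp(log_or - 1.96 * se)),
                          ci_high=float(np.exp(log_or + 1.96 * se)),
                          p_value=float(p), method="wald")


def fit_logistic(design: pd.DataFrame, outcome) -> LogisticFit:
    """Maximum-likelihood logistic fit of a design table (with intercept).

    ``design`` must already contain an intercept column (any constant
    column); categorical covariates are expected dummy-coded. Delegates to
    the IRLS core; raises ``CollinearityError`` for rank-deficient designs
    and warns ``SeparationWarning`` on perfect separation.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values in design or outcome")
    return irls_logistic(X, y, names=list(design.columns))


def _dummy_code(cohort: pd.DataFrame, covariates: list[str],
                reference: dict[str, str]) -> pd.DataFrame:
    """Numeric design columns; categoricals dummy-coded against a reference."""
    cols = {}
    for cov in covariates:
        s = cohort[cov]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool:
            s = s.astype(str)
            ref = reference.get(cov, sorted(s.unique())[0])
            for level in sorted(s.unique()):
                if level != ref:
                    cols[f"{cov}[{level}]"] = (s == level).astype(float)
        else:
            cols[cov] = s.astype(float)
    return pd.DataFrame(cols, index=cohort.index)


# nested covariate sets for the adjustment ladder (crude; +demographics;
# +socioeconomic; +metabolic/lifestyle)
MODEL_LADDER_COVARIATES: list[list[str]] = [
    [],
    ["age", "gender"],
    ["age", "gender", "education", "ethnicity", "tdi"],
    ["age", "gender", "education", "ethnicity", "tdi",
     "glucose", "drinking_status", "smoking_status"],
]

DEFAULT_REFERENCE = {"gender": "female", "education": "College",
                     "ethnicity": "White", "smoking_status": "Never",
                     "drinking_status": "Never"}


def model_ladder(cohort: pd.DataFrame, ra_group: str = "ra_group",
                 outcome: str = "masld",
                 covariate_sets: list[list[str]] | None = None,
                 reference: dict[str, str] | None = None):
    """Fit the nested adjustment models and return the RA-term OR from each.

    The exposure term is the binary low-RA indicator. Returns a list of
    (model_name, EffectEstimate, LogisticFit).
    """
    covariate_sets = MODEL_LADDER_COVARIATES if covariate_sets is None else covariate_sets
    reference = {**DEFAULT_REFERENCE, **(reference or {})}
    low = (cohort[ra_group].astype(str) == "low").astype(float)
    y = cohort[outcome].astype(float)
    results = []
    for i, covs in enumerate(covariate_sets):
        design = pd.DataFrame({"intercept": np.ones(len(cohort)), "low_ra": low})
        if covs:
            design = pd.concat([design, _dummy_code(cohort, covs, reference)], axis=1)
        fit = fit_logistic(design, y)
        coef, se = fit.coef("low_ra"), fit.se("low_ra")
        est = EffectEstimate(
            or_=float(np.exp(coef)),
            ci_low=float(np.exp(coef - Z_95 * se)),
            ci_high=float(np.exp(coef + Z_95 * se)),
            p_value=float(2 * stats.norm.sf(abs(coef / se))) if se > 0 else float("nan"),
            method="logistic")
        name = "crude" if i == 0 else f"adjusted{i}"
        results.append((name, est, fit))
    return results


def baseline_table(cohort: pd.DataFrame, group: str,
                   continuous: list[str], categorical: list[str]) -> pd.DataFrame:
    """Baseline characteristics by group with ANOVA / chi-square tests.

    Continuous variables are summarised as mean (SD) per group and compared
    with one-way ANOVA; categoricals as count (percent within group) and
    compared with Pearson chi-square (no continuity correction). Returns a
    long table with one row per variable (or per category level).
    """
    groups = sorted(cohort[group].astype(str).unique())
    sizes = cohort[group].astype(str).value_counts()
    if any(sizes.get(g, 0) == 0 for g in groups) or len(groups) < 2:
        raise ValueError("every group must be non-empty (need >= 2 groups)")
    rows = []
    rows.append({"variable": "Group number", "level": "",
                 **{g: f"{sizes[g]}" for g in groups},
                 "statistic": np.nan, "p_value": np.nan, "test": ""})
    for var in continuous:
        samples = [cohort.loc[cohort[group].astype(str) == g, var].astype(float)
                   for g in groups]
        f, p = stats.f_oneway(*samples)
        rows.append({"variable": var, "level": "",
                     **{g: f"{s.mean():.2f} ({s.std(ddof=1):.2f})"
                        for g, s in zip(groups, samples)},
                     "statistic": float(f), "p_value": float(p), "test": "anova"})
    for var in categorical:
        ct = pd.crosstab(cohort[var].astype(str), cohort[group].astype(str))
        chi2, p, _, _ = stats.chi2_contingency(ct, correction=False)
        for level in ct.index:
            rows.append({"variable": var, "level": level,
                         **{g: f"{ct.loc[level, g]} ({100 * ct.loc[level, g] / sizes[g]:.1f})"
                            for g in groups},
                         "statistic": float(chi2), "p_value": float(p),
                         "test": "chi-square"})
    return pd.DataFrame(rows)


def percent_of_group(count: int, group_size: int, decimals: int = 1) -> float:
    """Percentage cell as printed in a baseline table (rounded)."""
    if group_size <= 0:
        raise ValueError("group size must be positive")
    return round(100.0 * count / group_size, decimals)


def impute_covariates(cohort: pd.DataFrame, covariates: list[str] | None = None
                      ) -> pd.DataFrame:
    """Median (continuous) / mode (categorical) imputation with audit columns.

    Ties in the mode are broken by the lexicographically smallest category.
    For each imputed covariate a ``<name>_imputed`` indicator is added.
    """
    out = cohort.copy()
    cols = covariates if covariates is not None else list(cohort.columns)
    for col in cols:
        s = out[col]
        if not s.isna().any():
            continue
        if s.notna().sum() == 0:
            raise ValueError(f"covariate {col!r} entirely missing: cannot impute")
        if pd.api.types.is_numeric_dtype(s):
            fill = s.median()
        else:
            counts = s.dropna().value_counts()
            top = counts[counts == counts.max()]
            fill = sorted(top.index)[0]
        out[f"{col}_imputed"] = s.isna()
        out[col] = s.fillna(fill)
    return out
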