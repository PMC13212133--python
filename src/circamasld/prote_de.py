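"""Moderated two-group differential abundance screen for a protein matrix.

Per protein, a two-group linear model gives the mean difference (log_fc on
the already-log abundance scale) and the pooled residual variance s2_g with
df_g = n - 2 degrees of freedom. An empirical-Bayes step shrinks the
per-protein variances toward a shared prior: the prior degrees of freedom
d0 and prior variance s0^2 are estimated by matching the first two moments
of ln(s2_g) to the scaled-F sampling model (digamma/trigamma moment
equations), and each variance is replaced by the posterior mean

    s2_tilde = (d0 * s0^2 + df_g * s2_g) / (d0 + df_g).

Moderated t statistics are referenced to a t distribution with d0 + df_g
degrees of freedom, p-values are Benjamini-Hochberg adjusted, and the two
contrasts' significant sets are intersected to obtain the common DEPs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinMatrix",
    "DEPSets",
    "fit_per_protein",
    "moderate",
    "bh_adjust",
    "moderated_de",
    "intersect_deps",
]

D0_CAP = 1e6  # stands in for an infinite prior df (all variances identical)
MAX_MISSING_FRACTION = 0.20


@dataclass
class ProteinMatrix:
    """Proteins x participants abundance matrix (log scale assumed).

    Proteins with more than 20% missing values are dropped (count logged);
    remaining missing entries are mean-imputed per protein.
    """

    values: np.ndarray
    protein_ids: list[str]
    participant_ids: list[str]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ProteinMatrix":
        """Build from a proteins-as-rows DataFrame (columns = participants)."""
        vals = frame.to_numpy(dtype=float)
        frac_missing = np.isnan(vals).mean(axis=1)
        keep = frac_missing <= MAX_MISSING_FRACTION
        dropped = int((~keep).sum())
        if dropped:
            logger.info("dropped %d proteins with >%.0f%% missing values",
                        dropped, 100 * MAX_MISSING_FRACTION)
        vals = vals[keep]
        ids = [p for p, k in zip(frame.index.astype(str), keep) if k]
        if np.isnan(vals).any():
            row_means = np.nanmean(vals, axis=1)
            idx = np.where(np.isnan(vals))
            vals[idx] = row_means[idx[0]]
        return cls(values=vals, protein_ids=ids,
                   participant_ids=[str(c) for c in frame.columns])


@dataclass(frozen=True)
class DEPSets:
    deps_ra: frozenset
    deps_masld: frozenset
    common: frozenset


def fit_per_protein(matrix: ProteinMatrix, group) -> pd.DataFrame:
    """Two-group pooled-variance linear model per protein (vectorised).

    ``group`` is a binary vector over participant columns (1 = exposed
    group). Returns a DataFrame with log_fc (group1 - group0 mean
    difference), s2_g (pooled residual variance), df_g = n - 2 and the
    ordinary t statistic and two-sided p value.
    """
    g = np.asarray(group, dtype=int)
    if g.shape[0] != matrix.values.shape[1]:
        raise ValueError("group vector length does not match participant columns")
    n1, n0 = int(g.sum()), int((1 - g).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("each group needs at least 2 members")
    X1, X0 = matrix.values[:, g == 1], matrix.values[:, g == 0]
    m1, m0 = X1.mean(axis=1), X0.mean(axis=1)
    ss1 = ((X1 - m1[:, None]) ** 2).sum(axis=1)
    ss0 = ((X0 - m0[:, None]) ** 2).sum(axis=1)
    df = n1 + n0 - 2
    s2 = (ss1 + ss0) / df
    log_fc = m1 - m0
    se = np.sqrt(s2 * (1 / n1 + 1 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = log_fc / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return pd.DataFrame({
        "protein_id": matrix.protein_ids, "log_fc": log_fc, "s2_g": s2,
        "df_g": float(df), "t": t, "p_value": p,
        "n1": n1, "n0": n0,
    })


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the inverse scale)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def moderate(s2_g, df_g: float, log_fc=None, n1: int | None = None,
             n0: int | None = None, d0_override: float | None = None) -> dict:
    """Estimate the variance prior (d0, s0^2) and moderate the statistics.

    Moment matching on z = ln(s2_g): under the hierarchical model,
    E z = digamma(df/2) - ln(df/2) + ln(s0^2) - digamma(d0/2) + ln(d0/2)
    and Var z = trigamma(df/2) + trigamma(d0/2). A nonpositive excess
    variance means the variances are essentially identical, in which case
    d0 is set to a large cap and s2_tilde collapses to s0^2.

    Returns a dict with d0, s0_sq, s2_tilde and, when log_fc and group
    sizes are given, moderated t, its df and two-sided p-values.
    """
    s2 = np.asarray(s2_g, dtype=float)
    if s2.size < 10:
        raise ValueError("need at least 10 proteins to estimate the prior")
    if np.any(s2 <= 0):
        s2 = np.maximum(s2, 1e-12)
    z = np.log(s2)
    e = z - special.digamma(df_g / 2) + np.log(df_g / 2)
    ebar = float(np.mean(e))
    n = s2.size
    excess = float(np.mean((e - ebar) ** 2) * n / (n - 1) - special.polygamma(1, df_g / 2))
    if d0_override is not None:
        d0 = max(float(d0_override), 1e-8)  # d0 -> 0 recovers the ordinary t
    elif excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        d0 = min(d0, D0_CAP)
    else:
        d0 = D0_CAP
    if d0 >= D0_CAP and d0_override is None:
        # no detectable spread: prior variance on the raw scale (limma convention)
        s0_sq = float(np.mean(s2))
    else:
        s0_sq = float(np.exp(ebar + special.digamma(d0 / 2) - np.log(d0 / 2)))
    s2_tilde = (d0 * s0_sq + df_g * s2) / (d0 + df_g)
    out = {"d0": float(d0), "s0_sq": s0_sq, "s2_tilde": s2_tilde}
    if log_fc is not None:
        if n1 is None or n0 is None:
            raise ValueError("group sizes required to form moderated t")
        se = np.sqrt(s2_tilde * (1 / n1 + 1 / n0))
        t_mod = np.asarray(log_fc, dtype=float) / se
        df_total = min(d0 + df_g, D0_CAP)
        p = 2 * stats.t.sf(np.abs(t_mod), df_total)
        out.update({"t_moderated": t_mod, "df_total": float(df_total), "p_value": p})
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def moderated_de(matrix: ProteinMatrix, group) -> pd.DataFrame:
    """Full screen: per-protein fit, EB moderation, BH adjustment."""
    fits = fit_per_protein(matrix, group)
    mod = moderate(fits["s2_g"].to_numpy(), float(fits["df_g"].iloc[0]),
                   log_fc=fits["log_fc"].to_numpy(),
                   n1=int(fits["n1"].iloc[0]), n0=int(fits["n0"].iloc[0]))
    out = fits.copy()
    out["d0"] = mod["d0"]
    out["s0_sq"] = mod["s0_sq"]
    out["s2_tilde"] = mod["s2_tilde"]
    out["t_moderated"] = mod["t_moderated"]
    out["p_value"] = mod["p_value"]
    out["p_adjusted"] = bh_adjust(mod["p_value"])
    out["neg_log10_p_adjusted"] = -np.log10(np.maximum(out["p_adjusted"], 1e-300))
    return out


def intersect_deps(results_ra: pd.DataFrame, results_masld: pd.DataFrame,
                   alpha: float = 0.05) -> DEPSets:
    """Significant sets per contrast (adjusted p < alpha) and their overlap."""
    uni_ra = set(results_ra["protein_id"])
    uni_ma = set(results_masld["protein_id"])
    if uni_ra != uni_ma:
        raise ValueError("contrasts cover different protein universes")
    sig_ra = frozenset(results_ra.loc[results_ra["p_adjusted"] < alpha, "protein_id"])
    sig_ma = frozenset(results_masld.loc[results_masld["p_adjusted"] < alpha, "protein_id"])
    return DEPSets(deps_ra=sig_ra, deps_masld=sig_ma, common=sig_ra & sig_ma)
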