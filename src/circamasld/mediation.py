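"""Causal mediation of the low-RA -> MASLD effect through single proteins.

For each candidate protein the estimator fits (i) a linear mediator model,
protein ~ exposure + covariates, and (ii) a logistic outcome model,
MASLD ~ exposure + protein + covariates, then applies the counterfactual
g-computation recipe: each participant's mediator value under exposure arm
t' is the fitted mean under t' plus their observed residual, and outcome
probabilities are predicted under the four exposure x mediator-regime
combinations. The average causal mediation effect (ACME) and average
direct effect (ADE) are each averaged over the two exposure arms, so the
total effect decomposes exactly as ACME + ADE on the probability scale.
Uncertainty comes from a nonparametric bootstrap over participants with
percentile intervals; the ACME p-value is the two-sided percentile p,
floored at 1/n_boot.

Screening keeps proteins with ACME p < 0.05 and proportion mediated
(ACME / total effect, at the point estimates) > 0.10.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._glm import SeparationWarning, irls_logistic

__all__ = [
    "MediationEstimate",
    "MediationScreenResult",
    "mediate",
    "screen_mediators",
    "mediate_many",
    "ACME_ALPHA",
    "PROP_MEDIATED_CUTOFF",
]

ACME_ALPHA = 0.05
PROP_MEDIATED_CUTOFF = 0.10


@dataclass
class MediationEstimate:
    protein_id: str
    acme: float
    ade: float
    total: float
    prop_mediated: float
    acme_p: float
    acme_ci: tuple[float, float]
    ade_ci: tuple[float, float]
    total_ci: tuple[float, float]
    n_boot: int
    seed: int
    reliable: bool = True
    notes: str = ""


@dataclass
class MediationScreenResult:
    passing: list[str]
    all_estimates: list[MediationEstimate] = field(repr=False, default_factory=list)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _point_effects(t, m, y, C):
    """(acme, ade, total) for one dataset; C includes no intercept."""
    n = t.shape[0]
    ones = np.ones((n, 1))
    Xm = np.column_stack([ones, t[:, None], C])
    # mediator model by least squares
    coef_m, *_ = np.linalg.lstsq(Xm, m, rcond=None)
    fitted = Xm @ coef_m
    resid = m - fitted
    a = coef_m[1]
    # counterfactual mediator values per participant
    base = fitted - a * t  # fitted mean with exposure forced to 0
    m0 = base + resid
    m1 = base + a + resid
    # outcome model
    Xy = np.column_stack([ones, t[:, None], m[:, None], C])
    fit = irls_logistic(Xy, y, check_rank=False)
    b0, bt, bm = fit.coefficients[0], fit.coefficients[1], fit.coefficients[2]
    rest = Xy[:, 3:] @ fit.coefficients[3:] if Xy.shape[1] > 3 else 0.0

    def p(t_val, m_vals):
        return _sigmoid(b0 + bt * t_val + bm * m_vals + rest)

    acme = 0.5 * (np.mean(p(0, m1) - p(0, m0)) + np.mean(p(1, m1) - p(1, m0)))
    ade = 0.5 * (np.mean(p(1, m0) - p(0, m0)) + np.mean(p(1, m1) - p(0, m1)))
    return acme, ade, acme + ade, fit.converged


def mediate(exposure, mediator, outcome, covariates=None, n_boot: int = 1000,
            seed: int = 0, protein_id: str = "") -> MediationEstimate:
    """Single-protein mediation estimate with bootstrap intervals.

    Parameters
    ----------
    exposure, mediator, outcome
        Aligned vectors: binary exposure (1 = low RA), continuous mediator
        abundance, binary outcome.
    covariates
        Optional numeric table (no intercept column) entering both models.
    n_boot
        Bootstrap resamples (>= 200).
    """
    t = np.asarray(exposure, dtype=float)
    m = np.asarray(mediator, dtype=float)
    y = np.asarray(outcome, dtype=float)
    C = (np.empty((t.shape[0], 0)) if covariates is None
         else np.asarray(covariates, dtype=float))
    if not (t.shape == m.shape == y.shape) or C.shape[0] != t.shape[0]:
        raise ValueError("exposure, mediator, outcome and covariates must align")
    if np.isnan(t).any() or np.isnan(m).any() or np.isnan(y).any() or np.isnan(C).any():
        raise ValueError("missing values not allowed in mediation inputs")
    if n_boot < 200:
        raise ValueError("n_boot must be at least 200")
    if np.std(m) == 0:
        raise ValueError("constant mediator: zero variance")

    reliable = True
    notes = ""
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", SeparationWarning)
        acme, ade, total, converged = _point_effects(t, m, y, C)
        if any(issubclass(w.category, SeparationWarning) for w in caught) or not converged:
            reliable = False
            notes = "separation in outcome model"
            warnings.warn("outcome model separation: mediation estimate unreliable",
                          SeparationWarning)

    rng = np.random.default_rng(seed)
    n = t.shape[0]
    boots = np.empty((n_boot, 3))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SeparationWarning)
        for bidx in range(n_boot):
            idx = rng.integers(0, n, size=n)
            # resample until both outcome classes and exposure arms present
            tries = 0
            while (y[idx].min() == y[idx].max() or t[idx].min() == t[idx].max()) and tries < 20:
                idx = rng.integers(0, n, size=n)
                tries += 1
            boots[bidx] = _point_effects(t[idx], m[idx], y[idx], C[idx])[:3]

    lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
    frac_le = np.mean(boots[:, 0] <= 0)
    frac_ge = np.mean(boots[:, 0] >= 0)
    acme_p = max(2.0 * min(frac_le, frac_ge), 1.0 / n_boot)
    acme_p = min(acme_p, 1.0)
    prop = acme / total if total != 0 else np.nan
    return MediationEstimate(
        protein_id=protein_id, acme=float(acme), ade=float(ade), total=float(total),
        prop_mediated=float(prop), acme_p=float(acme_p),
        acme_ci=(float(lo[0]), float(hi[0])), ade_ci=(float(lo[1]), float(hi[1])),
        total_ci=(float(lo[2]), float(hi[2])), n_boot=n_boot, seed=seed,
        reliable=reliable, notes=notes)


def mediate_many(exposure, proteome_values: np.ndarray, protein_ids, outcome,
                 covariates=None, n_boot: int = 1000, seed: int = 0
                 ) -> list[MediationEstimate]:
    """Mediation estimates for each row of a proteins x participants matrix.

    Per-protein seeds derive from the root seed plus the protein index so
    adding proteins never perturbs earlier estimates.
    """
    out = []
    for j, pid in enumerate(protein_ids):
        out.append(mediate(exposure, proteome_values[j], outcome,
                           covariates=covariates, n_boot=n_boot,
                           seed=int(seed) + j, protein_id=str(pid)))
    return out


def screen_mediators(estimates: list[MediationEstimate],
                     acme_alpha: float = ACME_ALPHA,
                     prop_cutoff: float = PROP_MEDIATED_CUTOFF
                     ) -> MediationScreenResult:
    """Keep proteins with ACME p < alpha and proportion mediated > cutoff."""
    passing = [e.protein_id for e in estimates
               if e.acme_p < acme_alpha and e.prop_mediated > prop_cutoff]
    return MediationScreenResult(passing=passing, all_estimates=list(estimates))


def estimates_table(estimates: list[MediationEstimate]) -> pd.DataFrame:
    rows = []
    for e in estimates:
        rows.append({
            "protein_id": e.protein_id, "acme": e.acme, "ade": e.ade,
            "total": e.total, "prop_mediated": e.prop_mediated,
            "acme_p": e.acme_p,
            "acme_ci_low": e.acme_ci[0], "acme_ci_high": e.acme_ci[1],
            "ade_ci_low": e.ade_ci[0], "ade_ci_high": e.ade_ci[1],
            "total_ci_low": e.total_ci[0], "total_ci_high": e.total_ci[1],
            "n_boot": e.n_boot, "seed": e.seed, "reliable": e.reliable,
        })
    return pd.DataFrame(rows)
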