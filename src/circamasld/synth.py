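"""Synthetic cohort generator for the circadian-rhythm / MASLD pipeline.

Emulates the statistical structure every downstream stage assumes, without
any real cohort data:

* 24-hour activity profiles follow a clipped cosinor,
  ``max(0, mesor + A cos(2 pi (h - acrophase) / 24) + noise)``, with the
  amplitude A drawn per participant from one of two regimes (a small
  "disrupted" group near the low end of ``amplitude_range`` and the rest
  near the high end), so the relative-amplitude distribution has the
  bulk-plus-low-tail shape the 2-SD grouping rule expects.
* the latent disruption exposure is continuous: the standardized negative
  noise-free relative amplitude of each participant's cosinor. The binary
  low-RA label produced downstream is a coarsening of this real signal.
* planted mediator proteins depend linearly on the exposure
  (slope ``mediator_a``) plus heteroscedastic noise whose per-protein
  variances follow a scaled inverse-chi-square, so the empirical-Bayes
  moderation step has a real prior to recover; the remaining proteins are
  independent of exposure and outcome given covariates.
* the MASLD outcome is Bernoulli with logit = intercept + direct effect x
  exposure + sum of mediator contributions + covariate effects (continuous
  covariates centered at their cohort means).

Covariates (age, sex, BMI, lipids, blood pressure, sleep questionnaire
items, ...) are drawn independently with moments matched to the published
cohort descriptives. Every random component uses its own substream of the
single global seed, so enlarging the proteome never perturbs the
covariate or profile draws.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .actigraphy import profile_metrics
from .prote_de import ProteinMatrix

__all__ = ["SynthConfig", "SyntheticCohort", "generate_cohort",
           "generate_activity_profile", "planted_acme", "write_cohort"]

HOURS = 24


class InvalidConfigError(ValueError):
    """Synthetic-cohort configuration violates an invariant."""


@dataclass
class SynthConfig:
    """Generator parameters; defaults are the emulated study conditions.

    Counts default to the proteomics subcohort scale (8,843 participants,
    2,923 proteins, an 18-protein mediating panel). Activity units are
    milli-gravity-like hourly means; ``mediator_a`` is abundance units per
    SD of the disruption exposure, ``mediator_b`` log-odds per abundance
    unit, ``direct_c`` log-odds per exposure SD.
    """

    n_participants: int = 8843
    n_proteins: int = 2923
    n_mediators: int = 18
    mesor: float = 25.0
    amplitude_range: tuple[float, float] = (16.0, 24.0)
    acrophase_hours: float = 14.0
    noise_sd: float = 2.0
    mediator_a: float = 0.5
    mediator_b: float = 0.4
    direct_c: float = 0.3
    covariate_effects: dict = field(
        default_factory=lambda: {"bmi": 0.15, "age": 0.02, "sex_male": 0.8})
    outcome_intercept: float = -1.6
    seed: int = 0
    low_group_fraction: float = 0.037  # matches the observed low-RA share
    amplitude_sd: float = 1.5

    def validate(self) -> None:
        if self.seed is None:
            raise InvalidConfigError("seed is required")
        if self.n_participants <= 0 or self.n_proteins <= 0:
            raise InvalidConfigError("counts must be positive")
        if self.n_mediators < 0 or self.n_mediators > self.n_proteins:
            raise InvalidConfigError("n_mediators must be in [0, n_proteins]")
        low, high = self.amplitude_range
        if not (0 <= low <= high):
            raise InvalidConfigError("amplitude_range must satisfy 0 <= low <= high")
        if self.mesor <= 0:
            raise InvalidConfigError("mesor must be positive")
        if self.noise_sd < 0 or self.amplitude_sd < 0:
            raise InvalidConfigError("noise SDs must be nonnegative")
        if not 0 <= self.low_group_fraction < 1:
            raise InvalidConfigError("low_group_fraction must be in [0, 1)")


@dataclass
class SyntheticCohort:
    participants: pd.DataFrame
    profiles: pd.DataFrame
    proteome: ProteinMatrix
    truth: dict


def generate_activity_profile(amplitude: float, mesor: float, acrophase: float,
                              noise_sd: float, rng: np.random.Generator
                              ) -> np.ndarray:
    """One clipped-cosinor 24-value hourly profile."""
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    if mesor <= 0:
        raise ValueError("mesor must be positive")
    h = np.arange(HOURS)
    clean = mesor + amplitude * np.cos(2 * np.pi * (h - acrophase) / HOURS)
    noise = rng.normal(0.0, noise_sd, HOURS) if noise_sd > 0 else 0.0
    return np.maximum(clean + noise, 0.0)


def _covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    sex = np.where(rng.random(n) < 0.4425, "male", "female")
    male = sex == "male"
    df = pd.DataFrame({
        "participant_id": [f"P{i:06d}" for i in range(n)],
        "age": rng.normal(56.18, 7.81, n).clip(40, 70),
        "sex": sex,
        "bmi": np.exp(rng.normal(np.log(27.0), 0.15, n)),
        "tg": np.exp(rng.normal(np.log(1.5), 0.45, n)),          # mmol/L
        "ggt": np.exp(rng.normal(np.log(30.0), 0.5, n)),         # U/L
        "wc": np.where(male, rng.normal(98, 10, n), rng.normal(85, 12, n)).clip(55, 160),
        "fasting_glucose": rng.normal(92, 14, n).clip(55, 250),  # mg/dL
        "hba1c": rng.normal(5.5, 0.55, n).clip(3.5, 12),         # percent
        "hdl": np.where(male, rng.normal(1.30, 0.30, n),
                        rng.normal(1.62, 0.35, n)).clip(0.4, 4),
        "sbp": rng.normal(137.5, 17.5, n).clip(80, 220),
        "dbp": rng.normal(82.5, 9.9, n).clip(40, 130),
        "antihypertensive_use": rng.random(n) < 0.20,
        "t2dm": rng.random(n) < 0.03,
        "tdi": rng.normal(-1.74, 2.80, n),
        "glucose": rng.normal(5.07, 1.05, n).clip(3, 15),        # mmol/L lab value
        "education": rng.choice(["College", "Other levels", "Unknown"], n,
                                p=[0.43, 0.48, 0.09]),
        "ethnicity": rng.choice(["White", "Other"], n, p=[0.97, 0.03]),
        "smoking_status": rng.choice(["Never", "Previous", "Current"], n,
                                     p=[0.57, 0.36, 0.07]),
        "drinking_status": rng.choice(["Current", "Never", "Previous"], n,
                                      p=[0.944, 0.028, 0.028]),
        "chronotype": rng.choice([1, 2, 3, 4], n, p=[0.25, 0.35, 0.28, 0.12]),
        "duration_hours": np.round(rng.normal(7.2, 1.1, n)).clip(3, 12).astype(int),
        "insomnia": rng.choice(["never-rarely", "sometimes", "usually"], n,
                               p=[0.24, 0.47, 0.29]),
        "snoring": rng.random(n) < 0.37,
        "daytime_sleepiness": rng.choice(["never-rarely", "sometimes", "often"], n,
                                         p=[0.75, 0.22, 0.03]),
    })
    return df


def generate_cohort(config: SynthConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort (deterministic for a fixed seed)."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    rng_cov, rng_amp, rng_prof, rng_prot, rng_out = (
        np.random.default_rng(s) for s in root.spawn(5))

    n = config.n_participants
    participants = _covariates(n, rng_cov)

    low, high = config.amplitude_range
    spread = config.amplitude_sd if high > low else 0.0
    latent_low = rng_amp.random(n) < config.low_group_fraction
    centers = np.where(latent_low, low, high)
    amplitude = np.maximum(centers + rng_amp.normal(0.0, 1.0, n) * spread, 0.0)

    h = np.arange(HOURS)
    cosine = np.cos(2 * np.pi * (h[None, :] - config.acrophase_hours) / HOURS)
    clean = np.maximum(config.mesor + amplitude[:, None] * cosine, 0.0)
    noise = rng_prof.normal(0.0, config.noise_sd, (n, HOURS)) if config.noise_sd > 0 else 0.0
    profiles = np.maximum(config.mesor + amplitude[:, None] * cosine + noise, 0.0)
    from .actigraphy import matrix_metrics
    ra_true = matrix_metrics(clean)[4] if np.all(clean.sum(axis=1) > 0) \
        else np.array([profile_metrics(row).ra if row.sum() > 0 else 0.0
                       for row in clean])

    sd_ra = ra_true.std()
    if sd_ra > 0:
        exposure = (ra_true.mean() - ra_true) / sd_ra  # higher = more disrupted
    else:
        exposure = np.zeros(n)

    # proteome: planted mediators respond to the exposure; per-protein noise
    # variances follow a scaled inverse-chi-square prior (d0=8, s0^2=1)
    p = config.n_proteins
    protein_ids = [f"PROT{j:04d}" for j in range(p)]
    a_j = np.zeros(p)
    b_j = np.zeros(p)
    mediator_flags = np.zeros(p, dtype=bool)
    mediator_flags[: config.n_mediators] = True
    a_j[mediator_flags] = config.mediator_a
    b_j[mediator_flags] = config.mediator_b
    prior_d0, prior_s0_sq = 8.0, 1.0
    noise_var = prior_d0 * prior_s0_sq / rng_prot.chisquare(prior_d0, p)
    values = a_j[:, None] * exposure[None, :] + \
        rng_prot.normal(0.0, 1.0, (p, n)) * np.sqrt(noise_var)[:, None]

    # outcome from the planted logistic model
    eta = np.full(n, config.outcome_intercept, dtype=float)
    eta += config.direct_c * exposure
    eta += (b_j[:, None] * values).sum(axis=0)
    for name, coef in config.covariate_effects.items():
        if name == "sex_male":
            col = (participants["sex"] == "male").astype(float).to_numpy()
        else:
            col = participants[name].astype(float).to_numpy()
            col = col - col.mean()
        eta += coef * col
    masld = (rng_out.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    participants["masld"] = masld

    prof_df = pd.DataFrame(profiles, columns=[f"hour_{i}" for i in range(HOURS)])
    prof_df.insert(0, "participant_id", participants["participant_id"])

    truth = {
        "config": {**asdict(config),
                   "amplitude_range": list(config.amplitude_range)},
        "protein_ids": protein_ids,
        "a_j": a_j.tolist(),
        "b_j": b_j.tolist(),
        "direct_c": config.direct_c,
        "outcome_intercept": config.outcome_intercept,
        "mediator_flags": mediator_flags.tolist(),
        "noise_var": noise_var.tolist(),
        "prior_d0": prior_d0,
        "prior_s0_sq": prior_s0_sq,
        "amplitude": amplitude.tolist(),
        "ra_true": ra_true.tolist(),
        "exposure": exposure.tolist(),
        "latent_low": latent_low.tolist(),
    }
    proteome = ProteinMatrix(values=values, protein_ids=protein_ids,
                             participant_ids=list(participants["participant_id"]))
    return SyntheticCohort(participants=participants, profiles=prof_df,
                           proteome=proteome, truth=truth)


def planted_acme(cohort: SyntheticCohort, low_labels, protein_id: str,
                 n_rep: int = 50, seed: int = 12345) -> float:
    """Monte-Carlo ACME implied by the true structural equations.

    For the binary low-RA contrast defined by ``low_labels``, draws arm
    exposures from the cohort's arm-specific exposure distributions and
    g-computes, on the true outcome model, the average effect of switching
    the target protein between its two counterfactual arm values while
    holding the exposure and every other protein at a fixed arm. Averaged
    over both exposure arms and ``n_rep`` Monte-Carlo replicates.
    """
    truth = cohort.truth
    j = truth["protein_ids"].index(protein_id)
    a = np.asarray(truth["a_j"])
    b = np.asarray(truth["b_j"])
    exposure = np.asarray(truth["exposure"])
    low = np.asarray(low_labels, dtype=bool)
    if low.sum() == 0 or (~low).sum() == 0:
        raise ValueError("both exposure arms must be non-empty")
    pools = {1: exposure[low], 0: exposure[~low]}
    values = cohort.proteome.values
    n = exposure.size
    # participant-level structural residuals
    eps = values - a[:, None] * exposure[None, :]
    cfg = truth["config"]
    cov_term = np.zeros(n)
    parts = cohort.participants
    for name, coef in cfg["covariate_effects"].items():
        if name == "sex_male":
            col = (parts["sex"] == "male").astype(float).to_numpy()
        else:
            col = parts[name].astype(float).to_numpy()
            col = col - col.mean()
        cov_term += coef * col
    base = truth["outcome_intercept"] + cov_term
    rng = np.random.default_rng(seed)
    acc = 0.0
    for _ in range(n_rep):
        e1 = rng.choice(pools[1], size=n)
        e0 = rng.choice(pools[0], size=n)
        mj1 = a[j] * e1 + eps[j]
        mj0 = a[j] * e0 + eps[j]
        for t_arm in (0, 1):
            et = rng.choice(pools[t_arm], size=n)
            other = (b[:, None] * (a[:, None] * et[None, :] + eps)).sum(axis=0) \
                - b[j] * (a[j] * et + eps[j])
            eta_base = base + truth["direct_c"] * et + other
            p1 = 1.0 / (1.0 + np.exp(-(eta_base + b[j] * mj1)))
            p0 = 1.0 / (1.0 + np.exp(-(eta_base + b[j] * mj0)))
            acc += np.mean(p1 - p0) / 2.0
    return acc / n_rep


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Persist as participants.csv, profiles.csv, proteome.csv, truth.json."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.participants.to_csv(out / "participants.csv", index=False)
    cohort.profiles.to_csv(out / "profiles.csv", index=False)
    wide = pd.DataFrame(cohort.proteome.values.T,
                        columns=cohort.proteome.protein_ids)
    wide.insert(0, "participant_id", cohort.proteome.participant_ids)
    wide.to_csv(out / "proteome.csv", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh)
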