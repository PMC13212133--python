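"""End-to-end pipeline: synth -> actigraphy -> phenotype -> association ->
differential abundance -> mediation screen -> panel -> enrichment.

Every stage writes flat CSV/TSV/JSON intermediates into the run directory
and the manifest records seeds, thresholds and the participant/protein
counts before and after each filter, so each reported number can be
recomputed from persisted files.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import actigraphy, assoc, mediation, netenrich, panel, phenotype, prote_de, synth

__all__ = ["PipelineConfig", "run_pipeline", "predict_risk",
           "save_panel_model", "load_panel_model"]


@dataclass
class PipelineConfig:
    """Thresholds default to the analysis constants: DEP alpha 0.05, ACME
    alpha 0.05, mediated-proportion cutoff 0.10, parsimony tolerance 0.01,
    low-RA rule mean - 2 SD, FLI cutoff 60, 70/30 split, 10 CV folds."""

    out_dir: str = "run"
    synth: dict | None = None          # SynthConfig overrides, or None
    participants_csv: str | None = None
    profiles_csv: str | None = None
    proteome_csv: str | None = None
    dep_alpha: float = 0.05
    acme_alpha: float = mediation.ACME_ALPHA
    prop_cutoff: float = mediation.PROP_MEDIATED_CUTOFF
    parsimony_tolerance: float = panel.PARSIMONY_TOLERANCE
    train_fraction: float = 0.7
    cv_folds: int = 10
    n_boot: int = 1000
    seed: int = 0
    mediation_covariates: list = field(default_factory=lambda: ["age", "bmi"])
    gmt_file: str | None = None
    edges_file: str | None = None
    max_mediation_proteins: int | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def save_panel_model(model: panel.PanelModel, path) -> None:
    """Persist a logistic panel model as reloadable JSON."""
    if model.classifier_name != "logistic":
        raise ValueError("only logistic panel models serialize to JSON")
    fit = model.fitted_params
    payload = {
        "classifier": "logistic",
        "panel_ids": list(model.panel_ids),
        "feature_means": np.asarray(model.feature_means).tolist(),
        "feature_sds": np.asarray(model.feature_sds).tolist(),
        "coefficients": np.asarray(fit.coefficients).tolist(),  # intercept first
        "auc": model.auc,
        "split_seed": model.split_seed,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_panel_model(path) -> dict:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("classifier") != "logistic":
        raise ValueError("model file does not hold a logistic panel model")
    return payload


def predict_risk(model: dict, protein_values: dict) -> float:
    """Probability from a stored logistic panel model for one sample.

    Unknown protein names are ignored with a warning; a missing panel
    protein is an error naming the absent ids.
    """
    ids = model["panel_ids"]
    missing = [p for p in ids if p not in protein_values]
    if missing:
        raise KeyError(f"missing panel proteins: {missing}")
    unknown = sorted(set(protein_values) - set(ids))
    if unknown:
        warnings.warn(f"ignoring unknown proteins: {unknown}")
    x = np.array([float(protein_values[p]) for p in ids])
    z = (x - np.asarray(model["feature_means"])) / np.asarray(model["feature_sds"])
    coefs = np.asarray(model["coefficients"])
    return float(_sigmoid(coefs[0] + z @ coefs[1:]))


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage; returns the run directory.

    Stops gracefully (with the stage recorded in the manifest) when a
    filter leaves nothing for the next stage to work on.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "counts": {},
                      "thresholds": {
                          "dep_alpha": config.dep_alpha,
                          "acme_alpha": config.acme_alpha,
                          "prop_cutoff": config.prop_cutoff,
                          "parsimony_tolerance": config.parsimony_tolerance,
                          "train_fraction": config.train_fraction,
                          "cv_folds": config.cv_folds,
                      }}

    def checkpoint(stage: str, **counts):
        manifest["stages"].append(stage)
        manifest["counts"].update(counts)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)

    # --- inputs -----------------------------------------------------------
    cohort = None
    if config.synth is not None:
        scfg = synth.SynthConfig(**{"seed": config.seed, **config.synth})
        cohort = synth.generate_cohort(scfg)
        synth.write_cohort(cohort, out / "cohort")
        participants = cohort.participants
        profiles = cohort.profiles
        proteome_wide = pd.DataFrame(cohort.proteome.values.T,
                                     columns=cohort.proteome.protein_ids)
        proteome_wide.insert(0, "participant_id", cohort.proteome.participant_ids)
        checkpoint("synth", n_participants=len(participants),
                   n_proteins=len(cohort.proteome.protein_ids))
    else:
        if not (config.participants_csv and config.profiles_csv):
            raise PipelineStageError("inputs", "need a synth block or input CSVs")
        participants = pd.read_csv(config.participants_csv)
        profiles = pd.read_csv(config.profiles_csv)
        proteome_wide = (pd.read_csv(config.proteome_csv)
                         if config.proteome_csv else None)
        checkpoint("load", n_participants=len(participants))

    # --- actigraphy -------------------------------------------------------
    ra = actigraphy.metrics_table(profiles)
    ra.to_csv(out / "ra_metrics.csv", index=False)
    checkpoint("actigraphy", n_low_ra=int((ra["ra_group"] == "low").sum()))

    # --- phenotype --------------------------------------------------------
    pheno = phenotype.phenotype_table(participants)
    pheno = pheno.merge(ra[["participant_id", "ra", "ra_group"]], on="participant_id")
    pheno = assoc.impute_covariates(pheno)
    pheno.to_csv(out / "phenotyped.csv", index=False)
    checkpoint("phenotype", n_masld=int(pheno["masld"].sum()))

    # --- association ------------------------------------------------------
    table = assoc.ContingencyTable2x2(
        a=int(((pheno["ra_group"] == "low") & (pheno["masld"] == 1)).sum()),
        b=int(((pheno["ra_group"] == "low") & (pheno["masld"] == 0)).sum()),
        c=int(((pheno["ra_group"] == "high") & (pheno["masld"] == 1)).sum()),
        d=int(((pheno["ra_group"] == "high") & (pheno["masld"] == 0)).sum()))
    crude = assoc.odds_ratio_2x2(table)
    ladder_covs = [
        [],
        ["age", "gender"],
        ["age", "gender", "education", "ethnicity", "tdi"],
        ["age", "gender", "education", "ethnicity", "tdi", "glucose",
         "drinking_status", "smoking_status"],
    ]
    pheno["gender"] = pheno["sex"]
    ladder = assoc.model_ladder(pheno, covariate_sets=ladder_covs)
    pd.DataFrame([{"model": nm, "or": e.or_, "ci_low": e.ci_low,
                   "ci_high": e.ci_high, "p": e.p_value}
                  for nm, e, _ in ladder]).to_csv(out / "model_ladder.csv", index=False)
    base_tab = assoc.baseline_table(
        pheno.assign(masld_group=np.where(pheno["masld"] == 1, "MASLD", "non-MASLD")),
        group="masld_group",
        continuous=["age", "bmi", "tg", "hdl", "sbp", "dbp", "ra"],
        categorical=["sex", "smoking_status", "sleep_pattern"])
    base_tab.to_csv(out / "baseline_masld.csv", index=False)
    checkpoint("assoc", crude_or=crude.or_, adjusted_or=ladder[-1][1].or_)

    if proteome_wide is None:
        checkpoint("end", note="no proteome supplied; stopping after association")
        return out

    # --- differential abundance (both contrasts) --------------------------
    prot_frame = proteome_wide.set_index("participant_id").T
    matrix = prote_de.ProteinMatrix.from_frame(prot_frame)
    order = {pid: i for i, pid in enumerate(pheno["participant_id"].astype(str))}
    col_order = np.argsort([order[p] for p in matrix.participant_ids])
    matrix.values = matrix.values[:, col_order]
    matrix.participant_ids = [matrix.participant_ids[i] for i in col_order]
    low = (pheno["ra_group"] == "low").astype(int).to_numpy()
    mas = pheno["masld"].astype(int).to_numpy()
    res_ra = prote_de.moderated_de(matrix, low)
    res_ma = prote_de.moderated_de(matrix, mas)
    res_ra.to_csv(out / "de_ra.tsv", sep="\t", index=False)
    res_ma.to_csv(out / "de_masld.tsv", sep="\t", index=False)
    deps = prote_de.intersect_deps(res_ra, res_ma, alpha=config.dep_alpha)
    with open(out / "dep_sets.json", "w") as fh:
        json.dump({"deps_ra": sorted(deps.deps_ra),
                   "deps_masld": sorted(deps.deps_masld),
                   "common": sorted(deps.common)}, fh, indent=1)
    checkpoint("prote_de", n_deps_ra=len(deps.deps_ra),
               n_deps_masld=len(deps.deps_masld), n_deps_common=len(deps.common))
    if not deps.common:
        checkpoint("end", note="empty common DEP set; stopping before mediation")
        return out

    # --- mediation screen -------------------------------------------------
    candidates = sorted(deps.common)
    if config.max_mediation_proteins is not None:
        candidates = candidates[: config.max_mediation_proteins]
    idx = [matrix.protein_ids.index(p) for p in candidates]
    covs = pheno[config.mediation_covariates].astype(float).to_numpy()
    estimates = mediation.mediate_many(low, matrix.values[idx], candidates, mas,
                                       covariates=covs, n_boot=config.n_boot,
                                       seed=config.seed)
    screen = mediation.screen_mediators(estimates, acme_alpha=config.acme_alpha,
                                        prop_cutoff=config.prop_cutoff)
    mediation.estimates_table(estimates).to_csv(out / "mediation.tsv", sep="\t",
                                                index=False)
    checkpoint("mediation", n_mediation_candidates=len(candidates),
               n_mediation_passing=len(screen.passing))
    if not screen.passing:
        checkpoint("end", note="no proteins passed the mediation screen")
        return out

    # --- panel ------------------------------------------------------------
    feats = pd.DataFrame(matrix.values[[matrix.protein_ids.index(p)
                                        for p in screen.passing]].T,
                         columns=screen.passing)
    lasso = panel.lasso_logistic_cv(feats, mas, n_folds=config.cv_folds,
                                    seed=config.seed)
    ranking = panel.rank_proteins(lasso)
    pd.DataFrame({"lambda": lasso.lambda_grid, "cv_deviance": lasso.cv_error,
                  "cv_sd": lasso.cv_error_sd}).to_csv(out / "lasso_path.tsv",
                                                      sep="\t", index=False)
    if not ranking:
        checkpoint("end", note="LASSO selected no proteins")
        return out
    tr, te = panel.split_stratified(mas, config.train_fraction, seed=config.seed)
    curve = panel.incremental_auc(ranking, feats, mas, tr, te)
    pd.DataFrame({"k": curve.k_values, "auc": curve.auc_at_k,
                  "protein": curve.ranking}).to_csv(out / "panel_curve.tsv",
                                                    sep="\t", index=False)
    k_star, panel_ids = panel.select_parsimonious(curve, config.parsimony_tolerance)
    models = panel.train_classifiers(feats[panel_ids], mas, (tr, te),
                                     seed=config.seed)
    save_panel_model(models["logistic"], out / "panel_model.json")
    pd.DataFrame([{"method": m, "auc": pm.auc} for m, pm in models.items()]
                 ).to_csv(out / "classifier_auc.csv", index=False)
    for m, pm in models.items():
        pd.DataFrame({"threshold": pm.roc.thresholds, "fpr": pm.roc.fpr,
                      "tpr": pm.roc.tpr}).to_csv(out / f"roc_{m}.tsv",
                                                 sep="\t", index=False)
    checkpoint("panel", n_lasso_nonzero=len(ranking), k_star=k_star,
               **{f"auc_{m}": pm.auc for m, pm in models.items()})

    # --- enrichment / network (optional inputs) ---------------------------
    if config.gmt_file:
        sets = netenrich.read_gmt(config.gmt_file)
        coll = netenrich.GeneSetCollection.from_sets(sets, matrix.protein_ids)
        enr = netenrich.hypergeom_enrich(panel_ids, coll)
        netenrich.enrichment_table(enr).to_csv(out / "enrichment.tsv", sep="\t",
                                               index=False)
        checkpoint("enrich", n_sets=len(enr))
    if config.edges_file:
        net = netenrich.InteractionNetwork.from_edges(
            netenrich.read_edge_list(config.edges_file))
        core = netenrich.degree_core(net)
        with open(out / "core_proteins.json", "w") as fh:
            json.dump(sorted(core), fh)
        checkpoint("network", n_core=len(core))

    checkpoint("end")
    return out
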