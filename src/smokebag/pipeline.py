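"""End-to-end orchestration: simulate -> QC -> PRS -> brain age ->
associations -> mediation -> enrichment, from one config with per-stage
seeds and a JSON run manifest.

The brain-age model is trained exclusively on never-smokers and its
ensemble + bias model are applied unchanged to the smoking group; the
optimal z-scored PRS and the corrected BAG feed the association,
comparison, mediation and enrichment stages.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, enrichment, mediation
from .brainage import BrainAgeModel, residualize
from .containers import SyntheticCohort
from .prs import ClumpConfig, ThresholdGrid, clump, threshold_scan
from .qc import QCThresholds, qc_filter
from .synthetic import SimConfig, simulate_cohort, simulate_gene_annotation

log = logging.getLogger("smokebag.pipeline")

RESIDUAL_COVARIATES = [
    "sex", "handedness", "bmi", "alcohol", "tiv", "site", "education",
]
MODEL1_COVARIATES = ["sex", "age"]
MODEL2_COVARIATES = [
    "sex", "age", "tiv", "handedness", "bmi", "alcohol", "site", "education",
]
PRS_SELECTION_COVARIATES = [
    "age", "sex", "handedness", "bmi", "alcohol", "tiv",
    "pc1", "pc2", "pc3", "pc4", "pc5",
]


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    qc: QCThresholds = field(default_factory=QCThresholds)
    clump: ClumpConfig = field(default_factory=ClumpConfig)
    grid: ThresholdGrid = field(default_factory=ThresholdGrid)
    top_k: int = 10
    brainage_param_grid: dict = field(
        default_factory=lambda: {
            "max_depth": [3], "learning_rate": [0.1], "n_estimators": [150],
        }
    )
    n_outer_folds: int = 5
    n_inner_folds: int = 5
    residual_covariates: list = field(default_factory=lambda: list(RESIDUAL_COVARIATES))
    model1_covariates: list = field(default_factory=lambda: list(MODEL1_COVARIATES))
    model2_covariates: list = field(default_factory=lambda: list(MODEL2_COVARIATES))
    prs_covariates: list = field(default_factory=lambda: list(PRS_SELECTION_COVARIATES))
    n_boot: int = 1000
    enrichment_flank_kb: float = 0.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        if "sim" in raw:
            cfg.sim = SimConfig(**raw["sim"])
        if "qc" in raw:
            cfg.qc = QCThresholds(**raw["qc"])
        if "clump" in raw:
            cfg.clump = ClumpConfig(**raw["clump"])
        if "grid" in raw:
            cfg.grid = ThresholdGrid(raw["grid"])
        for key in (
            "top_k", "brainage_param_grid", "n_outer_folds", "n_inner_folds",
            "residual_covariates", "model1_covariates", "model2_covariates",
            "prs_covariates", "n_boot", "enrichment_flank_kb", "seed",
        ):
            if key in raw:
                setattr(cfg, key, raw[key])
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid"] = {"n_thresholds": len(self.grid.p_thresholds)}
        return d


def corrected_bag_contrast(
    sim_config: SimConfig,
    param_grid: dict | None = None,
    seed: int = 0,
):
    """Smoker vs never-smoker contrast of the corrected brain-age gap.

    Simulates a cohort, residualizes the region volumes, trains the
    brain-age model on never-smokers only, predicts the smoking group with
    the training bias model applied unchanged, and returns the Welch/Cohen
    comparison (smokers minus never-smokers) of corrected BAG.
    """
    from . import association as _assoc

    sim = simulate_cohort(sim_config)
    t = sim.cohort.table
    region_cols = sim.cohort.region_columns
    feats = residualize(t[region_cols], t[RESIDUAL_COVARIATES])
    never = (t["smoking_status"] == "never").to_numpy()
    grid = param_grid or {
        "max_depth": [3], "learning_rate": [0.1], "n_estimators": [150],
    }
    res = BrainAgeModel(
        feats[never], t.loc[never, "age"].to_numpy(), param_grid=grid
    ).fit(seed=seed)
    _, cbag_smoker = res.predict_corrected(
        feats[~never], t.loc[~never, "age"].to_numpy()
    )
    return _assoc.two_sample_comparison(cbag_smoker, res.corrected_bag)


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage on a synthetic cohort; returns the manifest dict.

    All tabular outputs are TSV under ``out_dir``; the manifest records
    each stage's parameters, seed and output files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}}

    def stage(name: str, files: dict, **info):
        log.info("stage %s done: %s", name, info)
        manifest["stages"][name] = {"outputs": files, **info}

    # --- simulate -------------------------------------------------------
    sim: SyntheticCohort = simulate_cohort(config.sim)
    cohort = sim.cohort.table
    sim.genotypes.to_tsv(out / "genotypes.tsv", out / "snps.tsv")
    sim.summary_stats.to_tsv(out / "sumstats.tsv")
    sim.cohort.to_tsv(out / "cohort.tsv")
    stage(
        "simulate",
        {"genotypes": "genotypes.tsv", "sumstats": "sumstats.tsv",
         "cohort": "cohort.tsv"},
        seed=config.sim.seed, n_subjects=config.sim.n_subjects,
        n_snps=config.sim.n_snps,
    )

    # --- QC -------------------------------------------------------------
    geno_qc, report = qc_filter(sim.genotypes, config.qc)
    report.to_json(out / "qc_report.json")
    report.to_tsv(out / "qc_snps.tsv")
    cohort = cohort[cohort["subject"].isin(geno_qc.dosages.index)].reset_index(
        drop=True
    )
    stage(
        "qc", {"report": "qc_report.json", "snp_table": "qc_snps.tsv"},
        n_snps_out=report.n_snps_out, n_samples_out=report.n_samples_out,
    )

    # --- PRS ------------------------------------------------------------
    stats_qc = sim.summary_stats.table[
        sim.summary_stats.table["SNP"].isin(geno_qc.dosages.columns)
    ]
    from .containers import SummaryStats

    sumstats = SummaryStats(stats_qc.reset_index(drop=True))
    index_snps = clump(sumstats, geno_qc, config.clump)
    pd.Series(index_snps, name="SNP").to_csv(
        out / "clumped_snps.tsv", sep="\t", index=False
    )
    prs_res = threshold_scan(
        geno_qc,
        sumstats,
        index_snps,
        grid=config.grid,
        phenotype=cohort["smoker"].to_numpy(float),
        covariates=cohort[config.prs_covariates],
        top_k=config.top_k,
    )
    prs_res.per_threshold.to_csv(out / "prs_thresholds.tsv", sep="\t", index=False)
    cohort = cohort.assign(prs_z=prs_res.zscored_optimal.loc[cohort["subject"]].values)
    with open(out / "prs_result.json", "w") as fh:
        json.dump(prs_res.to_json_dict(), fh, indent=2)
    stage(
        "prs",
        {"clumped": "clumped_snps.tsv", "thresholds": "prs_thresholds.tsv",
         "result": "prs_result.json"},
        n_index_snps=len(index_snps),
        optimal_threshold=prs_res.optimal_threshold,
    )

    # --- brain age ------------------------------------------------------
    region_cols = sim.cohort.region_columns
    feats = residualize(cohort[region_cols], cohort[config.residual_covariates])
    never = cohort["smoking_status"] == "never"
    smoker = ~never
    model = BrainAgeModel(
        feats[never.to_numpy()],
        cohort.loc[never, "age"].to_numpy(),
        n_outer_folds=config.n_outer_folds,
        n_inner_folds=config.n_inner_folds,
        param_grid=config.brainage_param_grid,
    )
    res = model.fit(seed=config.seed + 11)
    cohort["corrected_bag"] = np.nan
    cohort.loc[never, "corrected_bag"] = res.corrected_bag
    pred_s = res.predict(feats[smoker.to_numpy()])
    _, cbag_s = res.predict_corrected(
        feats[smoker.to_numpy()], cohort.loc[smoker, "age"].to_numpy()
    )
    cohort.loc[smoker, "corrected_bag"] = cbag_s
    res.to_frame().to_csv(out / "brainage_train.tsv", sep="\t", index=False)
    m = res.metrics
    with open(out / "brainage_metrics.json", "w") as fh:
        json.dump(
            {
                "train_r": m.pearson_r, "train_r_ci": [m.r_ci_low, m.r_ci_high],
                "train_rmse": m.rmse, "train_mae": m.mae,
                "bias_slope": res.bias.slope, "bias_intercept": res.bias.intercept,
                "smoker_r": float(
                    np.corrcoef(pred_s, cohort.loc[smoker, "age"])[0, 1]
                ),
            },
            fh, indent=2,
        )
    stage(
        "brainage",
        {"train": "brainage_train.tsv", "metrics": "brainage_metrics.json"},
        seed=config.seed + 11, train_r=m.pearson_r, train_mae=m.mae,
    )

    # --- associations (Table-1-style) ----------------------------------
    rows = []
    outcomes = {"corrected_bag": cohort["corrected_bag"], "tgmv": cohort["tgmv"]}
    smokers_only = cohort[smoker.to_numpy()]
    for name, vec in outcomes.items():
        for tag, covs in (
            ("model1", config.model1_covariates),
            ("model2", config.model2_covariates),
        ):
            row = association.glm_association(
                vec, cohort["prs_z"], cohort[covs], outcome_name=name, model_tag=tag
            )
            rows.append(dataclasses.asdict(row))
    for name in ("pack_years", "quit_years"):
        for tag, covs in (
            ("model1", config.model1_covariates),
            ("model2", config.model2_covariates),
        ):
            row = association.glm_association(
                smokers_only[name], smokers_only["prs_z"], smokers_only[covs],
                outcome_name=name, model_tag=tag,
            )
            rows.append(dataclasses.asdict(row))
    assoc_table = pd.DataFrame(rows)
    assoc_table.to_csv(out / "associations.tsv", sep="\t", index=False)

    comp = {
        "bag": dataclasses.asdict(
            association.two_sample_comparison(
                cohort.loc[smoker, "corrected_bag"], cohort.loc[never, "corrected_bag"]
            )
        ),
        "prs": dataclasses.asdict(
            association.two_sample_comparison(
                cohort.loc[smoker, "prs_z"], cohort.loc[never, "prs_z"]
            )
        ),
    }
    with open(out / "comparisons.json", "w") as fh:
        json.dump(comp, fh, indent=2)

    region_scan = association.regionwise_scan(
        cohort["prs_z"], cohort[region_cols], cohort[config.model2_covariates]
    )
    region_scan.to_csv(out / "region_scan.tsv", sep="\t", index=False)

    gwas = association.gwas_scan(
        geno_qc, cohort["corrected_bag"].to_numpy(),
        cohort[config.model2_covariates],
    )
    gwas.table.to_csv(out / "gwas.tsv", sep="\t", index=False)
    stage(
        "association",
        {"table1": "associations.tsv", "comparisons": "comparisons.json",
         "regions": "region_scan.tsv", "gwas": "gwas.tsv"},
        smoker_bag_d=comp["bag"]["cohens_d"], gwas_m=gwas.m,
        genomewide_threshold=gwas.genomewide_threshold,
    )

    # --- mediation ------------------------------------------------------
    med = mediation.MediationModel(
        smokers_only["prs_z"].to_numpy(),
        smokers_only["pack_years"].to_numpy(),
        {
            "corrected_bag": smokers_only["corrected_bag"].to_numpy(),
            "tgmv": smokers_only["tgmv"].to_numpy(),
        },
        covariates=smokers_only[config.model2_covariates],
    ).fit(n_boot=config.n_boot, seed=config.seed + 23)
    with open(out / "mediation.json", "w") as fh:
        json.dump(med.to_json_dict(), fh, indent=2)
    stage(
        "mediation", {"result": "mediation.json"},
        seed=config.seed + 23, pm_percent=med.pm, n=med.n,
    )

    # --- enrichment -----------------------------------------------------
    intervals, sets = simulate_gene_annotation(geno_qc, seed=config.seed + 31)
    used = set()
    for t in prs_res.selected_thresholds:
        used |= set(
            sumstats.table.loc[
                sumstats.table["SNP"].isin(index_snps)
                & (sumstats.table["P"] < prs_res.optimal_threshold),
                "SNP",
            ]
        )
    snp_pos = geno_qc.snps.loc[sorted(used)][["chr", "pos"]]
    query = enrichment.map_snps_to_genes(
        snp_pos, intervals, flank_kb=config.enrichment_flank_kb
    )
    universe = intervals["gene"].tolist()
    collection = enrichment.GeneSetCollection(sets, source="synthetic")
    ora_table = enrichment.ora(query, collection, universe)
    ora_table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    stage(
        "enrichment", {"table": "enrichment.tsv"},
        n_query_genes=len(query), n_terms=len(ora_table),
    )

    cohort.to_csv(out / "cohort_analyzed.tsv", sep="\t", index=False)
    manifest["stages"]["final"] = {"outputs": {"cohort": "cohort_analyzed.tsv"}}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
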