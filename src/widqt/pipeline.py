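"""End-to-end driver: simulate/load -> variability -> train -> score ->
PRS -> stratify -> permute -> evaluate, with a manifest and a single JSON
report of the headline numbers."""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, io, prs, risk_strata, variability
from .config import PipelineConfig
from .permutation import permutation_null
from .qt_index import (compute_index, finalize_index,
                       fit_penalized_classifier, save_index, select_model)
from .synthetic_data import SET_LABELS, CohortConfig, generate_cohort

log = logging.getLogger("widqt")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[widqt:%(stage)s] %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


def _stage(name, msg, *args):
    log.info(msg, *args, extra={"stage": name})


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write manifest, artifacts, and report.

    Returns the report dictionary (also written to out_dir/report.json).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_digest": config.digest(), "seed": config.seed}

    stage = "inputs"
    try:
        if config.simulate:
            _stage(stage, "simulating cohort (seed=%d)", config.seed)
            cohort_cfg = CohortConfig(
                seed=config.seed,
                tissues=tuple(config.cohort.tissues),
                **config.cohort.model_dump(exclude={"tissues"}))
            bundle = generate_cohort(cohort_cfg)
            betas = bundle.betas_by_tissue[config.cohort.tissues[0]]
            phenotypes = bundle.phenotypes
            genotypes = bundle.genotypes
            weights = pd.Series(bundle.truth["prs_weights"])
            mqtl_cpgs = bundle.mqtl_cpgs
            (out / "truth.json").write_text(json.dumps(bundle.truth, indent=2))
        else:
            for key in ("beta_tsv", "genotypes", "phenotypes_csv"):
                path = getattr(config.inputs, key)
                if path and not Path(path).exists():
                    raise FileNotFoundError(f"input {key} not found: {path}")
            betas = io.read_beta_tsv(config.inputs.beta_tsv)
            phenotypes = io.read_phenotypes_csv(config.inputs.phenotypes_csv)
            wtab = io.read_prs_weights(config.inputs.prs_weights_tsv) \
                if config.inputs.prs_weights_tsv else None
            if config.inputs.genotype_format == "vcf":
                genotypes = io.read_vcf_genotypes(config.inputs.genotypes, wtab)
            else:
                genotypes = io.read_dosage_tsv(config.inputs.genotypes)
            weights = (wtab.set_index("snp_id")["weight"]
                       if wtab is not None
                       else pd.Series(1.0, index=genotypes.columns))
            mqtl_cpgs = list(betas.index)

        sets = phenotypes["set"]
        train_ids = phenotypes.index[sets == SET_LABELS[0]]
        internal_ids = phenotypes.index[sets == SET_LABELS[1]]
        validation_ids = phenotypes.index[sets == SET_LABELS[2]]
        discovery_ids = train_ids.union(internal_ids, sort=False)
        labels = phenotypes["case"]

        stage = "variability"
        _stage(stage, "per-CpG SD and immune-fraction stratification")
        var_table = variability.cpg_sd(betas)
        strat = variability.stratified_variability(
            {config.cohort.tissues[0] if config.simulate else "input": betas},
            mqtl_cpgs, phenotypes["immune_fraction"],
            bins=[tuple(b) for b in config.ic_bins])
        strat.to_csv(out / "variability.csv", index=False)
        report["median_sd_all_cpgs"] = float(var_table["sd"].median())

        stage = "train"
        _stage(stage, "training candidates: %s", config.penalties)
        mqtl_train = betas.loc[mqtl_cpgs, train_ids]
        candidates = [
            fit_penalized_classifier(mqtl_train, labels.loc[train_ids],
                                     penalty=pen, k_folds=config.k_folds,
                                     seed=config.seed)
            for pen in config.penalties
        ]
        best = select_model(candidates, betas.loc[mqtl_cpgs, internal_ids],
                            labels.loc[internal_ids])
        report["internal_validation_auc"] = {
            model.penalty: rep.internal_validation_auc
            for model, rep in candidates
        }
        report["selected_penalty"] = best.penalty

        stage = "finalize"
        _stage(stage, "refitting %s on the full discovery set", best.penalty)
        model, _ = finalize_index(best.penalty,
                                  betas.loc[mqtl_cpgs, discovery_ids],
                                  labels.loc[discovery_ids],
                                  k_folds=config.k_folds, seed=config.seed)
        save_index(model, out / "index_weights.tsv", out / "index_scaling.json")
        report["n_nonzero_cpgs"] = model.n_nonzero

        stage = "score"
        index_scores = compute_index(betas.loc[mqtl_cpgs], model)
        index_scores.to_frame().to_csv(out / "index_scores.csv")

        stage = "prs"
        _stage(stage, "genotype QC and PRS")
        geno_qc, qc_report = prs.qc_filter(genotypes)
        qc_report.to_csv(out / "qc_report.csv", index=False)
        prs_scores, prs_report = prs.compute_prs(geno_qc, weights)
        prs_scores.to_frame().to_csv(out / "prs_scores.csv")
        report["prs"] = prs_report

        stage = "stratify"
        tables = {}
        for set_name, ids in (("discovery", discovery_ids),
                              ("validation", validation_ids)):
            ids = ids.intersection(prs_scores.index)
            groups = risk_strata.combine_groups(
                risk_strata.median_split(prs_scores.loc[ids]),
                risk_strata.median_split(index_scores.loc[ids]))
            table = risk_strata.risk_table(groups, labels.loc[ids])
            table.to_csv(out / f"risk_table_{set_name}.csv")
            tables[set_name] = json.loads(table.to_json(orient="index"))
        report["risk_tables"] = tables

        stage = "evaluate"
        val_scores = index_scores.loc[validation_ids]
        val_labels = labels.loc[validation_ids]
        roc = evaluation.roc_auc(val_scores, val_labels)
        report["validation_auc"] = {"auc": roc.auc, "ci_low": roc.ci_low,
                                    "ci_high": roc.ci_high}
        report["validation_case_control_p"] = evaluation.group_difference_test(
            val_scores[val_labels == 1], val_scores[val_labels == 0])
        assoc = evaluation.covariate_association(
            val_scores, phenotypes.loc[validation_ids, "age"],
            val_labels.map({0: "control", 1: "case"}))
        report["age_association"] = json.loads(assoc.to_json(orient="index"))

        if config.n_perm > 0:
            stage = "permute"
            _stage(stage, "permutation null (n_perm=%d)", config.n_perm)
            perm = permutation_null(
                betas, mqtl_cpgs, labels, train_ids, validation_ids,
                n_perm=config.n_perm, n_cpgs=config.n_perm_cpgs,
                k_folds=config.k_folds, seed=config.seed)
            pd.Series(perm.aucs, name="auc").to_csv(out / "permutation_aucs.csv",
                                                    index=False)
            report["permutation"] = perm.summary()
    except Exception as err:      # noqa: BLE001 - stage context is the point
        raise StageError(stage, err) from err

    manifest = {
        "config": config.model_dump(),
        "config_digest": config.digest(),
        "seed": config.seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    (out / "report.json").write_text(json.dumps(report, indent=2,
                                                sort_keys=True))
    return report
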