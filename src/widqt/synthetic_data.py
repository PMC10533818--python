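"""Synthetic cohorts with genotype-coupled methylation.

The generator emulates the statistical structure the downstream analysis
relies on: per-SNP effect-allele dosages drawn under Hardy-Weinberg
proportions; CpG methylation driven on the logit scale by mQTL genotype
effects, case status, and centred age/BMI covariates, with additive
Gaussian noise; and bulk-sample cell-type mixing, where the observed beta
is a convex combination of an epithelial and an immune methylation state
weighted by the subject's immune-cell fraction. Cohorts carry disjoint
discovery-train / discovery-internal-validation / validation assignments.

A logit-normal epithelial signal mixed linearly on the beta scale keeps
every generated value inside [0, 1] without truncation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "SNPSpec", "MQTLPair", "TissueProfile", "EffectConfig", "CohortConfig",
    "CohortBundle", "generate_genotypes", "generate_methylation",
    "generate_cohort", "SET_LABELS",
]

SET_LABELS = ("discovery-train", "discovery-internal-validation", "validation")


@dataclass(frozen=True)
class SNPSpec:
    """A biallelic SNP: effect-allele frequency and PRS log-OR weight."""

    snp_id: str
    maf: float
    prs_weight: float = 0.0

    def __post_init__(self):
        if not 0 <= self.maf <= 1:
            raise ValueError(f"maf must lie in [0, 1], got {self.maf}")
        if not np.isfinite(self.prs_weight):
            raise ValueError("prs_weight must be finite")


@dataclass(frozen=True)
class MQTLPair:
    """SNP -> CpG link with a per-allele shift on the logit-methylation scale."""

    snp_id: str
    cpg_id: str
    effect: float


@dataclass
class TissueProfile:
    """Per-tissue epithelial/immune baselines and residual logit noise."""

    tissue_name: str
    baseline_logit: pd.Series        # per-CpG epithelial baseline
    immune_baseline_logit: pd.Series
    noise_sd: float = 0.5

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class EffectConfig:
    """Per-CpG effects of case status and centred covariates (logit scale)."""

    case_effect: pd.Series
    age_effect: pd.Series
    bmi_effect: pd.Series


@dataclass
class CohortConfig:
    """Study-design knobs for :func:`generate_cohort`.

    Defaults give a desk-scale mirror of the real design: 50 PRS SNPs with
    mQTL links to 120 CpGs embedded among 880 unlinked CpGs, and
    600/300/300 subjects in the discovery-train / internal-validation /
    validation sets with ~35% cases.
    """

    n_train: int = 600
    n_internal: int = 300
    n_validation: int = 300
    n_snps: int = 50
    n_mqtl_cpgs: int = 120
    n_background_cpgs: int = 880
    case_fraction: float = 0.35
    mqtl_effect: float = 0.5
    case_effect: float = 0.1
    n_case_cpgs: int = 30
    age_effect: float = 0.01
    bmi_effect: float = 0.01
    noise_sd: float = 0.5
    immune_alpha: float = 1.5
    immune_beta: float = 4.5
    tissues: tuple[str, ...] = ("cervical",)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_train, self.n_internal, self.n_validation) < 0:
            raise ValueError("set sizes must be non-negative")
        if not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must lie in (0, 1)")
        if self.n_case_cpgs > self.n_mqtl_cpgs:
            raise ValueError("n_case_cpgs cannot exceed n_mqtl_cpgs")


@dataclass
class CohortBundle:
    """Everything the pipeline consumes, plus the generating truth."""

    genotypes: pd.DataFrame                  # subjects x SNPs dosages
    betas_by_tissue: dict[str, pd.DataFrame]  # tissue -> CpGs x subjects
    phenotypes: pd.DataFrame
    snps: list[SNPSpec]
    mqtl_map: list[MQTLPair]
    truth: dict

    @property
    def mqtl_cpgs(self) -> list[str]:
        seen = dict.fromkeys(p.cpg_id for p in self.mqtl_map)
        return list(seen)


def generate_genotypes(n_subjects: int, snps: list[SNPSpec],
                       seed) -> pd.DataFrame:
    """Draw effect-allele dosages as independent Binomial(2, maf) per SNP."""
    if n_subjects < 0:
        raise ValueError("n_subjects must be non-negative")
    rng = np.random.default_rng(seed)
    subject_ids = [f"S{i:05d}" for i in range(n_subjects)]
    data = {
        s.snp_id: rng.binomial(2, s.maf, size=n_subjects).astype(float)
        for s in snps
    }
    return pd.DataFrame(data, index=subject_ids, dtype=float)


def generate_methylation(genotypes: pd.DataFrame,
                         mqtl_map: list[MQTLPair],
                         phenotypes: pd.DataFrame,
                         tissue: TissueProfile,
                         effects: EffectConfig,
                         seed) -> pd.DataFrame:
    """Simulate a CpGs x subjects beta matrix for one tissue.

    Epithelial logit-methylation for subject j at CpG i is

        baseline_i + sum_mQTL effect * dosage_j + case_effect_i * case_j
        + age_effect_i * (age_j - mean age) + bmi_effect_i * (bmi_j - mean)
        + Normal(0, noise_sd)

    and the observed beta mixes the epithelial and immune states by the
    subject's immune fraction f_j:

        beta_ij = (1 - f_j) * expit(logit_ij) + f_j * expit(immune_baseline_i)
    """
    rng = np.random.default_rng(seed)
    cpg_ids = tissue.baseline_logit.index
    subjects = phenotypes.index
    n_cpg, n_sub = len(cpg_ids), len(subjects)
    cpg_pos = {c: k for k, c in enumerate(cpg_ids)}

    logit = np.tile(tissue.baseline_logit.to_numpy(float)[:, None], (1, n_sub))
    dosages = genotypes.reindex(subjects)
    for pair in mqtl_map:
        if pair.snp_id not in dosages.columns:
            raise KeyError(f"mQTL map references unknown SNP {pair.snp_id!r}")
        logit[cpg_pos[pair.cpg_id]] += pair.effect * dosages[pair.snp_id].to_numpy(float)

    case = phenotypes["case"].to_numpy(float)
    age_c = phenotypes["age"].to_numpy(float) - phenotypes["age"].mean()
    bmi_c = phenotypes["bmi"].to_numpy(float) - phenotypes["bmi"].mean()
    logit += np.outer(effects.case_effect.reindex(cpg_ids, fill_value=0.0), case)
    logit += np.outer(effects.age_effect.reindex(cpg_ids, fill_value=0.0), age_c)
    logit += np.outer(effects.bmi_effect.reindex(cpg_ids, fill_value=0.0), bmi_c)
    logit += rng.normal(0.0, tissue.noise_sd, size=(n_cpg, n_sub))

    f = phenotypes["immune_fraction"].to_numpy(float)[None, :]
    immune = expit(tissue.immune_baseline_logit.to_numpy(float))[:, None]
    betas = (1.0 - f) * expit(logit) + f * immune
    return pd.DataFrame(betas, index=cpg_ids, columns=subjects)


def _default_effects(cpg_ids, mqtl_cpgs, config: CohortConfig,
                     rng) -> EffectConfig:
    case = pd.Series(0.0, index=cpg_ids)
    affected = list(mqtl_cpgs)[: config.n_case_cpgs]
    signs = rng.choice([-1.0, 1.0], size=len(affected))
    case.loc[affected] = config.case_effect * signs
    age = pd.Series(rng.normal(0.0, config.age_effect, size=len(cpg_ids)),
                    index=cpg_ids)
    bmi = pd.Series(rng.normal(0.0, config.bmi_effect, size=len(cpg_ids)),
                    index=cpg_ids)
    return EffectConfig(case_effect=case, age_effect=age, bmi_effect=bmi)


def generate_cohort(config: CohortConfig | None = None) -> CohortBundle:
    """Generate a full cohort bundle under the configured study design.

    One global seed is expanded into independent per-stage streams
    (panel, genotypes, phenotypes, per-tissue methylation) so that each
    stage is reproducible on its own.
    """
    config = config or CohortConfig()
    root = np.random.SeedSequence(config.seed)
    seed_panel, seed_geno, seed_pheno, seed_meth = root.spawn(4)
    rng_panel = np.random.default_rng(seed_panel)

    snps = [
        SNPSpec(snp_id=f"rs{i:06d}",
                maf=float(rng_panel.uniform(0.1, 0.5)),
                prs_weight=float(rng_panel.normal(0.0, 0.1)))
        for i in range(config.n_snps)
    ]
    mqtl_cpgs = [f"cg_mqtl_{i:05d}" for i in range(config.n_mqtl_cpgs)]
    bg_cpgs = [f"cg_bg_{i:05d}" for i in range(config.n_background_cpgs)]
    cpg_ids = pd.Index(mqtl_cpgs + bg_cpgs)
    mqtl_map = [
        MQTLPair(snp_id=snps[i % config.n_snps].snp_id, cpg_id=cpg,
                 effect=float(config.mqtl_effect * rng_panel.choice([-1.0, 1.0])))
        for i, cpg in enumerate(mqtl_cpgs)
    ]

    sizes = (config.n_train, config.n_internal, config.n_validation)
    n_total = sum(sizes)
    genotypes = generate_genotypes(n_total, snps, seed_geno)
    subjects = genotypes.index

    rng_ph = np.random.default_rng(seed_pheno)
    set_label = np.repeat(SET_LABELS, sizes)
    case = np.zeros(n_total, dtype=int)
    start = 0
    for n_set in sizes:                       # stratify cases within each set
        n_cases = int(round(config.case_fraction * n_set))
        idx = start + rng_ph.permutation(n_set)[:n_cases]
        case[idx] = 1
        start += n_set
    phenotypes = pd.DataFrame({
        "case": case,
        "age": rng_ph.normal(55.0, 8.0, n_total).clip(25, 85),
        "bmi": rng_ph.normal(26.0, 4.5, n_total).clip(16, 45),
        "immune_fraction": rng_ph.beta(config.immune_alpha, config.immune_beta,
                                       n_total),
        "set": set_label,
    }, index=subjects)

    effects = _default_effects(cpg_ids, mqtl_cpgs, config, rng_panel)
    betas_by_tissue = {}
    meth_children = seed_meth.spawn(len(config.tissues))
    for tissue_name, child in zip(config.tissues, meth_children):
        profile = TissueProfile(
            tissue_name=tissue_name,
            baseline_logit=pd.Series(
                rng_panel.normal(0.0, 1.2, len(cpg_ids)), index=cpg_ids),
            immune_baseline_logit=pd.Series(
                rng_panel.normal(0.0, 1.2, len(cpg_ids)), index=cpg_ids),
            noise_sd=config.noise_sd,
        )
        betas_by_tissue[tissue_name] = generate_methylation(
            genotypes, mqtl_map, phenotypes, profile, effects, child)

    truth = {
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(config).items()},
        "case_effect_cpgs": effects.case_effect[
            effects.case_effect != 0].to_dict(),
        "mqtl_effects": {f"{p.snp_id}:{p.cpg_id}": p.effect for p in mqtl_map},
        "prs_weights": {s.snp_id: s.prs_weight for s in snps},
        "mafs": {s.snp_id: s.maf for s in snps},
    }
    return CohortBundle(genotypes=genotypes, betas_by_tissue=betas_by_tissue,
                        phenotypes=phenotypes, snps=snps, mqtl_map=mqtl_map,
                        truth=truth)
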