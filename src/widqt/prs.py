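"""Genotype QC and polygenic risk score computation.

Genotypes are held as a subjects x SNPs DataFrame of effect-allele dosages
in {0, 1, 2} with NaN marking missing calls. QC mirrors standard
array-genotyping practice: subjects below a call-rate floor are dropped
first, then SNPs failing missing-rate, minor-allele-frequency, or exact
Hardy-Weinberg filters. The PRS for subject j is sum_i beta_i * x_ij over
the published log-odds-ratio weights, with missing dosages imputed at
twice the cohort effect-allele frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = ["QCThresholds", "hwe_exact_test", "qc_filter", "compute_prs"]


@dataclass(frozen=True)
class QCThresholds:
    """SNP/subject exclusion thresholds for genotype QC."""

    max_missing_rate: float = 0.05
    min_maf: float = 0.01
    hwe_alpha: float = 5e-6
    min_subject_call_rate: float = 0.95

    def __post_init__(self):
        for name in ("max_missing_rate", "min_maf", "hwe_alpha",
                     "min_subject_call_rate"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg test by heterozygote enumeration.

    Conditions on the observed allele counts and enumerates every
    heterozygote count of matching parity; the p-value sums the
    probabilities of all configurations no more likely than the observed
    one (probability-mass ordering).
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 or c != int(c) for c in counts):
        raise ValueError("genotype counts must be non-negative integers")
    n_hom_ref, n_het, n_hom_alt = (int(c) for c in counts)
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("at least one genotyped subject is required")

    n_alt = 2 * n_hom_alt + n_het          # minor-or-not does not matter:
    n_ref = 2 * n_hom_ref + n_het          # the law is symmetric in alleles
    rare = min(n_ref, n_alt)
    if rare == 0:
        return 1.0

    # P(het = h | allele counts) ∝ 2^h / (hom_ref! h! hom_alt!) with
    # hom_ref = (n_ref - h)/2 and hom_alt = (n_alt - h)/2; h must share the
    # parity of the allele counts
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_alt = (n_alt - hets) // 2
    hom_ref = (n_ref - hets) // 2
    logp = (hets * np.log(2.0) - gammaln(hom_ref + 1) - gammaln(hets + 1)
            - gammaln(hom_alt + 1))
    logp -= np.max(logp)
    probs = np.exp(logp)
    probs /= probs.sum()
    observed = probs[hets == n_het][0]
    return float(min(1.0, probs[probs <= observed * (1 + 1e-12)].sum()))


def _genotype_counts(dosages: pd.Series) -> tuple[int, int, int]:
    obs = dosages.dropna().round().astype(int)
    return int((obs == 0).sum()), int((obs == 1).sum()), int((obs == 2).sum())


def qc_filter(genotypes: pd.DataFrame,
              thresholds: QCThresholds | None = None
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply subject call-rate then SNP-level QC filters.

    Returns the filtered genotype matrix and a report DataFrame with one
    row per exclusion (``kind``, ``id``, ``reason``, ``value``). Subjects
    are filtered before SNP statistics are computed, matching the usual
    sample-first QC ordering.
    """
    thresholds = thresholds or QCThresholds()
    report = []

    call_rate = genotypes.notna().mean(axis=1)
    bad_subjects = call_rate[call_rate < thresholds.min_subject_call_rate]
    for sid, cr in bad_subjects.items():
        report.append(("subject", sid, "call_rate", float(cr)))
    kept = genotypes.drop(index=bad_subjects.index)

    drop_snps = []
    for snp in kept.columns:
        col = kept[snp]
        miss = float(col.isna().mean()) if len(col) else 1.0
        if miss > thresholds.max_missing_rate:
            report.append(("snp", snp, "missing_rate", miss))
            drop_snps.append(snp)
            continue
        obs = col.dropna()
        af = float(obs.mean() / 2.0) if len(obs) else 0.0
        maf = min(af, 1.0 - af)
        if maf < thresholds.min_maf:
            report.append(("snp", snp, "maf", maf))
            drop_snps.append(snp)
            continue
        if len(obs):
            p_hwe = hwe_exact_test(*_genotype_counts(col))
            if p_hwe < thresholds.hwe_alpha:
                report.append(("snp", snp, "hwe", p_hwe))
                drop_snps.append(snp)
    kept = kept.drop(columns=drop_snps)
    report_df = pd.DataFrame(report, columns=["kind", "id", "reason", "value"])
    return kept, report_df


def compute_prs(genotypes: pd.DataFrame, weights) -> tuple[pd.Series, dict]:
    """Polygenic risk score: weighted sum of effect-allele dosages.

    ``weights`` maps snp_id -> log odds ratio (a mapping, a Series, or a
    sequence of objects with ``snp_id``/``prs_weight`` attributes). Only
    SNPs present in both the weight table and the genotype matrix
    contribute; missing dosages are imputed as 2 x the cohort
    effect-allele frequency at that SNP. Returns the per-subject scores
    and a report of SNP overlap.
    """
    if isinstance(weights, pd.Series):
        wmap = weights.astype(float)
    elif isinstance(weights, dict):
        wmap = pd.Series(weights, dtype=float)
    else:
        wmap = pd.Series({s.snp_id: float(s.prs_weight) for s in weights})
    shared = [s for s in wmap.index if s in genotypes.columns]
    if not shared:
        raise ValueError("no overlap between weight SNPs and genotyped SNPs")

    dos = genotypes[shared].astype(float)
    af = dos.mean(axis=0, skipna=True) / 2.0
    filled = dos.fillna(2.0 * af)
    scores = filled.mul(wmap[shared], axis=1).sum(axis=1)
    scores.name = "prs"
    report = {
        "n_weight_snps": int(len(wmap)),
        "n_genotyped_snps": int(genotypes.shape[1]),
        "n_used": len(shared),
        "n_missing_imputed": int(dos.isna().to_numpy().sum()),
    }
    return scores, report
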