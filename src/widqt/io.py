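"""Readers and writers for the pipeline's tabular formats.

Beta matrices travel as TSV with CpGs in rows and a header row of sample
IDs; genotypes as either a dosage TSV (subjects in rows, SNPs in columns)
or a VCF with GT calls; phenotypes as CSV indexed by subject; PRS weights
as a TSV with columns snp_id, effect_allele, other_allele, weight.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_beta_tsv", "write_beta_tsv", "read_dosage_tsv", "write_dosage_tsv",
    "read_phenotypes_csv", "write_phenotypes_csv", "read_prs_weights",
    "read_vcf_genotypes", "write_vcf",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def read_beta_tsv(path) -> pd.DataFrame:
    betas = pd.read_csv(path, sep="\t", index_col=0)
    if ((betas < 0) | (betas > 1)).any().any():
        raise ValueError(f"{path}: beta values must lie in [0, 1]")
    return betas


def write_beta_tsv(betas: pd.DataFrame, path) -> None:
    betas.to_csv(path, sep="\t", index_label="cpg_id")


def read_dosage_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0).astype(float)


def write_dosage_tsv(genotypes: pd.DataFrame, path) -> None:
    genotypes.to_csv(path, sep="\t", index_label="subject_id")


def read_phenotypes_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_phenotypes_csv(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, index_label="subject_id")


def read_prs_weights(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    required = {"snp_id", "effect_allele", "weight"}
    if not required.issubset(tab.columns):
        raise ValueError(f"{path}: weight table needs columns {sorted(required)}")
    return tab


def read_vcf_genotypes(path, weights: pd.DataFrame | None = None
                       ) -> pd.DataFrame:
    """Read effect-allele dosages from a VCF (GT field).

    Without a weight table, dosages count the ALT allele. With one, each
    variant is harmonized to the table's effect allele: dosages are
    flipped when the effect allele is REF, strand-complemented matches
    are accepted, and strand-ambiguous A/T / C/G SNPs are used as-is
    with a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    wmeta = None
    if weights is not None:
        wmeta = weights.set_index("snp_id")
    data = {}
    for variant in vcf:
        vid = variant.ID
        if vid is None or (wmeta is not None and vid not in wmeta.index):
            continue
        if len(variant.ALT) != 1:
            warnings.warn(f"{vid}: multi-allelic variant skipped")
            continue
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = np.asarray(variant.gt_types, dtype=float)
        dos = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], np.nan)
        if wmeta is not None:
            dos = _harmonize(vid, variant.REF, variant.ALT[0],
                             str(wmeta.loc[vid, "effect_allele"]),
                             str(wmeta.loc[vid].get("other_allele", "")),
                             dos)
            if dos is None:
                continue
        data[vid] = dos
    return pd.DataFrame(data, index=samples)


def _harmonize(vid, ref, alt, effect, other, dos):
    ref, alt, effect = ref.upper(), alt.upper(), effect.upper()
    other = other.upper()
    ambiguous = _COMPLEMENT.get(ref) == alt
    if ambiguous:
        warnings.warn(f"{vid}: strand-ambiguous {ref}/{alt} SNP used as-is")
    if effect == alt and (not other or other == ref):
        return dos
    if effect == ref and (not other or other == alt):
        return 2.0 - dos
    if not ambiguous:
        c_eff = _COMPLEMENT.get(effect, "?")
        c_oth = _COMPLEMENT.get(other, "") if other else ""
        if c_eff == alt and (not c_oth or c_oth == ref):
            return dos
        if c_eff == ref and (not c_oth or c_oth == alt):
            return 2.0 - dos
    warnings.warn(f"{vid}: alleles {effect}/{other or '?'} do not match "
                  f"VCF {ref}/{alt}; variant skipped")
    return None


def write_vcf(genotypes: pd.DataFrame, path, ref: str = "A",
              alt: str = "G") -> None:
    """Write dosages as a minimal single-ALT VCF with GT genotypes.

    Missing dosages become ./. calls; chromosome and position are
    synthetic placeholders (one variant per position on chr1).
    """
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
             + "\t".join(genotypes.index)]
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    for pos, snp in enumerate(genotypes.columns, start=1):
        calls = [gt_map.get(int(d), "./.") if not np.isnan(d) else "./."
                 for d in genotypes[snp].to_numpy(float)]
        lines.append(f"1\t{pos}\t{snp}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                     + "\t".join(calls))
    Path(path).write_text("\n".join(lines) + "\n")
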