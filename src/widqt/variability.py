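"""Per-CpG variability and surrogate-tissue comparisons.

The premise: CpGs that vary across the tissue at cancer risk carry
information, and a good surrogate tissue is one where those same CpGs
remain variable. Variability is summarized as the per-CpG sample SD of
beta values; comparisons stratify surrogate samples by immune-cell
fraction, since cell-type mixing with an invariant immune compartment
attenuates epithelial variability roughly by (1 - immune fraction).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = ["cpg_sd", "top_variable", "stratified_variability",
           "DEFAULT_IC_BINS"]

DEFAULT_IC_BINS = ((0.0, 0.25), (0.25, 0.75), (0.75, 1.0))


def cpg_sd(betas: pd.DataFrame) -> pd.DataFrame:
    """Unbiased (n-1) standard deviation of each CpG across samples."""
    if betas.shape[1] < 2:
        raise ValueError("at least 2 samples are required to estimate SD")
    sd = betas.std(axis=1, ddof=1)
    return pd.DataFrame({"cpg_id": betas.index, "sd": sd.to_numpy()}
                        ).set_index("cpg_id")


def top_variable(var_table: pd.DataFrame, percentile: float) -> list[str]:
    """The ceil(percentile% of CpGs) most variable CpGs.

    Ties in SD break lexicographically on cpg_id for determinism.
    """
    if not 0 < percentile <= 100:
        raise ValueError("percentile must lie in (0, 100]")
    if var_table.empty:
        raise ValueError("variability table is empty")
    n = math.ceil(percentile / 100.0 * len(var_table))
    ordered = (var_table.assign(_cpg=var_table.index.astype(str))
               .sort_values(["sd", "_cpg"], ascending=[False, True]))
    return list(ordered.index[:n])


def _bin_label(lo: float, hi: float) -> str:
    return f"[{lo:g},{hi:g})"


def stratified_variability(betas_by_tissue: dict[str, pd.DataFrame],
                           cpg_set, immune_fractions,
                           bins=DEFAULT_IC_BINS) -> pd.DataFrame:
    """Summaries of CpG-set variability per tissue and immune-fraction bin.

    For each tissue and each immune-fraction bin, reports the median SD,
    interquartile range, and sample count over ``cpg_set`` plus a
    reference row over all CpGs. Bins must tile [0, 1] without overlap;
    an empty bin yields a row with n=0 and NaN summaries. An "all" bin
    covering every sample is always included.
    """
    bins = [tuple(b) for b in bins]
    edges = sorted(bins)
    for (lo1, hi1), (lo2, _) in zip(edges, edges[1:]):
        if hi1 != lo2:
            raise ValueError("immune-fraction bins must tile [0,1] "
                             "without gaps or overlap")
    if edges[0][0] != 0.0 or edges[-1][1] != 1.0:
        raise ValueError("immune-fraction bins must cover [0, 1]")
    immune_fractions = pd.Series(immune_fractions, dtype=float)
    cpg_set = list(cpg_set)

    rows = []
    for tissue, betas in betas_by_tissue.items():
        f = immune_fractions.reindex(betas.columns)
        bin_masks = [("all", pd.Series(True, index=betas.columns))]
        for k, (lo, hi) in enumerate(bins):
            upper_closed = hi >= 1.0         # last bin includes f == 1
            mask = (f >= lo) & ((f <= hi) if upper_closed else (f < hi))
            bin_masks.append((_bin_label(lo, hi), mask))
        for label, mask in bin_masks:
            cols = betas.columns[mask.to_numpy(bool)]
            for set_name, cpgs in (("selected", cpg_set),
                                   ("all_cpgs", list(betas.index))):
                present = [c for c in cpgs if c in betas.index]
                if len(cols) < 2:
                    rows.append((tissue, label, set_name, len(cols),
                                 np.nan, np.nan, np.nan))
                    continue
                sd = betas.loc[present, cols].std(axis=1, ddof=1)
                rows.append((tissue, label, set_name, len(cols),
                             float(sd.median()),
                             float(sd.quantile(0.25)),
                             float(sd.quantile(0.75))))
    return pd.DataFrame(rows, columns=[
        "tissue", "ic_bin", "cpg_set", "n", "median_sd", "q25_sd", "q75_sd"])
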