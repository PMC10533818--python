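"""Published case/control counts for the combined risk groups.

These are the 2x2-derivable counts reported by the source case-control
study for the four PRS x methylation-index risk groups, in the discovery
and validation sets, together with the odds ratios the study printed for
them. They serve as a deterministic benchmark: feeding the counts through
:func:`widqt.risk_strata.median_unbiased_or` should recover the printed
odds ratios and confidence limits.
"""

from __future__ import annotations

import pandas as pd

from .risk_strata import GROUP_LABELS, REFERENCE_GROUP, median_unbiased_or

__all__ = ["DISCOVERY_COUNTS", "VALIDATION_COUNTS", "PUBLISHED_ORS",
           "reproduce_published_tables"]

# group -> (cases, controls); groups are "<PRS>/<index>"
DISCOVERY_COUNTS = {
    "low/low": (16, 301),
    "high/low": (23, 221),
    "low/high": (89, 155),
    "high/high": (184, 132),
}
VALIDATION_COUNTS = {
    "low/low": (14, 70),
    "high/low": (18, 59),
    "low/high": (24, 53),
    "high/high": (55, 28),
}
# group -> (odds ratio, ci_low, ci_high) as printed
PUBLISHED_ORS = {
    "discovery": {
        "high/low": (1.9, 1.0, 3.9),
        "low/high": (11.0, 6.2, 19.0),
        "high/high": (26.0, 15.0, 47.0),
    },
    "validation": {
        "high/low": (1.5, 0.69, 3.4),
        "low/high": (2.2, 1.1, 4.9),
        "high/high": (9.6, 4.7, 21.0),
    },
}


def _table_from_counts(counts: dict, published: dict) -> pd.DataFrame:
    for group, pair in counts.items():
        if len(pair) != 2 or any(v < 0 or v != int(v) for v in pair):
            raise ValueError(f"counts for {group!r} must be a pair of "
                             "non-negative integers")
    if REFERENCE_GROUP not in counts:
        raise ValueError(f"counts must include the {REFERENCE_GROUP!r} group")
    c, d = counts[REFERENCE_GROUP]
    rows = []
    for group in GROUP_LABELS:
        if group not in counts:
            continue
        a, b = counts[group]
        if group == REFERENCE_GROUP:
            rows.append((group, a, b, 1.0, None, None, None, None, None, None))
            continue
        res = median_unbiased_or(a, b, c, d)
        pub = published.get(group, (None, None, None))
        rows.append((group, a, b, res.or_hat, res.ci_low, res.ci_high, res.p,
                     *pub))
    return pd.DataFrame(rows, columns=[
        "group", "cases", "controls", "or_hat", "ci_low", "ci_high", "p",
        "published_or", "published_ci_low", "published_ci_high",
    ]).set_index("group")


def reproduce_published_tables(discovery_counts: dict | None = None,
                               validation_counts: dict | None = None
                               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Recompute the published risk-group odds ratios from their counts.

    Returns (discovery, validation) tables with the recomputed
    median-unbiased estimates side by side with the printed values.
    """
    disc = _table_from_counts(discovery_counts or DISCOVERY_COUNTS,
                              PUBLISHED_ORS["discovery"])
    val = _table_from_counts(validation_counts or VALIDATION_COUNTS,
                             PUBLISHED_ORS["validation"])
    return disc, val
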