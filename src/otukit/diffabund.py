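"""Genus-level aggregation and between-group differential abundance.

OTU counts are summed over their genus-level assignment (or deepest
resolved rank when genus is unresolved), converted to relative abundances,
and compared between two sample groups with per-genus two-sided rank-sum
tests under Benjamini-Hochberg control of the false discovery rate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._stats import benjamini_hochberg, ranksum_test
from .core_io import AnalysisConfig, CountTable, TaxonomyTable

__all__ = [
    "aggregate_by_genus",
    "relative_abundance",
    "group_difference_test",
    "top_genera",
]


def aggregate_by_genus(table: CountTable, tax: TaxonomyTable) -> CountTable:
    """Sum OTU counts into genus-level (or deepest-resolved-rank) labels.

    Column sums are conserved exactly; OTUs without a taxonomy entry are
    pooled under ``Unclassified``.  Labels are ordered by first appearance.
    """
    labels = [tax.genus_label(o) for o in table.otu_ids]
    order: list[str] = []
    index: dict[str, int] = {}
    for lab in labels:
        if lab not in index:
            index[lab] = len(order)
            order.append(lab)
    agg = np.zeros((len(order), table.n_samples), dtype=np.int64)
    for i, lab in enumerate(labels):
        agg[index[lab]] += table.counts[i]
    return CountTable(tuple(order), table.sample_ids, agg)


def relative_abundance(table: CountTable) -> pd.DataFrame:
    """Column-normalized fractions (taxa x samples); columns sum to 1."""
    totals = table.counts.sum(axis=0).astype(float)
    if (totals == 0).any():
        bad = table.sample_ids[int(np.argmax(totals == 0))]
        raise ValueError(f"sample {bad!r} has zero total count")
    return pd.DataFrame(
        table.counts / totals, index=list(table.otu_ids), columns=list(table.sample_ids)
    )


def group_difference_test(
    relabund: pd.DataFrame,
    group1,
    group2,
    cfg: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Per-taxon rank-sum test of relative abundance between two groups.

    Taxa absent from every sample of both groups are excluded (noted in the
    ``note`` column of the output would be pointless — they are simply not
    testable); p-values are Benjamini-Hochberg adjusted across the tested
    taxa and the result is sorted by adjusted then raw p.
    """
    cfg = cfg or AnalysisConfig()
    group1, group2 = list(group1), list(group2)
    if len(group1) < 2 or len(group2) < 2:
        raise ValueError("both groups need at least 2 samples")
    sub1 = relabund[group1].to_numpy()
    sub2 = relabund[group2].to_numpy()
    rows = []
    for i, taxon in enumerate(relabund.index):
        a, b = sub1[i], sub2[i]
        if a.max() == 0 and b.max() == 0:
            continue
        stat, p = ranksum_test(a, b)
        med1, med2 = float(np.median(a)), float(np.median(b))
        rows.append(
            {
                "taxon": taxon,
                "median_group1": med1,
                "median_group2": med2,
                "direction": int(np.sign(med1 - med2)),
                "statistic": stat,
                "raw_p": p,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df.assign(adjusted_p=[], significant=[])
    df["adjusted_p"] = benjamini_hochberg(df["raw_p"].to_numpy())
    df["significant"] = df["adjusted_p"] < cfg.alpha_level
    return df.sort_values(
        ["adjusted_p", "raw_p", "taxon"], kind="mergesort"
    ).reset_index(drop=True)


def top_genera(relabund: pd.DataFrame, k: int) -> pd.DataFrame:
    """Top-k taxa by mean relative abundance across samples.

    Ties break lexicographically; the remainder is pooled as ``Other`` with
    its aggregate mean abundance.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    means = relabund.mean(axis=1)
    ranked = means.to_frame("mean_relabund").reset_index(names="taxon")
    ranked = ranked.sort_values(
        ["mean_relabund", "taxon"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    top = ranked.head(k).copy()
    rest = ranked.iloc[k:]
    if not rest.empty:
        top = pd.concat(
            [
                top,
                pd.DataFrame(
                    [{"taxon": "Other", "mean_relabund": rest["mean_relabund"].sum()}]
                ),
            ],
            ignore_index=True,
        )
    top["rank"] = np.arange(1, len(top) + 1)
    return top
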