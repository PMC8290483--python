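"""Within-sample diversity: rarefaction, observed richness, Shannon index,
and per-age-bin comparison against an adult reference bin.

Counts are subsampled without replacement to a common depth before
computing richness and Shannon diversity (natural-log units), then each age
bin is compared to the adult reference (mothers of one-month-olds) with a
two-sided rank-sum test, Bonferroni-adjusted across bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import bonferroni, ranksum_test
from .core_io import AnalysisConfig, CountTable, SampleMetadata

__all__ = [
    "BinTestResult",
    "rarefy",
    "shannon",
    "observed_richness",
    "alpha_table",
    "compare_bins_to_reference",
]


@dataclass(frozen=True)
class BinTestResult:
    age_bin: str
    n_bin: int
    n_reference: int
    statistic: float
    raw_p: float
    adjusted_p: float
    significant: bool


def rarefy(
    table: CountTable, depth: int, seed: int
) -> tuple[CountTable, list[str]]:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are excluded and returned as the
    second element.  Deterministic given ``seed`` (each draw is an exact
    multivariate hypergeometric sample).
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=0)
    keep, excluded = [], []
    for j, sid in enumerate(table.sample_ids):
        (keep if totals[j] >= depth else excluded).append((j, sid))
    if not keep:
        raise ValueError(f"no samples reach rarefaction depth {depth}")
    cols = []
    for j, sid in keep:
        col = table.counts[:, j]
        if totals[j] == depth:
            cols.append(col.copy())
        else:
            cols.append(rng.multivariate_hypergeometric(col, depth))
    out = CountTable(
        table.otu_ids,
        tuple(sid for _, sid in keep),
        np.column_stack(cols).astype(np.int64),
    )
    return out, [sid for _, sid in excluded]


def shannon(counts) -> float:
    """Shannon diversity H = -sum p_i ln p_i over taxa with positive counts."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("shannon requires at least one positive count")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def observed_richness(counts) -> int:
    """Number of taxa with count strictly greater than zero."""
    return int((np.asarray(counts) > 0).sum())


def alpha_table(
    table: CountTable, depth: int | None, seed: int
) -> tuple[pd.DataFrame, list[str]]:
    """Per-sample richness and Shannon diversity after a single rarefaction draw.

    ``depth=None`` uses the minimum sample total ("auto").  Returns the
    per-sample frame and the ids excluded for falling below the depth.
    """
    if depth is None:
        depth = int(table.counts.sum(axis=0).min())
    rare, excluded = rarefy(table, depth, seed)
    rows = [
        {
            "sample_id": sid,
            "richness": observed_richness(rare.counts[:, j]),
            "shannon": shannon(rare.counts[:, j]),
            "rarefaction_depth": depth,
            "seed": seed,
        }
        for j, sid in enumerate(rare.sample_ids)
    ]
    return pd.DataFrame(rows), excluded


def compare_bins_to_reference(
    alpha: pd.DataFrame,
    meta: SampleMetadata,
    reference_bin: str,
    metric: str,
    cfg: AnalysisConfig | None = None,
) -> list[BinTestResult]:
    """Rank-sum test of each age bin's diversity against the reference bin.

    Blanks and positive controls are never tested; bins with fewer than two
    samples are skipped with a warning.  Bonferroni adjustment runs over the
    number of bins actually tested.
    """
    cfg = cfg or AnalysisConfig()
    if metric not in ("richness", "shannon"):
        raise ValueError("metric must be 'richness' or 'shannon'")
    merged = alpha.merge(
        meta.frame[["sample_id", "age_bin", "sample_type"]], on="sample_id"
    )
    merged = merged[~merged["sample_type"].isin(["blank", "positive_control"])]
    ref = merged.loc[merged["age_bin"] == reference_bin, metric].to_numpy()
    if ref.size < 2:
        raise ValueError(
            f"reference bin {reference_bin!r} has {ref.size} samples (need >= 2)"
        )
    tested: list[tuple[str, int, float]] = []
    for bin_label, grp in merged.groupby("age_bin", sort=False):
        if bin_label == reference_bin:
            continue
        vals = grp[metric].to_numpy()
        if vals.size < 2:
            warnings.warn(
                f"age bin {bin_label!r} has {vals.size} sample(s); skipped",
                stacklevel=2,
            )
            continue
        stat, p = ranksum_test(vals, ref)
        tested.append((bin_label, vals.size, stat, p))
    adj = bonferroni([t[3] for t in tested])
    return [
        BinTestResult(
            age_bin=label,
            n_bin=n,
            n_reference=int(ref.size),
            statistic=stat,
            raw_p=p,
            adjusted_p=float(a),
            significant=bool(a < cfg.alpha_level),
        )
        for (label, n, stat, p), a in zip(tested, adj)
    ]
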