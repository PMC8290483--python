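"""Mother-infant shared-OTU analysis.

An OTU is "present" in a sample when its relative abundance strictly
exceeds a threshold (default 0.01%).  For each related mother-infant pair
the number of co-present OTUs is counted; the null comparison draws an
equal-size random subset of unrelated child x mother pairs from the same
postpartum window and maternal specimen type, and a two-sided rank-sum test
compares the two sets of shared counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import ranksum_test
from .core_io import AnalysisConfig, CountTable, SampleMetadata

__all__ = [
    "PresenceMatrix",
    "PairSet",
    "SharedOtuResult",
    "presence",
    "shared_count",
    "build_pairs",
    "related_vs_unrelated",
    "top_shared_otus",
]

# postpartum window -> (child age bin, maternal age bin)
WINDOWS = {
    "wk1": ("DOL 0-5", "Mother-wk1"),
    "wk4": ("DOL 26-35", "Mother-wk4"),
}


@dataclass
class PresenceMatrix:
    otu_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    presence: np.ndarray  # bool, OTU x sample
    threshold: float

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample_id!r}") from None


@dataclass
class PairSet:
    related_pairs: list[tuple[str, str]]
    candidate_unrelated: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if set(self.related_pairs) & set(self.candidate_unrelated):
            raise ValueError("related and unrelated pair sets overlap")


@dataclass
class SharedOtuResult:
    related_counts: np.ndarray
    unrelated_draws: list[np.ndarray]
    per_draw_p: list[float]
    summary_p: float
    median_related: float
    median_unrelated: float
    n_related: int
    n_draws: int
    draw_seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"group": "related", "draw": 0, "shared_otus": int(c)}
            for c in self.related_counts
        ]
        for d, draw in enumerate(self.unrelated_draws, start=1):
            rows += [
                {"group": "unrelated", "draw": d, "shared_otus": int(c)} for c in draw
            ]
        return pd.DataFrame(rows)


def presence(table: CountTable, threshold: float) -> PresenceMatrix:
    """Boolean presence calls: relative abundance strictly above threshold."""
    totals = table.counts.sum(axis=0).astype(float)
    if (totals == 0).any():
        bad = table.sample_ids[int(np.argmax(totals == 0))]
        raise ValueError(f"sample {bad!r} has zero total count")
    rel = table.counts / totals
    return PresenceMatrix(table.otu_ids, table.sample_ids, rel > threshold, threshold)


def shared_count(pm: PresenceMatrix, a: str, b: str) -> int:
    """Number of OTUs present in both samples."""
    ia, ib = pm.sample_index(a), pm.sample_index(b)
    return int(np.sum(pm.presence[:, ia] & pm.presence[:, ib]))


def build_pairs(
    meta: SampleMetadata,
    source: str,
    window: str,
    available: set[str] | None = None,
) -> PairSet:
    """Construct related and candidate-unrelated pairs for one analysis stratum.

    ``source`` is the maternal specimen type (``mother_stool`` or
    ``breast_milk``); ``window`` is ``wk1`` or ``wk4``.  A related pair links
    a child-stool sample to a sample of that type from its own mother in
    the same window; candidate unrelated pairs are all other child x mother
    combinations within the stratum.  ``available`` optionally restricts to
    samples surviving QC.
    """
    if window not in WINDOWS:
        raise ValueError(f"unknown window {window!r}; expected one of {list(WINDOWS)}")
    if source not in ("mother_stool", "breast_milk"):
        raise ValueError(f"unknown maternal source {source!r}")
    child_bin, mother_bin = WINDOWS[window]
    df = meta.frame
    if available is not None:
        df = df[df["sample_id"].isin(available)]
    children = df[(df["sample_type"] == "child_stool") & (df["age_bin"] == child_bin)]
    mothers = df[(df["sample_type"] == source) & (df["age_bin"] == mother_bin)]
    mother_by_subject = {
        row["subject_id"]: row["sample_id"] for _, row in mothers.iterrows()
    }
    related, unrelated = [], []
    for _, child in children.iterrows():
        own = mother_by_subject.get(child["mother_subject_id"])
        for subj, m_sid in mother_by_subject.items():
            if m_sid == own:
                related.append((child["sample_id"], m_sid))
            else:
                unrelated.append((child["sample_id"], m_sid))
    return PairSet(related_pairs=related, candidate_unrelated=unrelated)


def related_vs_unrelated(
    pm: PresenceMatrix, pairs: PairSet, cfg: AnalysisConfig
) -> SharedOtuResult:
    """Compare shared-OTU counts of related pairs against resampled unrelated pairs.

    Each of ``cfg.n_resample_draws`` draws selects, uniformly without
    replacement, as many unrelated pairs as there are related pairs, and a
    two-sided rank-sum test compares the two count distributions.  The
    summary p is the median across draws.
    """
    n_rel = len(pairs.related_pairs)
    if n_rel < 3:
        raise ValueError(f"need >= 3 related pairs, got {n_rel}")
    if len(pairs.candidate_unrelated) < n_rel:
        raise ValueError(
            f"only {len(pairs.candidate_unrelated)} unrelated candidates for "
            f"{n_rel} related pairs"
        )
    related = np.array([shared_count(pm, c, m) for c, m in pairs.related_pairs])
    rng = np.random.default_rng(cfg.rng_seed)
    draws, pvals = [], []
    all_unrel_counts = np.array(
        [shared_count(pm, c, m) for c, m in pairs.candidate_unrelated]
    )
    for _ in range(cfg.n_resample_draws):
        idx = rng.choice(len(pairs.candidate_unrelated), size=n_rel, replace=False)
        draw = all_unrel_counts[idx]
        _, p = ranksum_test(related, draw)
        draws.append(draw)
        pvals.append(p)
    return SharedOtuResult(
        related_counts=related,
        unrelated_draws=draws,
        per_draw_p=pvals,
        summary_p=float(np.median(pvals)),
        median_related=float(np.median(related)),
        median_unrelated=float(np.median(np.concatenate(draws))),
        n_related=n_rel,
        n_draws=cfg.n_resample_draws,
        draw_seed=cfg.rng_seed,
    )


def top_shared_otus(
    pm: PresenceMatrix, pairs: PairSet, table: CountTable
) -> pd.DataFrame:
    """Rank OTUs by how many related pairs share them.

    Each OTU is annotated with its mean relative abundance in the children
    and in the mothers of the related pairs, exposing whether a shared OTU
    is newborn-enriched or mother-enriched.
    """
    if not pairs.related_pairs:
        raise ValueError("need at least one related pair")
    totals = table.counts.sum(axis=0).astype(float)
    rel = table.counts / np.where(totals == 0, 1.0, totals)
    child_idx = [table.sample_index(c) for c, _ in pairs.related_pairs]
    mother_idx = [table.sample_index(m) for _, m in pairs.related_pairs]
    rows = []
    for i, otu in enumerate(pm.otu_ids):
        ti = table.otu_ids.index(otu)
        shared_by = sum(
            bool(
                pm.presence[i, pm.sample_index(c)] and pm.presence[i, pm.sample_index(m)]
            )
            for c, m in pairs.related_pairs
        )
        rows.append(
            {
                "otu_id": otu,
                "n_pairs_shared": shared_by,
                "mean_relabund_children": float(rel[ti, child_idx].mean()),
                "mean_relabund_mothers": float(rel[ti, mother_idx].mean()),
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["n_pairs_shared", "otu_id"], ascending=[False, True], kind="mergesort"
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)
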