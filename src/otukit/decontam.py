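"""Blank-based contaminant classification, background subtraction, and
low-depth sample filtering.

Template-free blanks are co-sequenced with specimens, so reagent-derived
OTUs show up in most blanks at counts comparable to (or exceeding) their
specimen counts.  The rule implemented here classifies each OTU by two
statistics:

* *blank prevalence* — the fraction of blanks where the OTU has any reads;
* a *dispersion score* — geometric mean plus one standard deviation of its
  counts, computed separately over blanks and over specimens.

An OTU present in strictly more than half the blanks is **removed** when its
blank dispersion score exceeds its specimen score (reads are blank-driven),
and **background-subtracted** otherwise (a genuinely abundant taxon that
also leaks into blanks): the arithmetic mean + SD of its blank counts is
subtracted from every specimen, floored at zero.  Everything else is kept.
Specimen groups with distinct blank sets (stool vs. breast milk) are
processed as independent strata and recombined afterwards.  Finally,
samples with fewer than ``min_sample_depth`` total reads are dropped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import AnalysisConfig, CountTable, StudyBundle

__all__ = [
    "OtuBlankStats",
    "DecontamDecision",
    "DecontamReport",
    "blank_prevalence",
    "dispersion_score",
    "classify_contaminants",
    "apply_decontam",
    "filter_low_depth",
    "run_decontam",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OtuBlankStats:
    otu_id: str
    blank_prevalence: float
    blank_dispersion: float
    sample_dispersion: float
    blank_background: float


@dataclass(frozen=True)
class DecontamDecision:
    otu_id: str
    action: str  # keep | remove | subtract
    stats: OtuBlankStats


@dataclass
class DecontamReport:
    decisions: list[DecontamDecision]
    dropped_samples: dict[str, int]
    stratum: str

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "otu_id": d.otu_id,
                "action": d.action,
                "blank_prevalence": d.stats.blank_prevalence,
                "blank_dispersion": d.stats.blank_dispersion,
                "sample_dispersion": d.stats.sample_dispersion,
                "blank_background": d.stats.blank_background,
                "stratum": self.stratum,
            }
            for d in self.decisions
        ]
        return pd.DataFrame(rows)


def blank_prevalence(table: CountTable, blank_ids: Iterable[str]) -> pd.Series:
    """Per-OTU fraction of blank samples with count strictly greater than 0."""
    blank_ids = list(blank_ids)
    if not blank_ids:
        raise ValueError(
            "no blank samples given — skip decontamination for this stratum"
        )
    missing = set(blank_ids) - set(table.sample_ids)
    if missing:
        raise KeyError(f"blank ids not in table: {sorted(missing)}")
    sub = table.subset_samples(blank_ids)
    frac = (sub.counts > 0).mean(axis=1)
    return pd.Series(frac, index=list(table.otu_ids))


def dispersion_score(counts) -> float:
    """Geometric mean plus one sample standard deviation of a count vector.

    The geometric mean uses the pseudocount convention
    ``exp(mean(log(c + 1))) - 1`` so zero counts are defined; SD uses the
    n-1 denominator and is 0 for a single observation.
    """
    c = np.asarray(counts, dtype=float)
    if c.size == 0:
        raise ValueError("dispersion_score requires a nonempty vector")
    gm = np.exp(np.mean(np.log(c + 1.0))) - 1.0
    sd = float(np.std(c, ddof=1)) if c.size > 1 else 0.0
    return float(gm + sd)


def _blank_background(counts) -> float:
    """Arithmetic mean plus one sample SD (the subtraction amount)."""
    c = np.asarray(counts, dtype=float)
    sd = float(np.std(c, ddof=1)) if c.size > 1 else 0.0
    return float(np.mean(c) + sd)


def classify_contaminants(
    table: CountTable,
    blank_ids: Iterable[str],
    specimen_ids: Iterable[str],
    cfg: AnalysisConfig,
) -> list[DecontamDecision]:
    """Assign keep / remove / subtract to every OTU of the table."""
    blank_ids, specimen_ids = list(blank_ids), list(specimen_ids)
    if not blank_ids or not specimen_ids:
        raise ValueError("blank and specimen sets must both be nonempty")
    if set(blank_ids) & set(specimen_ids):
        raise ValueError("blank and specimen sets must be disjoint")
    blanks = table.subset_samples(blank_ids)
    specimens = table.subset_samples(specimen_ids)
    prev = (blanks.counts > 0).mean(axis=1)
    decisions: list[DecontamDecision] = []
    for i, otu in enumerate(table.otu_ids):
        st = OtuBlankStats(
            otu_id=otu,
            blank_prevalence=float(prev[i]),
            blank_dispersion=dispersion_score(blanks.counts[i]),
            sample_dispersion=dispersion_score(specimens.counts[i]),
            blank_background=_blank_background(blanks.counts[i]),
        )
        if st.blank_prevalence > cfg.blank_prevalence_threshold:
            action = "remove" if st.blank_dispersion > st.sample_dispersion else "subtract"
        else:
            action = "keep"
        decisions.append(DecontamDecision(otu, action, st))
    return decisions


def apply_decontam(
    table: CountTable,
    decisions: Sequence[DecontamDecision],
    specimen_ids: Iterable[str],
) -> CountTable:
    """Apply remove/subtract decisions; output covers specimen columns only."""
    by_otu = {d.otu_id: d for d in decisions}
    missing = set(table.otu_ids) - set(by_otu)
    if missing:
        raise ValueError(f"decisions missing for OTUs: {sorted(missing)[:5]}")
    out = table.subset_samples(list(specimen_ids))
    keep_idx = []
    counts = out.counts.copy()
    for i, otu in enumerate(out.otu_ids):
        d = by_otu[otu]
        if d.action == "remove":
            continue
        if d.action == "subtract":
            counts[i] = np.maximum(
                0, np.floor(counts[i] - d.stats.blank_background)
            ).astype(np.int64)
        keep_idx.append(i)
    return CountTable(
        tuple(out.otu_ids[i] for i in keep_idx), out.sample_ids, counts[keep_idx, :]
    )


def filter_low_depth(
    table: CountTable, min_total: int
) -> tuple[CountTable, dict[str, int]]:
    """Drop samples whose total count is strictly below ``min_total``."""
    if min_total < 0:
        raise ValueError("min_total must be nonnegative")
    totals = table.counts.sum(axis=0)
    dropped = {
        s: int(t) for s, t in zip(table.sample_ids, totals) if t < min_total
    }
    if len(dropped) == table.n_samples and table.n_samples > 0:
        raise ValueError(
            f"all {table.n_samples} samples fall below {min_total} reads — "
            "inspect sequencing depth before filtering"
        )
    keep = [s for s in table.sample_ids if s not in dropped]
    return table.subset_samples(keep), dropped


def run_decontam(
    bundle: StudyBundle,
    strata: Mapping[str, tuple[Sequence[str], Sequence[str]]],
    cfg: AnalysisConfig,
) -> tuple[CountTable, list[DecontamReport]]:
    """Per-stratum classify -> subtract -> depth-filter, then recombine.

    ``strata`` maps a label (e.g. ``"stool"``, ``"breast_milk"``) to its
    ``(blank_ids, specimen_ids)``.  Strata with no blanks pass through with
    only the depth filter (and a warning); cleaned tables are recombined on
    the union of surviving OTUs with zero fill.
    """
    cleaned: list[CountTable] = []
    reports: list[DecontamReport] = []
    for label, (blank_ids, specimen_ids) in strata.items():
        sub = bundle.table.subset_samples(list(blank_ids) + list(specimen_ids))
        if not list(blank_ids):
            warnings.warn(
                f"stratum {label!r} has no blanks; passing through unfiltered",
                stacklevel=2,
            )
            decisions = [
                DecontamDecision(o, "keep", OtuBlankStats(o, 0.0, 0.0, 0.0, 0.0))
                for o in sub.otu_ids
            ]
            stage = sub.subset_samples(list(specimen_ids))
        else:
            decisions = classify_contaminants(sub, blank_ids, specimen_ids, cfg)
            stage = apply_decontam(sub, decisions, specimen_ids)
        stage, dropped = filter_low_depth(stage, cfg.min_sample_depth)
        reports.append(DecontamReport(decisions, dropped, label))
        # prune OTUs emptied within this stratum so recombination is tidy
        nonzero = stage.counts.sum(axis=1) > 0
        stage = CountTable(
            tuple(o for o, nz in zip(stage.otu_ids, nonzero) if nz),
            stage.sample_ids,
            stage.counts[nonzero, :],
        )
        cleaned.append(stage)
    frames = [t.to_dataframe() for t in cleaned if t.n_samples]
    if not frames:
        raise ValueError("decontamination left no samples in any stratum")
    merged = pd.concat(frames, axis=1).fillna(0).astype(np.int64)
    merged = merged.loc[sorted(merged.index)]
    logger.info(
        "decontam: %d strata, %d OTUs and %d samples retained",
        len(strata), merged.shape[0], merged.shape[1],
    )
    return CountTable.from_dataframe(merged), reports
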