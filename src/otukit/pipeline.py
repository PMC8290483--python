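"""End-to-end orchestration: QC -> alpha -> beta -> sharing -> diffabund.

Each stage is a thin composition of the module functions so the CLI, the
analysis drivers, and the acceptance checks all exercise identical code
paths.  Positive-control samples are excluded from every statistical
analysis; blanks participate only in decontamination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import alpha_diversity, beta_diversity, decontam, diffabund, sharing
from .core_io import AnalysisConfig, CountTable, SampleMetadata, TaxonomyTable

__all__ = ["DomainResult", "decontam_stage", "run_domain"]

ADULT_REFERENCE_BIN = "Mother-wk4"
CONVERGENCE_REFERENCE_BIN = "MOL 57-63"


@dataclass
class DomainResult:
    """All per-domain stage outputs for one amplicon domain."""

    cleaned: CountTable
    decontam_reports: list
    alpha: pd.DataFrame
    alpha_excluded: list[str]
    alpha_tests: dict[str, list]
    permanova: beta_diversity.PermanovaResult | None
    bin_distances: list
    sharing_results: dict[tuple[str, str], sharing.SharedOtuResult]
    genus_tests: pd.DataFrame | None


def _strata_for(meta: SampleMetadata, domain: str) -> dict:
    """stool and breast-milk decontamination strata for one domain."""
    strata = {}
    stool_specimens = meta.ids_where(
        sample_type=["child_stool", "mother_stool"], domain=domain
    )
    stool_blanks = meta.ids_where(sample_type="blank", domain=domain, batch="stool")
    strata["stool"] = (stool_blanks, stool_specimens)
    milk_specimens = meta.ids_where(sample_type="breast_milk", domain=domain)
    if milk_specimens:
        milk_blanks = meta.ids_where(
            sample_type="blank", domain=domain, batch="breast_milk"
        )
        strata["breast_milk"] = (milk_blanks, milk_specimens)
    return strata


def decontam_stage(
    table: CountTable, meta: SampleMetadata, tax: TaxonomyTable,
    domain: str, cfg: AnalysisConfig,
) -> tuple[CountTable, list]:
    """Stratified blank-based QC for one domain's table."""
    from .core_io import align_study

    domain_ids = meta.ids_where(domain=domain)
    bundle = align_study(table.subset_samples(domain_ids), meta, tax)
    strata = _strata_for(bundle.metadata, domain)
    return decontam.run_decontam(bundle, strata, cfg)


def run_domain(
    table: CountTable,
    meta: SampleMetadata,
    tax: TaxonomyTable,
    domain: str,
    cfg: AnalysisConfig,
    rarefaction_depth: int | None = None,
    sharing_sources: tuple[str, ...] = ("mother_stool", "breast_milk"),
    diffabund_groups: tuple[str, str] = ("Mother-wk1", "Mother-wk4"),
) -> DomainResult:
    """Run the full analysis for one amplicon domain."""
    cleaned, reports = decontam_stage(table, meta, tax, domain, cfg)

    # alpha: single rarefaction draw at the minimum retained depth
    alpha, excluded = alpha_diversity.alpha_table(
        cleaned, rarefaction_depth, seed=cfg.rng_seed
    )
    alpha_tests = {}
    for metric in ("richness", "shannon"):
        alpha_tests[metric] = alpha_diversity.compare_bins_to_reference(
            alpha, meta, ADULT_REFERENCE_BIN, metric, cfg
        )

    # beta: child samples only, age in days as the covariate
    child_ids = [
        s for s in cleaned.sample_ids
        if meta.frame.loc[s, "sample_type"] == "child_stool"
        and pd.notna(meta.frame.loc[s, "age_days"])
    ]
    permanova = None
    bin_dist = []
    if len(child_ids) >= 3:
        child_table = cleaned.subset_samples(child_ids)
        keep = [s for s in child_ids if child_table.column(s).sum() > 0]
        child_table = child_table.subset_samples(keep)
        dm = beta_diversity.bray_curtis(child_table)
        ages = meta.frame.loc[list(dm.ids), "age_days"].to_numpy(dtype=float)
        if np.ptp(ages) > 0:
            permanova = beta_diversity.permanova_continuous(
                dm, ages, n_perm=cfg.n_permutations, seed=cfg.rng_seed
            )
        ref_n = sum(
            meta.frame.loc[s, "age_bin"] == CONVERGENCE_REFERENCE_BIN for s in dm.ids
        )
        if ref_n >= 2:
            bin_dist = beta_diversity.distances_to_reference(
                dm, meta, CONVERGENCE_REFERENCE_BIN
            )
            bin_dist = beta_diversity.bin_distance_test(bin_dist, cfg)

    # sharing: per maternal source and postpartum window
    sharing_results = {}
    pm = None
    nonzero = [s for s in cleaned.sample_ids if cleaned.column(s).sum() > 0]
    pm_table = cleaned.subset_samples(nonzero)
    if pm_table.n_samples:
        pm = sharing.presence(pm_table, cfg.presence_threshold)
        for source in sharing_sources:
            for window in ("wk1", "wk4"):
                pairs = sharing.build_pairs(meta, source, window, available=set(nonzero))
                try:
                    sharing_results[(source, window)] = sharing.related_vs_unrelated(
                        pm, pairs, cfg
                    )
                except ValueError:
                    continue  # too few surviving pairs in this stratum

    # genus-level differential abundance between maternal windows
    genus_tests = None
    g1 = [s for s in cleaned.sample_ids
          if meta.frame.loc[s, "age_bin"] == diffabund_groups[0]
          and meta.frame.loc[s, "sample_type"] == "mother_stool"]
    g2 = [s for s in cleaned.sample_ids
          if meta.frame.loc[s, "age_bin"] == diffabund_groups[1]
          and meta.frame.loc[s, "sample_type"] == "mother_stool"]
    if len(g1) >= 2 and len(g2) >= 2:
        genus_table = diffabund.aggregate_by_genus(
            cleaned.subset_samples(g1 + g2), tax
        )
        relab = diffabund.relative_abundance(genus_table)
        genus_tests = diffabund.group_difference_test(relab, g1, g2, cfg)

    return DomainResult(
        cleaned=cleaned,
        decontam_reports=reports,
        alpha=alpha,
        alpha_excluded=excluded,
        alpha_tests=alpha_tests,
        permanova=permanova,
        bin_distances=bin_dist,
        sharing_results=sharing_results,
        genus_tests=genus_tests,
    )
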