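"""Truth-labelled synthetic amplicon studies.

Generates paired bacterial (16S) and fungal (ITS2) OTU count tables with the
structure the analysis pipeline assumes: age-binned child stool samples whose
bacterial composition follows the classic gut succession (Escherichia-type
dominance in the first week, Bifidobacterium-type dominance through infancy,
Prevotella-type dominance after the first year), maternal stool sampled one
and four weeks postpartum, breast-milk samples dominated by skin taxa,
fungal communities with no age trend and a sizeable fraction of fungus-free
samples, template-free blanks carrying spiked reagent contaminants, and
uneven sequencing depth including occasional samples below 1,000 reads.

Per-sample compositions are Dirichlet-multinomial: a genus-level mean profile
for the sample's age bin is spread across that genus's OTUs, jittered by a
Dirichlet draw at a configurable concentration, and reads are drawn
multinomially at a log-normal depth.  Mother-to-infant transmission copies a
configurable number of OTUs from the mother's realized composition into her
infant's sample so shared-OTU analyses have a known signal.  Every random
choice flows from a single seed, so identical configs give byte-identical
studies, and all spiked structure is reported as ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    AGE_BINS,
    CHILD_BINS,
    CountTable,
    SampleMetadata,
    TaxonomyTable,
    write_count_table,
    write_metadata,
    write_taxonomy,
)

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "succession_profiles",
    "fungal_profiles",
    "simulate_study",
    "write_study",
]

# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

BACTERIAL_GENERA = (
    "Escherichia",
    "Bifidobacterium",
    "Bacteroides",
    "Prevotella",
    "Faecalibacterium",
    "Blautia",
    "Streptococcus",
    "Enterococcus",
    "Staphylococcus",
    "Veillonella",
    "Clostridium",
    "Ruminococcus",
    "Lactobacillus",
    "Akkermansia",
    "Corynebacterium",
)

FUNGAL_GENERA = (
    "Candida",
    "Malassezia",
    "Aspergillus",
    "Saccharomyces",
    "Cryptococcus",
    "Penicillium",
    "Rhodotorula",
    "Cladosporium",
    "Debaryomyces",
    "Fusarium",
)

# Child-bin bacterial succession: early Escherichia dominance giving way to
# Bifidobacterium through infancy and Prevotella after the first year, with
# evenness (hence Shannon diversity) increasing toward the adult-like oldest
# bin.  Values are qualitative targets, normalized at load.
_BACT_PROFILES: dict[str, dict[str, float]] = {
    "DOL 0-5":     {"Escherichia": 0.62, "Streptococcus": 0.11, "Enterococcus": 0.09,
                    "Staphylococcus": 0.07, "Bifidobacterium": 0.04, "Bacteroides": 0.03,
                    "Veillonella": 0.02, "Lactobacillus": 0.02},
    "DOL 13-17":   {"Escherichia": 0.52, "Bifidobacterium": 0.16, "Bacteroides": 0.08,
                    "Streptococcus": 0.08, "Enterococcus": 0.06, "Staphylococcus": 0.04,
                    "Veillonella": 0.03, "Clostridium": 0.02, "Lactobacillus": 0.01},
    "DOL 26-35":   {"Escherichia": 0.34, "Bifidobacterium": 0.30, "Bacteroides": 0.12,
                    "Streptococcus": 0.06, "Enterococcus": 0.05, "Veillonella": 0.05,
                    "Clostridium": 0.04, "Lactobacillus": 0.03, "Staphylococcus": 0.01},
    "DOL 83-115":  {"Bifidobacterium": 0.38, "Escherichia": 0.19, "Bacteroides": 0.17,
                    "Veillonella": 0.05, "Streptococcus": 0.04, "Clostridium": 0.05,
                    "Lactobacillus": 0.04, "Enterococcus": 0.02, "Prevotella": 0.02,
                    "Ruminococcus": 0.02, "Faecalibacterium": 0.02},
    "DOL 165-200": {"Bifidobacterium": 0.33, "Bacteroides": 0.20, "Escherichia": 0.12,
                    "Veillonella": 0.06, "Clostridium": 0.06, "Streptococcus": 0.04,
                    "Lactobacillus": 0.04, "Ruminococcus": 0.05, "Prevotella": 0.06,
                    "Faecalibacterium": 0.04},
    "MOL 11-13":   {"Bifidobacterium": 0.28, "Bacteroides": 0.21, "Prevotella": 0.13,
                    "Faecalibacterium": 0.08, "Escherichia": 0.08, "Clostridium": 0.06,
                    "Ruminococcus": 0.06, "Veillonella": 0.04, "Lactobacillus": 0.04,
                    "Blautia": 0.02},
    "MOL 22-26":   {"Prevotella": 0.27, "Bacteroides": 0.15, "Faecalibacterium": 0.12,
                    "Bifidobacterium": 0.11, "Ruminococcus": 0.08, "Clostridium": 0.07,
                    "Blautia": 0.06, "Escherichia": 0.06, "Veillonella": 0.04,
                    "Lactobacillus": 0.04},
    "MOL 33-39":   {"Prevotella": 0.33, "Faecalibacterium": 0.14, "Bacteroides": 0.12,
                    "Ruminococcus": 0.09, "Clostridium": 0.08, "Blautia": 0.07,
                    "Bifidobacterium": 0.07, "Escherichia": 0.04, "Veillonella": 0.03,
                    "Lactobacillus": 0.02, "Akkermansia": 0.01},
    "MOL 57-63":   {"Prevotella": 0.37, "Faecalibacterium": 0.15, "Bacteroides": 0.11,
                    "Ruminococcus": 0.10, "Clostridium": 0.08, "Blautia": 0.07,
                    "Bifidobacterium": 0.04, "Escherichia": 0.03, "Veillonella": 0.03,
                    "Akkermansia": 0.02},
    # maternal stool: Escherichia-rich / Prevotella-poor in the first week,
    # Prevotella-dominant (adult-like) by the fourth
    "Mother-wk1":  {"Escherichia": 0.29, "Faecalibacterium": 0.17, "Blautia": 0.14,
                    "Bacteroides": 0.10, "Ruminococcus": 0.08, "Clostridium": 0.07,
                    "Streptococcus": 0.05, "Veillonella": 0.04, "Prevotella": 0.04,
                    "Bifidobacterium": 0.02},
    "Mother-wk4":  {"Prevotella": 0.35, "Faecalibacterium": 0.14, "Bacteroides": 0.12,
                    "Ruminococcus": 0.10, "Blautia": 0.08, "Clostridium": 0.08,
                    "Escherichia": 0.05, "Veillonella": 0.04, "Bifidobacterium": 0.03,
                    "Streptococcus": 0.01},
    # breast milk: skin-taxon dominated
    "Milk-wk1":    {"Streptococcus": 0.35, "Staphylococcus": 0.27, "Corynebacterium": 0.15,
                    "Escherichia": 0.05, "Bifidobacterium": 0.05, "Lactobacillus": 0.05,
                    "Enterococcus": 0.04, "Veillonella": 0.04},
    "Milk-wk4":    {"Streptococcus": 0.33, "Staphylococcus": 0.28, "Corynebacterium": 0.16,
                    "Escherichia": 0.04, "Bifidobacterium": 0.06, "Lactobacillus": 0.05,
                    "Enterococcus": 0.04, "Veillonella": 0.04},
}

# Fungal stool profile: Candida-dominated at every age (no age trend);
# breast milk dominated by Malassezia.
_FUNGAL_STOOL = {"Candida": 0.50, "Malassezia": 0.14, "Aspergillus": 0.12,
                 "Saccharomyces": 0.08, "Cryptococcus": 0.05, "Penicillium": 0.04,
                 "Rhodotorula": 0.03, "Cladosporium": 0.02, "Debaryomyces": 0.01,
                 "Fusarium": 0.01}
_FUNGAL_MILK = {"Malassezia": 0.55, "Candida": 0.20, "Aspergillus": 0.07,
                "Saccharomyces": 0.05, "Cryptococcus": 0.04, "Penicillium": 0.03,
                "Rhodotorula": 0.03, "Cladosporium": 0.02, "Debaryomyces": 0.01}

# Per-bin strain-richness factors: newborn guts carry very few strains per
# genus, adults many.  The factor scales the within-genus Dirichlet
# concentration, so OTU-level richness and evenness rise with age while the
# genus-level succession stays profile-driven.
_STRAIN_RICHNESS: dict[str, float] = {
    "DOL 0-5": 0.15, "DOL 13-17": 0.20, "DOL 26-35": 0.25,
    "DOL 83-115": 0.35, "DOL 165-200": 0.50, "MOL 11-13": 0.70,
    "MOL 22-26": 0.85, "MOL 33-39": 1.0, "MOL 57-63": 1.0,
    "Mother-wk1": 1.0, "Mother-wk4": 1.0, "Milk-wk1": 1.0, "Milk-wk4": 1.0,
}


def strain_richness_factors(preset: str = "ghana_default") -> dict[str, float]:
    """Per-bin multipliers for the within-genus concentration (strain count)."""
    if preset != "ghana_default":
        raise ValueError(f"unknown preset: {preset!r}")
    return dict(_STRAIN_RICHNESS)


# classic reagent-contaminant genera spiked into blanks
_CONTAMINANT_GENERA = {
    "stool": ("Ralstonia", "Sphingomonas", "Methylobacterium", "Burkholderia"),
    "breast_milk": ("Bradyrhizobium", "Pelomonas", "Acinetobacter"),
}


def _profile_vector(profile: dict[str, float], panel: tuple[str, ...]) -> np.ndarray:
    unknown = set(profile) - set(panel)
    if unknown:
        raise ValueError(f"profile names genera outside the panel: {sorted(unknown)}")
    v = np.array([profile.get(g, 0.0) for g in panel], dtype=float)
    if v.sum() <= 0:
        raise ValueError("profile must have positive mass")
    return v / v.sum()


def succession_profiles(preset: str = "ghana_default") -> tuple[tuple[str, ...], dict[str, np.ndarray]]:
    """Built-in bacterial genus panel and per-bin mean profiles.

    Returns ``(genus_panel, {bin_label: profile})`` with every profile
    normalized to sum to 1.
    """
    if preset != "ghana_default":
        raise ValueError(f"unknown preset: {preset!r}")
    return BACTERIAL_GENERA, {
        b: _profile_vector(p, BACTERIAL_GENERA) for b, p in _BACT_PROFILES.items()
    }


def fungal_profiles(preset: str = "ghana_default") -> tuple[tuple[str, ...], dict[str, np.ndarray]]:
    """Fungal genus panel and per-bin profiles (flat across child/mother bins)."""
    if preset != "ghana_default":
        raise ValueError(f"unknown preset: {preset!r}")
    profiles: dict[str, np.ndarray] = {}
    stool = _profile_vector(_FUNGAL_STOOL, FUNGAL_GENERA)
    milk = _profile_vector(_FUNGAL_MILK, FUNGAL_GENERA)
    for b in list(CHILD_BINS) + ["Mother-wk1", "Mother-wk4"]:
        profiles[b] = stool
    profiles["Milk-wk1"] = milk
    profiles["Milk-wk4"] = milk
    return FUNGAL_GENERA, profiles


@dataclass
class SimulationConfig:
    """Study-design knobs for :func:`simulate_study`.

    ``samples_per_bin`` covers the child bins not tied to the mother-infant
    windows; the DOL 0-5 and DOL 26-35 bins are sized by
    ``n_mother_infant_pairs`` since those children are the week-1 and
    week-4 infants.  ``dispersion`` is the Dirichlet concentration around
    the bin mean profile (larger = tighter); ``transmission_n_otus`` OTUs
    are copied from each related mother's realized stool (and breast-milk)
    composition into her infant's bacterial sample.
    """

    preset: str = "ghana_default"
    samples_per_bin: int = 12
    n_mother_infant_pairs: dict[str, int] = field(
        default_factory=lambda: {"wk1": 15, "wk4": 15}
    )
    otus_per_genus: int = 12
    dispersion: float = 50.0
    within_genus_kappa: float = 5.0
    depth_mean: float = 10_000.0
    depth_sigma: float = 0.35
    low_depth_fraction: float = 0.03
    fungal_zero_fraction: float = 0.30
    transmission_n_otus: int = 20
    contaminant_blank_mean: float = 300.0
    contaminant_leak_mean: float = 0.5
    carryover_blank_mean: float = 4.0
    n_carryover_otus: int = 2
    n_blanks: dict[str, int] = field(
        default_factory=lambda: {"stool": 4, "breast_milk": 2}
    )
    n_positive_controls: int = 2
    flat_bacterial_profiles: bool = False  # null mode: one profile for every bin
    seed: int = 0

    def __post_init__(self) -> None:
        if self.otus_per_genus < 1:
            raise ValueError("otus_per_genus must be >= 1")
        if not 0 <= self.fungal_zero_fraction <= 1:
            raise ValueError("fungal_zero_fraction must be in [0, 1]")
        if not 0 <= self.low_depth_fraction <= 1:
            raise ValueError("low_depth_fraction must be in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.transmission_n_otus < 0:
            raise ValueError("transmission_n_otus must be >= 0")


@dataclass
class SimulatedStudy:
    bacteria: CountTable
    fungi: CountTable
    metadata: SampleMetadata
    taxonomy: TaxonomyTable
    truth: dict

    def blank_ids(self, domain: str, stratum: str) -> list[str]:
        return self.metadata.ids_where(sample_type="blank", domain=domain, batch=stratum)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _make_otu_panel(
    genera: tuple[str, ...], otus_per_genus: int, prefix: str, kingdom: str
) -> tuple[list[str], dict[str, tuple[str, ...]], dict[str, list[int]]]:
    """OTU ids, lineages, and genus -> OTU-row-index mapping."""
    otu_ids: list[str] = []
    lineages: dict[str, tuple[str, ...]] = {}
    genus_rows: dict[str, list[int]] = {}
    for gi, genus in enumerate(genera):
        rows = []
        for k in range(otus_per_genus):
            oid = f"{prefix}_{genus[:4].upper()}_{k + 1:02d}"
            rows.append(len(otu_ids))
            otu_ids.append(oid)
            # every 5th genus leaves its last OTU unresolved at genus level,
            # exercising deepest-resolved-rank aggregation
            if gi % 5 == 4 and k == otus_per_genus - 1:
                lineages[oid] = (kingdom, f"{genus}_phylum", f"{genus}_class",
                                 f"{genus}_order", f"{genus}_family", "", "")
            else:
                lineages[oid] = (kingdom, f"{genus}_phylum", f"{genus}_class",
                                 f"{genus}_order", f"{genus}_family", genus, "")
        genus_rows[genus] = rows
    return otu_ids, lineages, genus_rows


def _sample_counts(
    rng: np.random.Generator,
    genus_profile: np.ndarray,
    panel: tuple[str, ...],
    genus_rows: dict[str, list[int]],
    n_otus: int,
    backbone: dict[str, np.ndarray],
    concentration: float,
    kappa: float,
    depth: int,
) -> np.ndarray:
    """One hierarchical Dirichlet-multinomial draw.

    Genus-level composition is a Dirichlet jitter (concentration
    ``concentration``) around the bin's mean profile; each genus's mass is
    then split across its OTUs by a per-sample Dirichlet draw (concentration
    ``kappa``) around the study-level backbone weights.  The per-sample
    split models strain-level individuality: which OTUs of a genus a given
    subject carries differs between subjects, while the genus-level
    structure stays bin-driven.
    """
    support = genus_profile > 0
    genus_comp = np.zeros_like(genus_profile)
    genus_comp[support] = rng.dirichlet(concentration * genus_profile[support])
    otu_comp = np.zeros(n_otus)
    for g, mass in zip(panel, genus_comp):
        if mass <= 0:
            continue
        w = rng.dirichlet(np.maximum(kappa * backbone[g], 1e-3))
        otu_comp[genus_rows[g]] = mass * w
    counts = np.zeros(n_otus, dtype=np.int64)
    pos = otu_comp > 0
    counts[pos] = rng.multinomial(depth, otu_comp[pos] / otu_comp[pos].sum())
    return counts


def _draw_depth(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    if rng.random() < cfg.low_depth_fraction:
        return int(rng.integers(150, 1000))
    mu = np.log(cfg.depth_mean) - cfg.depth_sigma**2 / 2
    return max(1, int(round(rng.lognormal(mu, cfg.depth_sigma))))


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Generate one fully truth-labelled study (both amplicon domains)."""
    rng = np.random.default_rng(cfg.seed)
    b_panel, b_profiles = succession_profiles(cfg.preset)
    f_panel, f_profiles = fungal_profiles(cfg.preset)
    strain_factor = strain_richness_factors(cfg.preset)
    if cfg.flat_bacterial_profiles:
        flat = b_profiles["MOL 57-63"]
        b_profiles = {b: flat for b in b_profiles}
        strain_factor = {b: 1.0 for b in strain_factor}

    b_otus, b_lineages, b_genus_rows = _make_otu_panel(
        b_panel, cfg.otus_per_genus, "BOTU", "Bacteria"
    )
    f_otus, f_lineages, f_genus_rows = _make_otu_panel(
        f_panel, cfg.otus_per_genus, "FOTU", "Fungi"
    )

    # Study-level within-genus backbone weights (the "strain pool").
    # The sparse Dirichlet makes each genus dominated by one or two OTUs,
    # as amplicon data show, so a bin dominated by one genus really is a
    # low-diversity community at the OTU level.
    b_backbone = {g: rng.dirichlet(np.full(cfg.otus_per_genus, 0.3)) for g in b_panel}
    f_backbone = {g: rng.dirichlet(np.full(cfg.otus_per_genus, 0.3)) for g in f_panel}

    # ---- study design ----------------------------------------------------
    meta_rows: list[dict] = []
    plan: list[tuple[str, str, str]] = []  # (base sample id, bin label, sample_type)
    mother_of: dict[str, str] = {}  # child base id -> mother stool base id
    milk_of: dict[str, str] = {}  # child base id -> milk base id (same mother)
    subj_counter = 0

    def child_row(base: str, bin_label: str, mother_subject: str | None) -> dict:
        lo, hi = AGE_BINS[bin_label]
        return {
            "base": base,
            "subject_id": f"C{base}",
            "mother_subject_id": mother_subject,
            "age_days": int(rng.integers(lo, hi + 1)),
            "age_bin": bin_label,
            "sample_type": "child_stool",
            "batch": "stool",
        }

    window_child_bin = {"wk1": "DOL 0-5", "wk4": "DOL 26-35"}
    paired_children: dict[str, list[dict]] = {}
    for window, n_pairs in cfg.n_mother_infant_pairs.items():
        bin_label = window_child_bin[window]
        paired_children[window] = []
        for _ in range(n_pairs):
            subj_counter += 1
            base = f"S{subj_counter:03d}"
            msubj = f"M{subj_counter:03d}"
            row = child_row(base, bin_label, msubj)
            meta_rows.append(row)
            mother_base = f"S{subj_counter:03d}MS"
            meta_rows.append({
                "base": mother_base, "subject_id": msubj, "mother_subject_id": None,
                "age_days": None, "age_bin": f"Mother-{window}",
                "sample_type": "mother_stool", "batch": "stool",
            })
            milk_base = f"S{subj_counter:03d}BM"
            meta_rows.append({
                "base": milk_base, "subject_id": msubj, "mother_subject_id": None,
                "age_days": None, "age_bin": f"Mother-{window}",
                "sample_type": "breast_milk", "batch": "breast_milk",
            })
            mother_of[base] = mother_base
            milk_of[base] = milk_base
            paired_children[window].append(row)

    for bin_label in CHILD_BINS:
        if bin_label in window_child_bin.values():
            continue
        for _ in range(cfg.samples_per_bin):
            subj_counter += 1
            base = f"S{subj_counter:03d}"
            meta_rows.append(child_row(base, bin_label, None))

    for stratum, n in cfg.n_blanks.items():
        for k in range(n):
            meta_rows.append({
                "base": f"BLK{stratum[:2].upper()}{k + 1}", "subject_id": f"blank_{stratum}_{k + 1}",
                "mother_subject_id": None, "age_days": None, "age_bin": "",
                "sample_type": "blank", "batch": stratum,
            })
    for k in range(cfg.n_positive_controls):
        meta_rows.append({
            "base": f"POS{k + 1}", "subject_id": f"pos_{k + 1}",
            "mother_subject_id": None, "age_days": None, "age_bin": "",
            "sample_type": "positive_control", "batch": "stool",
        })

    # ---- contaminant panel ----------------------------------------------
    contaminants: dict[str, list[str]] = {}
    for stratum, genera in _CONTAMINANT_GENERA.items():
        ids = []
        for genus in genera:
            oid = f"BCONT_{genus[:4].upper()}"
            b_otus.append(oid)
            b_lineages[oid] = ("Bacteria", f"{genus}_phylum", f"{genus}_class",
                               f"{genus}_order", f"{genus}_family", genus, "")
            ids.append(oid)
        contaminants[stratum] = ids
    pos_otu = "BPOS_SUP05"
    b_otus.append(pos_otu)
    b_lineages[pos_otu] = ("Bacteria", "Proteobacteria", "Gammaproteobacteria",
                           "Thiomicrospirales", "Thioglobaceae", "SUP05", "")

    n_b, n_f = len(b_otus), len(f_otus)
    b_index = {o: i for i, o in enumerate(b_otus)}

    # Carryover OTUs: abundant real taxa that also show up in blanks
    # (cross-well carryover), so the subtraction branch of decontamination
    # is exercised.  The dominant strain of a dominant genus is used so the
    # specimen dispersion score always dwarfs the blank one.
    def dominant_otus(genera: tuple[str, ...]) -> list[str]:
        return [
            b_otus[b_genus_rows[g][int(np.argmax(b_backbone[g]))]]
            for g in genera[: cfg.n_carryover_otus]
        ]

    carryover = {
        "stool": dominant_otus(("Escherichia", "Prevotella", "Bifidobacterium")),
        "breast_milk": dominant_otus(("Streptococcus", "Staphylococcus", "Corynebacterium")),
    }

    # ---- draw counts -----------------------------------------------------
    profile_for = {}
    for row in meta_rows:
        if row["sample_type"] == "child_stool":
            profile_for[row["base"]] = row["age_bin"]
        elif row["sample_type"] == "mother_stool":
            profile_for[row["base"]] = row["age_bin"]
        elif row["sample_type"] == "breast_milk":
            profile_for[row["base"]] = "Milk-" + row["age_bin"].split("-")[1]

    b_cols: dict[str, np.ndarray] = {}
    f_cols: dict[str, np.ndarray] = {}
    for row in meta_rows:
        base, stype = row["base"], row["sample_type"]
        if stype == "blank":
            col = np.zeros(n_b, dtype=np.int64)
            for oid in contaminants[row["batch"]]:
                col[b_index[oid]] = max(1, rng.poisson(cfg.contaminant_blank_mean))
            for oid in carryover[row["batch"]]:
                col[b_index[oid]] = rng.poisson(cfg.carryover_blank_mean)
            b_cols[base] = col
            fcol = np.zeros(n_f, dtype=np.int64)
            f_cols[base] = fcol
            continue
        if stype == "positive_control":
            col = np.zeros(n_b, dtype=np.int64)
            col[b_index[pos_otu]] = int(rng.normal(2e4, 1e3))
            b_cols[base] = col
            f_cols[base] = np.zeros(n_f, dtype=np.int64)
            continue
        bin_label = profile_for[base]
        kappa = cfg.within_genus_kappa * strain_factor.get(bin_label, 1.0)
        col = _sample_counts(
            rng, b_profiles[bin_label], b_panel, b_genus_rows, n_b, b_backbone,
            cfg.dispersion, kappa, _draw_depth(rng, cfg),
        )
        # reagent leakage into specimens
        for oid in contaminants[row["batch"]]:
            col[b_index[oid]] += rng.poisson(cfg.contaminant_leak_mean)
        b_cols[base] = col

        if rng.random() < cfg.fungal_zero_fraction:
            f_cols[base] = np.zeros(n_f, dtype=np.int64)
        else:
            f_cols[base] = _sample_counts(
                rng, f_profiles[bin_label], f_panel, f_genus_rows, n_f, f_backbone,
                cfg.dispersion, cfg.within_genus_kappa, _draw_depth(rng, cfg),
            )

    # ---- mother-to-infant transmission (bacterial domain) ----------------
    # only real taxa transmit; reagent contaminants in the maternal sample
    # are sequencing artifacts, not organisms the infant can acquire
    contam_idx = {
        b_index[oid] for ids in contaminants.values() for oid in ids
    }
    transmitted: dict[str, list[str]] = {}
    for child_base, sources in ((c, (mother_of[c], milk_of[c])) for c in mother_of):
        child_col = b_cols[child_base]
        child_total = child_col.sum()
        seeded: list[str] = []
        for src_base in sources:
            src = b_cols[src_base]
            src_total = src.sum()
            present = np.flatnonzero(src / max(src_total, 1) > 1e-4)
            present = np.array([i for i in present if i not in contam_idx], dtype=int)
            if present.size == 0 or cfg.transmission_n_otus == 0:
                continue
            n_pick = min(cfg.transmission_n_otus, present.size)
            picks = rng.choice(present, size=n_pick, replace=False)
            for i in picks:
                # seed as presence: abundance mirrors the source but is
                # capped at 0.2% so transmission never reshapes the
                # infant's bin-level composition
                frac = min(src[i] / src_total, 0.002)
                add = max(2, int(round(frac * child_total)))
                child_col[i] += add
                seeded.append(b_otus[i])
        transmitted[child_base] = sorted(set(seeded))

    # ---- assemble --------------------------------------------------------
    def build_table(cols: dict[str, np.ndarray], otus: list[str], suffix: str) -> CountTable:
        bases = [r["base"] for r in meta_rows]
        mat = np.column_stack([cols[b] for b in bases])
        return CountTable(tuple(otus), tuple(f"{b}_{suffix}" for b in bases), mat)

    bacteria = build_table(b_cols, b_otus, "16S")
    fungi = build_table(f_cols, f_otus, "ITS2")

    meta_frames = []
    for suffix, domain in (("16S", "bacteria_16S"), ("ITS2", "fungi_ITS2")):
        df = pd.DataFrame(meta_rows).copy()
        df["sample_id"] = df["base"] + f"_{suffix}"
        df["domain"] = domain
        meta_frames.append(df.drop(columns=["base"]))
    metadata = SampleMetadata(
        pd.concat(meta_frames, ignore_index=True)[
            ["sample_id", "subject_id", "mother_subject_id", "age_days",
             "age_bin", "sample_type", "domain", "batch"]
        ]
    )

    taxonomy = TaxonomyTable({**b_lineages, **f_lineages})
    truth = {
        "contaminants": {s: sorted(ids) for s, ids in contaminants.items()},
        "carryover_otus": carryover,
        "transmitted": {f"{c}_16S": otus for c, otus in sorted(transmitted.items())},
        "age_effect": "flat" if cfg.flat_bacterial_profiles else "succession",
        "fungal_age_effect": "flat",
        "config": dataclasses.asdict(cfg),
    }
    return SimulatedStudy(bacteria, fungi, metadata, taxonomy, truth)


def write_study(study: SimulatedStudy, out_dir: str | Path) -> None:
    """Emit the TSV inputs every other module consumes, plus a truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_count_table(study.bacteria, out / "counts_16s.tsv")
    write_count_table(study.fungi, out / "counts_its2.tsv")
    write_taxonomy(study.taxonomy, out / "taxonomy.tsv")
    write_metadata(study.metadata, out / "metadata.tsv")
    with open(out / "truth.json", "w") as fh:
        json.dump(study.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
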