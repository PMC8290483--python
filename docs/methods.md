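# Methods

This note documents the statistical procedures, the synthetic cohort
model, the numerical choices, and the limitations of `otukit`.

## Quality control against sequencing blanks

Reagent contamination is detected from template-free blanks co-sequenced
with the specimens. For every OTU, within each stratum:

* **blank prevalence** — fraction of blanks with count > 0. A blank counts
  as positive at any read (no minimum), since the operative notion is
  "present". Only OTUs in *strictly more than* the threshold (default
  50%) of blanks are contamination candidates.
* **dispersion score** — geometric mean plus one sample standard
  deviation of the OTU's counts, computed separately over blanks and over
  specimens. The geometric mean uses the pseudocount form
  `exp(mean(log(c+1))) - 1`, which is defined for zero counts and
  converges to the plain GM for large counts; the SD uses the n−1
  denominator and is 0 for a single observation.

Candidates whose blank score exceeds their specimen score are **removed**:
their reads are better explained by the reagents than by the specimens.
The remaining candidates — abundant taxa that also leak into blanks
through carryover — are **background-subtracted**: the arithmetic mean
plus one SD of the blank counts is subtracted from every specimen count,
rounded down and floored at zero (subtraction therefore never creates
negative counts and never increases a count). The keep/remove/subtract
partition is exhaustive and exclusive by construction: no numeric "high
abundance" cutoff is needed, because the two branches split the candidate
set by the dispersion comparison alone.

Breast-milk specimens are extracted and amplified separately from stool
and have their own blanks, so QC runs per stratum and the cleaned tables
are recombined afterwards (union of surviving OTUs, zero-filled). A
stratum without blanks passes through with a warning — which also makes
decontamination idempotent: re-running it on an already-cleaned table
(which has no blank columns left) changes nothing.

Samples with total counts strictly under `min_sample_depth` (default
1,000) are removed after subtraction; both the pre- and post-subtraction
totals are recorded. Ordering subtraction before depth filtering follows
the procedure's natural reading; the alternative order would only differ
for samples within a blank-background of the cutoff.

Positive-control samples (cloned single-template DNA) are excluded from
every statistical analysis; they exist to verify the sequencing run, not
the biology.

## Alpha diversity

Each retained sample is subsampled **without replacement** to a common
depth (exact multivariate hypergeometric draws), defaulting to the
minimum retained total; the depth used is recorded in every report.
A single rarefaction draw per sample is the default (with the seed
recorded); a replicate option averages over draws. Observed richness
counts OTUs with positive rarefied count; Shannon diversity is
`-sum p ln p` in natural-log units.

Each age bin is compared to the adult reference bin — mothers of
one-month-old infants ("Mother-wk4"), the cohort's adult microbiota —
with a two-sided Wilcoxon rank-sum test, Bonferroni-corrected over the
bins tested. Rank-sum tests use the exact null distribution when both
groups have ≤ 12 observations and the pooled sample is tie-free, and the
normal approximation with continuity and tie corrections otherwise; when
the U statistic sits exactly at the null center the two-sided p is 1 by
symmetry (the continuity-corrected approximation would otherwise report
~0.96 for two identical samples).

## Community composition

Bray–Curtis dissimilarities are computed on **unrarefied** cleaned counts
(subsampling is specified for alpha diversity only; a rarefied mode is
available). The variance-partitioning test for a continuous covariate is
the distance-matrix analogue of simple regression: squared distances are
Gower-centered (`G = J(-d²/2)J`), the model sum of squares is
`tr(HGH)` for the hat matrix of `[1, covariate]`, and
`pseudo-F = (SS_model/1) / (SS_residual/(n-2))`. Significance permutes the
covariate across samples, `p = (1 + #{F* ≥ F}) / (1 + n_perm)`; when
`n! ≤ n_perm` the full permutation group is enumerated and the p-value is
exact. If the covariate explains the distances perfectly (zero residual,
possible for constructed rank-one geometries) the pseudo-F is reported as
infinite and the permutation comparison still behaves correctly. The
implementation is cross-checked in the tests against R vegan's `adonis2`
and against exhaustive enumeration.

Convergence toward the oldest bin ("MOL 57-63", the 5-year-olds) collects
every bin member's distance to every reference member and compares that
distribution to the reference bin's internal pairwise distances with a
rank-sum test, Bonferroni-corrected. Repeated appearances of the same
reference individual across distances are treated as independent
observations — a simplification inherited from the procedure being
reproduced; its effect is anti-conservative p-values, which is why the
per-bin median distances (not only the p-values) are reported.

Ordination (NMDS) is deliberately excluded: it is visualization, not
inference.

## Mother–infant shared OTUs

Presence means relative abundance **strictly above** 0.01% (so one read
in exactly 10,000 is absent). Related pairs link a child's stool sample to
a sample from the child's own mother; candidate unrelated pairs are all
other child × mother combinations *within the same postpartum window and
maternal specimen type* (week-1 stool, week-4 milk, etc.), keeping the
null comparison free of window and specimen composition effects. Because
unrelated candidates vastly outnumber related pairs, each test draws an
equal-size uniform subset without replacement; the default is a single
recorded draw, and a multi-draw mode reports the p-value distribution and
its median to quantify the subsampling variability a single draw hides.
The most commonly shared OTUs are ranked by the number of related pairs
sharing them, annotated with mean relative abundance in children vs.
mothers to show the direction of enrichment.

## Genus-level differential abundance

OTU counts aggregate by genus assignment; OTUs unresolved at genus level
keep their deepest resolved rank as a prefixed label
(`f__Enterobacteriaceae`), so "genus level or above" taxa remain
countable, and OTUs with no taxonomy pool under `Unclassified`.
Aggregation conserves column sums exactly. Tests run on relative
abundances (the quantity the corresponding figures display) with
per-genus two-sided rank-sum tests and Benjamini–Hochberg adjustment.
The OTU-level negative-binomial Wald analysis that this confirms in the
original workflow is out of scope here by design: it belongs to an
external tool, and this package implements only the analysis it owns.

## The synthetic cohort generator

The generator produces truth-labelled studies with the structure the
pipeline assumes; it is the test bed for every stage.

**Design.** Nine child age bins from the first week of life to 5 years
(day-of-life bins 0–5 through 165–200, month-of-life bins 11–13 through
57–63), with the two youngest-infant bins formed by the mother–infant
pairs (default 15 per window) and 12 samples in each remaining bin;
mothers contribute stool and breast milk one and four weeks postpartum;
4 stool blanks and 2 milk blanks per domain; 2 positive controls.

**Composition model.** A hierarchical Dirichlet-multinomial. Each bin has
a genus-level mean profile (the succession: Escherichia-dominant in the
first weeks, Bifidobacterium-dominant from one month to a year,
Prevotella-dominant thereafter and in the adult-like bins; maternal
week-1 profiles Escherichia-rich and Prevotella-poor; milk dominated by
skin taxa; fungal profiles Candida-dominated and identical across ages).
A sample's genus composition is a Dirichlet draw around its bin profile
(concentration 50 — visible but not overwhelming between-subject
variation). Each genus's mass then splits across its 12 OTUs by a
per-sample Dirichlet draw (concentration `kappa × backbone`) around a
study-level sparse backbone (Dirichlet 0.3) — the "strain pool": every
genus is dominated by one or two OTUs, and which tail OTUs a subject
carries is individual. `kappa` rises with age (factor 0.15 in the first
week to 1.0 from age 3), encoding the strain-poor newborn gut and
producing the increasing OTU-level richness and evenness the age gradient
requires. Read depths are log-normal (mean 10,000, sigma 0.35) with a 3%
fraction forced under 1,000 reads to exercise the depth filter; 30% of
fungal stool samples are fungus-free (all-zero).

**Transmission.** Each related infant receives a configurable number of
OTUs (default 20) copied from its mother's realized stool and milk
compositions: only OTUs present above the 0.01% threshold and only real
taxa (never reagent contaminants) are eligible, and the copied abundance
mirrors the source but is capped at 0.2% so seeding marks presence
without reshaping the infant's bin-level composition. Because unrelated
mothers share the common backbone but not the individual tail, the
seeded OTUs create excess sharing specifically with the infant's own
mother. Setting the count to 0 makes related and unrelated pairs
exchangeable — the null case used for calibration.

**Contamination.** Reagent contaminants (classic kit genera: Ralstonia,
Sphingomonas, Methylobacterium, Burkholderia for stool; Bradyrhizobium,
Pelomonas, Acinetobacter for milk) appear in every blank of their stratum
(Poisson mean 300, clipped to ≥ 1 so blank prevalence is 1 by
construction) and leak into specimens at Poisson mean 0.5 — satisfying
the removal rule by construction, which is what makes the sensitivity
check meaningful. A second class, carryover of the stratum's dominant
real OTUs into blanks at Poisson mean 4, exercises the subtraction
branch.

**What the generator does not emulate**, and hence what passing tests do
not show about real data: compositional zero-inflation beyond the
Dirichlet tail, phylogenetic correlation between OTUs, batch and primer
effects, chimeras and index hopping, true strain genomes (transmission is
presence-copying, not strain tracking), within-subject longitudinal
correlation (the design is cross-sectional), and any fungal age trend.

## Problem sizes and determinism

Calibration checks run at desk scale as the package's own test design:
200 null replicates for the permutation test's type-I error, 100
simulated studies each for contaminant-recovery sensitivity, sharing-test
null and power (power at 30 seeded OTUs, 15 pairs), and the end-to-end
age-structure reproduction at the default preset. All randomness in the
package flows from explicit seeds threaded through `AnalysisConfig` /
`SimulationConfig`; every report records the seed, and identical seeds
give byte-identical outputs (this is itself under test).

## Known limitations

* The blank rule is a hard classifier; it has no notion of contamination
  probability and cannot use DNA-concentration information
  (frequency-based contaminant models are out of scope).
* The convergence test's rank-sum p-values ignore the dependence among
  distances sharing a reference individual (see above).
* The single-draw unrelated-pair comparison inherits subsampling noise;
  use `n_resample_draws > 1` to see it.
* Genus aggregation trusts the input taxonomy; no re-classification is
  attempted.
* BIOM support is read-only and covers the common HDF5 CSR layout.
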