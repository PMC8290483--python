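# otukit

Analysis pipeline for paired bacterial (16S) and fungal (ITS2) amplicon
OTU tables from a mother–infant cohort study: blank-based decontamination,
rarefied alpha diversity with an adult-reference comparison, Bray–Curtis
community analysis with permutational variance partitioning on age,
mother–infant shared-OTU testing against a resampled unrelated-pair null,
and genus-level differential abundance — together with a truth-labelled
synthetic cohort generator that makes every stage testable without any
sequencing data.

## Who this is for

Microbiome researchers analysing cross-sectional amplicon surveys of gut
community succession — in particular study designs with age-binned child
stool samples, maternal stool and breast-milk samples, and template-free
sequencing blanks — who want the bespoke statistics of such studies as
tested, reusable, seed-reproducible code rather than one-off scripts.

## The statistics at the core

**Decontamination.** With blank counts $b_1..b_m$ and specimen counts
$s_1..s_n$ for an OTU, define the dispersion score
$D(c) = \mathrm{GM}(c) + \mathrm{SD}(c)$ with
$\mathrm{GM}(c) = \exp(\overline{\ln(c_i+1)}) - 1$. An OTU present in
strictly more than 50% of blanks is **removed** if $D(b) > D(s)$
(blank-driven reads), otherwise its blank background
$\bar b + \mathrm{SD}(b)$ is **subtracted** from every specimen, floored
at zero. Breast milk is processed against its own blanks, then recombined
with stool. Samples under 1,000 total reads are dropped.

**Alpha diversity.** Counts are rarefied (exact without-replacement
subsampling) to a common depth; observed richness and Shannon diversity
$H = -\sum_i p_i \ln p_i$ are compared per age bin against the adult
reference bin (mothers four weeks postpartum) with two-sided Wilcoxon
rank-sum tests, Bonferroni-adjusted over bins.

**Community composition.** Bray–Curtis dissimilarity
$d(x,y) = \sum_i |x_i - y_i| / \sum_i (x_i + y_i)$ on counts. Variance
explained by age uses the distance-matrix linear model: with
$A_{ij} = -\tfrac12 d_{ij}^2$, Gower-centered $G = JAJ$, and hat matrix
$H$ of the design $[\mathbf{1}, \text{age}]$,
$R^2 = \mathrm{tr}(HGH)/\mathrm{tr}(G)$ and the pseudo-F is tested by
permuting the covariate (exhaustively when $n! \le$ the permutation
budget). Convergence toward the adult-like 5-year bin compares each bin's
distances to that bin against the bin's internal spread.

**Sharing.** An OTU is present when its relative abundance exceeds 0.01%
(strictly). Related mother–infant pairs' shared-OTU counts are compared to
an equal-size uniform draw of unrelated child × mother pairs from the same
postpartum window and specimen type.

**Differential abundance.** OTUs aggregate to genus (or deepest resolved
rank); per-genus rank-sum tests on relative abundance between the two
maternal windows are Benjamini–Hochberg adjusted.

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
cohort (`--seed 1` throughout; outputs under `results/`):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_decontaminate.py
python analysis/03_alpha_diversity.py
python analysis/04_community_composition.py
python analysis/05_mother_infant_sharing.py
python analysis/06_maternal_diffabund.py
```

which prints (abridged):

```
bacteria_16S: removed 7 contaminant OTUs, background-subtracted 4, dropped 2
  samples under 1000 reads; retained 159 OTUs x 172 samples
bacteria_16S: rarefied to 1062 reads; Shannon differs from the adult reference
  in 6 bins (DOL 0-5, DOL 26-35, DOL 13-17, DOL 83-115, MOL 11-13, MOL 22-26)
fungi_ITS2:   rarefied to 4411 reads; Shannon differs ... in 0 bins (none)
bacteria_16S: age explains 21.7% of community variance (p = 0.001);
  7/8 bins differ from the MOL 57-63 bin
fungi_ITS2:   age explains 1.7% of community variance (p = 0.131)
bacteria_16S mother_stool wk1: related pairs share more OTUs
  (median 28 vs 24, p = 0.00171)
fungi_ITS2 mother_stool wk1:   related pairs share more OTUs
  (median 39 vs 38, p = 1)
5 of 12 genera differ between maternal windows (BH-adjusted p < 0.05)
  higher week 1: Escherichia, Streptococcus, Blautia
  higher week 4: Prevotella, Bifidobacterium
```

Reading: all 7 spiked reagent contaminants were caught by the blank rule;
child bacterial diversity stays below adult levels through the second year
and catches up by age 3–5; age structures the bacterial but not the fungal
communities; infants share more bacterial (but not fungal) OTUs with their
own mother than with unrelated mothers; and the maternal stool community
shifts from Escherichia-rich in the first postpartum week to
Prevotella-dominant by the fourth.

The same pipeline runs on real tables through the CLI
(`otukit decontam|alpha|beta|shared|diffabund|run-all --help`), reading
TSV count/taxonomy/metadata tables (BIOM 2.x read-only).

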