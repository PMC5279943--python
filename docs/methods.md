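# Methods notes

This note records the models behind each stage, the tunable constants and
their defaults, what the synthetic-data generators do and do not emulate,
and the choices made where the design was genuinely open.

## Phenotype model

An ECG record is a (RR, QT) pair in ms. Rate correction divides QT by a
power of RR expressed in seconds: Fridericia uses exponent ⅓, Bazett ½;
both are the identity at RR = 1000 ms. The clinical phenotype is
ΔQTcf = QTcf(post-drug) − mean of the baseline-replicate QTcf values, with
each replicate corrected before averaging.

Extreme-arm selection takes the largest ΔQTcf values strictly above the
high threshold (default 35 ms) and the smallest strictly below the low
threshold (default 5 ms), at most `n_per_arm` (default 10) each, implying a
minimal 30 ms separation. Values exactly at a threshold join neither arm —
the selection rule is stated with strict inequalities and we read it
literally; this only matters on a set of measure zero for continuous data.

Design power treats the quoted "standard error of 15 ms" as the common
within-group SD: with n = 10 per group, a 20 ms difference and α = 0.05 the
noncentral-t closed form gives ≈ 0.807, matching the quoted 80%; no other
reading of the phrase reproduces that number. `power_two_sample` always
reports both the closed form and a seeded Monte-Carlo estimate so the two
can be checked against each other.

## MEA model

Within a recording, beats yield aligned inter-beat intervals (IBI, ms) and
raw field-potential durations (FPD, ms). The rate law is
FPD = F₀·(IBI/1000)^α; α is re-estimated per line by ordinary least squares
on log FPD vs log(IBI/1000) over baseline beats (pooling recordings is the
fallback when a line lacks ≥3 distinct rates; both modes are available and
neither is canonical). The over-correction diagnostic regresses adjusted
FPD on IBI: adjusting α = 0.35 data with Bazett's exponent ½ leaves a
significantly negative slope, while the fitted exponent leaves none.

Dose-response uses the mean aFPD over each 2-minute recording, expressed as
a fractional change from the vehicle recording. Hill fits
r(c) = Emax·cʰ/(cʰ + EC50ʰ) run from a multistart grid (7 log-spaced EC50
starts spanning the tested range ±1 decade × h ∈ {0.7, 1, 2}); EC50 is
parameterised on the log scale, h is fitted within [0.5, 4] rather than
fixed at 1, and an EC50 outside the tested span raises a warning rather
than an error (extrapolated potency).

The arrhythmia rule is qualitative in origin ("ectopic beats or irregular
rate"); the constants realising it are repo-defined and configurable:
ectopic = any IBI < 0.8 × median IBI; irregular = CV(IBI) >
max(0.10, 2 × baseline CV).

Line QC drops lines with a maximal reference-blocker (E4031) FPD change
below 5% (non-functional hERG response) and lines with an abnormal
karyotype. Classification predicts a high-sensitivity donor when the aFPD
change at 30 µM sotalol strictly exceeds 25%; ties go to low.

The repeated-measures ANOVA is the classical split-plot decomposition:
group (between lines) is tested against lines-within-groups;
concentration and group × concentration against the
concentration × lines-within-groups error. The implementation returns the
full sums-of-squares table (they add up to SS_total by construction) and is
cross-checked against `pingouin.mixed_anova` in the tests. Missing cells
raise; nothing is imputed.

## Genetics

MAF = Σ dosage / (2 × non-missing subjects); missing genotypes shrink the
denominator per SNP per group (standard practice). The imbalance screen
compares groups with a two-sided Fisher exact test on the 2×2
minor/major **allele-count** table — the genotype-level alternative is not
used because group MAFs are the quantity being contrasted — and applies no
multiplicity correction: the screen is an exploratory ranking. Genomic
intervals are 0-based half-open everywhere, including the BED reader.

The packaged SNP table carries printed per-group MAFs and p-values as
annotations: reconstructed allele-count Fisher tests do not reproduce every
printed p-value (the original software's test is unspecified), so the
fixture is data, not recomputed truth.

## Transcriptomics

Depth equalisation removes reads uniformly without replacement until every
library matches the smallest total (a multivariate-hypergeometric draw per
sample), so that detection sensitivity — the number of genes with nonzero
counts — is comparable across samples. FPKM = counts·10⁹/(length·total).

The DEG statistic is a Welch t on log2(FPKM+1) with Benjamini-Hochberg
control, isolated behind `deg_test` so it can be swapped; a gene is called
at q ≤ 0.05 and |log2((FPKM_A+1)/(FPKM_B+1))| ≥ log2 1.3 on group-mean
FPKM. "Up" in a female-vs-male comparison means higher in the female
group; this sign convention is declared, not derived.

For the 2-vs-2 netto comparisons a per-gene variance floor (the pooled
10th-percentile gene variance) guards against zero-variance degeneracy, and
because that floor is estimated from thousands of genes it is treated as
known: the statistic is referred to a standard normal instead of a
df ≈ 2 Welch t. Without this moderation no 2-vs-2 comparison can survive
BH adjustment at any effect size and the netto statistic would be
identically zero, which would defeat its purpose as a confound diagnostic.
The netto count is (up − down detections)/n_combinations ∈ [−1, 1]; the
quadrant rule calls a gene gender-consistent when its group fold change and
netto count share a nonzero sign, with a configurable |netto| < 0.1 zero
band below which no gender trend is claimed (the quadrant plot is read
qualitatively; the band makes that reading explicit).

## Network analysis

Interactome merging pools 2-column edge lists, maps non-upper-case (i.e.
non-human-cased) symbols through the orthology map **before** filtering to
official symbols (matching the stated order of operations), drops unmapped
or invalid nodes with their edges, removes self-loops, deduplicates
unordered pairs and keeps per-edge source provenance. Candidate genes are
differentially expressed members of the union adjacency of the seed genes,
excluding the seeds themselves (seeds are the disease genes, drawn as a
separate node class; their own expression is compared separately) — the
exclusion is explicit and configurable. TF enrichment is a one-sided
hypergeometric tail on target-set overlap with the DE genes; the background
defaults to the genes present in the expression matrix, since no other
universe is defined. Ranking is by ascending p with deterministic
tie-breaks (larger overlap, then symbol order).

## Synthetic-data generators

All generators are pure functions of their spec (seed included). They
emulate the statistical structure each stage consumes — not the raw
signals: no sequencing reads, no electrode voltage traces, no
action-potential waveforms.

- **Cohort** (default n = 92): latent per-subject QTc ~ N(399, 18.6²) ms,
  RR ~ N(950, 120²) ms, QT from the ⅓-exponent rate law plus N(0, 4²) ms
  measurement noise; the post-drug shift is a two-component mixture with
  means 48.5 and 0.2 ms (SD 10 ms), mixing proportion 0.48 so the overall
  mean lands at ≈23.4 ms. The mixture is a deliberate simplification of
  the real, presumably continuous sensitivity distribution: it gives every
  subject a recoverable latent label.
- **MEA panel** (default 14 lines, 7 vs 7): per-line rate drawn around
  1200 ms (across-line SD 150 ms; within-recording SD 40 ms — spontaneous
  rate varies much more between lines than within a 2-minute recording),
  F₀ = 300 ms, true α = 0.35, Hill prolongation with EC50 20 vs 60 µM and
  Emax 52% vs 27% for high- vs low-sensitivity classes (chosen so the
  class separation at 30 µM brackets the 25% threshold), h = 1,
  multiplicative FPD noise CV 2% (a free parameter — no measurement-noise
  model is prescribed anywhere). Ectopic injection replaces a random 5% of
  IBIs by 0.5 × median in flagged classes at the two highest doses; this is
  one concrete realisation of "ectopic beats", not a quantitative claim.
- **Expression** (default: the 17-sample panel layout, 9 high/8 low with
  the gender imbalance): negative-binomial counts (Poisson at
  dispersion 0) around lognormal baseline abundances, library totals
  uniform in [3·10⁵, 6·10⁵] (scaled down from real RNA-seq depths to keep
  simulation cheap; all statistics of interest are ratios and are
  depth-calibrated by the equalisation step), 50 planted group genes and
  50 planted gender genes at |lfc| = 1.5, disjoint by construction.
- **Genotypes**: dosage ~ Binomial(2, MAF_group) i.i.d. across subjects —
  no linkage disequilibrium, which a real chip would show.
- **Interactome**: Erdős–Rényi background (200 nodes, p = 0.02) over
  background + seed nodes, seeds chained so all 15 appear, and 4 up / 1
  down planted neighbors each wired to ≥1 seed. Real interactomes are
  scale-free and modular; nothing here depends on degree distribution, so
  the ER background suffices for recovery testing.

Passing tests on these generators show the estimators recover the planted
structure under the declared noise; they do not show robustness to
real-data pathologies (batch effects, LD, hub bias, waveform artefacts).

## Problem sizes and numerical choices

Tests run the generators at reduced sizes (1000–3000 genes, 100–200 beats,
100-seed recovery loops) — large enough for the Monte-Carlo tolerances
used (3·SE bands), small enough to keep the suite quick. Monte-Carlo
acceptance quantities use 50,000 replicates. Tolerances: α recovery
median error < 0.05; EC50 median relative error < 20% at 5-dose sampling;
exact-test comparisons to enumeration oracles at rel 10⁻⁹. Degenerate
inputs raise (`ValueError`) rather than warn: all-equal IBIs, constant
Hill response, missing ANOVA cells, zero-total libraries, empty groups.

## Known limitations

- The DEG statistic is a documented stand-in for the original pipeline's
  transcript-model test; absolute DEG lists will differ, which is why the
  fold-change/FDR rule and the confound statistic, not specific gene
  identities, are the tested contract.
- The Fisher screen is allele-based; printed p-values from the original
  genotype analysis are carried as annotations only.
- Classification and QC operate on recording summaries; no spike-level
  processing is attempted.
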