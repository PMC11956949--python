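# Methods

## The analysis problem

A bioorthogonal labeling experiment distinguishes newly synthesized
extracellular-matrix (ECM) proteins from pre-existing scaffold protein.
Human tumor cells grown on decellularized rat ECM (or as scaffold-free
tumoroids) incorporate Ac4GalNAz into the glycans of newly made
glycoproteins; click capture and streptavidin enrichment yield *eluate*
samples, paired with bulk *input* lysates. Label-free quantification
gives one protein-group × sample intensity matrix per search
configuration, with zero meaning "not observed". The analysis must
normalize samples, handle missing-not-at-random zeros, test for
differential deposition, summarize matrisome composition and species
selectivity, and quantify immunofluorescence validation images.

## Sum normalization

Within a *scope* (a set of samples normalized together), each sample is
scaled by `Sum_average / Sum_sample`, where the sums run over a chosen
protein subset and `Sum_average` is the scope mean of the original
sums. Consequences asserted in tests: post-normalization subset totals
are equal within a scope (relative tolerance 1e-9); the operation is
idempotent; a single-sample scope is the identity; zeros are preserved.
One algebraic subtlety: rescaling one sample's raw values by `c > 0`
leaves its normalized *profile* `X/Sum_sample` unchanged, but the
absolute normalized values shift by the scope-common factor
`Sum_average'/Sum_average`, because the rescaled sample moves the scope
mean. Tests assert the exact form of the invariance.

Scope conventions follow the study design: eluate comparisons within a
model normalize per treatment group over human proteins (the labeled,
cell-derived species); the cross-model comparison normalizes all
labeled eluates together over human proteins; the input workflow
normalizes all inputs together over human + rat proteins. Scope
membership is always declared, never inferred from sample names.

Sum normalization assumes the summed subset's composition is comparable
across samples. When a large intensity mass is genuinely differential
(e.g. heavy spike-ins concentrated in one arm), equalizing totals
deflects null proteins in the opposite direction — a known property of
total-intensity scaling, visible in the simulations and worth keeping
in mind when interpreting cross-group fold changes.

## Filtering, log2, QRILC imputation

Pre-filtering keeps proteins with at least `min_nonzero = 2` nonzero
values in *every* treatment group (the standard "min valid values per
group" convention). Log2 transform maps zeros to an explicit missing
marker.

QRILC (quantile regression imputation of left-censored data) treats
each sample column independently. With `k` observed of `n` total
values, the observed sorted values are regressed on standard-normal
quantiles at Blom plotting positions `(r − 0.375)/(n + 0.25)`, with the
observed ranks `r` placed after the censored count — the observed data
are modeled as the top-`k` order statistics of a complete Gaussian.
Slope and intercept estimate the complete distribution's σ and μ. Each
missing entry is drawn from `Normal(μ, σ·tune_sigma)` truncated above
at the sample's minimum observed value (the empirical detection limit).
Defaults: `tune_sigma = 1.0`; imputation is per sample; at least 3
observed values per sample are required. The exact plotting-position
and truncation conventions of the original R implementation are not
published alongside it; the choices above are one defensible reading,
validated by parameter recovery: on 2000 draws from Normal(25, 2)
censored at the lowest 20%, μ̂ lands within ±0.2 and σ̂ within ±0.3
(single seed), with mean bias within ±0.1 / ±0.2 over ten seeds.

## Differential statistics

Welch's t-test: `t = (x̄_a − x̄_b)/√(s²_a/n_a + s²_b/n_b)` with
Welch–Satterthwaite degrees of freedom and two-tailed Student p. Both
groups constant and equal gives `t = 0, p = 1` (warned); constant with
unequal means is undefined and raises.

Permutation FDR (SAM-style): the same label reshuffle is applied to
every protein; for each observed `|t|` threshold,
`FDR = (mean permuted count ≥ threshold)/(observed count ≥ threshold)`,
clipped to [0, 1]; a protein's q is the minimum FDR over all proteins
at or beyond it in p-rank, making q monotone non-decreasing in p. All
`C(n, n_a)` label assignments are enumerated when there are at most
1000 (e.g. 3-vs-3 → 20; 5-vs-5 → 252); otherwise 250 seeded random
reshuffles. The SAM fudge factor `s0` defaults to 0; the numerator
statistic can be switched from mean to median permuted count. Ties at
the threshold count inclusively (≥). Exhaustive runs match a
brute-force enumeration oracle exactly in tests; under a global null
(1000 proteins, 4 vs 4) the fraction with q < 0.05 stays ≤ 0.07.

Fold changes are ratios of geometric means on the decimal scale, so
`log2FC` equals the difference of group means on the log2 scale.
Volcano categories use strict inequalities (`log2FC > 1` and
`q < 0.05`); boundary equality is non-significant. Auxiliary tests —
pairwise-complete Pearson correlation, two-sided Grubbs single-outlier
test (critical value from the t distribution), paired t, one-way ANOVA
with Tukey HSD at 95% confidence — are validated against independently
coded textbook formulas and scipy cross-checks.

## Workflows

* `run_search1_within_model`: eluates of one model, GalNAz vs vehicle —
  per-treatment normalization (human subset) → pre-filter → log2 →
  Welch + permutation FDR on complete cases → volcano. Proteins that
  fail the filter or are incomplete are reported separately by group
  mean intensity (they cannot support the test but still carry
  presence/absence information).
* `run_search1_cross_model`: GalNAz eluates, dECM-tumor vs tumoroid —
  single-scope normalization (human subset) → log2 → QRILC → Welch +
  permutation FDR → volcano. All-zero rows are dropped before
  imputation (they carry no information and would be pure draws).
* `run_search2_species`: original-value human/rat totals, eluate vs
  input, as percent change `(E − I)/I × 100`.
* `run_search3_inputs`: all inputs normalized together over all
  proteins; normalized table plus per-sample scale-factor summary.

Outlier handling is advisory: `sample_qc` reports pairwise correlations
and a Grubbs screen on per-sample identification counts; removal is an
explicit caller decision, never automatic. Stage order is fixed
(normalize → log2 → impute); every result records the parameters and
seed that produced it, and identical config + seed reproduce outputs
byte-identically.

## Glyco modification masses

Monoisotopic atomic masses are pinned in source (C 12 exactly,
H 1.0078250319, N 14.0030740, O 15.9949146, S 31.97207117). The GalNAz
glycan residue is C8H12N4O5 — a HexNAc residue with an acetyl hydrogen
replaced by azide — giving +244.0808 Da on Ser/Thr; CuAAC conserves all
atoms of both reactants, so the clicked adduct is the element-wise sum
with alkyne-PEG4-desthiobiotin C21H37N3O6, i.e. C29H49N7O11 at
+671.3490 Da. Both four-decimal masses are reproduced from these first
principles in the test suite, and the definitions export as a plain
text block for search-engine configuration.

## DAPI-map image quantification

Pipeline order is fixed: (1) balance the blue channel by a linear
percentile contrast stretch (1st/99th percentiles by default) — the
"saturation balancing" step of the original acquisition program is not
specified beyond its intent, so the common auto-contrast reading is
implemented and parameterized; (2) binarize at 20% of the *balanced
channel's own* maximum; (3) remove 8-connected components smaller than
`min_component_area` (default 30 px); (4) close with a disk structuring
element (dilation then erosion, default radius 3 px) to connect nuclei
into a tissue footprint. An all-zero blue channel yields an empty map
with a warning (its maximum makes the threshold degenerate). Region
statistics normalize intensities by `2^bitdepth − 1` and report means
inside/outside the mask; marker scores can be normalized by mask area
or by a co-stain channel's inside mean. The defaults recover synthetic
ground-truth masks with Jaccard ≥ 0.8 and inside/outside levels within
2%; on real micrographs the balancing choice and the two structural
parameters are data-dependent and should be checked visually.

## Synthetic-data generators

`simulate_lfq` draws one baseline log2 mean per protein from
`Normal(baseline_log2_mean, baseline_log2_sd)` and adds i.i.d. Gaussian
replicate noise — the simplest structure satisfying the Welch model.
Effects enter as additive log2 shifts: an enrichment shift on human
(labeled-species) proteins in GalNAz eluates, and a true-differential
shift on a chosen fraction of human proteins along one contrast
(`differential_axis`: treatment or model — the two search-1 workflows
probe different contrasts, so the generator exposes which one carries
the planted truth). Censoring is per-sample and rank-based: the lowest
`censor_quantile` fraction of each sample's values becomes zero,
exactly the abundance-dependent left-censoring QRILC assumes; the
ground truth records censored entries and planted effects exactly.

Defaults, chosen once as a realistic rendering of this experiment type:
baseline mean 25 and sd 2 on the log2 scale (typical LFQ intensity
spread), replicate sd 0.5, enrichment `log2(5.3) ≈ 2.4` (the order of
protein-group augmentation such enrichments produce), 10% differential
proteins at log2FC 3, 20% censoring, 5 samples per group across the
full 2×2×2 design. The recovery tests fix the scenario to what each
check needs: spike-recovery for the within-model workflow switches the
enrichment off, because a global enrichment of all human proteins makes
every protein truly differential between treatment arms — there would
be no null set to measure a false-positive rate on.

What the generator does **not** emulate: peptide-level roll-up,
match-between-runs structure, contaminants, intensity-dependent
variance, correlated proteins, or rat-protein depletion dynamics in
eluates (rat eluate levels stay at baseline rather than dropping).
Passing tests therefore demonstrate the correctness and calibration of
the implemented procedures under their own model assumptions, not
performance on real LC-MS/MS data. `simulate_tissue_image` likewise
draws idealized uniform nuclei and flat marker levels — it validates
mask logic and arithmetic, not robustness to uneven illumination or
noise.

## Numerical choices and degenerate inputs

Zeros contribute 0 to normalization sums and remain 0 after scaling. A
zero-total sample in a scope, a sample with < 3 observed values at
imputation, a non-positive σ̂, both-constant-unequal groups in a t-test,
and constant nonzero paired differences all raise named errors rather
than producing silent output. Grubbs with zero spread and imputation
with no missing entries are no-ops with warnings where the contract
says so. Problem sizes in the test suite (≤ 1000 proteins, ≤ 10⁴
t-test replicates, 256² images) were chosen so the whole suite runs in
a few seconds while keeping Monte-Carlo error well inside the asserted
tolerances.
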