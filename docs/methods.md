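# Methods

This note documents the models, the synthetic data that exercises them, the
numerical choices, and the limits of what the test suite demonstrates.

## Meiosis simulator

`simdata` generates haploid segregants of a biparental cross. Each
chromosome is a genetic map of length L Morgans with fixed marker
positions; a gamete starts on either parental haplotype with probability
1/2 and switches at crossover points drawn as a Poisson process with rate 1
per Morgan (the Haldane, no-interference model). Consequences the tests
verify: every marker segregates ~1:1; the recombination fraction between
markers d Morgans apart is (1 − e^(−2d))/2; crossover counts per chromosome
are Poisson(L); and allele agreement between markers decays monotonically
with map distance.

`simulate_structured_population` iterates the same meiosis over
`n_generations` of random mating from `n_founders` founder haplotypes
(founders 0 and 1 are the two "parental" genomes, further founders are
Bernoulli(1/2) haplotypes). Intermediate generations use a modest breeding
pool (default `max(2·n_founders, 12)` lines) so final lines share recent
ancestors — the relatedness structure that makes kinship-based prediction
work on crop panels. Output coding is haploid {0,1} or diploid {−1,0,1}
(dosage of the two final gametes). A two-founder, one-generation population
reduces exactly to `simulate_cross`.

Traits are y = Σβⱼgⱼ + Σγᵢⱼgᵢgⱼ + e. The noise variance is calibrated on
the *realized* genetic score of the generated sample so that
var(genetic)/var(total) equals the requested h² exactly on that sample
(rather than in expectation under the theoretical marker distribution); the
returned vector is standardized to mean 0 and unit (n−1) variance. The
epistatic term is the product of coded alleles, the standard statistical
encoding of pairwise epistasis.

What the generator does *not* emulate: crossover interference, mutation,
genotyping error, selection or selfing, environment-by-genotype structure,
and non-Gaussian trait noise. Passing tests therefore demonstrate protocol
and estimator correctness under the idealized cross model, not performance
on any particular real data set.

## Preprocessing conventions

Genotype files are plain TSV (marker ids in the header, sample ids in the
first column, `NA` for missing) with a separate 3-column map. Imputation is
either per-marker column mean (rice convention) or heterozygote = 0
(wheat convention, diploid coding only); observed entries are never
altered. LD pruning is a greedy left-to-right sliding-window scan (window,
step, r² threshold as in PLINK's `--indep-pairwise`); within a window the
later-positioned marker of an offending pair is removed, and constant
markers are defined to have r² = 0 with everything. Output parity with any
external tool is not claimed. Phenotype normalization standardizes observed
entries to mean 0 and unit variance using the n−1 (sample) variance — the
default of the statistical environments used in this field; replicate
averaging (mean of available replicates) precedes normalization.

## Genomic BLUP

K = ZZᵀ/p over polymorphic markers, with Z column-standardized using the
population (n) variance so the mean diagonal of K is exactly 1 — the
VanRaden-style similarity up to scaling. REML profiles μ and σg² out of the
restricted likelihood, leaving a 1-D problem in λ = σe²/σg², solved by
bounded search over log λ on [10⁻⁶, 10⁶] with tolerance 10⁻⁸ after one
eigendecomposition of K (cached on the `GSM` object and reused across
traits and random ratios). σg² = 0 is a documented degenerate case:
predictions equal the fitted mean. With K = I the training predictions
collapse to ridge shrinkage toward the mean, which the tests exploit as a
closed-form oracle.

Heritability recovery is tested with a *polygenic* architecture (50 loci,
N(0,1) effects): REML on data generated from the model itself recovers h²
essentially unbiasedly, while a handful of large equal effects violates the
infinitesimal assumption and biases ĥ² downward (≈0.31 for a true 0.5 in
our experiments). That bias is a property of the estimand mismatch, not a
defect of the optimizer, so the recovery test uses the architecture the
model assumes.

## Sequential QTL mapping

LOD_j = −(n/2)·log₁₀(1 − ρ_j²) is computed for all markers at once from
standardized genotypes; ρ² is clipped at 1 − 10⁻¹² so collinear markers get
a large finite score. The permutation null shuffles the residual vector (B
permutations, default 1000; 40–100 in tests) keeping genotypes fixed, and
the threshold is the smallest observed statistic t with plug-in FDR(t) =
(mean null count ≥ t)/(observed count ≥ t) ≤ the level, with the ratio
clipped at 1 (so level 1 degenerates to the smallest observed value). The
plug-in estimator is a design choice; thresholding on the genome-wide
maximum per permutation is a common alternative and would be more
conservative.

Forward selection runs at most 4 stages. Within a stage, contiguous runs of
significant markers on a chromosome collapse to the single peak-LOD marker
(avoiding an LD block flooding the model); the joint model is refit by OLS
with rank-guarding (later-entering collinear markers are dropped), residuals
are recomputed, and permutations are re-seeded per stage. The interaction
scan computes the LR statistic n·ln(RSS_red/RSS_full) for every (selected
marker m, marker j) pair by Frisch–Waugh residualization against the
additive design followed by sequential orthogonalization of the g_j and
g_m·g_j columns — numerically equivalent to two nested OLS fits (oracle
agreement ≤ 10⁻⁸) and vectorized over j. Degenerate geometry (j collinear
with the base design, or the product column collinear with [base, g_j]) is
handled by dropping the zero-information direction only.

## Learner tuning policies

The numerics (coordinate descent, tree growing, SMO) are scikit-learn's;
this package owns the protocol. Penalized fits tune λ by internal 10-fold
CV over a 100-value log-spaced path auto-scaled from the data (for pure
ridge, which has no auto path, the grid spans ±4 decades around
‖Xᵀy‖∞/n). Elastic-net α defaults to a given mixing value, with the
endpoints α = 0/1 delegating to the pure ridge/lasso routes. Random forest
uses 700 trees, p/3 split candidates (floored at 1) and minimum node size
5, untuned. GBM tunes depth {1,2,3} × shrinkage {0.001,0.01,0.1} with 1000
trees and subsample 0.5 on an internal 70/30 split of the training fold,
choosing the prediction iteration count on the validation part, then refits
on the whole fold. SVR (RBF, ε-insensitive) grids over ε {0.01,0.1,0.5},
C {0.1,1,10,100} and γ (10 log-spaced values in [10⁻⁴,1]) on the same
internal split. A `FAST_POLICY` with reduced grids and forests is provided
for small simulations and is what the test suite uses; defaults match the
full policies above.

## Evaluation engine

cvR² = 1 − Σ(yᵢ−ỹᵢ)²/Σ(yᵢ−ȳ)² over accumulated out-of-fold predictions;
each observed sample is predicted exactly once per CV run, repeats are
averaged over independent random fold partitions (unstratified). Missing
phenotypes are dropped before folding but genotyped samples remain
predictable. For GBLUP the similarity matrix is computed once from all
genotypes — genotypes carry no phenotype information, so this is not
leakage — and indexed per fold. Degradation operators: class noise shifts a
nested random subset of phenotype values by ±2·(original SD) with
independent random signs; marker and sample deletion remove nested random
subsets (nesting reduces cross-level variance); curves report mean degraded
R² / baseline R² per level, undefined (NaN) when the baseline is ≤ 0.
Multi-task stacking concatenates per-trait observation rows and appends a
one-hot trait indicator (scikit-learn estimators take no categorical
dtype, so one-hot serves both tree and linear learners); the test set is
the union of per-trait test sets.

## Rank statistics

Per-trait midranks (rank 1 = most accurate), Friedman χ² with the standard
tie correction C = 1 − Σ(t³−t)/(nk(k²−1)) — the correction is what makes
the statistic reproduce published p-values from tables containing display
ties — and Nemenyi pairwise p-values from the studentized range
distribution with k groups and infinite degrees of freedom at z√2.
Average ranks are displayed with half-even rounding (4.125 → 4.12); raw
values are always retained. The three published accuracy tables shipped in
`phenobench/data/` are transcribed at printed precision; statistics
recomputed from rounded tables can differ in the last digit from values
computed on unrounded accuracies (observed for the Nemenyi p-values, e.g.
3.9×10⁻⁸ recomputed vs 3.4×10⁻⁸ published for the top pair).

## Marker fusion

Gene+intergenic fusion emits one majority-vote attribute per gene
containing ≥ 1 marker and one per maximal intergenic marker run (chromosome
ends included); overlapping genes are separate attributes and a marker
under two genes contributes to both; majority ties resolve to 0
(config-exposed). Gene+flanks fusion drops genes fully nested in another
gene and assigns each remaining gene the region from the midpoint to its
left neighbour to the midpoint to its right neighbour. Fusion is defined
for haploid coding. The prediction-parity property (fused ≈ raw accuracy)
holds in the dense-marker regime where within-block markers are redundant;
the parity test uses 120 markers/Morgan, chosen to emulate the marker
density of a fully genotyped cross (a sparse map makes fusion lossy by
construction).

## Problem sizes and known limitations

The suite runs everything at synthetic scale chosen for completeness of the
statistical checks: crosses of 300–1000 segregants over 90–200 markers,
20-replicate recovery experiments, 200 null traits for FDR calibration,
100 permutations in test configurations. One directional claim is not
reproduced at this scale and its check is expected to fail: the ordering
"random forest degrades less than GBM under ≥75% class-noise
contamination". In our synthetic experiments (additive and interaction-rich
traits, several grids and sample sizes) the two tree ensembles' accuracy
ratios are statistically indistinguishable, with GBM if anything slightly
more robust — validation-chosen iteration counts act as early stopping and
regularize GBM under noise. The ordering may require the scale and trait
diversity of real data panels. Other limitations: LD pruning does not claim
output parity with external tools; the interaction scan reports all
significant pairs including LD neighbours of a true pair (no pair-level
peak reduction); and SVR tuning grids are coarser than an exhaustive
search.
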