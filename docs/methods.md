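# Methods

This note documents the models, estimators and numerical choices behind
`epistrat`, what the synthetic-cohort generator does and does not
emulate, and the design decisions taken where more than one reasonable
option existed.

## Synthetic cohorts

The generator produces the statistical structure the analysis assumes,
with ground truth attached.

**Counts.** Gene g in sample s is negative-binomial with mean
μ_gs = L_s · 2^(b_g + σ_g z_gs + e_g·1[g marks s's program] + λ_g f_s)
and variance μ + α μ² (gamma–Poisson mixture, dispersion α = 0.2 by
default). Components and defaults:

- library size L_s ~ Uniform(0.5, 2), removed downstream by
  median-of-ratios normalization;
- baseline log2 abundance b_g ~ Uniform(2, 9) — a wide dynamic range so
  count noise (which shrinks with the mean) differs across genes;
- biological noise σ_g ~ Uniform(0.05, 0.9) for background genes. This
  heterogeneity is what gives the epifactor panel a continuum of
  per-gene SDs for the variable-gene selector to cut through; signature
  genes use σ = 0.3 so the between-program shift dominates;
- program effect e_g ~ N(2.0, 0.5) log2 units (clipped below at 0.5),
  applied to the 40 signature genes of the sample's program;
- proliferation module: 30 non-epifactor genes (the first named
  literally `PCNA`) at high baseline (2⁹) share a standard-normal latent
  factor f_s with loading λ solved so each gene's correlation with the
  factor is √prolif_cor, giving gene–PCNA correlations near prolif_cor
  (0.8) after count noise.

Samples split evenly between programs. Signature genes live inside the
720-gene epifactor block; the proliferation module outside it, since the
meta-PCNA signature is genome-wide rather than epifactor-specific.

**Survival.** Each endpoint (PFI, DSS, OS) is an independent exponential
time with hazard h_s = h₀ · exp(β·1[program 2] + 0.1·(age−60)/10), with
h₀ = 10⁻³ events/day and β = 0.7 by default. Censoring is uniform
administrative on (0, c_max), with c_max solved by bisection so the
expected censored fraction matches `censor_frac` (0.4). Exponential
hazards satisfy proportional hazards exactly, matching the Cox models
downstream; the small age effect makes age a real (if weak) confounder
for the adjustment machinery to absorb.

**Metadata.** Two purity metrics ~ Beta(8,2) and Beta(6,2) (most samples
pass a 0.70 threshold, some do not); age ~ N(60, 10) clipped to
[18, 90]; sex balanced. The epifactor annotation assigns each of the 720
epifactors a functional category, optionally a writer/eraser/reader
subrole and a deposited mark, and membership in a closed vocabulary of
19 multiprotein complexes (8–30 members each).

**Replicates.** Gene-level structure (which genes are signatures, their
baselines and effects, the annotation) is a function of the seed alone;
sample-level randomness additionally depends on a `replicate` index.
`generate_cohort(cfg, replicate=1)` is therefore a held-out cohort from
the same population — required for honest train/validate experiments.

**Single cells.** Cells belong to four groups (none/A/B/both); groups
over-express the corresponding program signatures by the bulk effect
size. Counts are NB at 1/128 of bulk depth and the matrix is
log2(1 + CP10K).

**What is not emulated.** No batch effects, no purity-driven expression
mixtures (purity is metadata only), no isoforms, no gene–gene
correlation beyond the planted modules, no informative censoring, no
cell-type hierarchy in the single-cell matrices. Tests passing on these
cohorts demonstrate that the estimators recover planted structure under
their own model assumptions; they do not certify performance on real
tumors, where those assumptions fail in various ways.

## Preprocessing

Size factors are median-of-ratios: genes with a zero in any sample are
excluded from the reference; each sample's factor is the median of
count/geometric-mean over reference genes. Normalized expression is
log2(count/factor + 1); the pseudocount of 1 bounds zero counts at 0.
Variable epifactors are those with SD (denominator n−1) above a cutoff;
in automatic mode the cutoff is searched over the SD quantile grid
(steps of 0.005) for a panel size inside [500, 600], returning the
closest achievable size with a flag when the range is unreachable. The
purity filter keeps samples where **any** purity metric passes the
threshold, and flags cohorts smaller than 70 after filtering.

## Consensus NMF and rank selection

`nmf_factorize` implements multiplicative updates for the generalized
KL divergence (the Brunet variant), with uniform random initialization
scaled to the data mean, an explicit per-iteration objective trace
(non-increasing by construction; asserted in tests) and a relative
objective-change stopping rule. Divisions are guarded at 1e-12.

Consensus clustering runs the factorization `n_runs` times (seeds
seed+r), assigns each sample to its argmax H row per run, and averages
co-clustering indicators. Final labels come from cutting the
average-linkage dendrogram of (1 − consensus) at k, so labels are a
function of the consensus rather than a single run. Validation metrics:

- **cophenetic coefficient** — Pearson correlation between the
  consensus distances and the dendrogram's ultrametric distances;
  NaN with a warning when the distances are constant;
- **mean silhouette** — Euclidean, computed in the variable-gene
  expression space by default (a `metric_space="consensus"` switch uses
  1 − consensus instead; which space the original workflow used is
  ambiguous). Singleton clusters contribute 0;
- **connectivity** (Handl) — Σᵢ Σⱼ₌₁..L 1/j over the j-th nearest
  neighbors with a different label; L = 10, distance ties broken by
  sample index for determinism.

`select_rank` lets each metric vote for its best rank (higher better
for cophenetic/silhouette, lower for connectivity) and returns the
majority, with ties resolved to the smallest rank.

Signature genes use the Kim–Park score
s = 1 + (1/log₂k) Σ p log₂ p (0·log 0 = 0) on normalized basis rows; a
gene is selected when s > mean + 3·SD of all scores and its maximal
loading exceeds the median of W, and is assigned to its argmax basis
(lowest index on ties). Because basis order in a single fit is
arbitrary relative to the consensus labels, `align_signatures` maps each
basis to the consensus cluster its samples majority-vote for. With two
clusters, the one with lower Kaplan–Meier survival at the cohort's
median follow-up time is labeled "poor" (tie-break: sign of the log-rank
O − E); solutions with no events are left unlabeled and flagged.

## Survival analysis

The Kaplan–Meier estimator, the Mantel–Cox log-rank test (hypergeometric
variance, any number of groups) and the Cox model are implemented
directly; the Cox fit maximizes the Efron partial likelihood by
Newton–Raphson with step halving, converging at a relative
log-likelihood change of 1e-9 or 25 iterations. Monotone likelihood
(perfect separation) is reported via `converged=False` and a flag when a
coefficient exceeds 10 in absolute value or a standard error degenerates
(non-finite or > 100). Estimates agree with `lifelines` to ~1e-4 in the
test suite, and the score test at β = 0 reproduces the log-rank
statistic on tie-free data to 1e-6.

The per-gene prognostic screen dichotomizes each gene at the optimal
cutpoint — the candidate (leaving ≥ ⌈minprop·n⌉ = 10% of samples on each
side) maximizing the absolute standardized two-group log-rank statistic,
lowest cutpoint on ties — then fits Cox with the high/low indicator plus
adjustment covariates (age + sex by default, optionally the meta-PCNA
score), takes the indicator's Wald p, applies BH across tested genes and
flags adjusted p < α = 0.05. Direction "poor-with-high" means the
high-expression group has HR > 1; reports carry the direction explicitly
since the inverted convention (HR of high vs low below 1) is also in
circulation.

**Cutpoint-selection optimism.** The Wald p of a dichotomy chosen to
maximize the log-rank statistic is anti-conservative: in the package's
null simulations ~40% of pure-noise genes reach raw p < 0.05 (the
classical maximally-selected-rank-statistics inflation). This is a
deliberate fidelity choice — the screen reproduces the
surv_cutpoint → coxph workflow rather than substituting a
selection-corrected p — and it has consequences: under a global null BH
still keeps the flagged fraction below α (the inflated p-values rarely
reach the Bonferroni-like leading BH threshold), but in mixed panels
with many strong true positives the BH threshold rises and null genes
enter the flagged set, so the screen's precision against planted truth
plateaus well below 1 (~0.45 at default conditions, recall ~0.9). Users
who need calibrated per-gene inference should treat the flags as a
ranking, not as an error-controlled discovery set.

The meta-PCNA signature is the top 1% of genes (⌈0.01·(G−1)⌉) by Pearson
correlation with `PCNA`; the per-sample score is the median of the
signature genes' log2 normalized values and enters the Cox model as a
covariate. In a two-pathway simulation (genes tied to outcome only
through a shared proliferation factor vs a directly prognostic gene),
adding the covariate removes the BH-adjusted prognostic flag from the
proliferation-only genes in ≥ 80% of replicates while the direct gene
keeps its flag.

Prognostic residuals count, per gene across cohorts, N (cohorts where
high expression is poor-prognostic) and M (low expression
poor-prognostic); per grouping (all genes, functional category, subrole,
mark) the positive/negative residual counts are compared with an exact
two-sided binomial sign test. Genes with N = M = 0, or a zero residual,
carry no direction information and are excluded from the sign counts.

## Enrichment statistics

Fisher's exact test is two-tailed (conditional hypergeometric); sample
odds ratios with a zero cell are reported as 0 or ∞ with flags rather
than continuity-corrected. Complex enrichment permutes the top/not-top
labels over the variable-gene universe: with margins fixed, the
permuted overlap is exactly hypergeometric, so the null odds ratios are
generated by hypergeometric draws of the overlap (one per iteration —
distribution-identical to explicit label shuffling and much cheaper).
The empirical p is one-sided with the plus-one rule,
(1 + #{null OR ≥ observed})/(n_perm + 1), so it is never zero and
super-uniform under the null; infinite observed odds ratios are matched
only by infinite null ones. BH is applied across complexes within a
cohort. Note the discreteness of small complexes: their permutation
p-values are conservative (super-uniform), and uniformity diagnostics
should use sets large enough that the overlap support is fine-grained.
Alteration-frequency comparisons test only genes altered in ≥ 10% of
either cluster (two-tailed Fisher, BH across tested genes).

## Single-sample signature scores

The score is a weighted Kolmogorov–Smirnov running sum per sample:
genes are ranked by expression (average ranks on ties); walking down the
ranking, in-set genes add rank^0.25 (normalized to the set's total
weight) and out-of-set genes subtract 1/(G−|S|); the raw score is the
sum of the running sum over all positions — the single-sample GSEA
convention rather than the kernel-CDF variant, a divergence documented
here. Rank weighting gives the raw score a positive expectation even for
random sets, so by default the expected random-set path (cumulative
weight share of all genes minus the uniform path) is subtracted; the
centering is constant per sample, preserving the extremal-placement and
monotonicity properties, and makes scores of differently composed sets
comparable. `center=False` returns the raw running-sum total.
Classification of validation samples takes the higher of the poor/better
signature scores; exact ties are left unclassified.

## Single-cell module scores

Genes are placed into 24 equal-occupancy bins of average expression
across cells; each set gene contributes 100 control genes sampled from
its bin excluding set genes (with replacement when the remainder of the
bin is smaller; when a bin is entirely inside the set the gene
self-matches, which makes the all-genes set score exactly zero). The
score is mean(set) − mean(control) per cell, so global additive shifts
cancel. A cell is positive for a module when its score strictly exceeds
the module's mean score across cells (strict inequality makes the
all-identical case well-defined as "none"; a fixed-cutoff rule is
available via `cutoff_rule="fixed"`), yielding the four groups
none/poor/better/both. One-vs-rest differential expression uses the
two-sided Wilcoxon rank-sum test — exact for pooled n ≤ 25 without ties,
normal approximation with tie and continuity correction otherwise —
with Bonferroni correction across genes within each comparison and
groups under 3 cells skipped with a reason.

## Orchestration and reproducibility

`run_pipeline` executes the staged workflow with explicit dependencies
(requesting a stage without its producer raises a typed dependency
error). A single top-level seed derives per-stage seeds by hashing
`"{seed}:{stage}"` (SHA-256, reduced below 2³¹), so stages are
independently reproducible; the manifest records the config, stage
seeds and SHA-256 digests of every output file, and identical config +
seed yields identical digests. Errors are typed
(configuration / data-contract / numerical / dependency) so failure
modes are assertable.

## Problem sizes in the test suite

The simulation-based tests choose sizes that keep the full suite around
five minutes on one CPU while leaving the study conditions (effect
sizes, noise levels, hazard ratios, censoring) at the generator
defaults: 20 seeds × ranks {2,3,4} × 10 consensus restarts for rank
selection and cluster recovery on the default 200-sample cohort; 50
replicates at n = 400 (reduced gene panel) for Cox coverage of the
planted log-HR; 200 replicates of a reduced-panel null cohort for
log-rank calibration; 400 complexes × 1000 permutations for the
enrichment null; 3 seeds of the full screen for recall/precision.

## Known limitations

- The prognostic screen's uncorrected post-dichotomization p-values are
  optimistic by design (see above); its precision against planted truth
  reflects that and is reported honestly by the test suite.
- The KL-NMF uses only uniform random initialization (no NNDSVD) and no
  sparsity penalties.
- The microarray probe-collapsing utility ("highest-expression probe
  wins") is provided but untested against real array data.
- Exponential survival and independent censoring are simpler than real
  follow-up; time-varying effects, competing risks and frailty are out
  of scope.
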