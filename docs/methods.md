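# Methods

## Coordinates and CpG feature geometry

Intervals are 1-based and end-inclusive in memory (`size = end − start + 1`,
matching the region-string convention `chrom:start-end` used as the island
identity key throughout); on-disk BED is the standard 0-based half-open
form, and the readers/writers are the only code that shifts offsets.

Islands are supplied (or simulated); shores are the 2 kb flanks, shelves
the next 2 kb (2–4 kb from an island), inter-CpG the remainder — the
UCSC-style convention.  Flanks of nearby islands are truncated at the gap
midpoint, which is exactly "assign each base to its nearest island" with
ties going left; the test suite verifies the resulting partition base by
base against that independent rule.  The chromosome universe is whatever
the annotation covers (the simulator emits autosome-style names).

## Fragment counting

Each fragment increments exactly one feature: maximal base overlap, ties
broken by class priority island > shore > shelf > inter, then leftmost.
Single assignment (rather than multi-feature coverage counting) makes
per-class read percentages a true partition of the library, which is what
gives TPM class shares their interpretation.  Row filters drop inter-CpG
rows and rows that are zero in every sample; the island-only reduction is a
separate, explicit step.

## Negative-binomial Wald test

Counts are modeled as `K_ij ~ NB(μ_ij, α_i)` with
`μ_ij = s_j · 2^(β_i0 + β_i1 x_j)` and `Var = μ + αμ²`.

* **Size factors** — median-of-ratios against the per-feature geometric
  mean, restricted to features nonzero in all samples, rescaled to
  geometric mean 1.
* **Dispersion** — within-group method of moments on normalized counts,
  `α̂_g = (v̂_g − m̂_g·c_g)/m̂_g²` where `c_g` is the group mean of `1/s_j`
  (the Poisson-level variance inflation that dividing by size factors
  introduces; omitting it biases α upward when depths vary).  Group
  estimates are pooled with df weights, floored at `α_floor = 1e-8`, then
  shrunk toward a fitted trend `α(μ) = a₁/μ + a₀` by log-space averaging
  with weight 0.5.  This is deliberately simpler than a full empirical
  Bayes treatment; simulation calibration (below) is the accuracy contract.
* **GLM fit** — with a two-level factor the IRLS normal equations decouple
  into one weighted intercept per group, so the fit is vectorized across
  all features; convergence at Δdeviance < 1e-8 or 100 iterations,
  initialized at log group means with pseudocount 0.5.  A log-mean floor of
  −50 keeps all-zero groups finite: such features keep their (large,
  negative or positive) fold-change estimate, and their Wald statistic is
  driven to insignificance by the vanishing Fisher information.
* **Test** — Wald `z = β̂₁/se(β̂₁)` with `se² = 1/W_control + 1/W_case`
  from the converged IRLS weights, two-sided normal p, in-package BH
  step-up (missing p excluded from the family size).  No independent
  filtering, fold-change shrinkage, or outlier replacement: the fold-change
  gate operates on the MLE.  DMCGI calls use strict inequalities,
  q < 0.1 and |FC| > 2; hyper and hypo calls partition the FC-passing
  significant set.  Top-k ranking is by descending log2 fold change with
  ties broken by ascending q then feature id, making it order-stable.

Under the simulator's global null (2,000 islands, 12 vs 16 samples) the
Wald p-values are uniform by KS test and BH at 0.1 yields no discoveries
across 20 seeds; with 7–10% planted islands at fold change 4 and
dispersion 0.05, sensitivity is 1.0 and the median estimated log2FC is
within 0.1 of the true value (the small downward bias is the usual
finite-sample NB MLE shrinkage toward zero).  A cross-check against the
reference NB Wald implementation (pydeseq2) on a small fixture agrees on
fold changes of strongly planted islands to < 0.3 log2 units and on their
calls; bit-level equality is a non-goal since the dispersion machinery
differs.

## Array-side testing and harmonization

Beta values (methylation fractions in [0, 1]) are tested site-wise between
two groups with the one-way two-group linear-model F (df1 = 1, identical to
the squared pooled-variance t); the effect is the difference of group
means, Δβ.  Betas are tested directly, not M-values, because the call
threshold (Δβ > 0.2) lives on the beta scale and effect and test should
share a scale.  DMC calling is one-sided hypermethylated (Δβ > 0.2 strict,
q < 0.1), reflecting the tumor-methylome asymmetry the pipeline targets.
Sites with exactly zero pooled variance are degenerate: equal means give
p = 1, unequal means give p = 0 with a flag.  DMC sites are mapped to
islands, deduplicated, and non-island sites discarded; island-level beta
matrices are unweighted means of member sites (neighboring sites are
positively correlated, so the mean is a stable one-number summary).
Pairing of tumor/normal samples is ignored (two-group testing), matching
how the comparison is framed.

## Intersection

Island identity is the exact region string; the sequencing and array sides
are harmonized to the same annotation before intersecting, so no fuzzy
coordinate matching is needed (an optional ≥ 1 bp overlap matcher exists
behind a flag for mismatched annotations, default off).  Tumor-derived
DMCGIs are the three-way intersection of plasma, tumor-vs-normal, and
tumor-vs-PBMC sets; the PBMC leg removes clonal-hematopoiesis signal.
Cancer-type-specific sets contain members of exactly one cancer's set.
Overlap percentages round half-up to one decimal.  Venn accounting is
exact over the seven exclusive regions and is property-tested against
element enumeration.

## Consensus-LASSO protocol

Per repeat: a class-balanced 80/20 split (per-class half-up rounding,
seeded), then an L1-penalized logistic regression (alpha = 1) on the
training split.  λ parametrizes the per-sample penalty, solved via
liblinear with `C = 1/(n·λ)` over a 12-point log grid from λ_max (smallest
λ zeroing all coefficients) down to λ_max/100; λ is chosen to minimize
mean out-of-fold binomial deviance over 10 stratified folds (the
"λ-min" convention — a flag-free switch to the 1-SE rule was considered
and left out; λ-min is the default behavior of the reference tooling).
The reported model refits at λ-min on the full training split;
standardization (train-set mean/variance) happens inside the fit and
coefficients return on the original scale, so no test-set information
leaks.  Held-out performance is the rank-based AUC (Mann–Whitney U with
half-credit ties).  Consensus classifiers are features non-zero in every
one of the 100 repeats — a deliberately strict stability filter.  Repeat
seeds derive from the master seed by a counter; reports are byte-stable
under the same master seed.  Multi-class cohorts run one-vs-all-others per
class with offset master seeds.

With λ-min and moderate effects (~1.5 SD), a noise feature that is
spuriously correlated with the outcome across the whole cohort can survive
all repeats, so exact consensus recovery is reliable only for strong
effects; at the count-scale effects the pipeline produces for fold-change-4
islands (≈ 6 SD on log2 normalized counts) recovery of exactly the planted
set is the norm, and label permutation empties the consensus.

## Synthetic data: what it does and does not emulate

`simulate_counts` draws NB counts with per-feature means
`baseline_mean × class bias × lognormal jitter (σ = 0.25)` and per-sample
library factors uniform in [0.5, 2].  Class bias (island ×30, shore ×8,
shelf ×3, inter ×1) is chosen so island reads dominate the library the way
capture data behave, not fitted to any dataset.  Defaults encode the
targeted study shape: 12 cases vs 16 controls, dispersion 0.05 (global,
optional lognormal jitter), 7% of islands planted hypermethylated at fold
change 4, and a hypomethylated minority at 0.2% of plantings, mirroring
the strong hyper/hypo asymmetry of tumor CpG-island methylation.
`simulate_betas` draws Beta(μc, (1−μ)c) site values (c = 50) with tumor
mean base + Δ (0.2 + 0.35) at planted islands for a 21/21/61
tumor/normal/PBMC cohort.  `simulate_spikein` maps capture efficiencies to
Ct shifts at amplification base 2.

Not emulated: fragment-length and GC structure, read-level errors,
mean-dispersion trends estimated from real libraries, probe-level array
artifacts, batch effects, or biological correlation between neighboring
islands.  Passing tests therefore demonstrate the correctness and
calibration of the algorithms under the assumed generative model, not
performance on clinical cohorts.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale: annotations of
100–2,000 islands, cohorts of 28 (discovery) and 166 (validation-style)
samples, 5–20 simulation seeds per calibration check, 100 protocol
repeats.  These sizes give stable Monte-Carlo estimates for the calibration
margins used while keeping a full run in minutes.  Degenerate inputs
(all-zero rows/columns, single-class folds, zero-variance sites,
inverted intervals) raise explicit errors or flagged results rather than
silent NaNs; ties everywhere have documented deterministic resolutions
(leftmost island, lower CpG density bin, smaller q, lexicographic ids).
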