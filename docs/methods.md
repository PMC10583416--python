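# Methods

## Setting and model

`medimr` implements two-sample Mendelian randomization (MR) on GWAS summary
statistics.  Genetic variants serve as instruments for an exposure X; under
the instrumental-variable assumptions (relevance, exchangeability, exclusion
restriction), the ratio of a variant's outcome association to its exposure
association estimates the causal effect of X on the outcome Y.  The package's
focus is the drug-target variant of this design — instruments restricted to
cis variants of the gene encoding a drug's target, scaled by a downstream
biomarker so that effects read as pharmacological modulation — combined with
a two-step mediation analysis over a panel of candidate mediators M:

* step 1: β₁ = effect of X on M (univariable MR, SD per SD);
* step 2: β₂ = effect of M on Y adjusted for X (multivariable MR, log-odds
  per SD);
* indirect effect β₁β₂; mediated proportion β₁β₂/θ_total, where θ_total is
  the univariable X→Y estimate.

All binary-outcome effects are handled on the log-odds scale and reported as
odds ratios alongside.

## Harmonization

All traits are aligned to the first exposure's effect allele.  Exact allele
matches are kept; swapped alleles negate β and mirror the effect-allele
frequency; strand flips are resolved by complementing before aligning.
Palindromic (A/T, C/G) variants cannot be resolved from allele labels: under
the default `drop_all` policy they are removed; under `infer_by_eaf` they
are kept only when every trait's allele frequency lies outside [0.42, 0.58]
and are oriented by which side of 0.5 the frequencies fall on.  A
palindromic variant with a missing frequency is always dropped.  These are
conventional two-sample MR defaults; the window bounds are a documented
choice, and harmonization is idempotent by construction.

## Instrument selection

Greedy p-value clumping: repeatedly keep the remaining variant with the
smallest p-value (ties broken lexicographically by id for determinism) and
remove variants with r² ≥ the threshold AND within the distance window —
both conditions must trip, so correlated variants beyond the window
survive.  Biomarker instruments use p < 5×10⁻⁸ with r² < 0.01 / 10,000 kb;
drug-target instruments use the biomarker filter p < 1×10⁻⁴ inside the gene
region, a colocalization gate, and permissive clumping r² < 0.8 / 250 kb.
Residual correlation among permissively clumped instruments is thereafter
*ignored* by all estimators (independent-instrument working model) — a
documented limitation of the design this package reproduces, not an
oversight.  Per-variant instrument strength is F = (β/SE)², the squared
Wald z; F < 10 flags a weak instrument.

With `invert_sign` the exposure axis is negated after selection so that
estimates read per 1 SD *lowering* of the biomarker — the natural direction
for inhibition of the target.  This is an axis relabeling, not an allele
flip.

## Colocalization

Per variant and trait, the Wakefield log approximate Bayes factor is
0.5·[ln(1−r) + r·z²] with r = W/(V+W), V the squared standard error, W the
squared effect-scale prior SD (defaults 0.2 for quantitative traits, 0.15
for binary).  Under a single causal variant per trait, summing
configurations gives the five hypothesis weights (H0 none; H1/H2 one trait;
H3 two distinct causal variants; H4 one shared), with per-variant priors
p1 = p2 = 1×10⁻⁴, p12 = 1×10⁻⁵ — field-standard defaults, since only the
decision rule (PP.H4 > 70%) is prescribed by the analysis this mirrors.
All sums use log-sum-exp; H3 uses a log-space difference and is exactly
zero for a single-variant region.  The posterior vector is renormalized so
it sums to one exactly.

## Univariable estimators

* **Wald ratio** θ = β_Y/β_X with first-order SE |σ_Y/β_X| (uncertainty in
  β_X ignored; second-order terms deliberately omitted).
* **IVW**: weighted regression through the origin, weights 1/σ_Y².  Default
  inference is multiplicative random effects: SE × max(1, √(Q/(J−1))).  The
  floor means homogeneous data reproduce fixed-effect inference; the type-I
  error under the null is therefore mildly conservative (≈0.03–0.04 at
  nominal 0.05 with 10 instruments), which the calibration test documents.
* **MR-Egger**: variants oriented so β_X ≥ 0, weighted regression with
  intercept; dispersion max(1, √(Q/(J−2))); t inference with J−2 df for
  slope and intercept.
* **Weighted median**: ratios sorted with normalized weights
  (β_X/σ_Y)²; the estimate interpolates the 0.5 crossing of the cumulative
  midpoint function.  SE from a parametric bootstrap (betas redrawn from
  their reported normals; n_boot = 1,000 default; seed mandatory in the
  pipeline).
* **Mode-based estimates**: normal-kernel density over ratios with
  bandwidth φ·0.9·min(sd, mad)·J^(−1/5) (MAD scaled SD-consistent, φ = 1
  default), evaluated on 1,000 grid points spanning [min−3b, max+3b];
  simple mode unweighted, weighted mode with the weighted-median weights.
  If the bandwidth degenerates to zero (more than half the ratios
  coincide) the estimate is the median of the ratios, which equals the
  common ratio when all coincide.
* 95% intervals are θ ± 1.96·SE for normal-based methods (the constant
  1.96, not the exact quantile, so intervals match the printed-table
  convention) and t-based for Egger.

## Outlier diagnostics

**MR-PRESSO.**  Observed residual sum of squares uses leave-one-out IVW
expectations; `n_sim` (default 1,000) simulated datasets redraw both β_X
and β_Y from their reported normals.  Monte-Carlo p-values use the add-one
rule, so the smallest attainable p is 1/(n_sim+1).  Per-variant p-values
are Bonferroni-adjusted by J; outliers are adjusted p < 0.05.  The
corrected estimate is IVW on the remainder, and a distortion p-value
compares the corrected-vs-full difference against random removals of the
same count.

**Radial MR.**  With first-order radial weights W = β_X²/σ_Y², the radial
slope is algebraically identical to fixed-effect IVW; per-variant
Q contributions are χ²(1) outlier statistics (p < 0.05), removed
iteratively until none remain.

The pipeline removes the **union** of MR-PRESSO and radial outliers before
the main estimator battery, and applies the same filter at every screening
stage by default (switchable), treating outlier filtering as a
pre-analysis step wherever an IVW fit is made.  The filter refuses to shrink a set below
two variants.

## Multivariable MR and mediation

MV-IVW regresses β_Y on the J×K exposure matrix without intercept, weights
1/σ_Y²; per-exposure SEs are inflated by max(1, √(Q/(J−K))); rank
deficiency raises an error naming the entangled exposures.  MVMR-Egger
orients all variants to one exposure's positive direction and adds an
intercept (t inference, J−K−1 df).

The mediated proportion's delta-method variance propagates **only the
product term**: se² = β₁²σ₂² + β₂²σ₁², and se_prop = se_indirect/|θ_total|
with the total treated as fixed.  This choice reproduces the interval
behavior of the published worked example; the full ratio delta method
(propagating σ_total, markedly wider) and the second-order product term
are available as switches.  No β₁–β₂ covariance term is included: the two
estimates come from separate regressions in a two-sample design.
Proportions are stored as fractions and reported as percentages.

Ambiguity note: published summaries sometimes describe the "indirect
effect" with the odds ratio of the MVMR mediator-on-outcome estimate.  The
package reports both exp(β₁β₂) (`indirect_or`) and the MVMR β₂ row,
labeled distinctly, and does not conflate them.

## Pipeline

Stages run in a fixed order with stage-level logging to standard error:
instrument selection → outlier filter → univariable battery (Table-1
surface; MR-PRESSO row included) → screen 1 (X→each mediator, 0.05/M) →
screen 2 (survivors→Y with their own genome-wide instruments, 0.05/m₁) →
MVMR per survivor (0.05/m₂, Table-2 surface with MVMR-Egger annotation) →
mediation.  Family sizes are the actual data-driven counts.  Screening
decisions are made with IVW (the main analysis); Egger/PRESSO annotate but
never gate.  An empty stage produces a report completed through the last
feasible stage with explicit skip markers rather than an error.  All
randomness derives from a single configured seed via seed-sequence
spawning, so identical config + inputs give byte-identical reports.

## Synthetic-data generator

The generator works directly on the summary scale — no individual-level
genotypes — which is both fast and faithful to what two-sample MR actually
consumes.  Per-variant standard errors follow the standardized-trait form
1/√(2p(1−p)n); observed effects are truth plus independent normal noise
(optionally correlated between the exposure and mediator GWAS through
`overlap_rho`, emulating participant overlap; default 0 = non-overlapping
samples).  Binary outcomes are generated directly on the log-odds scale
rather than via a liability threshold; this matches the scale the whole
pipeline operates on and sidesteps attenuation questions the analysis
itself never confronts.

Default study conditions: 10 exposure instruments explaining 1.5% of
exposure variance (per-variant F ≈ 300–600, comfortably above the weak
instrument cutoff, as in the motivating analysis where all F > 16), GWAS
sample sizes 300,000 for each trait, β₁ = 0.42, β₂ = ln(0.88), and a
direct effect chosen so θ_total = ln(0.51), giving a true mediated
proportion of ≈8%.  Each candidate mediator carries its own block of 10
instruments explaining 2% of its variance — metabolites are heritable in
their own right, and without mediator-specific instruments the
multivariable step would be unidentified (the exposure-block mediator
effects are proportional to the exposure effects).  Null panel mediators
have no exposure effect and no outcome effect but keep their own genetics.
Pleiotropy options: none (default), balanced N(0, sd), directional
N(mean, sd); planted outliers displace the outcome effect by a configured
multiple of its SE and are recorded in the truth object.

What the generator does **not** emulate: real LD panels (the main study
uses independent variants; AR(1) regions are provided separately for
clumping/colocalization tests), winner's curse in instrument selection,
liability-scale binary traits, annotation, and population structure.
Passing tests therefore demonstrate correctness of the estimators and the
screening logic under the stated sampling model, not robustness to every
artifact of real GWAS data.

## Problem sizes used in the checks

The simulation-based checks run at sizes chosen to make Monte-Carlo error
small relative to the tolerances they assert: 1,000 replicates for IVW
calibration, 20 seeded runs for outlier recovery, 20 seeds for
colocalization power at λ = 6 and n = 10,000 per trait with 50 variants,
200 seeds for mediated-proportion recovery, and 50 full pipeline runs with
a 31-mediator panel (1 true among 30 nulls).

## Numerical choices

* LD matrices are symmetrized after an asymmetry check at 1e-8 and the
  diagonal pinned to 1; |r| is clipped to 1.
* Clumping tie-breaks by lexicographic variant id after p-value.
* Colocalization arithmetic is entirely in log space.
* Monte-Carlo p-values never return 0 (add-one rule).
* Seeds are split with numpy `SeedSequence.spawn`, and every derived seed is
  reduced below 2³¹.

## Known limitations

* Correlated instruments after permissive clumping are treated as
  independent (no generalized-least-squares IVW).
* The Wald ratio SE is first-order only.
* No MR-RAPS, debiased IVW, SuSiE-style colocalization, multi-mediator
  joint decomposition, or network MR.
* The eQTL table for drug-target selection is taken as a single pre-merged
  input; multi-source merging is out of scope.
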