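# Methods

## The problem and the model

The package implements a discovery-and-evaluation workflow for small SNP
panels predicting ordinal pigmentation phenotypes (eye and hair color) in a
cohort drawn from several genetically divergent regions.  Phenotypes are
5-grade ordinal scales of dark-pigment concentration (for hair, grade 0 is
red, which is biologically a separate axis).  The workflow treats the 5-grade
scale as a continuous target for association scoring and model fitting, and
converts it to coarse class scales (eye: blue/intermediate/brown; hair:
red/blond/brown/dark, optionally blond+brown merged) only for classification
and per-class evaluation.

Three per-SNP association scores are computed on a stratified training split:

* **Univariate F test.** Pearson correlation r between the additive genotype
  code and the grade; `F = r²/(1−r²)·(n−2)`, p from the upper tail of
  F(1, n−2).  SNPs are gated at p < 0.01 before F-ranking; constant SNPs are
  excluded.  Implemented via `sklearn.feature_selection.f_regression`.
* **kNN mutual information.** Nearest-neighbor entropy estimation in nats.
  Genotype-like features (few distinct values, possibly after mean
  imputation) use the mixed discrete/continuous estimator: for each sample,
  the distance to its k-th nearest target value *within its own genotype
  level* defines a radius, and the estimate is
  ψ(n) + ⟨ψ(k)⟩ − ⟨ψ(level count)⟩ − ⟨ψ(#targets strictly inside the radius)⟩,
  clipped at 0.  Continuous pairs use the standard joint-space
  Chebyshev-ball estimator.  The implementation is vectorized per feature
  (sorting + window scans instead of per-feature KD-trees), which makes a
  5000-SNP dataset cost ~1.5 s instead of ~11 s; it agrees with
  `sklearn.mutual_info_regression` to float precision on untied data (tests
  cross-check this).  Tiny seeded noise (1e-10 relative) breaks grade ties,
  so estimates on heavily tied targets are reproducible given the seed but,
  as for any kNN entropy estimator, tie-breaking-sensitive at the ~0.05-nat
  level.  Default k = 3 neighbors.
* **Lasso path.** `min_w ‖Xw−y‖²/(2n) + α‖w‖₁` with an unpenalized
  intercept, solved by cyclic coordinate descent (`sklearn.linear_model
  .Lasso`, tol 1e-6, max_iter 10⁴), warm-started from the largest alpha of
  the fixed grid {0.7, 0.5, 0.2, 0.1, 0.05, 0.01, 0.005, 0.001, 0.0005}.
  Features are **not standardized**: the downstream scoring rules threshold
  raw absolute coefficients (≥ 0.1, > 0.05), which are only meaningful on the
  0/1/2 allele-count scale.  "Non-zero" means |coef| > 1e-8 to absorb solver
  noise.  α = 0 falls back to OLS.

## Scoring rules and SNP sets

Scores 0–3 are assigned per dataset from declarative rules (data, not code),
with a SNP receiving the maximum score among matching rules:

* pooled eye — 3: top-5 F, |coef| ≥ 0.1 at α 0.2, or non-zero at α 0.5;
  2: top-10 F or MI, or non-zero at α 0.2; 1: |coef| ≥ 0.1 at α 0.005.
* regional eye (max 2) — 2: top-5 by both F and MI, |coef| ≥ 0.1 at α 0.5,
  or non-zero at α 0.7; 1: top-6 by both F and MI, or non-zero at both α 0.7
  and 0.5.  The top-rank conjunction ("F **and** MI") for regions versus the
  pooled disjunction follows the rule sets as stated; both variants are
  expressible in the rule data.
* pooled hair — 3: top-5 F or MI, |coef| **>** 0.05 at α 0.2 (strict), or
  non-zero at α 0.5; 2: top-10 F or MI; 1: the rest of the best list
  (the union of top-10 F/MI, non-zero sets at α 0.5 and 0.2, and
  |coef| ≥ 0.1 at α 0.005).

Ranking ties break by (higher score metric, then lexicographic SNP id) so
every list is deterministic.  Per-dataset scores are summed into a total
(missing datasets contribute 0); all-zero SNPs are dropped.  The **optimal**
set is every SNP with a non-zero pooled score; the **minimal** set is the top
scoring tier — total ≥ 3 for eyes (a configurable flag can additionally
require support from more than one dataset; on the published 36-SNP worked
example both variants give the same 7-SNP set) and pooled score 3 for hair.
Hair is scored on the pooled dataset only by default, since the regional rule
set is defined for the eye analysis; regional hair scoring can be enabled.

## Classifier and evaluation

The classifier is an ordinary least-squares regression of the 5-grade target
on the additive codes of the selected SNPs; a tiny ridge penalty (1e-6) is
substituted only when the design is rank-deficient or underdetermined
(selected panels often contain same-LD-block variants).  The continuous
prediction maps to the nearest class center, with midpoint ties going to the
darker class.  Standalone, centers are the mean grades mapped to each class;
inside the pipeline they are calibrated as the mean *training* prediction per
true class (training-only, hence leakage-safe), because least-squares
predictions of an ordinal target are shrunk toward the cohort mean and
grade-scale midpoints would otherwise over-assign the middle class.  Per-class one-vs-rest AUC orients
the score toward each class: negated for the lightest class, raw for the
darkest, negated absolute distance to the class center for middle classes
(a convention; middle-class AUC from a one-dimensional score is inherently
orientation-dependent).  Precision/recall come from the hard classes,
accuracy overall, and r² from the continuous prediction against the 5-grade
truth.  Classes with fewer than 10 test samples report N/A.  One seeded
60:40 split, stratified by class × region (train count = round(0.6·n) per
stratum, clamped so both sides are non-empty; singletons go to training), is
reused across panels so comparisons are paired.  External panel predictions
(CSV with per-sample classes and optional per-class probabilities) run
through the same evaluation code path.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
any specific population:

* **Structure.** Each region's allele frequencies follow the Balding–Nichols
  model: Beta-distributed around the ancestral frequency with variance
  p(1−p)·divergence.  Default divergence 0.1, an FST-like magnitude for
  strongly differentiated metapopulations.  Default cohort: 4 regions × 75
  samples (the eye analysis uses 3 regions by default; one region is
  realistically dark-eye monomorphic and enters hair analyses only).
* **LD.** SNPs come in blocks (default 5 SNPs) generated from two shared
  latent haplotype variables per sample with per-SNP recombination
  probability 0.1.  Ancestral frequencies are drawn per block (within-block
  jitter sd 0.05) and regional drift is applied per block, because haplotype
  sharing only yields tight LD between SNPs of similar frequency and drift
  acts on haplotypes; block members end up with genotype correlations of
  ~0.7–0.85, an HERC2-like architecture.
* **Phenotypes.** Liability = Σ effect·genotype + N(0, noise_sd²).  Defaults:
  5 causal eye SNPs (distinct blocks, ancestral frequencies in 0.3–0.7) with
  effect 1.0 each and noise sd 0.8, so the causal set explains ≈ 75–80% of
  liability variance.  Grades count the ordered cutpoints below the
  liability; by default cutpoints sit at cohort liability quantiles chosen to
  reproduce realistic class proportions (≈ 33% light / 3% intermediate / 64%
  dark eyes; ≈ 14/31/55% blond/brown/dark hair).  Hair has its own causal
  set; red hair is a dedicated recessive locus (frequency 0.25 → ≈ 6% red).
* **Nuisance.** Genotypes are missing at random (rate 0.02); per-variant
  QUAL ~ Uniform(20, 100) and DP ~ Poisson(30), so the QUAL > 40 & DP > 5
  filter removes a substantial fraction of variants — including, sometimes,
  causal SNPs, which the pipeline must then recover through LD proxies.
* **Determinism.** All randomness flows from the single config seed;
  identical seeds give byte-identical output files.

What the generator does **not** emulate: realistic human LD maps and allele
frequencies, haplotype-length variation, linked selection, genotyping error
beyond missingness, correlated QUAL/causality, or phenotype measurement
error.  Passing tests therefore show that the machinery recovers planted
signal under idealized structure, not that it would match any particular
real cohort's numbers.

## Problem sizes and observed behavior

The recovery study runs the full pipeline on cohorts of 3 regions × 100
samples × 5000 SNPs (a deliberate stand-in for the ~10⁵-SNP scale of real
call sets) over 20 seeds in the test suite (12 in the acceptance script).
Under these conditions the planted causal SNPs or their block proxies land in
the optimal set in ≈ 90% of seeds; the failures are honest small-sample
events (an entire causal block failing the synthetic QUAL filter, or a causal
SNP drifting to a low regional frequency and losing statistical
detectability).  The minimal-set classifier's held-out extreme-class AUC
averages ≈ 0.87: relative to the ≈ 0.95 of an oracle fit on the true causal
genotypes, the gap is mostly QC-forced proxy substitution (r ≈ 0.8 proxies
attenuate r² by ≈ 0.64×) plus winner's-curse coefficient estimation, since —
by design of the original workflow — selection and fitting share the training
split.  The optimal set additionally absorbs a few dozen noise SNPs through
the score-1 rule (|coef| ≥ 0.1 at α 0.005 interpolates when p ≫ n), so its
classifier overfits at this scale (train r² ≈ 0.9, held-out ≈ 0.1): a
useful, deliberately preserved illustration of why the compact high-score
tier generalizes better than the full candidate list.

## Numerical and design choices

* Mean imputation uses training-sample statistics only; the leakage tests
  assert that permuting held-out labels changes no selection, scoring or
  fitted-model output.
* DP is read from INFO with a fallback to the mean per-sample FORMAT DP;
  multiallelic and non-SNP VCF lines are skipped with a warning; phased
  genotypes are treated as unphased; half-missing calls count as missing.
* Coordinates are kept verbatim (1-based) in SNP ids
  (`chrom:pos_ref_alt`); no liftover.
* The 5→3 eye mapping {0,1}→blue, {2}→intermediate, {3,4}→brown and the hair
  {2,3}→brown assignment are the symmetric defaults; all scale mappings are
  configurable.
* Degenerate inputs: empty QC output, empty cohorts, all-dropped samples and
  empty SNP sets raise typed errors; an empty selection in the orchestrated
  pipeline downgrades to a warning with empty sets so null cohorts remain
  analyzable.
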