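# Methods

## Overview

`salivaflux` analyses the path of fermentable saccharides from the
bloodstream to the tooth surface in a two-group cohort (normoglycemic
controls, participants with type 2 diabetes sampled at baseline and after
two weeks of intensive glycemic treatment). Three matrices are measured
per participant: plasma, glandular saliva (collected at the sublingual
caruncle, upstream of oral microbial activity) and whole saliva; a
supragingival-plaque metagenome provides species / pathway / enzyme
relative abundances; and an oral examination provides caries counts,
periodontal inflamed surface area (PISA), plaque index and salivary flow.

## Metabolomics QC chain

The normalization chain is applied per biofluid table, in fixed order:

1. **Internal standard.** Every sample's intensities are divided by its
   ribitol intensity (ribitol is spiked at a fixed absolute amount per
   vial). This removes the per-injection response factor and makes the
   whole chain scale-equivariant: multiplying all raw intensities by a
   constant leaves the final output unchanged.
2. **LOWESS drift correction.** Per batch and per metabolite, a locally
   weighted regression of pooled-QC intensity on injection order is
   fitted (span 0.5 by default; the pooled QC is injected first and after
   every six biological samples, giving roughly 15 points per batch, for
   which a span of 0.5 is robust). Every sample's intensity is divided by
   the curve evaluated at its injection order and rescaled by the batch
   QC mean. Division (not log-scale subtraction) is used; for a
   multiplicative drift model the two coincide up to the rescaling
   constant. Between QC injections the fitted curve is linearly
   interpolated; beyond the first/last QC it is linearly extended so
   trailing injections are still corrected. Batches with fewer than three
   QC injections are left uncorrected with a warning. A flat QC series
   reproduces the input exactly, so the correction is idempotent.
3. **Collected amount.** Biological samples are divided by the collected
   amount (aliquot volume in mL; for glandular saliva the collected mass
   in g, converted to volume assuming a saliva density of 1.0 g/mL —
   masses are recorded to five decimal places pre/post collection).
4. **Feature filters.** A feature is blank-dominated when its mean
   biological signal is below 3× its mean blank signal (the multiplier is
   configurable; features absent from blanks always pass). Of the
   remaining features, those with QC coefficient of variation above 30 %
   are discarded. The CV uses the sample (n−1) standard deviation over
   QC injections, with zero/missing intensities treated as missing for
   the CV only (zeros are retained in the data for rank-based statistics
   downstream). The filter report partitions the feature set exactly.

## Migration scores

For each fluid, participants are ranked from lowest to highest on
glucose, fructose and glucose + fructose, and assigned septiles 1–7.
Bins are balanced rank bins (type-1 quantile bins of the sorted sample):
a value of average rank r among n receives bin ⌊(r−1)·7/n⌋+1, so bin
sizes differ by at most one when values are distinct, and ties — resolved
by average rank — fall deterministically, with a fully tied sample landing
in the median bin (4). Composite scores sum the three per-fluid septiles
of one quantity (GlcMig, FruMig, GlcFruMig), each spanning 3–21. All
scores are invariant to strictly increasing transforms of any fluid's
measurements.

Septile cut-points are computed within a caller-chosen ranking pool — by
default the baseline cross-section — and frozen: the stored edge k is the
largest pool value assigned to a bin ≤ k, and an out-of-pool value scores
1 + #{edges below it}. Post-treatment samples are therefore scored
against the baseline distribution and remain directly comparable with
baseline scores. (Re-ranking pre and post jointly is the other defensible
choice; freezing the baseline cut-points keeps the cross-sectional results
unchanged when follow-up samples are added.)

Clinical effect sizes are ordinary least squares of a composite score on
one clinical parameter with age and gender as covariates; constant
covariates are dropped (they carry no information and would alias the
intercept), and exactly collinear designs raise an error naming the
offending columns.

## Variance partitioning and correlations

Bray–Curtis dissimilarity d(u,v) = Σ|u−v|/Σ(u+v) is computed on
nonnegative profiles; normalized metabolite tables that contain negative
values are min-shifted to zero per feature first (with a warning).

PERMANOVA uses the adonis formulation: with A = −½D², G = CAC the
Gower-centred matrix (C the centring matrix) and H the hat matrix of the
design (intercept + dummy-coded factor, or intercept + slope for a
continuous biomarker), SS_model = tr(HGH), SS_total = tr(G),
R² = SS_model/SS_total and pseudo-F = (SS_model/df_m)/(SS_res/df_r).
For a categorical factor this reduces exactly to the classical group
sums SS_total = (1/N)Σ_{i<j}d²ᵢⱼ and SS_within = Σ_g(1/n_g)Σ_{i<j∈g}d²ᵢⱼ
(verified against that form in the tests). Continuous biomarkers are
used as-is in the single-slope model rather than discretized. The
permutation p-value is (1 + #{F_perm ≥ F_obs})/(1 + n_perm) with 999
permutations by default and an explicit seed.

Pareto scaling divides each mean-centred feature by the square root of
its standard deviation before the PCA singular-value decomposition —
a compromise that damps, without erasing, the dominance of high-intensity
metabolites. Zero-variance features are excluded with a warning.

Per-feature Spearman correlations use scipy's n-dependent p-values;
constant features have no defined rank correlation and are reported as
missing. All p-value families are Benjamini–Hochberg adjusted. Alpha
diversity is Shannon entropy (natural log) or the inverse Simpson index.

## Metagenome preparation

A feature is *present* in a sample when its relative abundance is at or
above the level-specific threshold (0.1 % species, 0.001 % pathways,
0.00001 % enzymes); retention requires presence in at least
max(⌈0.10·n⌉, 1) samples. Requiring at least one present sample even at
a prevalence threshold of zero means a feature below its abundance
threshold everywhere is always removed — the abundance and prevalence
rules are conjoined, which is the natural reading of excluding features
that fail *either* rule. Deduplication then collapses connected
components of the Spearman ρ > 0.9 graph to their most abundant member
(ties broken by name); it applies to functional features, with species
tables passing through unchanged unless forced. Prefilter runs before
dedup, and the two reports reconcile exactly to the input feature set.

Covariates are encoded as balanced rank tertiles (age, PISA, caries
count; same tie convention as septiles) and salivary flow is dichotomized
at 0.67 mL/min, with the boundary value assigned to the low-flow group
(the cutoff is exclusive upward).

## Association models

Abundances are total-sum scaled and log2-transformed with a per-feature
pseudocount of half the smallest positive value (zeros map to
log2(half-min-positive)). Each exposure is tested separately, one
feature at a time, in a linear model adjusted for age tertile, PISA
tertile, caries tertile and flow group (tertiles as categorical dummies);
cross-sectional models use fixed effects only, since the baseline
cross-section has one sample per participant. p-values come from the
exact t reference distribution; BH q-values are computed within each
exposure's feature family and the discovery threshold is q < 0.25, a
deliberately permissive rate standard in discovery-phase microbiome
work (q < 0.05 earns `**`, 0.05 ≤ q < 0.25 earns `*`). This specifies
the MaAsLin2-style modelling strategy directly — TSS + LOG + linear
model — so every estimate is reproducible against a normal-equations
oracle rather than delegated to an external tool.

Pre/post-treatment contrasts fit, per feature, a random-intercept model
with participant as the grouping factor (REML). In the balanced
two-timepoint design without covariates the fixed-effect estimate equals
the mean within-participant difference for any variance ratio; this
equivalence is the estimator's contract and its test oracle (tolerance
1e-8). When the within-pair differences are numerically constant the
REML problem degenerates (zero residual variance) and the exact
paired-difference solution is returned directly. Features with fewer
than three complete pairs are skipped.

## Synthetic cohort generator

The generator emulates, on a log10 intensity scale with linear couplings,
the causal structure the analysis assumes:

* plasma glucose and fructose are log-normal, elevated by
  `glycemia_shift` (default 0.4 log10 units ≈ 2.5×) in T2D at baseline
  and by a quarter of that after treatment;
* the latent migration variable M is the mean of the standardized log
  plasma saccharides times the glandular transfer fraction
  (`gland_transfer`, default 0.6); standardization uses the baseline
  cross-section so post-treatment samples stay on the same scale;
* glandular log levels are `gland_transfer` × plasma log levels + noise;
* taxon log abundances respond linearly to M with signed per-taxon
  effects (default: 10 % of taxa at +0.5, cariogenic-like; 10 % at −0.5,
  health-associated-like; the rest null) and are closed to relative
  abundances; responsive taxa are drawn at moderate base abundance, as
  their real-world counterparts are common community members that clear
  the 0.1 % abundance prefilter;
* whole-saliva log levels are glandular levels minus
  `consumption_strength` × (summed relative abundance of the
  positive-effect taxa) + noise. The default strength of 1.0 keeps the
  Spearman correlation between glycemic markers and whole-saliva
  saccharides positive but clearly attenuated, reproducing the
  decreasing plasma → glandular → whole-saliva ordering;
* caries counts are Poisson with log-rate 1.0 + `caries_link`·M
  (default link 0.5), capped at 28 teeth; PISA and plaque index carry
  weak positive couplings to M; ages are drawn older in the T2D group
  (≈64 vs ≈42 years), deliberately reproducing the confounding the
  covariate adjustment must handle.

Measured intensities add a per-injection response factor (removed by IS
normalization) and, for glandular saliva, scale with the collected mass
(removed by amount normalization). Pooled-QC injections — the mean of all
biological samples — are inserted first and after every six biological
samples; an optional drift function of injection index multiplies all
intensities. Two extraction blanks carry trace signal plus two designated
contaminant features at biological signal level, exercising the blank
filter. Group sizes default to 30 controls and 31 T2D participants.
Everything derives from a single integer seed and regenerates bit for
bit; the latent truth (M, taxon effects, caries link) is always emitted
so tests never re-derive it.

The functional form linking hyperglycemia to glucose vs fructose
transfer is unknown; the shared-latent form used here is a modelling
choice. The generator does not emulate compositional zero-inflation
beyond what log-normal closure produces, batch effects across
acquisition batches, missing metabolite annotations, or realistic
phylogenetic correlation among taxa — so passing tests demonstrate
correctness of the estimators under the assumed structure, not
robustness to every pathology of real data.

## Verification and problem sizes

The suite checks every estimator against an independent oracle: septile
assignment against brute-force sort-and-cut, regression betas against
normal-equations solves, PERMANOVA against the classical group-sum
formulas, exhaustive label enumeration at n = 6 and scikit-bio's
implementation, BH q-values against the step-up recursion, Pareto PCA
against a dense eigensolver, and the paired model against within-pair
differences. Calibration checks use 50 simulated cohorts of 60
participants for planted-effect recovery (≥80 % of non-null taxa
recovered with the correct sign at q < 0.25), 200 null cohorts for
type-I error (rejection rate within two Monte-Carlo standard errors of
5 %), and 20 null end-to-end pipeline runs (no feature flagged at
q < 0.05 in ≥90 % of runs). These sizes keep each simulation suite in
the tens of seconds while leaving Monte-Carlo error well inside the
asserted margins.

## Known limitations

* Cross-sectional models are fixed-effects only; repeated-measures
  exposures other than the two-timepoint contrast are out of scope.
* The PERMANOVA design supports one factor or one continuous covariate
  at a time (matching per-parameter omnibus testing), not multi-term
  models with marginal sums of squares.
* No zero-inflated or compound Poisson abundance models; the linear
  model on transformed abundances relies on the prevalence prefilter to
  limit zero-inflation.
* The LOWESS span is fixed per run, not tuned per metabolite.
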