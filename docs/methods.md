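# Methods

## Model and pipeline

The unit of analysis is the parent-child trio. For a gene region, the
pipeline is:

1. **Site selection.** Biallelic sites inside the region with founder minor
   allele frequency 0 < MAF < threshold (default 0.01; 0.03 is the looser
   published choice). MAF is computed on founders only — transmitted alleles
   appear in both a parent and a child, so pooling everyone double-counts
   them — with a flag to use all individuals. Monomorphic sites are excluded
   even below threshold; they carry no transmission information.
2. **Transmission scoring.** x_ij = c_ij − (f_ij + m_ij)/2 per trio i and
   site j, with values in {−1, −½, 0, ½, 1} and zero Mendelian expectation
   for every parental genotype pair (verified exhaustively in the tests).
   Missing child or parent genotypes and Mendelian-inconsistent triples
   score 0 (uninformative) and are counted in a QC report rather than
   treated as fatal — imputed pedigree data contain inconsistencies.
   Columns with zero score variance ("noninformative": no rare-allele
   transmission opportunity, or constant distortion) are removed; a gene
   with no informative column is reported untestable, never an error.
3. **SVM.** Soft-margin Gaussian-kernel SVM trained in the dual by SMO with
   maximal-violating-pair selection (iteration cap 10⁵, KKT gap tolerance
   10⁻⁵; solutions verified against a generic box-constrained QP solver and
   scikit-learn's SVC in the tests). σ² defaults to 1; features are not
   standardised because transmission scores share the [−1, 1] scale by
   construction. No class weighting is applied despite case/control
   imbalance.
4. **Cross-validated composite scores.** Stratified 5-fold partition with
   fold membership keyed to (seed, trio id) via CRC32, so folds are
   reproducible and independent of row order. The penalty C is chosen from
   the grid {1..10} by maximal cross-validated AUC, ties toward the smaller
   (more regularised) C; model selection and final scoring share the same
   partition (no nested CV). Composite scores are out-of-fold: each child is
   scored by the model trained without its fold. A resubstitution flag
   exists for comparison; resubstitution AUCs of a Gaussian-kernel SVM are
   optimistically biased and should not be tested.
5. **AUC test.** Decision scores are negated (the affected class sits at
   vertex −1) so that greater distortion among cases maps to θ > 0.5. The
   test is one-sided, H₀: θ ≤ 0.5 vs Hₐ: θ > 0.5, with z = (θ̂ − 0.5)/SE
   referred to the standard normal.

## Variance of the cross-validated AUC

The statistically delicate step is SE(θ̂). Within one fold the held-out
scores come from a single model that never saw their labels, so conditional
on the model they are an iid sample and the DeLong placement-variance
estimator applies; our null simulations confirm per-fold DeLong SEs match
the per-fold empirical spread. Two naive extensions fail:

* **Pooling all out-of-fold scores** into one AUC mixes scores from five
  different models (different offsets and scales) and treats them as one
  sample. Measured on 200-replicate null simulations at the default design
  (66/209 trios, 50 sites), the pooled z-test rejected at 0.135 instead of
  0.05.
* **Averaging fold AUCs with independent variances** ignores that the five
  models are trained on largely the same data, so all five partially track
  the same accidental label-feature alignments. The measured inter-fold AUC
  correlation is ≈ 0.21 (and ≈ 0.6 for split halves, where both halves
  estimate the same alignment in opposite directions); the naive average
  rejected at ≈ 0.09.

`cross_validated_auc` therefore averages the fold AUCs and inflates the
combined DeLong variance by the cross-validation dependence factor of
Nadeau & Bengio's corrected resampled estimator,

    1 + (F − 1) · n_test / n_train  =  2   for equal F-fold splits,

whose implied inter-fold correlation (1/(F−1) · … = 0.25) closely matches
the measured 0.21. With this correction the same 200-replicate null design
rejects at 0.050 (α = 0.05) and 0.005 (α = 0.01), with mean θ̂ = 0.5045
(Monte-Carlo SE 0.004) — the modest upward shift of the point estimate from
choosing C by maximal CV AUC is absorbed by the corrected SE. Degenerate
folds (perfect separation or all-tied scores) contribute θ_f with zero
estimated variance; a gene whose folds are all degenerate is reported with
reason `degenerate_se` rather than p = 0, since the asymptotics do not
apply.

The worked examples against published AUC/SE/p triples only reproduce the
printed p-values when the statistic is centred at the null value 0.5, i.e.
z = (θ̂ − 0.5)/SE; the package centres accordingly.

## Synthetic data generator

The generator emulates the statistical structure of the published
experimental design rather than any particular cohort:

* per-site MAFs uniform on [0.001, 0.03] by default (the rarer published
  filter), 50 sites per gene;
* parents Binomial(2, MAF) under HWE; children receive one allele per
  parent with probability count/2;
* disease is logistic on the child's causal-allele counts,
  P(affected) = expit(β₀ + Σ β_j c_j), with mixed-sign β_j so variants may
  confer risk or protection. β₀ = logit(0.2) puts prevalence near the
  affected fraction of the published 66-case / 209-control sample, to which
  ascertainment quotas default. The published underlying simulation was a
  longitudinal quantitative blood-pressure model with dichotomisation and
  mixed-model covariate adjustment on restricted data; the logistic model
  preserves the tested structure (a few causal rare variants of mixed
  direction) without those inaccessible ingredients.
* optional two-subpopulation stratification: draws alternate between
  subpopulations whose MAF vectors differ by a multiplier (clipped at 0.5)
  and whose baseline log-odds may be shifted;
* bootstrap resampling of whole trios, label-preserving but not stratified
  by class — class proportions vary binomially around the source ratio.

Replicate seeds derive deterministically from (master seed, replicate
index) via `numpy` seed sequences, so experiments are reproducible and
order-independent. Untestable replicates are excluded from rejection-rate
denominators with a warning (frequent exclusion would bias rates; at the
default design none occur).

What the generator does *not* emulate: linkage disequilibrium between
sites, relatedness between trios (every simulated trio is independent),
genotyping/imputation error, and covariate effects. Passing calibration and
power checks on this generator therefore demonstrates the statistical
machinery under the method's own assumptions, not robustness to pedigree LD
— the known failure mode for real multigenerational data.

## Experiment scales

Calibration experiments use 200 replicates of the full 66/209 design (null
and two-subpopulation stratified null). Power experiments use 60 replicates
per condition (40 at 1000 bootstrap trios) with eight causal sites,
|log OR| = 2, six risk / two protective — enough to resolve the monotone
trend across 275 → 500 → 1000 trios and the MAF < 0.03 vs < 0.01 filter
ordering well beyond Monte-Carlo error.

## Known limitations

* **Prevalence-stratified populations.** The transmission encoding is
  mean-zero per site regardless of subpopulation, which protects any
  *linear* statistic from allele-frequency stratification, and the null
  simulations confirm nominal type-I error when two subpopulations differ
  twofold in MAF. But when subpopulations differ in disease prevalence *as
  well*, ascertainment enriches cases for the high-prevalence
  subpopulation; if that subpopulation also has higher MAFs, its trios have
  more nonzero scores, and the Gaussian kernel can discriminate on score
  *variance*. Measured rejection under a 2× MAF + prevalence-shift null was
  0.18 at α = 0.05. This is a genuine property of the nonlinear kernel, not
  an implementation artifact; treat results from prevalence-heterogeneous
  samples with caution.
* **Pedigree LD.** Trios extracted from extended pedigrees are treated as
  independent, matching the published procedure; rare variants riding a
  causal founder haplotype in a nearby gene can then create association
  signals in the wrong gene.
* **Selection-on-the-same-folds.** C is selected and θ̂ computed on one
  partition (no nested CV). The corrected SE empirically covers the
  selection effect at the default grid; very large grids may need nesting.
* **Small classes.** The per-fold DeLong variance needs at least two cases
  and two controls per fold, so genes with fewer than 2 × folds members in
  either class are reported untestable (`too_few_per_class`).
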