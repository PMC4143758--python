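# triosvm

Gene-level rare-variant association testing in parent-child trios with a
Gaussian-kernel support vector machine.

## The problem

Single rare variants (MAF below 1–3%) carry too little information to be
tested one at a time, so gene-level tests aggregate them. `triosvm`
implements a family-based aggregation strategy for *trios* — a phenotyped
child with both parents genotyped. Each child *i* is encoded by a vector of
per-site transmission distortions

    x_ij = c_ij − (f_ij + m_ij) / 2,

the observed minus Mendelian-expected number of rare alleles transmitted at
site *j* given the parental counts *f*, *m* (the conditioning used by
family-based association tests). Under the null the scores have zero mean at
every site, and only heterozygous parents contribute, which makes the
encoding insensitive to allele-frequency differences between
subpopulations. The method is agnostic to the direction of each variant's
effect: risk and protective alleles both produce distortion.

Affected (label −1) and unaffected (label +1) children are then separated by
a soft-margin SVM with Gaussian kernel K(x, x′) = exp(−‖x−x′‖²/2σ²),
trained in its dual form (an SMO solver written in-package, verified against
a generic QP solver). Each child receives an out-of-fold composite score
f(x) = Σ_s α_s y_s K(x_s, x) + b from 5-fold cross-validation; the penalty C
is chosen on the same folds by maximal cross-validated AUC.

The gene-level statistic is the Mann–Whitney AUC θ of the composite scores
(cases vs controls, ties counted ½), tested one-sided against θ ≤ 0.5 with

    z = (θ̂ − 0.5) / SE(θ̂),   p = Φ̄(z).

θ̂ is averaged over CV folds and SE(θ̂) combines per-fold DeLong variances
with a cross-validation dependence correction (see `docs/methods.md`) so the
test holds its nominal level.

A synthetic trio generator (HWE parents, Mendelian transmission, logistic
disease model with mixed-direction effects, case/control ascertainment,
optional two-subpopulation stratification, bootstrap resampling) supports
type-I-error and power experiments with the same per-gene pipeline.

## Worked example

Create a small demonstration dataset (30 trios × 50 sites; `geneA` contains
six causal variants with |log OR| = 3, `geneB` is empty) and test both
genes:

```sh
triosvm fixture --seed 3 --out-dir demo
triosvm run --ped demo/fixture.ped --map demo/fixture.map \
    --regions demo/fixture.regions.tsv --maf-threshold 0.2 \
    --c-grid 1-10 --folds 5 --seed 3 --out demo/results.tsv
```

`demo/results.tsv` (header comment omitted):

```
gene   n_case n_control n_sites_input n_sites_used penalty_chosen theta_hat se       z         p_one_sided reason
geneA  15     15        25            25           2              0.866667  0.125708 2.91682   0.00176812
geneB  15     15        25            25           4              0.622222  0.144016 0.848668  0.198033
```

Reading the rows: all 25 rare sites in each gene were informative
(`n_sites_used`), the causal gene's composite scores separate affected from
unaffected children (AUC 0.87, one-sided p ≈ 0.0018) while the empty gene
stays compatible with the null (AUC 0.62 at n = 30, p ≈ 0.20). A
`reason` code (e.g. `no_rare_sites`, `degenerate_se`) marks untestable genes
instead of a p-value. The companion `results.tsv.qc.tsv` counts
noninformative sites, Mendelian inconsistencies and missing-genotype
zeroings per gene.

The `simulate` and `calibrate` subcommands expose the generator directly,
e.g. a null calibration:

```sh
triosvm calibrate --replicates 200 --alphas 0.05,0.01 --seed 1 --out null.tsv
```

## Caveats

Trios sharing parents or drawn from extended pedigrees are treated as
independent; in deep pedigrees, linkage disequilibrium travels with founder
haplotypes, so rare variants riding a causal haplotype in a *nearby* gene
can produce association signals — interpret significant genes from pedigree
data accordingly. Stratification robustness covers allele-frequency
differences between subpopulations; see `docs/methods.md` for the case where
subpopulations also differ in disease prevalence.
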