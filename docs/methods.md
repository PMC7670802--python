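# Methods

This note records the statistical models, parameter defaults, generator
assumptions and numerical choices implemented in `gutherit`.

## 1. Viability screen (`gutherit.screen`)

Paired libraries per fish: one PMA-treated, one untreated. Both arms are
rarefied to a common depth by multivariate-hypergeometric subsampling
(sampling without replacement; samples below depth in either arm are
excluded before any classification). For each sample and OTU the ratio

    r = (u + 1) / (p + 1)

of untreated to PMA counts is computed with a +1 pseudocount so that
absent-in-one-arm OTUs remain classifiable. Labels per sample:
contaminant if r > 6, dead if 3 < r ≤ 6, live if r ≤ 3, undetected if
both counts are zero. Contaminant takes precedence over dead. The
filtered table carries the untreated arm's rarefied counts with each
sample's dead/contaminant OTUs zeroed; dataset-level dead and contaminant
read fractions are read-weighted over the untreated arm, and OTU-level
labels are the modal per-sample call.

Defaults: rarefaction depth 10,000; fold thresholds 3 (dead) and 6
(contaminant). Community summaries report OTUs above 1 % mean relative
abundance; rank agreement between samples or arms uses Spearman
correlation.

**Resolution limit.** At depth d an OTU with untreated share s carries
≈ s·d reads; the pseudocount bounds the observable ratio, so folds are
only resolvable when s·d is well above ~10 reads. The recovery fixtures
plant contaminants at shares where the signal is resolvable (see tests).

## 2. Genomic relationships (`gutherit.grm`)

Genotype QC first drops individuals with > 10 % missing calls, then SNPs
with minor allele frequency < 1 % or call rate ≤ 90 %. The GRM is
VanRaden method 1:

    G = Z Z' / (2 Σⱼ pⱼ(1 − pⱼ)),   Z = M − 2p,

with M the dosage matrix, p per-SNP allele frequencies, and missing
dosages mean-imputed (zero deviation). Frequencies default to the sample;
an external (e.g. founder) frequency vector can be supplied, which
matters in strongly family-structured samples. `loco_grm` rebuilds G
excluding one chromosome.

## 3. Variance components (`gutherit.reml`)

Animal model per OTU (response: natural log of relative abundance, or any
phenotype):

    y = Xb + Z_a a + Z_t t + e,
    a ~ N(0, G σ²ₐ),  t ~ N(0, I σ²ₜ),  e ~ N(0, I σ²ₑ)

with sampling day in the fixed design. Estimation is average-information
REML on the restricted log-likelihood

    logL = −½ [ log|V| + log|X'V⁻¹X| + y'Py ].

Numerical scheme:

- EM warm-up (3 iterations; 6 on restart), then AI steps with
  step-halving (down to 1/64) and an EM fallback whenever the AI step
  would decrease the likelihood.
- Boundary handling: a negative proposal is pinned at 1e-5·var(y); a
  component is fixed at zero and held only after three consecutive pins
  with a downward gradient. The residual is never held. One restart from
  positive values protects against spurious early boundaries and is
  accepted only if it converges to a strictly better likelihood.
- A ridge of 1e-6·var(y) on the diagonal of V guards Cholesky factors;
  the exact (ridge-free) likelihood is available via
  `restricted_loglik` and is used by the oracle tests with `ridge=0`.
- Convergence: relative log-likelihood change < 1e-8 together with a
  parameter delta < 1e-6·var(y), or a stationary likelihood for three
  consecutive iterations (parameter drift along a flat ridge of a
  non-identifiable split does not change the fit). Maximum 200
  iterations.

Reported: components with standard errors from the inverse AI matrix;
h² = σ²ₐ/(σ²ₐ+σ²ₜ+σ²ₑ) and c² = σ²ₜ/(σ²ₐ+σ²ₜ+σ²ₑ) with delta-method
SEs; GLS fixed effects; boundary flags. The genetic term is tested by
LR = 2(logL₁ − logL₀) against χ²(1); because the null pins a variance at
its boundary this p-value is conservative, and the ½χ²₀:½χ²₁ mixture is
available behind `boundary_mixture=True`.

Validation oracles: balanced one-way designs against the closed-form
ANOVA REML estimators (agreement ≈ 1e-15); full-sib instances against an
independent Nelder-Mead maximiser of the same restricted likelihood
(≈ 1e-9); planted-h² recovery on simulated data.

## 4. LOCO GWAS (`gutherit.gwas`)

For each chromosome c the null model (intercept + optional covariates,
polygenic term with G built from all chromosomes except c) is fitted by
REML, re-estimating σ² g per excluded chromosome. The eigendecomposition
of G_loco whitens the data (weights 1/√(σ²g dᵢ + σ²ₑ)); each SNP on c is
then tested by weighted least squares with the residual scale
re-estimated per SNP and a t-based p-value — this collapses exactly to
simple-regression inference when σ²g = 0. A generalized likelihood-ratio
alternative (`test="lr"`, n·log(RSS₀/RSS₁) against χ²(1)) and a pinned
variance (`fix_sigma_g2`, diagnostic) are provided. Genome-wide control
is Bonferroni: threshold α/m with α = 0.05; the genomic inflation factor
λ (median statistic over the χ²(1) median) is reported as a calibration
diagnostic.

## 5. Phenotype association (`gutherit.assoc`)

Each phenotype is regressed on the log abundances of the dominant OTUs
(jointly by default, optionally one at a time) in the same animal model
(G-structured animal effect + tank + residual; day as a covariate).
Collinear regressor sets are rejected with the offending columns named
(QR with pivoting); note that with families nested in tanks some
contrasts are confounded by design. Per-regressor Wald F tests
(F = (b/se)², df 1 and n − rank(X)) are reported with significance
markers at 0.005 and 0.05.

## 6. Outlier diagnostics (`gutherit.qc`)

Log transformation requires strictly positive relative abundances (an
OTU must be present in every retained sample). Regression outliers are
flagged by hat-matrix leverage above 3p/n (Cook's distance available as
an alternative), computed via statsmodels influence measures; the fixed
design is rank-checked first, naming collinear columns.

## 7. Synthetic-data generator (`gutherit.simulate`)

What it emulates:

- **Design**: 23 families, each split across 2 tanks with 5 fish per
  tank (230 phenotyped fish), sampled over 4 days; founder parents are
  genotyped. All counts are configurable.
- **Genotypes**: founders drawn in Hardy–Weinberg equilibrium at
  uniform(0.1, 0.5) frequencies; offspring receive Mendelian gametes.
  Default 2000 SNPs split evenly over 29 chromosomes.
- **OTU abundances**: per-animal latent log abundance = base + additive
  genetic value (infinitesimal SNP effects rescaled to the exact target
  variance) + tank effect + day effect + residual, with planted h² and
  c² per OTU; counts are multinomial draws from the softmax of the
  latent log abundances (compositional closure is therefore a real
  feature of the data).
- **Paired PMA arms**: dead and contaminant OTUs appear in the untreated
  arm inflated by planted fold factors (> 3 and > 6 respectively), then
  the composition is renormalised and counts drawn multinomially. Closure
  shrinks the observed fold below the planted one; the closure equation
  q = s/(f − s·f + s) gives the live-arm share that yields an untreated
  read share s.
- **Phenotypes**: 13 growth/feed-efficiency traits, linear in latent log
  abundances with planted coefficients plus animal, tank, day and
  residual terms.

What it does **not** emulate: sequencing error and chimeras, taxonomy
assignment, overdispersion beyond multinomial sampling, dominance or
epistasis, linkage disequilibrium within chromosomes (SNPs segregate
independently given parental genotypes), and selection or mortality.

Because counts are compositional, planted per-OTU heritabilities are
recovered without bias only on the *latent* log-abundance scale, which
the generator returns alongside the count tables; estimates on closed
(renormalised) data are systematically distorted for dominant OTUs.

## 8. Problem sizes and runtimes

Unit and acceptance tests run at desk scale: 10–50 families, 100–500
phenotyped animals, 200–1000 SNPs on 2–5 chromosomes, rarefaction depth
2000–20,000. The full test suite completes in well under a minute on one
CPU; `scripts/acceptance.py` takes ~30 s. Defaults in `PipelineConfig`
remain the full study design and are never reduced implicitly.

## 9. Limitations

- LR p-values for variance components are conservative at the boundary
  (mixture correction available but off by default for comparability).
- The AI inverse underestimates SE uncertainty near boundaries; boundary
  flags should be consulted before interpreting SEs.
- The LOCO scan refits the null once per chromosome, not per SNP; with
  very strong single-SNP effects the per-chromosome variance estimates
  absorb some signal.
- Rank-based and compositional alternatives (CLR transforms, zero
  imputation models) are out of scope; the log transform requires OTUs
  present in all samples, matching the dominant-OTU focus.
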