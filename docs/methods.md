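# Methods

`popfam` implements a combined test of genetic association for dichotomous
traits in *hybrid designs*: studies that pool affected families, unrelated
controls and (optionally) unrelated cases. This note records the model, the
estimation choices, the simulator's scope, and the numerical conventions.

## The combined statistic

For a biallelic SNP, two component statistics are computed, each
asymptotically standard normal under the null hypothesis of no association:

* **X — signed-root wQLS** (population evidence). Let g_i be the
  minor-allele count of individual i, Y_i = g_i/2, and let the analysis set
  be all typed cases (affected family members and independent cases,
  indicator r_i = 1) and controls (r_i = 0). With K the genotype correlation
  matrix (K_ii = 1, K_ij = 2φ_ij from the pedigree kinship coefficients,
  block-diagonal over families), the quasi-likelihood allele-frequency
  estimate is p̂ = (1ᵀK⁻¹Y)/(1ᵀK⁻¹1), the score is
  U = rᵀK⁻¹(Y − p̂1), its variance
  V = σ̂²[rᵀK⁻¹r − (rᵀK⁻¹1)²/(1ᵀK⁻¹1)] with σ̂² = p̂(1 − p̂)/2, and
  X = sign(U)·√(U²/V). A positive X means the minor allele is enriched in
  cases. The case-indicator vector r is a configuration hook so that
  phenotype-weighted variants can be substituted.

* **Y — PDT** (family evidence). Per family i,
  D_i = Σ_triads X_T + Σ_DSP X_S, where a transmission unit is an affected
  offspring with both parents typed (each heterozygous parent contributes
  +1 if it transmitted the minor allele, −1 otherwise; homozygous parents
  contribute 0) and a discordant sib pair contributes the affected-minus-
  unaffected genotype difference. Y = Σ_i D_i / √(Σ_i D_i²) over families
  with at least one unit. The default is this *sum* variant; a per-family
  *averaged* variant (`pdt_variant="avg"`) divides D_i by the family's unit
  count before normalising.

Both components read the affected families' genotypes, so (X, Y) is
correlated under the null; its limiting law is bivariate normal with unit
variances and correlation ρ. The combined statistic is the quadratic form

    Q = (x, y) Σ_τ⁻¹ (x, y)ᵀ,   Σ_τ = [[1, ρ̂τ], [ρ̂τ, 1]],

with τ ∈ [0, 1] a user-set scaling of the off-diagonal (default 0.5). τ = 1
gives the Mahalanobis form — exactly χ² with 2 df under the null; τ = 0
gives the Euclidean distance from the origin, which rewards coherent
alternatives (sign(x) = sign(y), both away from zero) relative to the χ²
geometry. Because Q is evaluated with the scaled correlation while (X, Y)
keeps the unscaled one, its null law for 0 < τ < 1 is a weighted mixture of
two χ²(1) variables (eigenvalues of Σ^{1/2} Σ_τ⁻¹ Σ^{1/2}) — not χ²(2) —
so p-values are computed by parametric bootstrap.

## Estimation pipeline, per SNP

1. **MAF**: allele counting over a configurable source (default: controls;
   automatic fallback to all samples when the source is monomorphic or
   untyped, recorded in the output).
2. **ρ̂ by gene dropping**: founders (including every unrelated control and
   case, which are part of X's null sampling variability) receive two
   alleles i.i.d. Bernoulli(p̂); non-founders inherit one uniformly random
   allele from each parent; the observed missingness pattern is
   superimposed; (X, Y) is recomputed per replicate and ρ̂ is the Pearson
   correlation over replicates where both are defined (defaults: 1,000
   drops; undefined replicates are discarded and counted).
3. **Q and p-value**: parametric bootstrap drawing pairs from
   BVN(0, [[1, ρ̂], [ρ̂, 1]]) (the *unscaled* correlation), scoring each with
   the τ-scaled form, and returning the add-one estimator
   (1 + #{Q* ≥ Q_obs})/(1 + t) so p > 0 always (default t = 10,000).
4. **Comparators**: MAX = max(|x|, |y|) with a bootstrap p-value under the
   same bivariate normal (two-sided by default; a signed one-sided variant
   is available), and the χ²(2) survival probability at x² + y².

All randomness derives from one seed; each SNP gets an independent child
stream, so results are reproducible and order-independent.

## Kinship

Kinship coefficients are computed by the standard recursion over a
topological ordering (founders non-inbred and mutually unrelated):
φ(i,i) = ½(1 + φ(fa_i, mo_i)), φ(i,j) = ½(φ(fa_i, j) + φ(mo_i, j)) for j
processed earlier. The matrix is stored as per-family dense blocks; the
wQLS solves are per-family and reuse a single factorisation across gene-drop
replicates, which is what makes per-replicate correlation estimation cheap.
Correctness is checked against brute-force Monte-Carlo identity-by-descent
sharing on random pedigrees.

## Simulator

The simulator emulates a candidate-gene family study: a biallelic disease
locus and a test SNP with equal MAFs, linked without recombination within
families, with LD set by Lewontin's D′ (haplotype frequencies
p(DA) = p_D p_A + D′·Dmax, the minor alleles positively coupled). Affection
is Bernoulli in the disease-locus genotype with dominant or recessive
penetrances solved in closed form from a fixed 5% prevalence and a
genotype relative risk; parents and offspring are phenotyped by the same
model. Unrelated controls are sampled conditional on being unaffected,
independent cases on being affected.

The default family structure table is 47 case-parent triads plus 292
nuclear families of sizes 4–7 (counts 126/89/48/29, i.e. 2–5 offspring).
Ascertainment:

* triads are retained when the offspring is affected and the family has at
  least two affected members (positive family history);
* larger families are retained when they have at least one affected
  offspring and, whenever an affected full-sib pair exists, the summed
  excess identity-by-descent sharing at the disease locus over affected sib
  pairs (read from true descent) is strictly positive. Families without an
  affected sib pair carry no variable sharing — their co-segregation
  statistic is degenerate at zero — and are retained.

This true-descent sharing rule is a deliberate proxy for a multipoint
co-segregation (NPL/LOD) screen, which is out of scope; under the null
(D′ = 0) the proxy cannot affect the size of any test because the test SNP
segregates independently of the disease locus. By default the structure
table is interpreted as *post-filter* targets (cells are regenerated until
filled, so every replicate has an identical design); a strict *pre-filter*
mode (`ascertainment="pre"`) instead simulates proband-ascertained families
to the table counts and analyses only the subset with affirmative history
and co-segregation evidence, which yields a much smaller and variable
analysis set. The post-filter reading reproduces the intended design
composition (about 88% of nuclear families with a single affected
offspring) and a correctly calibrated family component; the strict subset
leaves too few families for the PDT normal approximation to hold.

Experiment runners measure empirical type I error (D′ = 0; a trait model is
still required to drive ascertainment, defaulting to dominant RR = 2, which
cannot affect size) and power (D′ = 0.8) over independent replicates, with
binomial confidence intervals, using one child RNG stream per replicate.

## What the simulator does and does not emulate

It reproduces the two-locus LD structure, penetrance-based affection,
prevalence constraint, family-history/co-segregation ascertainment and the
hybrid sample layout. It deliberately omits residual familial aggregation
(polygenic background or shared environment), covariates, age of onset,
genotyping error, recombination between the two loci, and marker-panel
linkage analysis. The omission of residual aggregation matters for power
under the alternative: with a single-locus trait model, an affected
offspring's disease status is maximally attributable to the simulated
locus, so transmission distortion — and hence family-component power — is
an upper bound on what designs with substantial non-locus familial risk
would show. Calibration conclusions (type I error, p-value uniformity) are
unaffected. Passing tests therefore demonstrate correct null behaviour and
internally consistent power ordering, not the absolute power of any
particular real study.

## Numerical conventions and edge cases

* Genotypes are minor-allele counts; the minor allele is estimated from
  controls (ties broken lexicographically), "0" is the missing allele code,
  phenotype 0/−9 is unknown.
* Individuals missing the genotype at a SNP are dropped from that SNP's
  statistics (no imputation); transmission units require child and both
  parents typed; discordant sib pairs require both sibs typed.
* X is undefined (NaN) when the analysis set is monomorphic (V ≤ 0); Y is
  undefined when Σ D_i² = 0; such SNPs are reported with a reason, and such
  gene-drop replicates are discarded from ρ̂.
* A singular within-family correlation block (e.g., duplicated samples with
  φ = ½) raises an error naming the SNP and family.
* |ρ̂τ| ≥ 1 is rejected before combination (cannot occur for τ ≤ 1 and a
  proper correlation, but ρ̂ is an estimate).
* The bootstrap add-one estimator bounds p away from 0 at 1/(t+1); p-value
  resolution is 1/(t+1).
* Bootstrap and gene-drop replicate counts in the bundled experiment
  configurations (500 replicates × 200 drops × 2,000 draws) are scaled-down
  problem sizes chosen so a full calibration experiment runs in tens of
  seconds on one core; library defaults are 1,000 and 10,000.

## Known limitations

* Autosomal biallelic SNPs only; no X-linked or multiallelic markers.
* Founders are assumed non-inbred and mutually unrelated; inbreeding enters
  only through pedigree loops.
* The exact historical weighting variants of both components (the modified
  quasi-score weighting; PDT sum vs average) are exposed as configuration
  rather than fixed, since the literature uses several; defaults are the
  unweighted case indicator and the sum variant.
* Gene-level summaries report raw minimum p-values across SNPs (fine-mapping
  usage); Bonferroni adjustment is optional and off by default.
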