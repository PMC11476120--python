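# Methods

This note documents the models, defaults and numerical choices behind
`mirfa`, and what the synthetic-data suite does and does not demonstrate.

## Synthetic herd generator (`simdata`)

The generator emulates the data structure of a milk-recording genetics
study: a pedigree, SNP genotypes, repeated test-day phenotypes and FT-MIR
spectra.

**Pedigree.** `n_founders` unrelated animals; each subsequent generation
is produced by random matings whose parents are drawn from a sire half and
a dam half of the previous generation. The pedigree is topologically
ordered and parent ids of founders are 0. There is no selection and no
assortative mating.

**Genotypes.** Founder haplotypes are Bernoulli draws at per-SNP minor
allele frequencies sampled uniformly from `maf_range` (default
0.05–0.5); descendants receive one allele per parent by gene dropping.
SNPs are placed on chromosomes 1–29 and X with strictly increasing
positions. Consequence: linkage disequilibrium arises only from pedigree
co-inheritance, not from chromosomal linkage — marker maps are treated as
unlinked (transmission is independent per SNP).

**Trait model.** Each record is
y = μ + parity + lactation-stage + season + HTD + u + c + e.
The additive value u is the sum of a QTN part (dosages of `n_qtn` marked
SNPs times effects) and an infinitesimal polygenic part propagated as
u_off = ½(u_sire+u_dam) + N(0, ½σ²_poly(1−F̄)) with F̄ the mean parental
inbreeding from the tabular A matrix. σ²ᵤ is partitioned between the two
parts by `qtn_variance_frac` (default 0.5): QTN effects are drawn N(0,1)
and rescaled so their founder-frequency variance Σ2pⱼqⱼβⱼ² hits the QTN
share, which gives downstream GWAS detectable signals while the pedigree
still carries covariance for REML. Permanent environment c ~ N(0, σ²𝚌)
per cow, residual e ~ N(0, σ²ₑ) per record, herd-test-date effects
i.i.d. N(0, htd_sd²) over `n_htd` labels. Default variances
(0.3, 0.2, 0.5) give h² = 0.3 and repeatability 0.5, a typical
medium-heritability milk-composition trait. Records per cow default to
4–7 (recording schemes average roughly five to six test days per
lactation); parity, days in milk (5–365) and calving month are drawn per
record, and calving season follows the month mapping Mar–May = Spring,
Jun–Aug = Summer, Sep–Nov = Autumn, Dec–Feb = Winter.

**Spectra.** Absorbance(w) = Σₖ concₖ·φₖ(w) + baseline(w) + ε(w) on the
1060-point grid 925.66–5010.15 cm⁻¹ (Beer–Lambert linearity). Component
signatures φₖ are sums of three Gaussian peaks with centers drawn from
plausible mid-IR bands (fingerprint 1000–1500, ester carbonyl
1730–1770, C–H stretch 2840–2980 cm⁻¹) using a per-name deterministic
RNG, so a component's signature is stable across runs. ε is Gaussian with
standard deviation `noise_sd` (default 0.002 absorbance units) inflated
6× inside the two water-associated regions 1597.21–1712.95 and
3063.25–3641.95 cm⁻¹. Not emulated: instrument drift, scatter effects,
non-linearity at high absorbance. Passing tests on these spectra
demonstrate that the pipeline machinery is correct, not that real milk
spectra carry the simulated information content.

**Reference values.** Where a wet-chemistry reference is needed
(calibration, duplicate-error QC), duplicates are simulated as the true
trait value times independent 5% relative errors, and the reference is
their mean — consistent with a QC rule that tolerates up to 10% relative
disagreement between duplicates. This keeps calibration R² realistically
below 1.

## Spectral preprocessing and QC (`spectra`)

Savitzky–Golay derivatives use window 9 and polynomial order 3 by default
(derivative order 1 or 2), computed with respect to the grid index; the
published wavenumber grid is uniform to within rounding (≈3.86 cm⁻¹
spacing), so index-space and wavenumber-space derivatives differ only by
a constant factor that PLSR absorbs. Two-pass recipes (D1+D1, D2+D2,
D1+D2) apply the passes left to right.

Characteristic-wave selection is a deterministic stand-in for manual
curation: within optional wavenumber windows, waves are ranked by absolute
Pearson correlation with the target on training samples and the top
`n_keep` (default 600, within the 459–709 range used for published
models) are kept; ties break toward the lower wavenumber; zero-variance
waves get correlation 0. Water regions are *not* excluded by default.

The GH statistic is computed in PCA-score space: spectra are projected on
the leading `n_components` principal components (fitted on the same set),
and GH is the squared Mahalanobis distance of the scores from their
centroid divided by the component count, so E[GH] ≈ 1 and the
conventional cut GH ≤ 3 is scale-free. A raw 1060-dimensional covariance
would be singular at realistic sample sizes; score space is the standard
chemometric reading. Singular score covariances are ridge-regularized
with a warning.

Record QC applies togglable rules — fat 1.5–9%, protein 1–7%,
SCC ≤ 10⁶/mL, duplicate relative error |m₁−m₂|/mean ≤ 10%, GH ≤ 3 —
and logs one row per violated rule, so kept + rejected = input.

## PLSR calibration (`calibration`)

`fit_plsr` is NIPALS PLS1 on centered data: iteratively extract the
weight vector X′y/‖X′y‖, scores, loadings and response loading, deflate,
and assemble coefficients B = W(P′W)⁻¹q. With as many components as the
rank it reproduces least squares (tested against a normal-equations
oracle and against scikit-learn's PLSRegression as an independent
implementation). The latent-component grid defaults to 8–10.

Cross-validation is 10-fold with fold assignment by hashing sample ids
(order-invariant); derivative preprocessing is per-sample and applied
once, while wave selection — which uses the target — is redone inside
each training fold. Metrics use the shared population denominator N, so
R² = 1 − 1/RPD² holds exactly on any one set. Model selection ranks the
recipe × components × n_keep grid by R²_cv, breaking ties by lower
RMSE_cv and then the simpler model; the winner is refit on all training
data and evaluated once on the held-out 25% split.

## Phenotype correction (`phenocorrect`)

The correction model Y = μ + Pᵢ + Lⱼ + Sₖ + HTDₘ + e uses corner
(first-level-zero) constraints for estimability; aliased columns are
dropped with a warning. Level binning: parity 1–4 → levels 1–4, parity
5–10 → level 5; lactation level = ⌊(DIM−5)/30⌋+1 clamped to 12 (DIM 365
would otherwise spill one day past the twelfth 30-day bin); records
outside parity 1–10 or DIM 5–365 are flagged and excluded. HTD is random
with identity structure, fitted by the same REML engine as the animal
model. The corrected phenotype subtracts only the estimated fixed part
(μ + P + L + S) and averages over a cow's records: the HTD prediction is
deliberately left in the residual, where it averages toward zero across a
cow's test dates, because the correction is defined as removal of fixed
effects.

## Variance components and breeding values (`genparams`)

**Relationship matrices.** A by the tabular recursion
(aᵢᵢ = 1 + ½a_sd, off-diagonals ½(a_js+a_jd)); G by VanRaden method 1,
G = ZZ′/(2Σpⱼ(1−pⱼ)) with observed allele frequencies and per-SNP mean
imputation; H⁻¹ = A⁻¹ + [0, 0; 0, (wG + (1−w)A₂₂)⁻¹ − A₂₂⁻¹] on the
genotyped block with blend weight w = 0.95 guaranteeing invertibility.

**AI-REML.** The engine handles an arbitrary set of independent random
terms with i.i.d. residual via the mixed-model equations. Per iteration it
factorizes the coefficient matrix once, obtains the score vector from
trace identities on blocks of C⁻¹, builds the average-information matrix
from the working vectors (∂V/∂θᵢ)Py (each requiring only one extra MME
solve), and proposes a Newton step. Safeguards: step-halving into the
parameter space (variance floor 10⁻⁸ × total variance), acceptance only
if the restricted likelihood does not decrease, and otherwise the
monotone EM-REML update. Convergence uses the squared-relative-change
criterion Σ(βₜ−βₜ₋₁)²/Σβₜ² < 10⁻⁶ with at most 300 iterations. The
restricted likelihood computed from the MME factorization was verified
against a dense-V oracle to machine precision.

**Bivariate components.** Pairwise (co)variances use the sum-of-traits
decomposition: fit the univariate model to y₁, y₂ and y₁+y₂ and set
Cov_x = (σ²ₓ(y₁+y₂) − σ²ₓ(y₁) − σ²ₓ(y₂))/2 for x ∈ {u, c, e}. With both
traits recorded on the same rows (the case here — all traits are
predicted from the same spectra) this coincides with bivariate REML and
returns r_G = 1 exactly for duplicated traits; it avoids the fragility of
a joint 6-parameter fit at desk scale. Multi-trait correlation matrices
assembled pairwise can be bent to the nearest PSD matrix
(`bend_to_psd`, eigenvalue flooring).

**EBVs.** BLUP solutions of the MME at the REML estimates, centered to
mean 0 over evaluated animals. Two quality measures are reported:
the correlation between the per-cow corrected phenotype and the EBV
(the conventional field definition of "accuracy" for this design — note
it is optimistic, since the EBV is itself a shrunken function of those
phenotypes), and a PEV-based reliability 1 − PEV/(σ²ᵤKᵢᵢ) per animal.

## GWAS (`gwas`)

QC order: chromosome filter (1–29, X; X treated as autosomal since all
animals are cows), SNP call rate ≥ 0.98, individual call rate ≥ 0.98,
then the 1-df Hardy–Weinberg χ² (classic genotype-count test, matching
the conventional chip-QC default) at p ≥ 10⁻⁴. Missing dosages are
mean-imputed for scans.

GLM: ordinary least squares of the phenotype on intercept + k principal
components (default 5) + dosage, Wald t-test. MLM: the kinship variance
ratio is estimated once on the null model by profile REML over the
eigenvalues of K (the P3D shortcut) and every SNP is then tested by
generalized least squares in the eigenbasis; with K = I this reduces
exactly to the GLM. FarmCPU alternates (i) a fixed-effect step testing
every SNP with the current pseudo-QTNs as covariates (a pseudo-QTN is
tested with itself excluded) and (ii) a random-effect step choosing the
bin size ({5×10⁵, 5×10⁶, 5×10⁷} bp) and pseudo-QTN count
({2, 5, 10, 20}, eligibility p < 0.01) that maximize the REML likelihood
of a kinship built from the candidate set (computed with a low-rank
eigendecomposition, so the cost is linear in sample size). The loop stops
when the pseudo-QTN set stabilizes, after 10 loops, or immediately after
the first scan if no SNP reaches 0.05/m (the result is then the flagged
GLM scan). A pseudo-QTN's reported p-value is the one from the iteration
in which it was first tested as a candidate; this substitution is what
prevents the iterations from ratcheting chance signals on null data while
leaving real QTNs (whose conditional significance persists) untouched.

Significance uses the Bonferroni threshold α/m. Annotation is positional:
exonic if inside a listed exon, intronic if inside the gene body,
upstream/downstream within a window (default 2000 bp) of the TSS/TES on
the gene's strand, otherwise intergenic with both flanking genes and
distances; SNPs on chromosomes absent from the annotation are unknown.

## Validation (`snpvalidate`)

One-way fixed-effects ANOVA of the trait across AA/AB/BB classes per
candidate SNP; classes with fewer than 2 observations are dropped.
The Bonferroni multiplier is the number of SNPs carried into validation
(across-SNP correction; per-pair comparisons would multiply by 3 instead —
the across-SNP reading is stricter at the family level). Orderings are
reported as e.g. "AA > AB > BB" with a monotone vs heterozygote-extreme
classification of the allele-dosage pattern.

## Study conditions used by the statistical suites

Chosen once, as the conditions under which the estimators are exercised:

* REML recovery: 1,500 recorded cows × 3 records, pedigree A built over
  150 founders + two generations (1,650 animals), truth
  (σ²ᵤ, σ²𝚌, σ²ₑ) = (0.3, 0.2, 0.5); 10 seeds, agreement within 3
  empirical standard errors of the seed means.
* Null calibration: 800 unrelated cows × 5,000 independent SNPs for
  GLM/MLM; 500 × 2,000 for the 20 FarmCPU null runs.
* FarmCPU power: 1,000 cows × 5,000 SNPs, five QTNs at 3% of phenotypic
  variance each. Three percent was fixed from the noncentral-t power of
  the conditional marker test at this sample size (a 2% QTN sits almost
  exactly at the Bonferroni detection boundary, ≈60% power; 3% gives
  ≈93%), so the suite measures the algorithm rather than a coin flip.
* The pipeline default (250 cows, 800 SNPs) is sized so a full
  end-to-end run finishes in well under a minute; the published scale
  (~2,000 cows, ~42,500 SNPs) is a configuration, not a limit of the
  code.

## Known limitations

* No chromosomal linkage or LD beyond pedigree co-inheritance; FarmCPU's
  bin logic is exercised, but bins never contain correlated proxies of a
  causal SNP as they would on a real map.
* The 27-trait joint analysis of a full study is assembled pairwise, not
  fitted jointly.
* No genetic groups for unknown parents, no maternal or dominance
  effects, no Gibbs/Bayesian alternatives.
* The GH filter's score-space definition is one standard reading of the
  chemometric convention; vendor implementations differ in detail.
* Wave selection is algorithmic (correlation ranking); expert manual
  curation of absorption windows may behave differently on real spectra.
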