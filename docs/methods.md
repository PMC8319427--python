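# Methods

## The population being emulated

The synthetic generator mimics a multibreed Angus–Brahman beef herd bred
in a diallel design and binned into six breed groups (BGs) by Brahman
fraction: BG1 0–0.20, BG2 0.21–0.40, BG3 a fixed 0.375 cross, BG4
0.41–0.60, BG5 0.61–0.80, BG6 0.81–1.00. Individuals cycle through the six
groups and draw their Brahman fraction *b* uniformly within the group
range (BG3 is constant). Only the marginal breed-fraction spectrum is
simulated, not the pedigree itself: no pipeline stage consumes a pedigree,
and the genomic relationship matrix is estimated from markers.

## Genotypes

Per SNP, breed-endpoint allele frequencies p_A, p_B ~ Uniform(0.05, 0.95)
are drawn independently; an individual's alternate-allele frequency is the
linear blend p(b) = p_A + b·(p_B − p_A) and genotypes are Binomial(2, p(b)),
independent across SNPs. No linkage disequilibrium is simulated: the herd
study's inference never uses LD, and independent markers keep the GRM
well-conditioned and the recovery targets analyzable. Two consequences are
deliberate and realistic for a mixed population: (i) a Wahlund-effect
heterozygote deficit, so the HWE filter (p < 0.05) removes a substantial
SNP fraction (~15% at 2,000 SNPs); (ii) a dominant breed-gradient
eigenvector in the GRM, which is what makes variance ratios identifiable
at n = 200.

## Taxa

Per taxon, a latent log₁₀ abundance is

    intercept + breed_slope·b + sex_effect + g + e

with g drawn via a Cholesky factor of G + 1e-8·I scaled so
Var(g)/(Var(g)+Var(e)) equals the planted h², and a total latent SD of 0.6
(default). Intercepts ~ N(−2.5, 1) give a realistic abundance span; sex
effects ~ N(0, 0.1). Latent values are exponentiated, renormalized per
sample to sum to exactly 1, and any abundance below the detection floor
(2 × 0.00004613, i.e. twice the half-detection-limit constant of the 16S
workflow) is set to exactly 0 — flooring happens after closure, matching a
detection limit defined on relative abundance.

The closure step matters for interpretation: the observed log relative
abundance is the latent trait minus a shared log-total term that itself
contains genetic variance. Single-cohort per-taxon heritability estimates
on observed abundances are therefore noisy (per-replicate SD ≈ 0.29 at
n = 200 / 2,000 SNPs) and shifted upward by roughly +0.1 relative to the
planted latent ratio. The recovery simulations that validate the estimator
(and the acceptance script) generate the latent step-1 trait directly, so
they test the estimator, not the compositional distortion. Passing tests
show the REML/GLS machinery is calibrated and unbiased; they do not show
that per-taxon h² from one real cohort is precise — in the real study that
precision comes from 92k markers and family structure the desk-scale
generator does not reproduce.

## Phenotypes

Stage weight gain (WG) and IgG1 are fixed effects (sex, centered age) plus
a microbiome effect m with covariance M·σ²ₘ (M built from the cohort's own
core log abundances) plus iid residual, scaled so σ²ₘ/(σ²ₘ+σ²ₑ) equals the
planted microbiability; default planted values are 0.106 (WG) and 0.100
(IgG1). Body weights are constructed so the stage weight-gain identity
(WG = final BW − initial BW) holds exactly. Total WG SD is 25 kg; IgG1 is
10 ± 3 mg/mL. Effect sizes for sex and age on taxa and phenotypes are
arbitrary defaults (no printed values exist to calibrate them against) and
are documented here rather than tuned.

All randomness flows from one integer seed through `SeedSequence` children
(population, genotypes, taxa, phenotypes), so identical configs reproduce
byte-identical files.

## Genotype QC

Filters run in the printed order with strict `<` comparisons: (1) call
rate < 0.95 on both axes (statistics from the input matrix); (2)
individuals with outlying-high autosomal heterozygosity or maximum IBS —
operationalized as one-sided z-scores → normal p-values → BH, removing
FDR < 0.01, since the chip-QC tool the study used does not document its
internal outlier rule; (3) MAF < 0.05; (4) HWE chi-square (1 df) p < 0.05,
monomorphic SNPs returning p = 1; (5) Y-chromosome SNPs. SNP statistics
are recomputed after individual removal, each removal records its first
triggering rule, and missing genotypes are excluded from all frequency
computations (never imputed at QC).

## Diversity

Shannon uses log base 2 (the convention of the upstream 16S toolchain;
the base is an argument). Bray–Curtis comes from `scipy.spatial.pdist`,
held in a `skbio.DistanceMatrix`. PCoA is classical scaling — Gower
double-centering of −D²/2, `eigh`, coordinates from the top-k positive
eigenvalues, negative eigenvalues reported but never embedded. PERMANOVA
permutes raw group labels for a single fixed factor; when the number of
distinct label assignments is ≤ the requested permutation count it
enumerates all of them exhaustively (p = #{F* ≥ F}/total), otherwise
p = (#{F* ≥ F}+1)/(n_perm+1), ties counting toward the numerator. Both the
pseudo-F and the PCoA embedding are cross-checked against scikit-bio in
the test suite. Rarefaction subsamples without replacement via the
multivariate hypergeometric distribution at depth 10,840 by default;
relative abundances are computed from rarefied counts when rarefaction is
used. Phylogeny-aware metrics (UniFrac, Faith PD) are out of scope: the
analyses here only consume Shannon and Bray–Curtis.

The floor-log transform adds the half-detection-limit constant 0.00004613
only to taxa that contain at least one zero; taxa observed everywhere are
transformed unchanged. This keeps the transform strictly monotone within
every taxon column.

## Mixed models

`reml_single_component` profiles the restricted likelihood on the variance
ratio r ∈ [1e-6, 1−1e-6]: one eigendecomposition of K rotates y and X so
each likelihood evaluation is O(nq²); a 41-point grid seeds a bounded
scalar optimization (xatol 1e-9) with explicit endpoint checks. A
likelihood whose range over the grid is < 1e-6 (e.g. K = I, where only
σ²ᵤ+σ²ₑ is identifiable) is flagged flat and the ratio reported as NaN
rather than a spurious number. REML (not ML) is used throughout so fixed
effects do not bias the components.

The GRM is VanRaden method 1 — W = genotype − 2p, G = WWᵀ/(2Σp(1−p)) —
with allele frequencies from the analyzed cohort and missing calls
mean-imputed to 2p at this stage only. The microbial relationship matrix
standardizes taxa columns to mean 0, SD 1 (ddof 1; zero-variance taxa
dropped with a warning) and forms M = OOᵀ/n over the n core taxa, so
trace(M) = S−1.

The step-2 scan deliberately does **not** re-estimate variance components
per SNP — fixing V = Gσ²ᵤ + Iσ²ₑ from step 1 is the point of the two-step
scheme. One eigendecomposition whitens y, X and all dosages; each SNP is a
1-df Wald chi-square from the whitened simple regression after projecting
out X. SNPs with no observed dosage variation are flagged and untested.
Genomic control is the median-based estimator (median χ²/0.4549) with λ
clipped below at 1; the study's own inflation routine is regression-based
and undocumented, so the conventional estimator is used and recorded in
the run manifest. BH adjustment delegates to statsmodels.

`covariate_effect_test` (the bacteria-covariate animal model) whitens by
the null-model covariance and t-tests the covariate on n − rank(X) − 1
degrees of freedom; with σ²ᵤ = 0 it reduces exactly to the plain multiple
regression variant, which is also exposed directly.

## Association scans and classification

Breed composition enters regressions as the continuous Brahman fraction;
the six discrete groups are used for PERMANOVA. Sex is a single indicator,
age is centered days. Classification uses the printed cutoffs with both
boundaries resolved strictly: p < 0.05 significant; 0.05 ≤ p < 0.10
tendency (p = 0.05 falls in neither printed interval and is assigned to
tendency); p ≥ 0.10 not significant. No multiple-testing correction is
applied in the regression scans — BH is reserved for the genomic scans —
so raw p-values with class labels are reported. Weight-gain models add the
stage's initial body weight as a covariate (newborn weight for the
preweaning stage, and so on).

## Co-occurrence network

Spearman correlations (average-rank ties, two-sided t-approximation p) over
core taxa; BH over the upper triangle only, each unordered pair tested
once; edges require |ρₛ| > 0.25 AND adjusted p < 0.001, both strict, so a
correlation exactly at 0.25 is excluded. All nodes tied for maximal degree
are reported as hubs (the singular "hub" only when unique). Layout and
styling are left to downstream tools; the package emits the edge list and
GraphML with degree and sign attributes.

## Problem sizes

Default simulations use 200 individuals, 2,000 SNPs and 100 taxa — the
scale at which the variance-ratio estimators are comfortably identifiable
and the full test suite and recovery runs complete in minutes on one CPU.
The recovery protocol (100 replicates per planted value) bounds the
Monte-Carlo error of a recovery mean at roughly ±0.03 for heritability and
±0.007 for microbiability (per-replicate SDs ≈ 0.29 and ≈ 0.07).

## Known limitations

- No LD, no pedigree, single-stage cohorts only; the three growth stages
  of a real herd share animals, which is not simulated.
- The compositional closure couples taxa; planted per-taxon parameters are
  recovered on the latent scale, attenuated/shifted on the observed scale
  (see above). Planted breed slopes can even flip sign for low-abundance
  taxa when many taxa share the slope — association tests therefore plant
  sparse, strong slopes.
- Heritability h² is estimated with age and sex as fixed effects; whether
  breed composition should also be conditioned on is genuinely open, so
  both designs are possible by passing a different X (neither is asserted
  as canonical).
- The exact-test alternative for HWE is noted but not implemented; the
  1-df chi-square is the default and only test.
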