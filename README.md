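# herdscan

Host genetics of the hindgut microbiota in a multibreed beef herd —
a tested, reusable implementation of the full analysis chain: SNP-chip
quality control, microbiota diversity and ordination, taxon heritability,
two-step mixed-model genome scans with genomic control, microbiability of
growth and immune phenotypes, breed-composition and phenotype association
scans, and Spearman co-occurrence networks. A synthetic multibreed herd
generator with known ground truth makes every stage testable without any
external data.

## Who this is for

Quantitative geneticists and microbiome researchers who want to ask, for
a structured animal population (here: a graded Angus–Brahman spectrum in
six breed groups), *how much of the variation in gut-microbial abundance
is attributable to the host genome, and how much of the variation in host
phenotypes is attributable to the microbiome* — and to do so with explicit,
replayable statistical machinery rather than a pile of one-off scripts.

## The models

**Taxon heritability (animal model).** For each core taxon (nonzero in
≥50% of animals at a growth stage), the log₁₀ relative abundance *y* is
modeled as

    y = Xβ + Zu + e,   u ~ N(0, G σ²ᵤ),   e ~ N(0, I σ²ₑ)

where X carries fixed effects (sex, age), G is the VanRaden genomic
relationship matrix from post-QC SNPs, and h² = σ²ᵤ/(σ²ᵤ+σ²ₑ). Variance
components are estimated by REML, profiled on the variance ratio through a
one-time eigendecomposition of G.

**Two-step SNP scan.** Step 1 fits the model above once; step 2 tests every
SNP by generalized least squares under the *fixed* covariance
V = Gσ²ᵤ + Iσ²ₑ:

    y = Xβ + X_SNP β_SNP + ε,   Var(ε) = G σ²ᵤ + I σ²ₑ

with a 1-df Wald test per SNP, median-based genomic control
(λ = median χ²/0.4549, clipped at 1), and Benjamini–Hochberg FDR at 0.05.

**Microbiability.** Replacing G with the microbial relationship matrix
M = OOᵀ/n — O the column-standardized log abundances of the n core taxa —
the same REML machinery partitions a phenotype (stage weight gain, plasma
IgG1) into microbiome-associated and residual variance; m² = σ²ₘ/(σ²ₘ+σ²ₑ).

**Around them:** prevalence-based core-taxon filtering, a log₁₀ transform
adding half the 16S detection limit (0.00004613) to any taxon containing
zeros, rarefaction, Shannon index, Bray–Curtis / PCoA / one-factor
PERMANOVA (with exhaustive enumeration on small designs), OLS association
scans classified significant (p < 0.05) / tendency (0.05 ≤ p < 0.10), and a
co-occurrence network keeping taxon pairs with |ρₛ| > 0.25 and BH-adjusted
p < 0.001.

## Worked example

```python
import numpy as np
from herdscan.synth import SimulationConfig, simulate_cohort
from herdscan.diversity import core_taxa_filter, log10_floor_transform
from herdscan.mixed_model import genomic_relationship_matrix, reml_single_component

config = SimulationConfig(seed=2026, n_individuals=200, n_snps=2000,
                          n_taxa=100, taxon_h2=0.3)
truth, geno, abundance, meta = simulate_cohort(config)

log_core = log10_floor_transform(core_taxa_filter(abundance))
grm = genomic_relationship_matrix(geno)
age = meta["age_days"].to_numpy(float)
x = np.column_stack([np.ones(200), (meta["sex"] == "M").astype(float),
                     age - age.mean()])
vc = reml_single_component(log_core.iloc[:, 0].to_numpy(), x, grm)
print(f"h2 = {vc.ratio:.3f}")
```

The numbered drivers under `analysis/` run the whole per-stage workflow on
a 200-animal, 2,000-SNP, 100-taxon synthetic cohort and narrate what they
find. On seed 2026 they print, among other things:

```
PERMANOVA breed group: pseudo-F = 7.84, p = 0.001 (999 permutations)
breed composition: 54 of 67 core taxa associated or tendency (80.6%)
microbiability of weight gain: m2 = 0.138
microbiability of IgG1: m2 = 0.167
67 core taxa, 116 co-occurrence edges
hub taxa (degree 11): taxon096
```

i.e. microbiota structure differs across breed groups (the generator
plants breed-graded taxa), both phenotypes carry a nonzero microbiome
variance fraction (0.106 and 0.100 were planted; single-cohort REML
estimates scatter around those), and the co-occurrence network has a
well-defined hub. The same stages are scriptable via the `herdscan` CLI
(`simulate`, `qc`, `diversity`, `heritability`, `network`, `all`) driven
by a YAML config; every run writes a manifest with its seed and
thresholds so deleting the output directory and re-running reproduces it
byte for byte.

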