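"""Parameter-recovery simulations: do the estimators get the truth back?

Heritability recovery plants a known variance ratio in a log-abundance
trait generated from the step-1 animal model over a simulated multibreed
genotype panel and re-estimates it with REML under the VanRaden GRM.
Microbiability recovery runs the full synthetic cohort (abundances, then a
phenotype whose microbiome effect has covariance proportional to M) and
re-estimates the planted variance fraction with REML under K = M.

Replicate seeds are derived deterministically from a base seed and kept
below 2**31.
"""

from __future__ import annotations

import numpy as np

from .diversity import core_taxa_filter, log10_floor_transform
from .mixed_model import (
    genomic_relationship_matrix,
    microbial_relationship_matrix,
    reml_single_component,
)
from .synth import (
    SimulationConfig,
    simulate_latent_trait,
    simulate_phenotypes,
    simulate_population,
    simulate_taxa,
)


def _rep_seed(base_seed: int, rep: int) -> int:
    return int((base_seed * 1_000_003 + rep) % 2**31)


def heritability_recovery(
    true_h2: float,
    n_reps: int = 100,
    n_individuals: int = 200,
    n_snps: int = 2000,
    base_seed: int = 1,
) -> np.ndarray:
    """REML heritability estimates over replicates with planted truth.

    Each replicate simulates a fresh herd (unlinked SNPs, breed-graded
    allele frequencies in Uniform(0.05, 0.95)), draws one trait from
    y = X beta + u + e at the planted ratio with sex and centered age as
    fixed effects, and fits the same model by REML with the VanRaden GRM.
    """
    estimates = np.empty(n_reps)
    for rep in range(n_reps):
        seed = _rep_seed(base_seed, rep)
        config = SimulationConfig(
            seed=seed, n_individuals=n_individuals, n_snps=n_snps
        )
        truth, geno, meta = simulate_population(config)
        grm = genomic_relationship_matrix(geno)
        rng = np.random.default_rng(seed + 7)
        age_c = meta["age_days"].to_numpy(float)
        age_c -= age_c.mean()
        x = np.column_stack(
            [
                np.ones(n_individuals),
                (meta["sex"] == "M").astype(float).to_numpy(),
                age_c,
            ]
        )
        beta = np.array([0.0, 0.1, 0.002])
        y = simulate_latent_trait(grm, true_h2, x, beta, rng)
        vc = reml_single_component(y, x, grm)
        estimates[rep] = vc.ratio
    return estimates


def microbiability_recovery(
    true_m2: float,
    phenotype: str = "WG",
    n_reps: int = 100,
    n_individuals: int = 200,
    n_taxa: int = 100,
    base_seed: int = 1,
) -> np.ndarray:
    """REML microbiability estimates over replicates with planted truth.

    Each replicate simulates a cohort whose abundances come from the taxa
    generator (small 500-SNP panel for the genetic component), builds
    M = O O^T / n from the standardized core log abundances, generates the
    phenotype with microbiome-effect covariance M sigma2_m at the planted
    fraction, and re-estimates the fraction with REML under K = M.
    """
    resp_col = {"WG": "WG_preweaning", "IgG1": "IgG1"}[phenotype]
    estimates = np.empty(n_reps)
    for rep in range(n_reps):
        seed = _rep_seed(base_seed, rep)
        config = SimulationConfig(
            seed=seed,
            n_individuals=n_individuals,
            n_snps=500,
            n_taxa=n_taxa,
            taxon_h2=0.25,
            phenotype_m2={phenotype: true_m2},
        )
        truth, geno, meta = simulate_population(config)
        abundance = simulate_taxa(truth, geno, config)
        meta = simulate_phenotypes(truth, abundance, meta, config)

        o = log10_floor_transform(core_taxa_filter(abundance, 0.5))
        m_mat = microbial_relationship_matrix(o)
        age_c = meta["age_days"].to_numpy(float)
        age_c -= age_c.mean()
        x = np.column_stack(
            [
                np.ones(n_individuals),
                (meta["sex"] == "M").astype(float).to_numpy(),
                age_c,
            ]
        )
        y = meta[resp_col].to_numpy(float)
        vc = reml_single_component(y, x, m_mat)
        estimates[rep] = vc.ratio
    return estimates
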