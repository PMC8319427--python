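"""Synthetic multibreed herd generator with known ground truth.

Emulates the structure of a graded Angus-Brahman beef herd: six breed
groups spanning the Brahman-fraction spectrum (BG1 mostly Angus through
BG6 mostly Brahman, with BG3 the fixed 37.5%-Brahman cross), per-SNP
allele frequencies interpolated between breed-specific endpoints,
compositional taxon abundances with a detection floor, additive-genetic
taxon effects with chosen heritabilities, and phenotypes (stage weight
gain, plasma IgG1) with a chosen microbiability.  Every planted parameter
is recorded so downstream estimators can be validated against truth.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` children, one per simulation stage, so
identical configs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix
from .diversity import (
    HALF_DETECTION_LIMIT,
    core_taxa_filter,
    log10_floor_transform,
)
from .mixed_model import (
    genomic_relationship_matrix,
    microbial_relationship_matrix,
)

# Brahman-fraction range per breed group; BG3 is a fixed 5/8 Angus cross.
BG_RANGES: dict[int, tuple[float, float]] = {
    1: (0.0, 0.20),
    2: (0.21, 0.40),
    3: (0.375, 0.375),
    4: (0.41, 0.60),
    5: (0.61, 0.80),
    6: (0.81, 1.00),
}

STAGE_AGE_DAYS = {
    "preweaning": (90.0, 10.0),
    "postweaning": (365.0, 15.0),
    "fattening": (540.0, 20.0),
}

# initial body weight per stage for weight-gain definitions (kg)
STAGE_WG_BASE = {
    "preweaning": ("BW_newborn", "BW_preweaning", 200.0),
    "postweaning": ("BW_preweaning", "BW_postweaning", 110.0),
    "fattening": ("BW_postweaning", "BW_fattening", 160.0),
}


@dataclass
class SimulationConfig:
    """Parameters of one synthetic single-stage cohort.

    ``taxon_h2`` and ``breed_slope`` may be scalars (applied to every
    taxon) or per-taxon arrays; ``phenotype_m2`` maps phenotype name to its
    planted microbiability.  ``detection_floor`` is twice the half-
    detection-limit constant 0.00004613 of the 16S workflow.
    """

    seed: int
    n_individuals: int = 200
    n_snps: int = 2000
    n_taxa: int = 100
    detection_floor: float = 2 * HALF_DETECTION_LIMIT
    taxon_h2: float | np.ndarray = 0.25
    breed_slope: float | np.ndarray = 0.0
    phenotype_m2: dict = field(
        default_factory=lambda: {"WG": 0.106, "IgG1": 0.100}
    )
    latent_sd: float = 0.6  # total genetic+residual SD of log10 abundance
    sex_effect_sd: float = 0.1
    stage: str = "preweaning"
    wg_sd: float = 25.0  # microbial+residual SD of weight gain (kg)
    igg1_mean: float = 10.0  # mg/mL
    igg1_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("an explicit seed is required")
        for name in ("n_individuals", "n_snps", "n_taxa"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_snps < 2:
            raise ValueError("need at least two SNPs")
        if not 0 < self.detection_floor < 1:
            raise ValueError("detection_floor must be in (0, 1)")
        h2 = np.atleast_1d(np.asarray(self.taxon_h2, dtype=float))
        if ((h2 < 0) | (h2 >= 1)).any():
            raise ValueError("taxon_h2 must be in [0, 1)")
        for name, m2 in self.phenotype_m2.items():
            if not 0 <= m2 < 1:
                raise ValueError(f"phenotype_m2[{name}] must be in [0, 1)")
        if self.stage not in STAGE_AGE_DAYS:
            raise ValueError(f"unknown stage {self.stage!r}")


@dataclass
class PopulationTruth:
    """Ground-truth record of every planted parameter."""

    n_individuals: int
    brahman_fraction: np.ndarray
    breed_group: np.ndarray
    sex: np.ndarray
    angus_allele_freq: np.ndarray
    brahman_allele_freq: np.ndarray
    seed: int
    true_h2: np.ndarray | None = None
    true_m2: dict | None = None
    polygenic_values: np.ndarray | None = None  # n x taxa, filled by taxa sim
    latent_abundance: np.ndarray | None = None
    microbiome_effects: dict | None = None  # phenotype -> n-vector


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_population(
    config: SimulationConfig,
) -> tuple[PopulationTruth, GenotypeMatrix, pd.DataFrame]:
    """Draw the herd: breed composition, sex, age, and unlinked genotypes.

    Individuals cycle through the six breed groups; each draws its Brahman
    fraction b uniformly within its group's range.  Per SNP, breed-endpoint
    frequencies p_A, p_B ~ Uniform(0.05, 0.95) and an individual's
    alternate-allele frequency is p(b) = p_A + b (p_B - p_A); genotypes are
    Binomial(2, p(b)) independently per SNP (no linkage disequilibrium).
    """
    rng_pop, rng_geno = _child_rngs(config.seed, 4)[:2]
    n = config.n_individuals

    breed_group = np.array([(i % 6) + 1 for i in range(n)])
    lo = np.array([BG_RANGES[bg][0] for bg in breed_group])
    hi = np.array([BG_RANGES[bg][1] for bg in breed_group])
    brahman_fraction = rng_pop.uniform(lo, hi)

    sex = np.where(rng_pop.random(n) < 0.5, "F", "M")
    age_mean, age_sd = STAGE_AGE_DAYS[config.stage]
    age = np.round(rng_pop.normal(age_mean, age_sd, size=n)).astype(int)

    p_angus = rng_geno.uniform(0.05, 0.95, size=config.n_snps)
    p_brahman = rng_geno.uniform(0.05, 0.95, size=config.n_snps)
    p_ind = p_angus[None, :] + brahman_fraction[:, None] * (
        p_brahman - p_angus
    )[None, :]
    calls = rng_geno.binomial(2, p_ind).astype(float)

    chrom = [str((j % 29) + 1) for j in range(config.n_snps)]
    pos = [10_000 + 1_000 * (j // 29) for j in range(config.n_snps)]
    snps = pd.DataFrame(
        {"chrom": chrom, "pos": pos},
        index=pd.Index(
            [f"snp{j:05d}" for j in range(config.n_snps)], name="snp"
        ),
    )
    individuals = [f"animal{i:04d}" for i in range(n)]
    geno = GenotypeMatrix(calls, individuals, snps)

    meta = pd.DataFrame(
        {
            "breed_group": breed_group,
            "brahman_fraction": brahman_fraction,
            "sex": sex,
            "age_days": age,
            "stage": config.stage,
        },
        index=pd.Index(individuals, name="animal"),
    )
    truth = PopulationTruth(
        n_individuals=n,
        brahman_fraction=brahman_fraction,
        breed_group=breed_group,
        sex=sex,
        angus_allele_freq=p_angus,
        brahman_allele_freq=p_brahman,
        seed=config.seed,
    )
    return truth, geno, meta


def _scaled_effects(k: np.ndarray, ratio: float, total_var: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Draw one effect vector with covariance K * (ratio * total_var)."""
    n = k.shape[0]
    if ratio == 0:
        return np.zeros(n)
    chol = np.linalg.cholesky(k + 1e-8 * np.eye(n))
    return np.sqrt(ratio * total_var) * (chol @ rng.standard_normal(n))


def simulate_latent_trait(
    k: np.ndarray,
    ratio: float,
    x: np.ndarray,
    beta: np.ndarray,
    rng: np.random.Generator,
    total_var: float = 1.0,
) -> np.ndarray:
    """One quantitative trait from the animal model y = X beta + u + e with
    var(u)/(var(u)+var(e)) equal to ``ratio``."""
    n = k.shape[0]
    u = _scaled_effects(k, ratio, total_var, rng)
    e = rng.standard_normal(n) * np.sqrt((1 - ratio) * total_var)
    return np.asarray(x, float) @ np.asarray(beta, float) + u + e


def simulate_taxa(
    truth: PopulationTruth,
    geno: GenotypeMatrix,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Compositional taxon abundances with planted heritabilities.

    Per taxon, latent log10 abundance = intercept + breed_slope * Brahman
    fraction + sex effect + g + e with cov(g) = G sigma2_u (Cholesky of
    G + 1e-8 I) and the variance ratio equal to the taxon's target h2.
    Latent values are exponentiated, renormalized per sample to sum to 1,
    and abundances below the detection floor are zeroed.
    """
    rng = _child_rngs(config.seed, 4)[2]
    n, t = config.n_individuals, config.n_taxa
    h2 = np.broadcast_to(
        np.atleast_1d(np.asarray(config.taxon_h2, float)), (t,)
    )
    slope = np.broadcast_to(
        np.atleast_1d(np.asarray(config.breed_slope, float)), (t,)
    )
    grm = genomic_relationship_matrix(geno)
    chol = np.linalg.cholesky(grm + 1e-8 * np.eye(n))

    intercepts = rng.normal(-2.5, 1.0, size=t)
    sex_eff = rng.normal(0.0, config.sex_effect_sd, size=t)
    is_male = (truth.sex == "M").astype(float)
    total_var = config.latent_sd**2

    g_mat = np.empty((n, t))
    latent = np.empty((n, t))
    for j in range(t):
        g = np.sqrt(h2[j] * total_var) * (chol @ rng.standard_normal(n))
        e = rng.standard_normal(n) * np.sqrt((1 - h2[j]) * total_var)
        g_mat[:, j] = g
        latent[:, j] = (
            intercepts[j]
            + slope[j] * truth.brahman_fraction
            + sex_eff[j] * is_male
            + g
            + e
        )

    raw = 10.0**latent
    rel = raw / raw.sum(axis=1, keepdims=True)
    rel[rel < config.detection_floor] = 0.0

    truth.true_h2 = np.asarray(h2, float).copy()
    truth.polygenic_values = g_mat
    truth.latent_abundance = latent
    individuals = [f"animal{i:04d}" for i in range(n)]
    return pd.DataFrame(
        rel,
        index=pd.Index(individuals, name="animal"),
        columns=[f"taxon{j:03d}" for j in range(t)],
    )


def simulate_phenotypes(
    truth: PopulationTruth,
    abundance: pd.DataFrame,
    meta: pd.DataFrame,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Fill body weights, stage weight gain and IgG1 with planted m2.

    The stage phenotype is fixed effects (sex, centered age) plus a
    microbiome effect m with cov(m) = M sigma2_m, where M is the microbial
    relationship matrix of the core-filtered, floor-logged, standardized
    table, plus iid residual; sigma2_m/(sigma2_m+sigma2_e) equals the
    planted microbiability.  Body-weight fields are built so the stage
    weight-gain definition (WG = final BW - initial BW) holds exactly.
    """
    if list(abundance.index) != list(meta.index):
        raise ValueError("abundance and metadata must share individuals")
    rng = _child_rngs(config.seed, 4)[3]
    n = len(meta)
    core = core_taxa_filter(abundance, 0.5)
    o = log10_floor_transform(core)
    m_mat = microbial_relationship_matrix(o)

    is_male = (meta["sex"] == "M").astype(float).to_numpy()
    age_c = meta["age_days"].to_numpy(float)
    age_c = age_c - age_c.mean()

    out = meta.copy()
    effects: dict[str, np.ndarray] = {}

    init_col, final_col, wg_mean = STAGE_WG_BASE[config.stage]
    m2_wg = config.phenotype_m2.get("WG", 0.0)
    m = _scaled_effects(m_mat, m2_wg, config.wg_sd**2, rng)
    e = rng.standard_normal(n) * np.sqrt((1 - m2_wg) * config.wg_sd**2)
    wg = wg_mean + 8.0 * is_male + 0.3 * age_c + m + e
    effects["WG"] = m

    bw_init = np.round(rng.normal(32.0, 4.0, size=n), 1)
    if config.stage != "preweaning":
        # earlier-stage weights are carried as plausible historical values
        bw_init = np.round(rng.normal(230.0, 20.0, size=n), 1)
    out[init_col] = bw_init
    out[final_col] = bw_init + wg
    out[f"WG_{config.stage}"] = out[final_col] - out[init_col]

    m2_igg = config.phenotype_m2.get("IgG1", 0.0)
    m_i = _scaled_effects(m_mat, m2_igg, config.igg1_sd**2, rng)
    e_i = rng.standard_normal(n) * np.sqrt(
        (1 - m2_igg) * config.igg1_sd**2
    )
    out["IgG1"] = (
        config.igg1_mean + 0.5 * is_male + 0.01 * age_c + m_i + e_i
    )
    effects["IgG1"] = m_i

    truth.true_m2 = dict(config.phenotype_m2)
    truth.microbiome_effects = effects
    return out


def simulate_cohort(config: SimulationConfig):
    """Convenience wrapper running all three stages of the generator."""
    truth, geno, meta = simulate_population(config)
    abundance = simulate_taxa(truth, geno, config)
    meta = simulate_phenotypes(truth, abundance, meta, config)
    return truth, geno, abundance, meta
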