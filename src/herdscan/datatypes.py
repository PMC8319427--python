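"""Core in-memory containers shared across the pipeline.

Genotypes are held as an N x P float array of alternate-allele counts
(0/1/2) with ``nan`` marking missing calls; abundance tables and metadata
are plain pandas DataFrames so every stage can use ordinary pandas
indexing.  Distance matrices use :class:`skbio.DistanceMatrix`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AUTOSOMES = {str(c) for c in range(1, 30)}  # Bos taurus autosomes 1-29


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs alternate-allele counts.

    Parameters
    ----------
    calls:
        N x P float array with values in {0, 1, 2} and ``nan`` for missing.
    individuals:
        Ordered unique individual ids (length N).
    snps:
        DataFrame indexed by SNP id with columns ``chrom`` (str; "1"-"29",
        "X", "Y") and ``pos`` (1-based int).
    """

    calls: np.ndarray
    individuals: list[str]
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        self.individuals = list(self.individuals)
        if self.calls.shape != (len(self.individuals), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.snps)} SNPs"
            )
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("duplicate individual ids")
        if self.snps.index.has_duplicates:
            raise ValueError("duplicate SNP ids")
        valid = np.isnan(self.calls) | np.isin(self.calls, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("genotype calls must be 0/1/2 or missing")
        if (np.asarray(self.snps["pos"]) <= 0).any():
            raise ValueError("SNP positions must be positive (1-based)")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snps.index)

    def autosomal_mask(self) -> np.ndarray:
        return self.snps["chrom"].astype(str).isin(AUTOSOMES).to_numpy()

    def subset(self, individuals=None, snps=None) -> "GenotypeMatrix":
        """Return a copy restricted to the given individual / SNP ids."""
        ind_idx = np.arange(self.n_individuals)
        snp_idx = np.arange(self.n_snps)
        ids = self.individuals
        snp_df = self.snps
        if individuals is not None:
            lookup = {v: i for i, v in enumerate(self.individuals)}
            ind_idx = np.array([lookup[i] for i in individuals])
            ids = list(individuals)
        if snps is not None:
            snp_idx = self.snps.index.get_indexer(list(snps))
            if (snp_idx < 0).any():
                raise KeyError("unknown SNP id in subset request")
            snp_df = self.snps.loc[list(snps)]
        return GenotypeMatrix(
            self.calls[np.ix_(ind_idx, snp_idx)].copy(), ids, snp_df.copy()
        )


@dataclass
class VarianceComponents:
    """REML variance components of the single-random-effect animal model."""

    sigma2_u: float
    sigma2_e: float
    ratio: float
    log_restricted_likelihood: float
    converged: bool = True
    flat_likelihood: bool = False

    @property
    def total(self) -> float:
        return self.sigma2_u + self.sigma2_e


@dataclass
class QcReport:
    """Per-run record of every removal and the statistics behind it."""

    removed_individuals: pd.DataFrame  # columns: id, reason
    removed_snps: pd.DataFrame  # columns: id, reason
    snp_stats: pd.DataFrame  # call_rate, alt_freq, maf, hwe_p on input
    sample_stats: pd.DataFrame  # call_rate, heterozygosity, max_ibs on input
    metadata: dict = field(default_factory=dict)

    def reconciles(self, n_individuals_in: int, n_snps_in: int,
                   n_individuals_out: int, n_snps_out: int) -> bool:
        return (
            n_individuals_in == n_individuals_out + len(self.removed_individuals)
            and n_snps_in == n_snps_out + len(self.removed_snps)
        )


class PipelineError(RuntimeError):
    """Raised when a pipeline stage cannot proceed."""
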