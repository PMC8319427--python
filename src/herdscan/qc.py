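"""Marker and individual quality control for SNP-chip genotype matrices.

The filter chain mirrors the standard GWAS pre-processing for a multibreed
beef herd genotyped on a dense chip, applied per growth stage:

1. individuals and SNPs with call rate < 0.95,
2. individuals with outlying-high autosomal heterozygosity or outlying-high
   maximum identity-by-state (FDR < 1% on upper-tail z-scores),
3. SNPs with minor allele frequency < 0.05,
4. SNPs deviating from Hardy-Weinberg equilibrium (chi-square p < 0.05),
5. SNPs on the Y chromosome.

All thresholds are strict ``<`` comparisons; a SNP exactly at call rate
0.95 or MAF 0.05 is kept.  Missing genotypes are excluded from every
frequency computation and are never imputed here.  SNP statistics are
recomputed after individual removal, before the SNP filters run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import GenotypeMatrix, PipelineError, QcReport


@dataclass
class QcThresholds:
    """Filter thresholds; defaults are the conventional chip-QC values."""

    min_call_rate: float = 0.95
    min_maf: float = 0.05
    hwe_alpha: float = 0.05
    outlier_fdr: float = 0.01
    drop_y: bool = True


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Chi-square (1 df) goodness-of-fit p-value for Hardy-Weinberg.

    Expected genotype counts are computed at the observed allele frequency.
    Monomorphic input carries no information about HWE and returns p = 1.
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n <= 0:
        raise ValueError("at least one genotyped individual required")
    f_A = (2 * n_AA + n_Aa) / (2 * n)
    if f_A in (0.0, 1.0):
        return 1.0
    expected = n * np.array([f_A**2, 2 * f_A * (1 - f_A), (1 - f_A) ** 2])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def snp_summary(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP call rate, alternate-allele frequency, MAF and HWE p.

    All-missing SNPs get call rate 0 and NaN frequency/MAF/HWE p.
    """
    if g.n_individuals < 1:
        raise ValueError("need at least one individual")
    calls = g.calls
    present = ~np.isnan(calls)
    n_typed = present.sum(axis=0)
    call_rate = n_typed / g.n_individuals
    with np.errstate(invalid="ignore"):
        alt_freq = np.nansum(calls, axis=0) / (2 * n_typed)
    alt_freq = np.where(n_typed > 0, alt_freq, np.nan)
    maf = np.minimum(alt_freq, 1 - alt_freq)
    hwe_p = np.full(g.n_snps, np.nan)
    for j in range(g.n_snps):
        if n_typed[j] == 0:
            continue
        col = calls[present[:, j], j]
        n_aa = int((col == 0).sum())
        n_Aa = int((col == 1).sum())
        n_AA = int((col == 2).sum())
        hwe_p[j] = hwe_test(n_AA, n_Aa, n_aa)
    return pd.DataFrame(
        {
            "call_rate": call_rate,
            "alt_freq": alt_freq,
            "maf": maf,
            "hwe_p": hwe_p,
        },
        index=g.snps.index,
    )


def ibs_matrix(g: GenotypeMatrix) -> np.ndarray:
    """Pairwise identity-by-state: mean over shared non-missing SNPs of
    ``1 - |g_i - g_j| / 2``.  Pairs with no shared SNPs get NaN."""
    calls = g.calls
    indicators = [
        np.where(np.isnan(calls), 0.0, (calls == v).astype(float))
        for v in (0.0, 1.0, 2.0)
    ]
    i0, i1, i2 = indicators
    shared = (i0 + i1 + i2) @ (i0 + i1 + i2).T
    absdiff = (
        i0 @ i1.T + i1 @ i0.T + i1 @ i2.T + i2 @ i1.T
        + 2.0 * (i0 @ i2.T + i2 @ i0.T)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        ibs = 1.0 - absdiff / (2.0 * shared)
    ibs[shared == 0] = np.nan
    if np.isnan(ibs[np.triu_indices_from(ibs, k=1)]).any():
        warnings.warn("some pairs share no non-missing SNPs; IBS undefined")
    return ibs


def sample_summary(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-individual call rate, autosomal heterozygosity, max pairwise IBS."""
    if g.n_individuals < 2:
        raise ValueError("need at least two individuals for IBS")
    calls = g.calls
    present = ~np.isnan(calls)
    call_rate = present.sum(axis=1) / g.n_snps
    auto = g.autosomal_mask()
    auto_calls = calls[:, auto]
    auto_present = ~np.isnan(auto_calls)
    n_auto = auto_present.sum(axis=1)
    with np.errstate(invalid="ignore"):
        het = np.where(
            n_auto > 0,
            np.nansum(auto_calls == 1, axis=1) / n_auto,
            np.nan,
        )
    ibs = ibs_matrix(g)
    np.fill_diagonal(ibs, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        max_ibs = np.nanmax(ibs, axis=1)
    return pd.DataFrame(
        {"call_rate": call_rate, "heterozygosity": het, "max_ibs": max_ibs},
        index=pd.Index(g.individuals, name="individual"),
    )


def _upper_tail_outliers(values: np.ndarray, fdr: float) -> np.ndarray:
    """Flag upper-tail outliers: z-score -> one-sided normal p -> BH < fdr."""
    finite = np.isfinite(values)
    flags = np.zeros(len(values), dtype=bool)
    v = values[finite]
    if len(v) < 3 or np.std(v, ddof=1) == 0:
        return flags
    z = (v - v.mean()) / v.std(ddof=1)
    p = stats.norm.sf(z)
    reject, _, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    flags[finite] = reject
    return flags


def apply_qc(
    g: GenotypeMatrix,
    thresholds: QcThresholds | None = None,
    outlier_filters: bool = True,
) -> tuple[GenotypeMatrix, QcReport]:
    """Run the five-step filter chain; returns kept matrix and full report.

    Each removal records the first rule (in chain order) that triggered it.
    Raises :class:`PipelineError` if every individual or every SNP is
    removed (the report is attached to the exception).
    """
    thr = thresholds or QcThresholds()
    snp_stats_in = snp_summary(g)
    samp_stats_in = sample_summary(g) if g.n_individuals >= 2 else None

    removed_ind: list[tuple[str, str]] = []
    removed_snp: list[tuple[str, str]] = []

    # (1) call rate, both axes, on the input matrix
    low_cr_snp = snp_stats_in["call_rate"] < thr.min_call_rate
    removed_snp += [(s, "call_rate") for s in snp_stats_in.index[low_cr_snp]]
    if samp_stats_in is not None:
        low_cr_ind = samp_stats_in["call_rate"] < thr.min_call_rate
        removed_ind += [
            (i, "call_rate") for i in samp_stats_in.index[low_cr_ind]
        ]

    kept_ind = [i for i in g.individuals if i not in {r[0] for r in removed_ind}]
    kept_snp = [s for s in g.snp_ids if s not in {r[0] for r in removed_snp}]
    if not kept_ind or not kept_snp:
        raise PipelineError("call-rate filter removed everything")
    current = g.subset(individuals=kept_ind, snps=kept_snp)

    # (2) heterozygosity / IBS outliers (FDR-controlled upper tail)
    if outlier_filters and current.n_individuals >= 3:
        stats_now = sample_summary(current)
        het_out = _upper_tail_outliers(
            stats_now["heterozygosity"].to_numpy(), thr.outlier_fdr
        )
        ibs_out = _upper_tail_outliers(
            stats_now["max_ibs"].to_numpy(), thr.outlier_fdr
        )
        for idx, ind in enumerate(stats_now.index):
            if het_out[idx]:
                removed_ind.append((ind, "high_heterozygosity"))
            elif ibs_out[idx]:
                removed_ind.append((ind, "high_ibs"))
        kept_ind = [
            i for i in kept_ind if i not in {r[0] for r in removed_ind}
        ]
        if not kept_ind:
            raise PipelineError("outlier filter removed every individual")
        current = current.subset(individuals=kept_ind)

    # (3)-(5) SNP filters on statistics recomputed after individual removal
    stats_now = snp_summary(current)
    chroms = current.snps["chrom"].astype(str)
    for snp_id in stats_now.index:
        maf = stats_now.at[snp_id, "maf"]
        hwe_p = stats_now.at[snp_id, "hwe_p"]
        if np.isfinite(maf) and maf < thr.min_maf:
            removed_snp.append((snp_id, "maf"))
        elif np.isfinite(hwe_p) and hwe_p < thr.hwe_alpha:
            removed_snp.append((snp_id, "hwe"))
        elif thr.drop_y and chroms[snp_id] == "Y":
            removed_snp.append((snp_id, "y_chromosome"))
    kept_snp = [s for s in kept_snp if s not in {r[0] for r in removed_snp}]
    if not kept_snp:
        raise PipelineError("SNP filters removed every marker")
    current = current.subset(snps=kept_snp)

    report = QcReport(
        removed_individuals=pd.DataFrame(
            removed_ind, columns=["id", "reason"]
        ),
        removed_snps=pd.DataFrame(removed_snp, columns=["id", "reason"]),
        snp_stats=snp_stats_in,
        sample_stats=(
            samp_stats_in
            if samp_stats_in is not None
            else pd.DataFrame(
                columns=["call_rate", "heterozygosity", "max_ibs"]
            )
        ),
        metadata={
            "thresholds": vars(thr).copy(),
            "outlier_filters": outlier_filters,
            "outlier_rule": "one-sided z-score, BH-adjusted, FDR < "
            f"{thr.outlier_fdr}",
            "comparison": "strict < at every threshold",
        },
    )
    assert report.reconciles(
        g.n_individuals, g.n_snps, current.n_individuals, current.n_snps
    )
    return current, report
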