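"""Single-random-effect animal models for taxon heritability, the two-step
SNP scan, and microbiability.

Model.  y = X beta + u + e with u ~ N(0, K sigma2_u), e ~ N(0, I sigma2_e),
one record per animal.  K is either the VanRaden genomic relationship
matrix G (then sigma2_u/(sigma2_u+sigma2_e) is the heritability of the
log-abundance trait) or the microbial relationship matrix M = O O^T / n
over standardized log abundances (then the ratio is the microbiability of
the phenotype).

Estimation.  Restricted likelihood profiled on the variance ratio via a
one-time eigendecomposition of K: with K = U L U^T and V proportional to
r K + (1-r) I, rotating by U^T makes every likelihood evaluation O(n q^2).
The ratio is maximized by bounded scalar optimization over [1e-6, 1-1e-6]
seeded from a coarse grid, with explicit endpoint checks; a likelihood
whose range over the grid is below 1e-6 is flagged flat (only the total
variance is identifiable, e.g. when K = I) and the ratio reported as NaN.

Scan.  Step 2 tests every SNP by generalized least squares under the fixed
covariance V = K sigma2_u + I sigma2_e from step 1 (variance components are
deliberately not re-estimated per SNP); Wald chi-square p-values are then
deflated by the median-based genomic-control lambda and BH-adjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .datatypes import GenotypeMatrix, PipelineError, VarianceComponents

CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, df=1))  # 0.4549...


# ---------------------------------------------------------------- matrices


def genomic_relationship_matrix(g: GenotypeMatrix) -> np.ndarray:
    """VanRaden (method 1) genomic relationship matrix.

    W = genotype - 2p per SNP with missing calls mean-imputed to 2p;
    G = W W^T / (2 sum p(1-p)), allele frequencies from the analyzed cohort.
    Monomorphic SNPs are excluded.
    """
    calls = g.calls
    present = ~np.isnan(calls)
    n_typed = present.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nansum(calls, axis=0) / (2 * n_typed)
    poly = (n_typed > 0) & (p > 0) & (p < 1)
    if not poly.any():
        raise PipelineError("no polymorphic SNPs; GRM undefined")
    calls = calls[:, poly]
    p = p[poly]
    w = np.where(np.isnan(calls), 0.0, calls - 2 * p)
    denom = 2 * np.sum(p * (1 - p))
    grm = w @ w.T / denom
    return (grm + grm.T) / 2


def microbial_relationship_matrix(log_abundance: pd.DataFrame) -> np.ndarray:
    """Microbial relationship matrix M = O O^T / n over standardized logs.

    Columns (taxa) are centered to mean 0 and scaled to SD 1 (ddof=1);
    zero-variance taxa are dropped with a warning; n is the number of taxa
    entering the product.
    """
    o = log_abundance.to_numpy(dtype=float)
    sd = o.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance taxa from M"
        )
    if not keep.any():
        raise PipelineError("no variable taxa; M undefined")
    o = o[:, keep]
    o = (o - o.mean(axis=0)) / o.std(axis=0, ddof=1)
    m = o @ o.T / o.shape[1]
    return (m + m.T) / 2


# ------------------------------------------------------------------- REML


def _check_design(x: np.ndarray, names=None) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify offending columns by greedy rank growth
        names = list(names) if names is not None else [
            f"col{i}" for i in range(x.shape[1])
        ]
        bad = []
        kept: list[int] = []
        for j in range(x.shape[1]):
            sub = x[:, kept + [j]]
            if np.linalg.matrix_rank(sub) == len(kept) + 1:
                kept.append(j)
            else:
                bad.append(names[j])
        raise ValueError(f"design matrix is rank-deficient; collinear: {bad}")


@dataclass
class _Rotated:
    """y, X and eigenvalues rotated to the eigenbasis of K."""

    eigenvalues: np.ndarray
    y: np.ndarray
    x: np.ndarray
    n: int
    q: int


def _rotate(y, x, k) -> _Rotated:
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if len(y) != x.shape[0] or len(y) != k.shape[0]:
        raise ValueError("y, X and K must have aligned rows")
    eigval, eigvec = np.linalg.eigh((k + k.T) / 2)
    eigval = np.clip(eigval, 0.0, None)
    return _Rotated(
        eigenvalues=eigval,
        y=eigvec.T @ y,
        x=eigvec.T @ x,
        n=len(y),
        q=x.shape[1],
    )


def _restricted_loglik(rot: _Rotated, ratio: float) -> float:
    """REML log-likelihood at a given variance ratio (profile over scale).

    Constant terms not depending on the ratio are dropped.
    """
    w = ratio * rot.eigenvalues + (1 - ratio)
    if (w <= 0).any():
        return -np.inf
    wi = 1.0 / w
    xtwx = rot.x.T @ (rot.x * wi[:, None])
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(xtwx, rot.x.T @ (rot.y * wi))
    resid = rot.y - rot.x @ beta
    rss = float((resid**2 * wi).sum())
    df = rot.n - rot.q
    sigma2 = rss / df
    if sigma2 <= 0:
        return -np.inf
    return -0.5 * (
        df * np.log(sigma2) + np.log(w).sum() + logdet_xtwx + df
    )


def reml_single_component(
    y, x, k, x_names=None, grid_size: int = 41
) -> VarianceComponents:
    """REML fit of the one-random-effect animal model.

    Returns the two variance components, their ratio
    ``sigma2_u / (sigma2_u + sigma2_e)`` (heritability for K = G,
    microbiability for K = M), the restricted log-likelihood at the
    optimum, and a flag for likelihoods flat in the ratio.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    _check_design(x, x_names)
    rot = _rotate(y, x, np.asarray(k, dtype=float))

    lo, hi = 1e-6, 1 - 1e-6
    grid = np.linspace(lo, hi, grid_size)
    ll_grid = np.array([_restricted_loglik(rot, r) for r in grid])
    flat = float(ll_grid.max() - ll_grid.min()) < 1e-6

    best_i = int(np.argmax(ll_grid))
    bracket_lo = grid[max(best_i - 1, 0)]
    bracket_hi = grid[min(best_i + 1, grid_size - 1)]
    res = optimize.minimize_scalar(
        lambda r: -_restricted_loglik(rot, r),
        bounds=(bracket_lo, bracket_hi),
        method="bounded",
        options={"xatol": 1e-9},
    )
    candidates = [(float(-res.fun), float(res.x))]
    candidates += [(float(ll_grid[0]), lo), (float(ll_grid[-1]), hi)]
    ll_best, ratio = max(candidates)

    # recover the variance scale at the optimum
    w = ratio * rot.eigenvalues + (1 - ratio)
    wi = 1.0 / w
    xtwx = rot.x.T @ (rot.x * wi[:, None])
    beta = np.linalg.solve(xtwx, rot.x.T @ (rot.y * wi))
    resid = rot.y - rot.x @ beta
    sigma2_total = float((resid**2 * wi).sum()) / (rot.n - rot.q)

    if flat:
        return VarianceComponents(
            sigma2_u=np.nan,
            sigma2_e=sigma2_total,
            ratio=np.nan,
            log_restricted_likelihood=ll_best,
            converged=bool(res.success),
            flat_likelihood=True,
        )
    return VarianceComponents(
        sigma2_u=ratio * sigma2_total,
        sigma2_e=(1 - ratio) * sigma2_total,
        ratio=ratio,
        log_restricted_likelihood=ll_best,
        converged=bool(res.success),
        flat_likelihood=False,
    )


# ------------------------------------------------------------------- scan


def _whiten(y, x, k, vc: VarianceComponents):
    """Rotate and scale by V^{-1/2} with V = K sigma2_u + I sigma2_e."""
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    eigval, eigvec = np.linalg.eigh((np.asarray(k, float) + np.asarray(k, float).T) / 2)
    eigval = np.clip(eigval, 0.0, None)
    w = vc.sigma2_u * eigval + vc.sigma2_e
    scale = 1.0 / np.sqrt(w)
    return scale[:, None] * (eigvec.T @ np.column_stack([y, x])), eigvec, scale


def gwas_scan(
    y, x, k, g: GenotypeMatrix, vc: VarianceComponents
) -> pd.DataFrame:
    """Step-2 per-SNP GLS scan under fixed V = K sigma2_u + I sigma2_e.

    One eigendecomposition of K whitens the response, covariates and all
    SNP dosages; each SNP is then a one-degree-of-freedom Wald test
    (chi-square 1) of its regression coefficient, with missing dosages
    mean-imputed to 2p.  Monomorphic SNPs are flagged and left untested.
    """
    yx, eigvec, scale = _whiten(y, x, k, vc)
    y_w, x_w = yx[:, 0], yx[:, 1:]
    q_mat, _ = np.linalg.qr(x_w)
    y_perp = y_w - q_mat @ (q_mat.T @ y_w)

    calls = g.calls
    present = ~np.isnan(calls)
    with np.errstate(invalid="ignore"):
        p_freq = np.nansum(calls, axis=0) / (2 * present.sum(axis=0))
    dosages = np.where(np.isnan(calls), 2 * p_freq, calls)
    # untestable: no observed dosage variation (includes monomorphic SNPs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mono = ~(np.nanstd(calls, axis=0) > 0)

    g_w = scale[:, None] * (eigvec.T @ dosages)
    g_perp = g_w - q_mat @ (q_mat.T @ g_w)
    gtg = (g_perp**2).sum(axis=0)
    gty = g_perp.T @ y_perp
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = gty / gtg
        se = 1.0 / np.sqrt(gtg)
        chi2 = beta**2 * gtg
    beta[mono] = np.nan
    se[mono] = np.nan
    chi2[mono] = np.nan
    p_raw = np.where(np.isfinite(chi2), stats.chi2.sf(chi2, df=1), np.nan)
    return pd.DataFrame(
        {
            "chrom": g.snps["chrom"].to_numpy(),
            "pos": g.snps["pos"].to_numpy(),
            "beta": beta,
            "se": se,
            "chi2": chi2,
            "p_raw": p_raw,
            "monomorphic": mono,
        },
        index=g.snps.index,
    )


def genomic_control(records: pd.DataFrame) -> pd.DataFrame:
    """Median-based genomic-control correction of a SNP scan.

    lambda = median(chi2) / 0.4549 (the chi-square-1 median), clipped below
    at 1; corrected statistics chi2/lambda give ``p_gc``.  Adds columns
    ``chi2_gc``, ``p_gc`` and attribute ``lambda_gc``.
    """
    chi2 = records["chi2"].to_numpy(dtype=float)
    finite = np.isfinite(chi2)
    if not finite.any():
        raise PipelineError("no finite test statistics for genomic control")
    if finite.sum() < 100:
        warnings.warn(
            "fewer than 100 tested SNPs; genomic-control lambda is unstable"
        )
    lam = max(float(np.median(chi2[finite])) / CHI2_MEDIAN_1DF, 1.0)
    out = records.copy()
    out["chi2_gc"] = chi2 / lam
    out["p_gc"] = np.where(
        finite, stats.chi2.sf(chi2 / lam, df=1), np.nan
    )
    out.attrs["lambda_gc"] = lam
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone in p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any(where=np.isfinite(p)):
        raise ValueError("p-values must be in [0, 1]")
    q = np.full(p.shape, np.nan)
    finite = np.isfinite(p)
    if finite.any():
        _, q_fin, _, _ = multipletests(p[finite], method="fdr_bh")
        q[finite] = q_fin
    return q


@dataclass
class CovariateTest:
    """GLS test of one continuous per-animal covariate in the animal model."""

    beta: float
    se: float
    statistic: float  # t
    df: int
    p_value: float


def covariate_effect_test(
    y, x, x_cov, k=None, vc: VarianceComponents | None = None
) -> CovariateTest:
    """t-test of a per-animal covariate, optionally under the animal model.

    With ``k``/``vc`` supplied the data are whitened by the null-model
    covariance V = K sigma2_u + I sigma2_e before ordinary least squares
    (controlling for the polygenic animal effect); without them this is the
    plain multiple-regression variant.  The t statistic has
    ``n - rank(X) - 1`` degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    x_cov = np.asarray(x_cov, dtype=float).ravel()
    if np.std(x_cov) == 0:
        raise ValueError("covariate is constant; effect not estimable")
    if vc is not None and k is not None and vc.sigma2_u > 0:
        yx, eigvec, scale = _whiten(y, x, k, vc)
        y_w, x_w = yx[:, 0], yx[:, 1:]
        c_w = scale * (eigvec.T @ x_cov)
    else:
        y_w = np.asarray(y, dtype=float).ravel()
        x_w = x
        c_w = x_cov
    design = np.column_stack([x_w, c_w])
    _check_design(design)
    n, q1 = design.shape
    beta_hat, _, _, _ = np.linalg.lstsq(design, y_w, rcond=None)
    resid = y_w - design @ beta_hat
    df = n - q1
    sigma2 = float(resid @ resid) / df
    xtxi = np.linalg.inv(design.T @ design)
    se = float(np.sqrt(sigma2 * xtxi[-1, -1]))
    t_stat = float(beta_hat[-1] / se)
    p = float(2 * stats.t.sf(abs(t_stat), df=df))
    return CovariateTest(
        beta=float(beta_hat[-1]), se=se, statistic=t_stat, df=df, p_value=p
    )
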