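"""Multiple-regression association scans and breed-genotype correlations.

Breed composition enters the regressions as the continuous Brahman
fraction; the six discrete breed groups are kept for PERMANOVA-style
contrasts.  Per-test classification follows the reporting convention of
the herd study: p < 0.05 significant, 0.05 <= p < 0.10 tendency,
otherwise not significant (both interval boundaries resolved strictly,
with p = 0.05 assigned to tendency).  No multiple-testing correction is
applied in these scans; raw p-values with class labels are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datatypes import GenotypeMatrix
from .mixed_model import covariate_effect_test

SIGNIFICANT = "significant"
TENDENCY = "tendency"
NOT_SIGNIFICANT = "ns"

# stage -> (initial body-weight column, weight-gain column)
STAGE_WG_COLUMNS = {
    "preweaning": ("BW_newborn", "WG_preweaning"),
    "postweaning": ("BW_preweaning", "WG_postweaning"),
    "fattening": ("BW_postweaning", "WG_fattening"),
}


def classify_p(p: float) -> str:
    """Significance class from the printed cutoffs (strict boundaries)."""
    if not np.isfinite(p):
        return NOT_SIGNIFICANT
    if p < 0.05:
        return SIGNIFICANT
    if p < 0.10:
        return TENDENCY
    return NOT_SIGNIFICANT


def associated_percent(n_associated: int, n_total: int) -> float:
    """Scan-summary percentage of associated taxa, one decimal place."""
    if n_total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * n_associated / n_total, 1)


def summarize_scan(results: pd.DataFrame) -> dict:
    """Counts and percentage of significant-or-tendency records in a scan."""
    n_total = len(results)
    n_assoc = int(results["class"].isin([SIGNIFICANT, TENDENCY]).sum())
    return {
        "n_total": n_total,
        "n_associated": n_assoc,
        "percent_associated": associated_percent(n_assoc, n_total),
    }


@dataclass
class OlsFit:
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    r_squared: float
    df_resid: int


def fit_ols(y, x: pd.DataFrame, add_intercept: bool = True) -> OlsFit:
    """Least-squares fit with per-coefficient two-sided t-tests.

    Raises on rank-deficient designs (naming the collinear columns) and on
    designs with no residual degrees of freedom.
    """
    x = pd.DataFrame(x)
    design = sm.add_constant(x, has_constant="add") if add_intercept else x
    arr = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        kept: list[int] = []
        bad = []
        for j, name in enumerate(design.columns):
            if np.linalg.matrix_rank(arr[:, kept + [j]]) == len(kept) + 1:
                kept.append(j)
            else:
                bad.append(str(name))
        raise ValueError(f"collinear design columns: {bad}")
    if arr.shape[0] <= rank:
        raise ValueError("more parameters than observations")
    res = sm.OLS(np.asarray(y, dtype=float), arr).fit()
    names = list(design.columns)
    return OlsFit(
        params=pd.Series(res.params, index=names),
        bse=pd.Series(res.bse, index=names),
        tvalues=pd.Series(res.tvalues, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        r_squared=float(res.rsquared),
        df_resid=int(res.df_resid),
    )


def _base_design(meta: pd.DataFrame) -> pd.DataFrame:
    """Brahman fraction + centered age + sex indicator."""
    age = meta["age_days"].astype(float)
    return pd.DataFrame(
        {
            "brahman_fraction": meta["brahman_fraction"].astype(float),
            "age_days": age - age.mean(),
            "sex_M": (meta["sex"] == "M").astype(float),
        },
        index=meta.index,
    )


def breed_association_scan(
    log_abundance: pd.DataFrame, meta: pd.DataFrame
) -> pd.DataFrame:
    """Regress each core taxon's log10 abundance on breed composition.

    Model per taxon: log10 abundance ~ Brahman fraction + age + sex; the
    record carries the breed-composition coefficient, its p-value and the
    significance class.
    """
    x = _base_design(meta.loc[log_abundance.index])
    rows = []
    for taxon in log_abundance.columns:
        fit = fit_ols(log_abundance[taxon], x)
        p = float(fit.pvalues["brahman_fraction"])
        rows.append(
            {
                "response": taxon,
                "predictor": "brahman_fraction",
                "beta": float(fit.params["brahman_fraction"]),
                "p": p,
                "class": classify_p(p),
            }
        )
    return pd.DataFrame(rows).set_index("response")


def phenotype_association_scan(
    meta: pd.DataFrame,
    log_abundance: pd.DataFrame,
    response: str,
    stage: str,
    with_animal_effect: bool = False,
    grm: np.ndarray | None = None,
    vc=None,
) -> pd.DataFrame:
    """Test each taxon's log abundance against weight gain or IgG1.

    Covariates: age, sex, breed composition, plus initial body weight for
    weight gain.  Without the animal effect this is multiple regression;
    with it, each taxon is tested by GLS under the null-model animal
    covariance (``grm`` and ``vc`` required).
    """
    if response == "WG":
        if stage not in STAGE_WG_COLUMNS:
            raise ValueError(f"unknown stage {stage!r}")
        init_col, resp_col = STAGE_WG_COLUMNS[stage]
        if resp_col not in meta.columns:
            raise ValueError(f"{resp_col} not present for stage {stage!r}")
    elif response == "IgG1":
        init_col, resp_col = None, "IgG1"
        if resp_col not in meta.columns:
            raise ValueError("IgG1 not present in metadata")
    else:
        raise ValueError("response must be 'WG' or 'IgG1'")

    meta = meta.loc[log_abundance.index]
    x = _base_design(meta)
    if init_col is not None:
        x = x.assign(initial_bw=meta[init_col].astype(float))
    y = meta[resp_col].astype(float)

    if with_animal_effect and (grm is None or vc is None):
        raise ValueError("animal-effect scan needs grm and vc")

    rows = []
    for taxon in log_abundance.columns:
        if with_animal_effect:
            design = np.column_stack(
                [np.ones(len(x)), x.to_numpy(dtype=float)]
            )
            test = covariate_effect_test(
                y.to_numpy(), design, log_abundance[taxon].to_numpy(),
                k=grm, vc=vc,
            )
            beta, p = test.beta, test.p_value
        else:
            fit = fit_ols(y, x.assign(taxon=log_abundance[taxon]))
            beta = float(fit.params["taxon"])
            p = float(fit.pvalues["taxon"])
        rows.append(
            {
                "response": resp_col,
                "predictor": taxon,
                "beta": beta,
                "p": p,
                "class": classify_p(p),
            }
        )
    return pd.DataFrame(rows).set_index("predictor")


def breed_phenotype_association(
    meta: pd.DataFrame, response: str, stage: str
) -> pd.DataFrame:
    """Breed composition alone against a phenotype (no taxon covariate)."""
    if response == "WG":
        init_col, resp_col = STAGE_WG_COLUMNS[stage]
    else:
        init_col, resp_col = None, "IgG1"
    x = _base_design(meta)
    if init_col is not None:
        x = x.assign(initial_bw=meta[init_col].astype(float))
    fit = fit_ols(meta[resp_col].astype(float), x)
    p = float(fit.pvalues["brahman_fraction"])
    return pd.DataFrame(
        [
            {
                "response": resp_col,
                "predictor": "brahman_fraction",
                "beta": float(fit.params["brahman_fraction"]),
                "p": p,
                "class": classify_p(p),
            }
        ]
    ).set_index("predictor")


def genotype_breed_correlation(
    geno: GenotypeMatrix, meta: pd.DataFrame, snp_ids=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman correlation of 0/1/2 genotype with Brahman fraction.

    Returns a per-SNP table (rho, p, class, monomorphic flag) and a MAF
    table per breed group.  Monomorphic SNPs are flagged and untested.
    """
    if snp_ids is None:
        snp_ids = geno.snp_ids
    sub = geno.subset(snps=list(snp_ids))
    fraction = meta.loc[sub.individuals, "brahman_fraction"].to_numpy(float)
    bg = meta.loc[sub.individuals, "breed_group"].to_numpy()
    rows = []
    maf_rows = []
    for j, snp_id in enumerate(sub.snp_ids):
        col = sub.calls[:, j]
        present = ~np.isnan(col)
        vals = col[present]
        mono = len(np.unique(vals)) < 2
        if mono:
            rho, p = np.nan, np.nan
        else:
            rho, p = stats.spearmanr(vals, fraction[present])
        rows.append(
            {
                "snp": snp_id,
                "rho": float(rho) if np.isfinite(rho) else np.nan,
                "p": float(p) if np.isfinite(p) else np.nan,
                "significant": bool(np.isfinite(p) and p < 0.05),
                "monomorphic": mono,
            }
        )
        for group in sorted(set(bg)):
            gv = col[present & (bg == group)]
            if len(gv) == 0:
                maf = np.nan
            else:
                f = gv.sum() / (2 * len(gv))
                maf = min(f, 1 - f)
            maf_rows.append(
                {"snp": snp_id, "breed_group": group, "maf": maf}
            )
    per_snp = pd.DataFrame(rows).set_index("snp")
    maf_by_bg = pd.DataFrame(maf_rows).pivot(
        index="snp", columns="breed_group", values="maf"
    )
    return per_snp, maf_by_bg
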