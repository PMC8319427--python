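"""Relationship matrices, REML, the two-step scan, genomic control, BH."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from herdscan.datatypes import PipelineError
from herdscan.mixed_model import (
    bh_adjust,
    covariate_effect_test,
    genomic_control,
    genomic_relationship_matrix,
    gwas_scan,
    microbial_relationship_matrix,
    reml_single_component,
)
from herdscan.synth import SimulationConfig, simulate_population

from conftest import make_genotypes


class TestGrm:
    def test_hand_computed_entry(self):
        # SNP1=(0,1,2), SNP2=(2,1,1): p=(0.5, 2/3), 2*sum p(1-p)=17/18
        g = make_genotypes([[0, 2], [1, 1], [2, 1]])
        grm = genomic_relationship_matrix(g)
        assert grm[0, 0] == pytest.approx(26 / 17)

    def test_identical_individuals_share_rows(self):
        g = make_genotypes([[0, 1, 2, 1], [0, 1, 2, 1], [2, 1, 0, 0]])
        grm = genomic_relationship_matrix(g)
        np.testing.assert_allclose(grm[0], grm[1], atol=1e-12)
        assert grm[0, 0] == pytest.approx(grm[0, 1])

    def test_mean_diagonal_near_one_under_hwe(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.1, 0.9, size=1000)
        calls = rng.binomial(2, p, size=(300, 1000)).astype(float)
        grm = genomic_relationship_matrix(make_genotypes(calls))
        assert np.mean(np.diag(grm)) == pytest.approx(1.0, abs=0.05)

    def test_monomorphic_only_raises(self):
        with pytest.raises(PipelineError):
            genomic_relationship_matrix(make_genotypes([[0, 2], [0, 2]]))


class TestMrm:
    def test_identical_microbiomes_share_rows(self):
        rng = np.random.default_rng(1)
        o = rng.normal(size=(5, 8))
        o[1] = o[0]
        m = microbial_relationship_matrix(pd.DataFrame(o))
        np.testing.assert_allclose(m[0], m[1], atol=1e-12)

    def test_trace_is_samples_minus_one(self):
        # each standardized column (ddof=1) has squared norm S-1; summed
        # over n taxa and divided by n the trace is S-1
        rng = np.random.default_rng(2)
        o = pd.DataFrame(rng.normal(size=(12, 30)))
        m = microbial_relationship_matrix(o)
        assert np.trace(m) == pytest.approx(11.0, abs=1e-10)

    def test_symmetric_psd(self):
        rng = np.random.default_rng(3)
        m = microbial_relationship_matrix(
            pd.DataFrame(rng.normal(size=(10, 20)))
        )
        np.testing.assert_allclose(m, m.T, atol=1e-12)
        assert np.linalg.eigvalsh(m).min() > -1e-10


def _grid_reml_oracle(y, x, k, step=0.001):
    """Brute-force restricted-likelihood grid search by direct inversion."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    n, q = x.shape
    best = (-np.inf, np.nan)
    for r in np.arange(step, 1.0, step):
        v = r * k + (1 - r) * np.eye(n)
        vi = np.linalg.inv(v)
        xtvx = x.T @ vi @ x
        beta = np.linalg.solve(xtvx, x.T @ vi @ y)
        resid = y - x @ beta
        sigma2 = float(resid @ vi @ resid) / (n - q)
        ll = -0.5 * (
            (n - q) * np.log(sigma2)
            + np.linalg.slogdet(v)[1]
            + np.linalg.slogdet(xtvx)[1]
            + (n - q)
        )
        if ll > best[0]:
            best = (ll, r)
    return best[1]


class TestReml:
    def test_identity_k_flags_flat_likelihood(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=30)
        x = np.ones((30, 1))
        vc = reml_single_component(y, x, np.eye(30))
        assert vc.flat_likelihood
        assert np.isnan(vc.ratio)

    def test_matches_grid_search_oracle_on_fixed_fixture(self):
        """n=8 kinship with duplicated blocks; REML ratio must match a
        0.001-step restricted-likelihood grid search to +-0.001."""
        block = np.array([[1.0, 0.8], [0.8, 1.0]])
        k = np.kron(np.eye(4), block)
        rng = np.random.default_rng(5)
        x = np.column_stack([np.ones(8), rng.normal(size=8)])
        for seed in (0, 1, 2):
            r = np.random.default_rng(seed)
            u = np.linalg.cholesky(k + 1e-8 * np.eye(8)) @ r.normal(size=8)
            y = x @ np.array([1.0, 0.5]) + u + 0.7 * r.normal(size=8)
            vc = reml_single_component(y, x, k)
            oracle = _grid_reml_oracle(y, x, k)
            assert vc.ratio == pytest.approx(oracle, abs=1e-3)

    def test_scale_invariance_of_ratio(self):
        rng = np.random.default_rng(6)
        truth, geno, _ = simulate_population(
            SimulationConfig(seed=10, n_individuals=80, n_snps=300)
        )
        k = genomic_relationship_matrix(geno)
        u = np.linalg.cholesky(k + 1e-8 * np.eye(80)) @ rng.normal(size=80)
        y = 1.5 + u + rng.normal(size=80)
        x = np.ones((80, 1))
        vc1 = reml_single_component(y, x, k)
        vc2 = reml_single_component(1000.0 * y, x, k)
        assert vc2.ratio == pytest.approx(vc1.ratio, abs=1e-6)
        assert vc2.sigma2_e == pytest.approx(1e6 * vc1.sigma2_e, rel=1e-4)

    def test_rank_deficient_design_names_columns(self):
        y = np.arange(6.0)
        x = np.column_stack([np.ones(6), np.ones(6)])
        with pytest.raises(ValueError, match="collinear"):
            reml_single_component(y, x, np.eye(6), x_names=["a", "b"])


class TestGwasScan:
    def _setup(self, seed=0, n=60, p=40):
        truth, geno, meta = simulate_population(
            SimulationConfig(seed=seed, n_individuals=n, n_snps=p)
        )
        k = genomic_relationship_matrix(geno)
        x = np.column_stack(
            [np.ones(n), (meta["sex"] == "M").astype(float).to_numpy()]
        )
        return geno, k, x

    def test_zero_sigma_u_equals_ols(self):
        from herdscan.datatypes import VarianceComponents

        geno, k, x = self._setup()
        rng = np.random.default_rng(1)
        y = rng.normal(size=geno.n_individuals)
        vc = VarianceComponents(0.0, 1.0, 0.0, 0.0)
        scan = gwas_scan(y, x, k, geno, vc)
        # OLS oracle per SNP
        for j in [0, 5, 17]:
            g_col = geno.calls[:, j]
            design = np.column_stack([x, g_col])
            beta = np.linalg.lstsq(design, y, rcond=None)[0][-1]
            assert scan["beta"].iloc[j] == pytest.approx(beta, abs=1e-10)

    def test_gls_closed_form_tiny_instance(self):
        from herdscan.datatypes import VarianceComponents

        k = np.array(
            [
                [1.0, 0.5, 0.0, 0.0, 0.0],
                [0.5, 1.0, 0.0, 0.0, 0.0],
                [0.0, 0.0, 1.0, 0.3, 0.0],
                [0.0, 0.0, 0.3, 1.0, 0.0],
                [0.0, 0.0, 0.0, 0.0, 1.0],
            ]
        )
        vc = VarianceComponents(0.6, 0.4, 0.6, 0.0)
        v = vc.sigma2_u * k + vc.sigma2_e * np.eye(5)
        y = np.array([1.0, 2.0, 0.5, 1.5, 3.0])
        x = np.ones((5, 1))
        g = make_genotypes(np.array([[0.0, 1, 2, 1, 0]]).T)
        scan = gwas_scan(y, x, k, g, vc)
        vi = np.linalg.inv(v)
        design = np.column_stack([x, g.calls])
        beta = np.linalg.solve(design.T @ vi @ design, design.T @ vi @ y)
        assert scan["beta"].iloc[0] == pytest.approx(beta[-1], abs=1e-10)

    def test_allele_flip_keeps_p_flips_beta(self):
        geno, k, x = self._setup(seed=2)
        rng = np.random.default_rng(3)
        n = geno.n_individuals
        u = np.linalg.cholesky(k + 1e-8 * np.eye(n)) @ rng.normal(size=n)
        y = u + rng.normal(size=n)
        vc = reml_single_component(y, x, k)
        scan1 = gwas_scan(y, x, k, geno, vc)
        flipped = make_genotypes(
            2.0 - geno.calls,
            chroms=geno.snps["chrom"],
        )
        scan2 = gwas_scan(y, x, k, flipped, vc)
        ok = (~scan1["monomorphic"]).to_numpy()
        np.testing.assert_allclose(
            scan1["p_raw"].to_numpy()[ok],
            scan2["p_raw"].to_numpy()[ok],
            atol=1e-10,
        )
        np.testing.assert_allclose(
            scan1["beta"].to_numpy()[ok],
            -scan2["beta"].to_numpy()[ok],
            atol=1e-10,
        )

    def test_null_type_one_error_calibrated(self):
        """2,000 null SNPs at n=300: empirical p<0.05 rate in [0.03, 0.07]."""
        config = SimulationConfig(seed=77, n_individuals=300, n_snps=2000)
        truth, geno, meta = simulate_population(config)
        k = genomic_relationship_matrix(geno)
        n = 300
        rng = np.random.default_rng(88)
        chol = np.linalg.cholesky(k + 1e-8 * np.eye(n))
        y = 0.5 * (chol @ rng.normal(size=n)) + rng.normal(size=n)
        x = np.column_stack(
            [np.ones(n), (meta["sex"] == "M").astype(float).to_numpy()]
        )
        vc = reml_single_component(y, x, k)
        scan = gwas_scan(y, x, k, geno, vc)
        frac = float((scan["p_raw"] < 0.05).mean())
        assert 0.03 <= frac <= 0.07

    def test_monomorphic_snp_flagged(self):
        from herdscan.datatypes import VarianceComponents

        g = make_genotypes([[1, 2], [1, 0], [1, 1], [1, 1]])
        scan = gwas_scan(
            np.arange(4.0),
            np.ones((4, 1)),
            np.eye(4),
            g,
            VarianceComponents(0.0, 1.0, 0.0, 0.0),
        )
        assert bool(scan["monomorphic"].iloc[0])
        assert np.isnan(scan["p_raw"].iloc[0])


class TestGenomicControl:
    def _records(self, chi2):
        return pd.DataFrame(
            {"chi2": chi2, "p_raw": stats.chi2.sf(chi2, 1)}
        )

    def test_lambda_one_keeps_p(self):
        rng = np.random.default_rng(5)
        chi2 = stats.chi2.rvs(1, size=500, random_state=rng)
        chi2 = chi2 * (stats.chi2.ppf(0.5, 1) / np.median(chi2))  # median at null
        out = genomic_control(self._records(chi2))
        assert out.attrs["lambda_gc"] == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(out["p_gc"], out["p_raw"], atol=1e-9)

    def test_median_doubled_halves_statistics(self):
        rng = np.random.default_rng(6)
        chi2 = stats.chi2.rvs(1, size=401, random_state=rng)
        chi2 = chi2 * (0.9098 / np.median(chi2))
        out = genomic_control(self._records(chi2))
        assert out.attrs["lambda_gc"] == pytest.approx(
            0.9098 / stats.chi2.ppf(0.5, 1), rel=1e-6
        )
        assert out.attrs["lambda_gc"] == pytest.approx(2.0, abs=2e-4)
        np.testing.assert_allclose(out["chi2_gc"], chi2 / out.attrs["lambda_gc"])

    def test_null_lambda_near_one(self):
        rng = np.random.default_rng(7)
        chi2 = stats.chi2.rvs(1, size=5000, random_state=rng)
        out = genomic_control(self._records(chi2))
        assert 0.9 <= out.attrs["lambda_gc"] <= 1.1

    def test_deflation_clipped_at_one(self):
        chi2 = np.full(200, 0.01)
        out = genomic_control(self._records(chi2))
        assert out.attrs["lambda_gc"] == 1.0


class TestBh:
    def test_hand_stepup(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_equal_and_single(self):
        np.testing.assert_allclose(
            bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2]
        )
        np.testing.assert_allclose(bh_adjust([0.07]), [0.07])
        assert bh_adjust([]).size == 0

    def test_monotone_in_p(self):
        rng = np.random.default_rng(8)
        p = rng.random(100)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p - 1e-12).all()


class TestCovariateEffect:
    def test_zero_sigma_u_matches_plain_regression(self):
        from herdscan.datatypes import VarianceComponents

        rng = np.random.default_rng(9)
        n = 50
        x = np.column_stack([np.ones(n), rng.normal(size=n)])
        cov = rng.normal(size=n)
        y = x @ [1.0, 0.5] + 0.3 * cov + rng.normal(size=n)
        plain = covariate_effect_test(y, x, cov)
        mixed = covariate_effect_test(
            y, x, cov, k=np.eye(n), vc=VarianceComponents(0.0, 1.0, 0.0, 0.0)
        )
        assert mixed.statistic == pytest.approx(plain.statistic, abs=1e-10)
        assert plain.df == n - x.shape[1] - 1

    def test_null_rejection_rate_calibrated(self):
        """beta_bac = 0: t-test rejects at ~5% over replicates."""
        rng = np.random.default_rng(10)
        n = 80
        rejections = 0
        reps = 500
        for _ in range(reps):
            x = np.column_stack([np.ones(n), rng.normal(size=n)])
            cov = rng.normal(size=n)
            y = x @ [1.0, 0.5] + rng.normal(size=n)
            if covariate_effect_test(y, x, cov).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07

    def test_planted_positive_effect_recovers_sign(self):
        rng = np.random.default_rng(11)
        n = 100
        hits = 0
        reps = 100
        for _ in range(reps):
            x = np.ones((n, 1))
            cov = rng.normal(size=n)
            y = 1.0 * cov + rng.normal(size=n)  # signal-to-noise 1
            if covariate_effect_test(y, x, cov).beta > 0:
                hits += 1
        assert hits >= 95

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError):
            covariate_effect_test(
                np.arange(5.0), np.ones((5, 1)), np.ones(5)
            )
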