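"""Preprocessing and community analysis: core filter, floor-log, rarefy,
Shannon, Bray-Curtis, PCoA, PERMANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.ordination import pcoa as skbio_pcoa

from herdscan.diversity import (
    HALF_DETECTION_LIMIT,
    bray_curtis,
    core_taxa_filter,
    log10_floor_transform,
    pcoa,
    permanova,
    rarefy,
    shannon_index,
)


def table(rows, taxa=None):
    rows = np.atleast_2d(rows)
    taxa = taxa or [f"t{j}" for j in range(rows.shape[1])]
    return pd.DataFrame(
        rows, index=[f"s{i}" for i in range(rows.shape[0])], columns=taxa
    )


class TestCoreFilter:
    def test_half_prevalence_is_inclusive(self):
        t = table([[0.1, 0.0], [0.2, 0.0], [0.0, 0.1], [0.1, 0.2]])
        # t0 present in 3/4, t1 in 2/4 -> both kept at 0.5
        assert list(core_taxa_filter(t).columns) == ["t0", "t1"]

    def test_below_threshold_dropped(self):
        t = table([[0.1, 0.0], [0.2, 0.0], [0.3, 0.0], [0.1, 0.2]])
        assert list(core_taxa_filter(t).columns) == ["t0"]

    def test_bad_prevalence_rejected(self):
        with pytest.raises(ValueError):
            core_taxa_filter(table([[1.0]]), min_prevalence=0.0)


class TestLogFloor:
    def test_zero_maps_to_log_of_half_limit(self):
        t = table([[0.0], [0.5]])
        out = log10_floor_transform(t)
        assert out.iloc[0, 0] == pytest.approx(
            np.log10(HALF_DETECTION_LIMIT), abs=1e-12
        )
        assert out.iloc[0, 0] == pytest.approx(-4.3360, abs=5e-5)

    def test_taxon_without_zeros_untouched(self):
        t = table([[0.01, 0.0], [1.0, 0.2]])
        out = log10_floor_transform(t)
        assert out.iloc[0, 0] == pytest.approx(-2.0, abs=1e-12)
        assert out.iloc[1, 0] == pytest.approx(0.0, abs=1e-12)
        # the zero-containing taxon is shifted everywhere
        assert out.iloc[1, 1] == pytest.approx(
            np.log10(0.2 + HALF_DETECTION_LIMIT)
        )

    def test_monotone_within_each_taxon(self):
        rng = np.random.default_rng(1)
        vals = rng.random((20, 5))
        vals[vals < 0.3] = 0
        out = log10_floor_transform(table(vals))
        for col in out.columns:
            order_in = np.argsort(vals[:, out.columns.get_loc(col)], kind="stable")
            order_out = np.argsort(out[col].to_numpy(), kind="stable")
            np.testing.assert_array_equal(order_in, order_out)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log10_floor_transform(table([[-0.1]]))


class TestRarefy:
    def test_sample_at_depth_unchanged(self):
        t = table([[6, 4]]).astype(int)
        out = rarefy(t, depth=10, seed=0)
        np.testing.assert_array_equal(out.to_numpy(), [[6, 4]])

    def test_shallow_sample_dropped_with_warning(self):
        t = table([[6, 4], [2, 1]]).astype(int)
        with pytest.warns(UserWarning):
            out = rarefy(t, depth=10, seed=0)
        assert list(out.index) == ["s0"]

    def test_deterministic_given_seed_and_depth_exact(self):
        rng = np.random.default_rng(5)
        t = table(rng.integers(0, 500, size=(8, 30))).astype(int)
        a = rarefy(t, depth=1000, seed=11)
        b = rarefy(t, depth=1000, seed=11)
        c = rarefy(t, depth=1000, seed=12)
        pd.testing.assert_frame_equal(a, b)
        assert not a.equals(c)
        assert (a.sum(axis=1) == 1000).all()


class TestShannon:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.25, 0.25, 0.25, 0.25], 2.0),
            ([1.0], 0.0),
            ([0.5, 0.25, 0.25], 1.5),
        ],
    )
    def test_known_values(self, p, expected):
        assert shannon_index(p) == pytest.approx(expected, abs=1e-12)

    def test_maximal_at_uniform(self):
        rng = np.random.default_rng(2)
        k = 6
        h_uniform = shannon_index(np.full(k, 1 / k))
        for _ in range(50):
            h = shannon_index(rng.dirichlet(np.ones(k)))
            assert h <= h_uniform + 1e-12

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon_index([0.0, 0.0])


class TestBrayCurtis:
    def test_hand_value(self):
        d = bray_curtis(table([[0.6, 0.4], [0.2, 0.8]]))
        assert d.data[0, 1] == pytest.approx(0.4, abs=1e-12)

    def test_identity_and_disjoint(self):
        d = bray_curtis(table([[0.5, 0.5, 0.0], [0.5, 0.5, 0.0],
                               [0.0, 0.0, 1.0]]))
        assert d.data[0, 1] == pytest.approx(0.0)
        assert d.data[0, 2] == pytest.approx(1.0)

    def test_properties_on_random_tables(self):
        rng = np.random.default_rng(3)
        t = table(rng.dirichlet(np.ones(10), size=15))
        d = bray_curtis(t).data
        np.testing.assert_allclose(d, d.T, atol=1e-12)
        assert (np.diag(d) == 0).all()
        assert (d >= 0).all() and (d <= 1 + 1e-12).all()


class TestPcoa:
    def test_right_triangle_embeds_exactly(self):
        d = DistanceMatrix(
            np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float),
            ids=["a", "b", "c"],
        )
        res = pcoa(d, 2)
        np.testing.assert_allclose(
            np.sort(pdist(res.coordinates.to_numpy())),
            [3, 4, 5],
            atol=1e-8,
        )

    def test_eigenvalue_sum_equals_centered_trace(self):
        rng = np.random.default_rng(4)
        x = rng.random((10, 4))
        d = DistanceMatrix(
            np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1)),
            ids=[str(i) for i in range(10)],
        )
        res = pcoa(d)
        d2 = d.data**2
        n = 10
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ d2 @ j
        assert res.eigenvalues.sum() == pytest.approx(np.trace(b), abs=1e-8)

    def test_matches_skbio_coordinates(self):
        rng = np.random.default_rng(6)
        x = rng.random((12, 3))
        d = DistanceMatrix(
            np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1)),
            ids=[str(i) for i in range(12)],
        )
        ours = pcoa(d, 3).coordinates.to_numpy()
        ref = skbio_pcoa(d).samples.to_numpy()[:, :3]
        # axes agree up to sign
        for k in range(3):
            assert min(
                np.abs(ours[:, k] - ref[:, k]).max(),
                np.abs(ours[:, k] + ref[:, k]).max(),
            ) < 1e-6


class TestPermanova:
    def toy(self):
        d = np.ones((6, 6))
        d[:3, :3] = 0
        d[3:, 3:] = 0
        np.fill_diagonal(d, 0)
        return DistanceMatrix(d, ids=list("abcdef"))

    def test_exhaustive_toy_p(self):
        """Perfect two-group separation: only 2 of C(6,3)=20 assignments
        attain the maximal pseudo-F, so the exhaustive p is 0.1."""
        res = permanova(self.toy(), ["g1"] * 3 + ["g2"] * 3, n_perm=999)
        assert res.method == "exhaustive"
        assert res.n_permutations == 20
        assert res.p_value == pytest.approx(2 / 20)

    def test_minimum_attainable_sampled_p(self):
        rng = np.random.default_rng(7)
        x = np.vstack([rng.normal(0, 1, (8, 3)), rng.normal(5, 1, (8, 3))])
        d = DistanceMatrix(
            np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1)),
            ids=[str(i) for i in range(16)],
        )
        res = permanova(
            d, ["a"] * 8 + ["b"] * 8, n_perm=999, seed=0
        )
        assert res.method == "sampled"
        # (0 + 1)/(999 + 1): the smallest p a 999-permutation test can give
        assert res.p_value == pytest.approx(1 / 1000)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            permanova(self.toy(), ["g"] * 6)

    def test_statistic_matches_skbio(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(15, 4))
        d = DistanceMatrix(
            np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1)),
            ids=[str(i) for i in range(15)],
        )
        labels = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        ours = permanova(d, labels, n_perm=99, seed=0)
        ref = skbio_permanova(d, grouping=labels, permutations=99)
        assert ours.statistic == pytest.approx(
            float(ref["test statistic"]), abs=1e-10
        )

    def test_null_p_is_uniform(self):
        """Permutation p-values under a true null pass a KS uniformity
        check (1% critical value) over replicated label shuffles."""
        rng = np.random.default_rng(9)
        n = 24
        pvals = []
        for _ in range(500):
            x = rng.normal(size=(n, 3))
            d = DistanceMatrix(
                np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1)),
                ids=[str(i) for i in range(n)],
            )
            labels = np.array(["a"] * 12 + ["b"] * 12)
            rng.shuffle(labels)
            res = permanova(d, labels, n_perm=99,
                            seed=int(rng.integers(2**31)))
            pvals.append(res.p_value)
        pvals = np.sort(pvals)
        grid = np.arange(1, 501) / 501
        ks = np.abs(pvals - grid).max()
        # 1% KS critical value ~ 1.63/sqrt(500); allow lattice slack for
        # the discrete p support (multiples of 1/100)
        assert ks < 1.63 / np.sqrt(500) + 0.01
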