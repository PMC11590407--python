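import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dysbiome.diversity import (
    DissimilarityMatrix,
    alpha_diversity,
    alpha_diversity_table,
    beta_diversity,
    bray_curtis,
    jaccard,
    jensen_shannon,
    pairwise_permanova,
    pcoa,
    permanova,
)
from dysbiome.tables import CountTable, to_relative

from conftest import euclidean_dm


def random_proportions_table(n_taxa, n_samples, seed):
    rng = np.random.default_rng(seed)
    X = rng.random((n_taxa, n_samples)) + 1e-6
    X = X / X.sum(axis=0)
    return CountTable(
        pd.DataFrame(X, index=[f"t{i}" for i in range(n_taxa)],
                     columns=[f"s{j}" for j in range(n_samples)]),
        unit="proportions",
    )


class TestAlpha:
    def test_uniform_four_taxa_entropy_two_bits(self):
        assert alpha_diversity([5, 5, 5, 5]).shannon == pytest.approx(2.0)

    def test_single_taxon(self):
        rec = alpha_diversity([0, 9, 0])
        assert rec.shannon == pytest.approx(0.0)
        assert rec.chao1 == pytest.approx(1.0)
        assert rec.observed == 1

    def test_bias_corrected_chao1_hand_case(self):
        # S_obs = 5, F1 = 2, F2 = 1 -> 5 + 2*1/(2*2) = 5.5
        rec = alpha_diversity([1, 1, 2, 3, 3])
        assert (rec.observed, rec.singletons, rec.doubletons) == (5, 2, 1)
        assert rec.chao1 == pytest.approx(5.5)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError, match="no counts"):
            alpha_diversity([0, 0, 0])

    def test_matches_skbio_on_random_counts(self):
        skbio_alpha = pytest.importorskip("skbio.diversity.alpha")
        rng = np.random.default_rng(0)
        for _ in range(20):
            counts = rng.integers(0, 12, size=30)
            if counts.sum() == 0:
                continue
            rec = alpha_diversity(counts)
            assert rec.chao1 == pytest.approx(
                float(skbio_alpha.chao1(counts, bias_corrected=True))
            )
            assert rec.shannon == pytest.approx(
                float(skbio_alpha.shannon(counts, base=2))
            )

    @given(st.lists(st.integers(min_value=0, max_value=50), min_size=2, max_size=40))
    @settings(max_examples=60, deadline=None)
    def test_entropy_and_chao1_bounds(self, counts):
        counts = np.array(counts)
        if counts.sum() == 0:
            return
        rec = alpha_diversity(counts)
        assert rec.chao1 >= rec.observed
        assert rec.shannon >= -1e-12
        assert rec.shannon <= np.log2(rec.observed) + 1e-9

    def test_table_indexes_by_sample(self, tiny_table):
        df = alpha_diversity_table(tiny_table)
        assert list(df.index) == tiny_table.sample_ids
        assert {"observed", "chao1", "shannon"} <= set(df.columns)


class TestBetaMetrics:
    @pytest.mark.parametrize("func", [bray_curtis, jaccard, jensen_shannon])
    def test_identity(self, func):
        assert func([0.2, 0.3, 0.5], [0.2, 0.3, 0.5]) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("func", [bray_curtis, jaccard, jensen_shannon])
    def test_disjoint_supports_give_one(self, func):
        assert func([1, 0, 2, 0], [0, 3, 0, 1]) == pytest.approx(1.0)

    def test_hand_values(self):
        assert bray_curtis([2, 0, 1], [1, 1, 0]) == pytest.approx(0.6)
        assert jaccard([2, 0, 1], [1, 1, 0]) == pytest.approx(2 / 3)
        assert jensen_shannon([1, 0], [0.5, 0.5]) == pytest.approx(0.5579, abs=1e-4)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_symmetry_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.random(6), rng.random(6)
        for func in (bray_curtis, jaccard, jensen_shannon):
            d = func(x, y)
            assert 0.0 <= d <= 1.0 + 1e-12
            assert d == pytest.approx(func(y, x))

    def test_jensen_shannon_triangle_inequality(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            p, q, r = rng.dirichlet(np.ones(5), size=3)
            assert jensen_shannon(p, r) <= jensen_shannon(p, q) + jensen_shannon(q, r) + 1e-12

    def test_beta_diversity_requires_proportions(self, tiny_table):
        with pytest.raises(ValueError, match="proportions"):
            beta_diversity(tiny_table, "braycurtis")

    def test_beta_diversity_unknown_metric(self, tiny_table):
        with pytest.raises(ValueError, match="metric"):
            beta_diversity(to_relative(tiny_table), "unifrac")

    def test_beta_diversity_matrix_structure(self, tiny_table):
        dm = beta_diversity(to_relative(tiny_table), "jensenshannon")
        assert dm.ids == tiny_table.sample_ids
        assert np.allclose(dm.data, dm.data.T)
        assert np.allclose(np.diag(dm.data), 0)


class TestPcoa:
    def test_collinear_points_have_one_positive_axis(self):
        dm = euclidean_dm(np.array([0.0, 1.0, 3.0]))
        res = pcoa(dm)
        assert res.coordinates.shape[1] == 1
        assert res.proportion_explained[0] == pytest.approx(1.0)

    def test_reconstructs_euclidean_distances(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(8, 3))
        dm = euclidean_dm(pts)
        res = pcoa(dm)
        coords = res.coordinates.to_numpy()
        diff = coords[:, None, :] - coords[None, :, :]
        D = np.sqrt((diff**2).sum(axis=2))
        np.testing.assert_allclose(D, dm.data, atol=1e-8)

    def test_identical_points_all_zero_eigenvalues(self):
        dm = DissimilarityMatrix(np.zeros((4, 4)), list("abcd"))
        res = pcoa(dm)
        assert res.coordinates.shape[1] == 0
        np.testing.assert_allclose(res.eigenvalues, 0.0, atol=1e-12)

    def test_too_few_samples_rejected(self):
        dm = DissimilarityMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), ["a", "b"])
        with pytest.raises(ValueError, match="3 samples"):
            pcoa(dm)

    def test_matches_skbio_variance_fractions(self):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        skbio = pytest.importorskip("skbio")
        table = random_proportions_table(6, 10, seed=5)
        dm = beta_diversity(table, "braycurtis")
        mine = pcoa(dm)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            theirs = skbio_ord.pcoa(skbio.DistanceMatrix(dm.data, dm.ids))
        k = mine.proportion_explained.size
        np.testing.assert_allclose(
            mine.proportion_explained[:3],
            np.asarray(theirs.proportion_explained)[:3],
            atol=1e-8,
        )


class TestPermanova:
    def worked_example_dm(self):
        D = np.ones((4, 4))
        D[0, 1] = D[1, 0] = D[2, 3] = D[3, 2] = 0.5
        np.fill_diagonal(D, 0.0)
        return DissimilarityMatrix(D, list("abcd"))

    def test_hand_computed_pseudo_f(self):
        res = permanova(self.worked_example_dm(), ["g1", "g1", "g2", "g2"],
                        n_permutations=99, seed=0)
        assert res.statistic == pytest.approx(7.0)
        assert res.ss_total == pytest.approx(res.ss_within + res.ss_between, abs=1e-9)
        assert res.ss_total == pytest.approx(1.125)

    def test_statistic_matches_skbio(self):
        sk_dist = pytest.importorskip("skbio.stats.distance")
        skbio = pytest.importorskip("skbio")
        table = random_proportions_table(8, 12, seed=9)
        dm = beta_diversity(table, "braycurtis")
        grouping = ["a"] * 6 + ["b"] * 6
        mine = permanova(dm, grouping, n_permutations=99, seed=0)
        theirs = sk_dist.permanova(
            skbio.DistanceMatrix(dm.data, dm.ids), grouping=grouping, permutations=99
        )
        assert mine.statistic == pytest.approx(float(theirs["test statistic"]), abs=1e-10)

    def test_deterministic_under_seed(self):
        table = random_proportions_table(5, 10, seed=2)
        dm = beta_diversity(table, "braycurtis")
        grouping = ["a"] * 5 + ["b"] * 5
        p1 = permanova(dm, grouping, n_permutations=199, seed=77).p_value
        p2 = permanova(dm, grouping, n_permutations=199, seed=77).p_value
        assert p1 == p2

    def test_invariant_to_group_renaming(self):
        table = random_proportions_table(5, 10, seed=2)
        dm = beta_diversity(table, "braycurtis")
        a = permanova(dm, ["a"] * 5 + ["b"] * 5, n_permutations=199, seed=5)
        b = permanova(dm, ["zzz"] * 5 + ["m"] * 5, n_permutations=199, seed=5)
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_value == b.p_value

    def test_degenerate_within_group_rejected(self):
        D = np.zeros((4, 4))
        D[:2, 2:] = 1.0
        D[2:, :2] = 1.0
        dm = DissimilarityMatrix(D, list("abcd"))
        with pytest.raises(ValueError, match="degenerate"):
            permanova(dm, ["g1", "g1", "g2", "g2"], n_permutations=99, seed=0)

    def test_small_group_rejected(self):
        dm = euclidean_dm(np.arange(5.0))
        with pytest.raises(ValueError, match="fewer than 2"):
            permanova(dm, ["a", "a", "a", "a", "b"], n_permutations=99)

    def test_stratified_permutations_run(self):
        table = random_proportions_table(5, 12, seed=4)
        dm = beta_diversity(table, "braycurtis")
        groups = ["a", "b"] * 6
        strata = [f"i{k // 2}" for k in range(12)]
        res = permanova(dm, groups, n_permutations=99, seed=0, strata=strata)
        assert 0 < res.p_value <= 1


class TestPairwisePermanova:
    def test_two_groups_q_equals_p(self):
        table = random_proportions_table(5, 10, seed=6)
        dm = beta_diversity(table, "braycurtis")
        df = pairwise_permanova(dm, ["a"] * 5 + ["b"] * 5, n_permutations=99, seed=0)
        assert len(df) == 1
        assert df["q_value"].iloc[0] == pytest.approx(df["p_value"].iloc[0])

    def test_three_groups_bh_ordering(self):
        table = random_proportions_table(6, 12, seed=8)
        dm = beta_diversity(table, "braycurtis")
        grouping = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        df = pairwise_permanova(dm, grouping, n_permutations=99, seed=1)
        assert len(df) == 3
        assert (df["q_value"] >= df["p_value"] - 1e-12).all()
        assert (df["q_value"] <= 1.0).all()
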