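import numpy as np
import pandas as pd
import pytest
from scipy.spatial import procrustes
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

import plasticome as pc
from plasticome import community_stats as cs


class TestPBRatio:
    def _inputs(self, rows):
        table = pd.DataFrame(
            rows, columns=["prev1", "bact1", "bact2", "other"],
            index=[f"s{i}" for i in range(len(rows))],
        )
        taxonomy = pd.DataFrame(
            {"genus": ["Prevotella", "Bacteroides", "Bacteroides", ""]},
            index=table.columns,
        )
        return table, taxonomy

    def test_pseudocount_when_prevotella_absent(self):
        table, tax = self._inputs([[0, 250, 250, 10]])
        pb = pc.pb_ratio(table, tax)
        assert pb.per_sample.iloc[0] == pytest.approx(1 / 500)

    def test_direct_ratio(self):
        table, tax = self._inputs([[30, 400, 600, 10]])
        pb = pc.pb_ratio(table, tax)
        assert pb.per_sample.iloc[0] == pytest.approx(0.03)

    def test_zero_bacteroides_excluded_with_warning(self):
        table, tax = self._inputs([[0, 0, 0, 10], [5, 100, 0, 1]])
        with pytest.warns(UserWarning, match="zero Bacteroides"):
            pb = pc.pb_ratio(table, tax)
        assert pb.excluded_samples == ["s0"]
        assert list(pb.per_sample.index) == ["s1"]

    def test_subject_mean_over_bl_samples(self, small_table, small_taxonomy, small_metadata):
        pb = pc.pb_ratio(small_table, small_taxonomy, metadata=small_metadata)
        assert set(pb.per_subject.index) <= set(small_metadata.subjects.index)
        shuffled = pc.pb_ratio(
            small_table.iloc[::-1], small_taxonomy, metadata=small_metadata
        )
        pd.testing.assert_series_equal(
            pb.per_subject.sort_index(), shuffled.per_subject.sort_index()
        )


class TestClassifyPB:
    @pytest.mark.parametrize(
        "ratio, expected", [(0.002, "low"), (0.03, "high"), (0.003, "high")]
    )
    def test_cutoff(self, ratio, expected):
        pb = cs.PBResult(
            per_sample=pd.Series(dtype=float),
            per_subject=pd.Series({"s": ratio}),
            excluded_samples=[],
        )
        assert pc.classify_pb(pb)["s"] == expected


class TestPCoA:
    def test_identical_samples_identical_coordinates(self):
        points = np.array([[0.0, 0], [0, 0], [3, 4], [6, 8]])
        dm = DistanceMatrix(squareform(pdist(points)), ids=list("abcd"))
        res = pc.pcoa(dm, n_axes=2)
        np.testing.assert_allclose(
            res.coordinates.loc["a"], res.coordinates.loc["b"], atol=1e-9
        )

    def test_recovers_planar_configuration(self):
        rng = np.random.default_rng(5)
        points = rng.normal(size=(12, 2))
        dm = DistanceMatrix(squareform(pdist(points)), ids=[str(i) for i in range(12)])
        res = pc.pcoa(dm, n_axes=2)
        _, _, disparity = procrustes(points, res.coordinates.to_numpy())
        assert disparity < 1e-8

    def test_euclidean_input_no_negative_eigenvalues(self):
        rng = np.random.default_rng(2)
        points = rng.normal(size=(10, 3))
        dm = DistanceMatrix(squareform(pdist(points)), ids=[str(i) for i in range(10)])
        res = pc.pcoa(dm, n_axes=3)
        assert np.all(res.negative_eigenvalues > -1e-10)

    def test_eigenvalues_non_increasing_and_proportions(self):
        rng = np.random.default_rng(3)
        points = rng.normal(size=(9, 4))
        dm = DistanceMatrix(squareform(pdist(points)), ids=[str(i) for i in range(9)])
        res = pc.pcoa(dm, n_axes=4)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        assert res.proportion_explained.sum() <= 1 + 1e-12

    def test_too_few_samples_rejected(self):
        dm = DistanceMatrix(np.array([[0.0, 1], [1, 0]]), ids=["a", "b"])
        with pytest.raises(ValueError):
            pc.pcoa(dm)


@pytest.fixture(scope="module")
def line_example():
    points = np.array([0.0, 1.0, 10.0, 11.0])[:, None]
    dm = DistanceMatrix(squareform(pdist(points)), ids=list("abcd"))
    groups = pd.Series(["g1", "g1", "g2", "g2"], index=list("abcd"))
    return dm, groups


class TestPermanova:
    def test_hand_computed_pseudo_f(self, line_example):
        dm, groups = line_example
        res = pc.permanova(dm, groups, n_perm=99, seed=1)
        assert res.pseudo_f == pytest.approx(200.0)
        assert res.r_squared == pytest.approx(100 / 101)

    def test_reproducible_with_seed(self, line_example):
        dm, groups = line_example
        r1 = pc.permanova(dm, groups, n_perm=199, seed=7)
        r2 = pc.permanova(dm, groups, n_perm=199, seed=7)
        assert r1.p_value == r2.p_value

    def test_matches_skbio_pseudo_f(self):
        rng = np.random.default_rng(11)
        points = rng.normal(size=(12, 3))
        dm = DistanceMatrix(squareform(pdist(points)), ids=[str(i) for i in range(12)])
        groups = pd.Series(
            ["a"] * 4 + ["b"] * 4 + ["c"] * 4, index=[str(i) for i in range(12)]
        )
        ours = pc.permanova(dm, groups, n_perm=99, seed=0)
        ref = skbio_permanova(dm, groups.to_frame("g"), column="g", permutations=99)
        assert ours.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_relabeling_invariance(self, line_example):
        dm, groups = line_example
        order = ["d", "b", "a", "c"]
        dm2 = dm.filter(order)
        res1 = pc.permanova(dm, groups, n_perm=49, seed=3)
        res2 = pc.permanova(dm2, groups.loc[order], n_perm=49, seed=3)
        assert res1.pseudo_f == pytest.approx(res2.pseudo_f)

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(21)
        pvals = []
        for _ in range(100):
            points = rng.normal(size=(10, 2))
            dm = DistanceMatrix(squareform(pdist(points)), ids=[str(i) for i in range(10)])
            groups = pd.Series(
                ["a"] * 5 + ["b"] * 5, index=[str(i) for i in range(10)]
            )
            res = pc.permanova(dm, groups, n_perm=99, seed=int(rng.integers(2**31)))
            pvals.append(res.p_value)
        from scipy.stats import kstest

        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_subject_level_permutation_controls_repeated_measures(
        self, small_table, small_metadata
    ):
        bl = small_metadata.samples.index[small_metadata.samples.window == "BL"]
        dm = pc.distance_matrix(small_table.loc[bl], "braycurtis")
        subj = small_metadata.samples.loc[list(dm.ids), "subject_id"]
        diet = small_metadata.subjects.loc[subj, "diet"]
        diet.index = list(dm.ids)
        naive = pc.permanova(dm, diet, n_perm=199, seed=2)
        stratified = pc.permanova(dm, diet, n_perm=199, seed=2, subjects=subj)
        # repeated daily samples inflate the naive whole-label permutation
        assert stratified.p_value >= naive.p_value
        assert stratified.pseudo_f == pytest.approx(naive.pseudo_f)

    def test_subject_spanning_groups_rejected(self, line_example):
        dm, groups = line_example
        subjects = pd.Series(["s1", "s1", "s1", "s2"], index=list("abcd"))
        with pytest.raises(ValueError, match="spans multiple groups"):
            pc.permanova(dm, groups, n_perm=9, seed=0, subjects=subjects)

    def test_p_bounded_below_by_permutation_resolution(self, line_example):
        dm, groups = line_example
        res = pc.permanova(dm, groups, n_perm=99, seed=1)
        assert res.p_value >= 1 / 100


class TestWilcoxon:
    def test_exact_small_sample(self):
        _, p = pc.wilcoxon_rank_sum([1, 2], [3, 4])
        assert p == pytest.approx(2 / 6)

    def test_identical_multisets_p_one(self):
        _, p = pc.wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self):
        x, y = [1.0, 5.0, 9.0], [2.0, 3.0, 12.0]
        _, p1 = pc.wilcoxon_rank_sum(x, y)
        _, p2 = pc.wilcoxon_rank_sum(np.exp(x), np.exp(y))
        assert p1 == pytest.approx(p2)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            pc.wilcoxon_rank_sum([], [1.0])


class TestSpearman:
    def test_perfect_correlations(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0])
        assert pc.spearman(x, x)[0] == pytest.approx(1.0)
        assert pc.spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_computed_rho(self):
        rho, _ = pc.spearman([1, 2, 3], [2, 1, 3])
        assert rho == pytest.approx(0.5)

    def test_exact_p_matches_enumeration(self):
        # n=4, all 24 pairings: |rho| >= 1 in 2 cases -> p = 1/12
        rho, p = pc.spearman([1, 2, 3, 4], [1, 2, 3, 4])
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 24)

    def test_constant_vector_missing_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            rho, p = pc.spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(rho) and np.isnan(p)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=30), rng.normal(size=30)
        rho, p = pc.spearman(x, y)
        from scipy.stats import spearmanr

        ref = spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)
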