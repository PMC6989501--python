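import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import plasticome as pc
from plasticome import diffabund as da
from plasticome.synthio import SimConfig


def _flat_voomfit(Y, X, block=None, weights=None):
    """Build a VoomFit directly from a response matrix (features x samples)."""
    samples = [f"s{i}" for i in range(Y.shape[1])]
    features = [f"f{i}" for i in range(Y.shape[0])]
    W = np.ones_like(Y) if weights is None else weights
    return da.VoomFit(
        y=pd.DataFrame(Y, index=features, columns=samples),
        weights=pd.DataFrame(W, index=features, columns=samples),
        trend_x=np.array([0.0]),
        trend_y=np.array([1.0]),
        size_factors=pd.Series(np.ones(len(samples)), index=samples),
        design=pd.DataFrame(X, index=samples, columns=[f"x{j}" for j in range(X.shape[1])]),
        block=None if block is None else pd.Series(block, index=samples),
    )


class TestPoscounts:
    def test_identical_samples_unit_factors(self):
        row = [5, 0, 3, 10]
        table = pd.DataFrame([row] * 4, index=list("abcd"))
        np.testing.assert_allclose(da.poscounts_size_factors(table), 1.0)

    def test_fourfold_sample_gives_half_and_two(self):
        table = pd.DataFrame([[2, 4, 0, 8], [8, 16, 0, 32]], index=["s1", "s2"])
        factors = da.poscounts_size_factors(table)
        np.testing.assert_allclose(factors, [0.5, 2.0])

    def test_all_zero_feature_is_ignored(self):
        t1 = pd.DataFrame([[2, 4], [8, 16]], index=["s1", "s2"])
        t2 = t1.copy()
        t2["zero"] = 0
        np.testing.assert_allclose(
            da.poscounts_size_factors(t1), da.poscounts_size_factors(t2)
        )

    def test_all_zero_sample_rejected(self):
        table = pd.DataFrame([[0, 0], [1, 2]], index=["s1", "s2"])
        with pytest.raises(ValueError, match="no positive counts"):
            da.poscounts_size_factors(table)

    def test_geometric_mean_one(self, small_table):
        factors = da.poscounts_size_factors(small_table)
        assert np.exp(np.mean(np.log(factors))) == pytest.approx(1.0)


class TestVoomAsinh:
    def _design(self, table):
        n = len(table)
        return pd.DataFrame(
            {"intercept": 1.0, "group": [i % 2 for i in range(n)]},
            index=table.index,
            dtype=float,
        )

    def test_normalization_invariance(self, small_table):
        design = self._design(small_table)
        sf = da.poscounts_size_factors(small_table)
        vf1 = da.voom_asinh(small_table, sf, design)
        vf2 = da.voom_asinh(small_table * 2, sf * 2, design)
        pd.testing.assert_frame_equal(vf1.y, vf2.y)

    def test_weights_positive_finite(self, small_table):
        design = self._design(small_table)
        sf = da.poscounts_size_factors(small_table)
        vf = da.voom_asinh(small_table, sf, design)
        w = vf.weights.to_numpy()
        assert np.all(w > 0) and np.all(np.isfinite(w))

    def test_homoscedastic_data_gets_flat_weights(self):
        rng = np.random.default_rng(1)
        n, n_feat = 40, 150
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        Y = rng.normal(5.0, 1.0, size=(n_feat, n))
        counts = pd.DataFrame(
            np.round(np.sinh(np.abs(Y.T))).astype(int) + 1,
            index=[f"s{i}" for i in range(n)],
        )
        design = pd.DataFrame(X, index=counts.index, columns=["i", "x"])
        sf = pd.Series(np.ones(n), index=counts.index)
        vf = da.voom_asinh(counts, sf, design)
        w = vf.weights.to_numpy()
        assert w.std() / w.mean() < 0.5  # no strong trend to exploit

    def test_rank_deficient_design_names_column(self, small_table):
        design = self._design(small_table)
        design["copy"] = design["group"]
        sf = da.poscounts_size_factors(small_table)
        with pytest.raises(ValueError, match="rank deficient"):
            da.voom_asinh(small_table, sf, design)


class TestConsensusCorrelation:
    def _paired_gaussian(self, rho, n_subj=30, n_feat=200, seed=0):
        rng = np.random.default_rng(seed)
        su = rng.normal(size=(n_feat, n_subj)) * np.sqrt(rho)
        eps = rng.normal(size=(n_feat, n_subj, 2)) * np.sqrt(1 - rho)
        Y = (su[:, :, None] + eps).reshape(n_feat, -1)
        block = [f"S{i}" for i in range(n_subj) for _ in range(2)]
        X = np.ones((2 * n_subj, 1))
        return _flat_voomfit(Y, X, block=block)

    def test_recovers_true_correlation(self):
        vf = self._paired_gaussian(0.5)
        assert da.consensus_correlation(vf) == pytest.approx(0.5, abs=0.1)

    def test_independent_noise_near_zero(self):
        vf = self._paired_gaussian(0.0, seed=3)
        assert abs(da.consensus_correlation(vf)) < 0.1

    def test_singleton_blocks_fall_back_to_zero(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(10, 6))
        X = np.ones((6, 1))
        vf = _flat_voomfit(Y, X, block=[f"S{i}" for i in range(6)])
        with pytest.warns(UserWarning, match="singleton"):
            assert da.consensus_correlation(vf) == 0.0


class TestFitModerated:
    def test_posterior_variance_formula(self):
        assert da.posterior_variance(2.0, 4, 4, 1.0) == pytest.approx(1.5)

    def test_infinite_prior_dominates(self):
        s2 = np.array([0.5, 2.0, 7.0])
        np.testing.assert_allclose(da.posterior_variance(s2, 4, np.inf, 1.3), 1.3)

    def test_zero_prior_df_disables_moderation(self):
        s2 = np.array([0.5, 2.0])
        np.testing.assert_allclose(da.posterior_variance(s2, 4, 0, 1.0), s2)

    def test_matches_ols_with_no_moderation(self):
        # rho=0, flat weights, d0=0: the stack must reduce to per-feature OLS
        rng = np.random.default_rng(7)
        n, p, n_feat = 8, 2, 5
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        Y = rng.normal(size=(n_feat, n))
        vf = _flat_voomfit(Y, X)
        contrast = np.array([0.0, 1.0])
        res = da.fit_moderated(vf, rho=0.0, contrasts={"slope": contrast}, prior_df=0)
        tab = res.tables["slope"]
        for f in range(n_feat):
            beta, rss, *_ = np.linalg.lstsq(X, Y[f], rcond=None)
            s2 = rss[0] / (n - p)
            cov = np.linalg.inv(X.T @ X)
            se = np.sqrt(s2 * cov[1, 1])
            t = beta[1] / se
            p_ols = 2 * stats.t.sf(abs(t), df=n - p)
            assert tab["logFC"].iloc[f] == pytest.approx(beta[1], abs=1e-8)
            assert tab["t"].iloc[f] == pytest.approx(t, abs=1e-8)
            assert tab["p"].iloc[f] == pytest.approx(p_ols, abs=1e-8)

    def test_trigamma_inverse_round_trip(self):
        from scipy.special import polygamma

        for x in (0.01, 0.5, 2.0, 50.0):
            y = da._trigamma_inverse(x)
            assert polygamma(1, y) == pytest.approx(x, rel=1e-6)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        adj, flags = da.bh_adjust([0.03])
        assert adj[0] == pytest.approx(0.03)
        assert flags[0]

    def test_stepup_hand_example(self):
        adj, _ = da.bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, 0.04)

    def test_all_ones(self):
        adj, flags = da.bh_adjust([1.0, 1.0, 1.0])
        np.testing.assert_allclose(adj, 1.0)
        assert not flags.any()

    def test_order_invariance(self):
        p = np.array([0.3, 0.001, 0.2, 0.05, 0.9])
        adj, flags = da.bh_adjust(p)
        perm = np.array([4, 2, 0, 1, 3])
        adj_p, flags_p = da.bh_adjust(p[perm])
        np.testing.assert_allclose(adj_p, adj[perm])
        np.testing.assert_array_equal(flags_p, flags[perm])

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=30)
    )
    def test_adjusted_at_least_raw_and_monotone(self, pvals):
        adj, _ = da.bh_adjust(pvals)
        pvals = np.asarray(pvals)
        assert np.all(adj >= pvals - 1e-12)
        order = np.argsort(pvals)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            da.bh_adjust([0.5, 1.2])


@pytest.fixture(scope="module")
def cohort():
    cfg = SimConfig(
        n_subjects_per_diet=12, n_taxa=80, days_per_window=2,
        include_w10=False, n_da_taxa=6, da_effect=2.0, seed=42,
    )
    return pc.simulate_cohort(cfg)


class TestRunDA:
    def test_detected_signs_match_truth(self, cohort):
        table, md, tree, tax, truth = cohort
        res = pc.run_da(table, md)
        for tab in res.tables.values():
            hits = tab[tab.significant]
            for feat in hits.index:
                if feat in truth.da_taxa:
                    assert np.sign(hits.loc[feat, "logFC"]) == np.sign(truth.da_taxa[feat])

    def test_sample_permutation_invariance(self, cohort):
        table, md, tree, tax, truth = cohort
        res1 = pc.run_da(table, md)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(table))
        table_p = table.iloc[perm]
        md_p = pc.CohortMetadata(samples=md.samples.loc[table_p.index], subjects=md.subjects)
        res2 = pc.run_da(table_p, md_p)
        for name in res1.tables:
            pd.testing.assert_frame_equal(
                res1.tables[name].sort_index(),
                res2.tables[name].sort_index(),
                atol=1e-9, rtol=1e-6,
            )

    def test_continuous_mode_runs(self, cohort):
        table, md, tree, tax, truth = cohort
        res = pc.run_da(table, md, mode="continuous")
        assert set(res.tables) == {"slope|low-carb", "slope|low-fat"}

    def test_cluster_level_uses_tree(self, cohort):
        table, md, tree, tax, truth = cohort
        res = pc.run_da(table, md, level="cluster", tree=tree)
        assert all(f.startswith("Cluster") for tab in res.tables.values() for f in tab.index)

    def test_adjusted_p_at_least_raw(self, cohort):
        table, md, *_ = cohort
        res = pc.run_da(table, md)
        for tab in res.tables.values():
            assert (tab["adj_p"] >= tab["p"] - 1e-12).all()
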