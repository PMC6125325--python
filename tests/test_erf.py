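import numpy as np
import pandas as pd
import pytest
from scipy import stats

import otuforest as of
from otuforest import erf


def welch_oracle(a, b):
    """Closed-form one-sided Welch t-test (H1: mean(a) > mean(b)) via the
    Welch-Satterthwaite degrees of freedom; independent of scipy.ttest_ind."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    if se2 == 0:
        ma, mb = a.mean(), b.mean()
        return 0.0 if ma > mb else (1.0 if ma < mb else 0.5)
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return float(stats.t.sf(t, df))


class TestShadowFeatures:
    def test_each_shadow_is_permutation_of_its_column(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 5))
        Xa = of.make_shadow_features(X, seed=1)
        assert Xa.shape == (20, 10)
        for j in range(5):
            np.testing.assert_array_equal(np.sort(Xa[:, 5 + j]), np.sort(X[:, j]))

    def test_constant_column_shadow_identical(self):
        X = np.column_stack([np.full(10, 3.0), np.arange(10.0)])
        Xa = of.make_shadow_features(X, seed=0)
        np.testing.assert_array_equal(Xa[:, 2], X[:, 0])

    def test_deterministic_per_seed(self):
        X = np.random.default_rng(2).normal(size=(15, 4))
        np.testing.assert_array_equal(
            of.make_shadow_features(X, seed=7), of.make_shadow_features(X, seed=7)
        )

    def test_shadow_label_correlation_centred_at_zero(self):
        rng = np.random.default_rng(3)
        y = np.repeat([0.0, 1.0], 15)
        x = y + rng.normal(0, 0.5, 30)  # feature genuinely correlated with y
        corrs = []
        for seed in range(200):
            Xa = of.make_shadow_features(x[:, None], seed=seed)
            corrs.append(np.corrcoef(Xa[:, 1], y)[0, 1])
        assert abs(np.mean(corrs)) < 3 * np.std(corrs) / np.sqrt(200)
        assert np.corrcoef(x, y)[0, 1] > 0.5

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            of.make_shadow_features(np.empty((1, 3)), seed=0)


class TestForestVim:
    def test_planted_feature_has_max_vim(self):
        rng = np.random.default_rng(4)
        y = np.repeat([0, 1], 20)
        X = rng.normal(size=(40, 10))
        X[:, 3] = y + rng.normal(0, 0.05, 40)
        Xa = of.make_shadow_features(X, seed=0)
        vim = of.fit_forest_vim(Xa, y, n_trees=100, seed=1)
        assert vim.argmax() == 3
        assert vim[3] > 0.1

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(5)
        y = np.repeat([0, 1], 10)
        Xa = of.make_shadow_features(rng.normal(size=(20, 6)), seed=2)
        v1 = of.fit_forest_vim(Xa, y, n_trees=50, seed=9)
        v2 = of.fit_forest_vim(Xa, y, n_trees=50, seed=9)
        np.testing.assert_array_equal(v1, v2)

    def test_single_class_rejected(self):
        Xa = of.make_shadow_features(np.random.default_rng(0).normal(size=(8, 4)), 0)
        with pytest.raises(ValueError, match="binary"):
            of.fit_forest_vim(Xa, np.zeros(8), n_trees=10, seed=0)

    def test_odd_column_count_rejected(self):
        with pytest.raises(ValueError, match="even"):
            of.fit_forest_vim(np.zeros((8, 3)), np.repeat([0, 1], 4), n_trees=10)

    def test_null_real_and_shadow_vims_indistinguishable(self):
        """With y independent of X, real and shadow VIM distributions match."""
        rng = np.random.default_rng(6)
        y = np.repeat([0, 1], 12)
        real_vims, shadow_vims = [], []
        for run in range(30):
            X = rng.normal(size=(24, 8))
            Xa = of.make_shadow_features(X, seed=1000 + run)
            v = of.fit_forest_vim(Xa, y, n_trees=60, seed=2000 + run)
            real_vims.extend(v[:8])
            shadow_vims.extend(v[8:])
        assert stats.ks_2samp(real_vims, shadow_vims).pvalue > 0.01


class TestStabilityVims:
    def test_shape_and_determinism(self):
        rng = np.random.default_rng(7)
        y = np.repeat([0, 1], 10)
        X = rng.normal(size=(20, 5))
        V1 = of.stability_vims(X, y, n_repetitions=2, n_trees=30, seed=3)
        V2 = of.stability_vims(X, y, n_repetitions=2, n_trees=30, seed=3)
        assert V1.shape == (10, 2)
        np.testing.assert_array_equal(V1, V2)

    def test_too_few_repetitions(self):
        with pytest.raises(ValueError, match="n_repetitions"):
            of.stability_vims(np.zeros((10, 2)), np.repeat([0, 1], 5), n_repetitions=1)

    def test_strong_feature_vim_is_stable(self):
        rng = np.random.default_rng(8)
        y = np.repeat([0, 1], 24)
        X = rng.normal(size=(48, 12))
        X[:, 0] = y + rng.normal(0, 0.2, 48)
        V = of.stability_vims(X, y, n_repetitions=10, n_trees=100, seed=4)
        cv = V[0].std(ddof=1) / V[0].mean()
        assert V[0].mean() > 0.05
        assert cv < 1.0


class TestRelevanceLikelihood:
    def test_separated_samples(self):
        vims = np.array([[0.9, 0.9, 0.9, 0.9], [0.0, 0.0, 0.0, 0.01]])
        p, lik = of.relevance_likelihood(vims)
        assert p[0] < 1e-6
        assert lik[0] > 99.9999

    def test_exchangeable_case_is_half(self):
        row = np.array([0.1, 0.2, 0.3])
        p, lik = of.relevance_likelihood(np.vstack([row, row]))
        assert p[0] == pytest.approx(0.5)
        assert lik[0] == pytest.approx(50.0)

    def test_zero_variance_degenerate_cases(self):
        const = lambda v: np.full(4, v)
        p, _ = of.relevance_likelihood(np.vstack([const(0.2), const(0.1)]))
        assert p[0] == 0.0
        p, _ = of.relevance_likelihood(np.vstack([const(0.05), const(0.1)]))
        assert p[0] == 1.0
        p, _ = of.relevance_likelihood(np.vstack([const(0.1), const(0.1)]))
        assert p[0] == 0.5

    def test_tested_against_top_mean_shadow(self):
        rng = np.random.default_rng(9)
        feat = rng.normal(0.5, 0.01, 6)
        other = rng.normal(0.1, 0.01, 6)
        weak_shadow = rng.normal(0.0, 0.01, 6)
        top_shadow = rng.normal(0.4, 0.01, 6)
        p, _ = of.relevance_likelihood(
            np.vstack([feat, other, weak_shadow, top_shadow])
        )
        assert p[0] == pytest.approx(welch_oracle(feat, top_shadow), abs=1e-12)
        assert p[1] == pytest.approx(welch_oracle(other, top_shadow), abs=1e-12)

    def test_matches_closed_form_oracle_on_random_instances(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            n_rep = int(rng.integers(2, 12))
            vims = rng.normal(0, 0.01, size=(6, n_rep))
            p, lik = of.relevance_likelihood(vims)
            top = vims[3:][np.argmax(vims[3:].mean(axis=1))]
            for j in range(3):
                assert p[j] == pytest.approx(welch_oracle(vims[j], top), abs=1e-10)
                assert lik[j] == pytest.approx(100 * (1 - p[j]), abs=1e-10)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="2p"):
            of.relevance_likelihood(np.zeros((3, 5)))
        with pytest.raises(ValueError, match="repetitions"):
            of.relevance_likelihood(np.zeros((4, 1)))


class TestSelection:
    def test_vacuous_thresholds_select_all(self):
        results = pd.DataFrame(
            {"mean_vim": [0.1, -0.2, 0.0], "likelihood_pct": [100.0, 0.0, 50.0]},
            index=pd.Index(["b", "a", "c"], name="otu_id"),
        )
        sel = of.select_relevant(results, likelihood_threshold=0,
                                 importance_threshold=-1)
        assert len(sel) == 3
        assert list(sel.index) == ["b", "c", "a"]  # mean_vim desc

    def test_sorted_with_lexicographic_ties(self):
        results = pd.DataFrame(
            {"mean_vim": [0.5, 0.5, 0.7], "likelihood_pct": [100.0] * 3},
            index=pd.Index(["z", "a", "m"], name="otu_id"),
        )
        sel = of.select_relevant(results, 0, 0)
        assert list(sel.index) == ["m", "a", "z"]

    def test_empty_selection_is_valid(self):
        results = pd.DataFrame(
            {"mean_vim": [0.0], "likelihood_pct": [10.0]},
            index=pd.Index(["a"], name="otu_id"),
        )
        assert len(of.select_relevant(results)) == 0


class TestDirectionOfChange:
    def test_fold_change_arithmetic(self):
        # treatment mean rel abundance 0.04 vs control 0.02 -> increased, ~2x
        table = pd.DataFrame(
            {"big": [96, 98, 92, 96], "small": [4, 2, 8, 4]},
            index=["c1", "c2", "t1", "t2"],
        )
        meta = pd.DataFrame(
            {"trial": "T1", "day": 35,
             "group": ["control", "control", "treatment", "treatment"]},
            index=table.index,
        )
        d = of.direction_of_change(table, meta)
        assert d.loc["small", "direction"] == "increased"
        assert d.loc["small", "fold_change"] == pytest.approx(2.0, rel=0.01)

    def test_tie_reported_unchanged(self):
        table = pd.DataFrame({"a": [5, 5], "b": [5, 5]}, index=["c", "t"])
        meta = pd.DataFrame(
            {"trial": "T1", "day": 35, "group": ["control", "treatment"]},
            index=table.index,
        )
        d = of.direction_of_change(table, meta)
        assert (d["direction"] == "unchanged").all()
        assert (d["fold_change"] == 1.0).all()

    def test_missing_otu_listed(self, small_sim):
        table, meta, _ = small_sim
        with pytest.raises(ValueError, match="OTU_9999"):
            of.direction_of_change(table, meta, ["OTU_9999"])

    def test_planted_directions_recovered(self, small_sim):
        table, meta, truth = small_sim
        d = of.direction_of_change(table, meta)
        for otu in truth.sensitive_otu_ids:
            assert d.loc[otu, "direction"] == truth.direction[otu]


class TestShadowRelevanceSelector:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(11)
        y = np.repeat([0, 1], 20)
        X = rng.normal(size=(40, 8))
        X[:, 2] = y + rng.normal(0, 0.1, 40)
        sel = of.ShadowRelevanceSelector(
            n_repetitions=6, n_trees=80, random_state=0
        ).fit(X, y)
        return X, y, sel

    def test_fitted_attributes(self, fitted):
        X, y, sel = fitted
        assert sel.vim_matrix_.shape == (16, 6)
        assert sel.mean_vim_.shape == (8,)
        assert sel.likelihood_pct_.shape == (8,)
        assert sel.support_.dtype == bool

    def test_planted_feature_selected_and_transform(self, fitted):
        X, y, sel = fitted
        assert sel.support_[2]
        Xt = sel.transform(X)
        assert Xt.shape == (40, sel.support_.sum())
        assert 2 in np.flatnonzero(sel.get_support())

    def test_sklearn_params_round_trip(self):
        from sklearn.base import clone

        sel = of.ShadowRelevanceSelector(n_repetitions=3, n_trees=10, random_state=5)
        params = sel.get_params()
        assert params["n_repetitions"] == 3
        c = clone(sel)
        assert c.get_params() == params

    def test_refit_same_seed_identical(self, fitted):
        X, y, sel = fitted
        again = of.ShadowRelevanceSelector(
            n_repetitions=6, n_trees=80, random_state=0
        ).fit(X, y)
        np.testing.assert_array_equal(sel.vim_matrix_, again.vim_matrix_)

    def test_results_frame_sorted(self, fitted):
        X, y, sel = fitted
        frame = sel.results_frame([f"OTU_{i}" for i in range(8)])
        assert frame["mean_vim"].is_monotonic_decreasing
        assert frame.index.name == "otu_id"

    def test_feature_order_permutation_invariance(self):
        """Shuffling feature columns leaves the selected id set unchanged.

        Shadow permutations and forest split draws are tied to column
        position, so exact invariance holds when no feature sits on the
        selection boundary; a small community with two strong planted OTUs
        keeps every feature clearly resolved.
        """
        rng = np.random.default_rng(12)
        y = np.repeat([0, 1], 30)
        X = rng.normal(size=(60, 20))
        X[:, 3] = y + rng.normal(0, 0.1, 60)
        X[:, 11] = -y + rng.normal(0, 0.1, 60)
        s1 = of.ShadowRelevanceSelector(n_repetitions=8, n_trees=100,
                                        random_state=21).fit(X, y)
        perm = np.random.default_rng(0).permutation(20)
        s2 = of.ShadowRelevanceSelector(n_repetitions=8, n_trees=100,
                                        random_state=21).fit(X[:, perm], y)
        sel1 = set(np.flatnonzero(s1.support_))
        sel2 = {perm[j] for j in np.flatnonzero(s2.support_)}
        assert sel1 == {3, 11}
        assert sel1 == sel2
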