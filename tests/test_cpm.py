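import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hubspin as hs
from hubspin.cpm import _edge_correlations
from hubspin.exceptions import DegenerateTargetError, InvalidArgumentError


def random_connectome(rng, n=6):
    w = np.abs(rng.standard_normal((n, n)))
    w = w + w.T
    np.fill_diagonal(w, 0.0)
    return hs.ConnectivityMatrix(w, tuple(f"r{i}" for i in range(n)))


def synthetic_edge_problem(n_subjects, n_regions=20, signal_cols=(0, 5, 11),
                           weights=(1.0, 1.0, -1.0), noise_frac=0.0, seed=0):
    """Edge data with a known linear signal in a few columns."""
    g = np.random.default_rng(seed)
    E = n_regions * (n_regions - 1) // 2
    X = g.standard_normal((n_subjects, E)) + 5.0
    signal = X[:, list(signal_cols)] @ np.asarray(weights)
    if noise_frac > 0:
        noise = g.standard_normal(n_subjects)
        noise *= signal.std() * np.sqrt(noise_frac / (1 - noise_frac)) / noise.std()
    else:
        noise = 0.0
    return X, signal + noise


class TestEdgeVector:
    def test_three_region_order(self):
        w = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
        ev = hs.vectorize_edges(hs.ConnectivityMatrix(w, ("a", "b", "c")))
        assert np.array_equal(ev.values, [1.0, 2.0, 3.0])
        assert ev.pair_labels == [("a", "b"), ("a", "c"), ("b", "c")]

    def test_length_for_62_regions(self, template):
        assert len(hs.vectorize_edges(template).values) == 62 * 61 // 2 == 1891

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_round_trip_exact(self, seed):
        m = random_connectome(np.random.default_rng(seed))
        back = hs.devectorize_edges(hs.vectorize_edges(m))
        assert np.array_equal(back.weights, m.weights)
        assert back.labels == m.labels


class TestSelectEdges:
    def test_perfect_edge_selected(self):
        g = np.random.default_rng(0)
        X = g.standard_normal((100, 50))
        target = X[:, 7].copy()
        pos, neg = hs.select_edges(X, target, 0.01)
        assert pos[7] and not neg[7]

    def test_negation_swaps_masks(self):
        g = np.random.default_rng(1)
        X = g.standard_normal((80, 100))
        target = X[:, :4] @ np.array([1.0, 1.0, -1.0, -1.0]) + 0.3 * g.standard_normal(80)
        pos, neg = hs.select_edges(X, target, 0.05)
        pos2, neg2 = hs.select_edges(X, -target, 0.05)
        assert np.array_equal(pos, neg2)
        assert np.array_equal(neg, pos2)

    def test_null_selection_rate(self):
        # under independence, selected fraction tracks selection_p
        g = np.random.default_rng(2)
        fractions = []
        for _ in range(200):
            X = g.standard_normal((50, 1891))
            target = g.standard_normal(50)
            pos, neg = hs.select_edges(X, target, 0.01)
            fractions.append((pos.sum() + neg.sum()) / 1891)
        assert np.mean(fractions) == pytest.approx(0.01, abs=0.005)

    def test_constant_target_rejected(self):
        X = np.random.default_rng(3).standard_normal((30, 10))
        with pytest.raises(DegenerateTargetError):
            hs.select_edges(X, np.ones(30), 0.01)

    def test_constant_edges_never_selected(self):
        g = np.random.default_rng(4)
        X = g.standard_normal((40, 5))
        X[:, 2] = 7.0
        pos, neg = hs.select_edges(X, g.standard_normal(40), 0.5)
        assert not pos[2] and not neg[2]


class TestSummarizeFeatures:
    def test_singleton_and_empty(self):
        edges = np.array([7.0, 1.0, 2.0])
        pos = np.array([True, False, False])
        neg = np.zeros(3, dtype=bool)
        scores = hs.summarize_features(edges, (pos, neg))
        assert scores[0] == 7.0
        assert scores[1] == 0.0

    def test_matches_loop_oracle(self, rng):
        edges = rng.standard_normal((15, 40))
        pos = rng.random(40) < 0.3
        neg = (rng.random(40) < 0.3) & ~pos
        scores = hs.summarize_features(edges, (pos, neg))
        for s in range(15):
            assert scores[s, 0] == pytest.approx(sum(edges[s, e] for e in range(40) if pos[e]))
            assert scores[s, 1] == pytest.approx(sum(edges[s, e] for e in range(40) if neg[e]))


class TestCrossval:
    def test_noiseless_linear_signal(self):
        # small edge pool keeps false selections rare, so the noiseless
        # 3-edge signal is recovered almost perfectly
        X, y = synthetic_edge_problem(200, n_regions=10, seed=5)
        model = hs.ConnectomePredictiveModel(X, y, hs.CPMConfig(seed=0))
        res = model.fit()
        assert res.r_true_pred > 0.95

    def test_each_subject_predicted_once(self):
        X, y = synthetic_edge_problem(100, noise_frac=0.5, seed=6)
        res = hs.ConnectomePredictiveModel(X, y, hs.CPMConfig(seed=1)).fit()
        seen = np.concatenate(res.fold_test_indices)
        assert sorted(seen) == list(range(100))

    def test_no_leakage_held_out_subject_cannot_change_training(self):
        X, y = synthetic_edge_problem(100, noise_frac=0.3, seed=7)
        cfg = hs.CPMConfig(seed=2, k=5)
        res = hs.ConnectomePredictiveModel(X, y, cfg).fit()
        test_subject = res.fold_test_indices[0][0]
        X2 = X.copy()
        X2[test_subject] += 100.0  # corrupt a held-out subject's connectome
        res2 = hs.ConnectomePredictiveModel(X2, y, cfg).fit()
        assert np.array_equal(res.fold_pos_masks[0], res2.fold_pos_masks[0])
        assert np.array_equal(res.fold_neg_masks[0], res2.fold_neg_masks[0])
        # other folds (which train on the corrupted subject) may differ

    def test_scale_invariance(self):
        X, y = synthetic_edge_problem(120, noise_frac=0.4, seed=8)
        cfg = hs.CPMConfig(seed=3)
        r1 = hs.ConnectomePredictiveModel(X, y, cfg).fit().r_true_pred
        r2 = hs.ConnectomePredictiveModel(10.0 * X, y, cfg).fit().r_true_pred
        assert r1 == pytest.approx(r2, abs=1e-10)

    def test_determinism(self):
        X, y = synthetic_edge_problem(90, noise_frac=0.4, seed=9)
        cfg = hs.CPMConfig(seed=4)
        a = hs.ConnectomePredictiveModel(X, y, cfg).fit()
        b = hs.ConnectomePredictiveModel(X, y, cfg).fit()
        assert np.array_equal(a.predicted, b.predicted)
        assert a.r_true_pred == b.r_true_pred

    def test_loo_scheme(self):
        X, y = synthetic_edge_problem(60, n_regions=10, seed=10)
        res = hs.ConnectomePredictiveModel(X, y, hs.CPMConfig(seed=5, cv_scheme="loo")).fit()
        assert res.n_folds == 60
        assert res.r_true_pred > 0.9

    def test_too_few_subjects(self):
        X, y = synthetic_edge_problem(20, seed=11)
        with pytest.raises(InvalidArgumentError):
            hs.ConnectomePredictiveModel(X, y, hs.CPMConfig(seed=0))

    def test_empty_model_falls_back_to_mean(self):
        g = np.random.default_rng(12)
        X = g.standard_normal((60, 200))
        y = g.standard_normal(60)
        cfg = hs.CPMConfig(seed=6, selection_p=1e-9)
        res = hs.ConnectomePredictiveModel(X, y, cfg).fit()
        assert len(res.empty_folds) == res.n_folds
        for fold, test in enumerate(res.fold_test_indices):
            train = np.setdiff1d(np.arange(60), test)
            assert np.allclose(res.predicted[test], y[train].mean())


class TestPermutationSignificance:
    def test_strong_signal_minimum_p(self):
        X, y = synthetic_edge_problem(100, seed=13)
        model = hs.ConnectomePredictiveModel(X, y, hs.CPMConfig(seed=7, n_permutations=100))
        res = model.permutation_significance(model.fit())
        assert res.p_perm == pytest.approx(1.0 / 101.0)

    def test_p_invariant_to_target_shift(self):
        X, y = synthetic_edge_problem(80, noise_frac=0.5, seed=14)
        cfg = hs.CPMConfig(seed=8, n_permutations=50)
        m1 = hs.ConnectomePredictiveModel(X, y, cfg)
        m2 = hs.ConnectomePredictiveModel(X, y + 100.0, cfg)
        p1 = m1.permutation_significance(m1.fit()).p_perm
        p2 = m2.permutation_significance(m2.fit()).p_perm
        assert p1 == p2

    def test_null_target_r_centered_near_zero(self):
        # cross-validated null predictions carry a small pessimistic bias
        # that shrinks with n; at n=300 the mean null r sits within +-0.05
        g = np.random.default_rng(15)
        X = g.standard_normal((300, 300)) + 3.0
        y = g.standard_normal(300)
        model = hs.ConnectomePredictiveModel(X, y, hs.CPMConfig(seed=9, n_permutations=100))
        res = model.permutation_significance(model.fit())
        assert abs(res.null_r.mean()) < 0.05


class TestTopPredictors:
    def test_noiseless_single_edge(self):
        g = np.random.default_rng(16)
        X = g.standard_normal((120, 66))  # 12 regions
        y = X[:, 23].copy()
        res = hs.ConnectomePredictiveModel(X, y, hs.CPMConfig(seed=10)).fit()
        top = res.top_predictors(1.0)
        ia, ib = np.column_stack(np.triu_indices(12, k=1))[23]
        assert top.iloc[0]["region_a"] == f"r{ia + 1}"
        assert top.iloc[0]["region_b"] == f"r{ib + 1}"

    def test_consistency_zero_returns_everything_ever_selected(self):
        X, y = synthetic_edge_problem(100, noise_frac=0.5, seed=17)
        res = hs.ConnectomePredictiveModel(X, y, hs.CPMConfig(seed=11)).fit()
        ever = (res.fold_pos_masks | res.fold_neg_masks).any(axis=0).sum()
        assert len(res.top_predictors(0.0)) == ever

    def test_planted_edges_recovered_from_cohort(self, parcellation):
        # end-to-end: the generator's planted PRS edges surface as top predictors
        data = hs.simulate_cohort(parcellation, hs.CohortConfig(seed=21, n_subjects=300))
        model = hs.ConnectomePredictiveModel.from_matrices(
            data.connectomes.matrices, data.subjects["prs"].to_numpy(), hs.CPMConfig(seed=12)
        )
        top = model.fit().top_predictors(1.0)
        got = {tuple(sorted(p)) for p in zip(top["region_a"], top["region_b"])}
        planted = {tuple(sorted(e)) for e in data.truth["planted_edges"]}
        assert len(got & planted) >= 4
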