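"""TAN: discretization, conditional MI, Chow-Liu structure, inference."""

import itertools

import numpy as np
import pytest

from dmrscan.benchmarks import enumerate_spanning_trees
from dmrscan.simulate import make_chain_task, make_tree_sampler
from dmrscan.tan import (Discretizer, TANModel, TANStructure,
                         build_tan_structure,
                         conditional_mutual_information, discretize_fit,
                         fit_naive_bayes, fit_tan, pairwise_cmi_matrix,
                         structure_from_cmi, tan_posterior)


class TestDiscretizer:
    def test_quartile_edges(self):
        X = np.arange(1, 101, dtype=float)[:, None]
        disc = discretize_fit(X, n_bins=4)
        assert disc.n_bins == [4]
        assert disc.transform(np.array([[1.0]]))[0, 0] == 0
        assert disc.transform(np.array([[100.0]]))[0, 0] == 3

    def test_constant_feature_single_bin(self):
        disc = discretize_fit(np.full((50, 1), 7.0), n_bins=4)
        assert disc.n_bins == [1]
        assert disc.transform(np.array([[7.0], [100.0]])).max() == 0

    def test_out_of_range_values_clip(self):
        disc = discretize_fit(np.arange(20, dtype=float)[:, None], 4)
        assert disc.transform(np.array([[-50.0]]))[0, 0] == 0
        assert disc.transform(np.array([[999.0]]))[0, 0] == 3

    def test_empty_matrix_errors(self):
        with pytest.raises(ValueError):
            discretize_fit(np.empty((0, 3)), 4)


class TestCMI:
    def test_independent_near_zero(self, rng):
        n = 100_000
        xi = rng.integers(0, 2, n)
        xj = rng.integers(0, 2, n)
        y = rng.integers(0, 2, n)
        assert conditional_mutual_information(xi, xj, y) < 5e-3

    def test_identical_uniform_binary_is_ln2(self, rng):
        # oracle: direct summation over the 8-cell joint table gives ln 2
        n = 200_000
        xi = rng.integers(0, 2, n)
        y = rng.integers(0, 2, n)
        value = conditional_mutual_information(xi, xi, y)
        assert value == pytest.approx(np.log(2), abs=5e-3)

    def test_constant_column_zero(self, rng):
        xi = np.zeros(100, dtype=int)
        xj = rng.integers(0, 3, 100)
        y = rng.integers(0, 2, 100)
        assert conditional_mutual_information(xi, xj, y) == 0.0

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            conditional_mutual_information([0, 1], [0, 1, 0], [0, 1])

    def test_symmetry(self, rng):
        for _ in range(20):
            xi = rng.integers(0, 3, 300)
            xj = rng.integers(0, 4, 300)
            y = rng.integers(0, 2, 300)
            w = rng.random(300)
            assert conditional_mutual_information(xi, xj, y, w) == \
                pytest.approx(conditional_mutual_information(xj, xi, y, w),
                              abs=1e-12)

    def test_pairwise_matrix_matches_direct(self, rng):
        X = rng.integers(0, 4, (400, 7))
        y = rng.integers(0, 2, 400)
        w = rng.random(400)
        M = pairwise_cmi_matrix(X, y, w)
        for i, j in itertools.combinations(range(7), 2):
            assert M[i, j] == pytest.approx(
                conditional_mutual_information(X[:, i], X[:, j], y, w),
                abs=1e-10)


class TestStructure:
    def test_three_attribute_example(self):
        # brute force over the 3 spanning trees: edges {0-1, 0-2} win
        cmi = np.array([[0, 0.5, 0.4], [0.5, 0, 0.1], [0.4, 0.1, 0]])
        structure = structure_from_cmi(cmi)
        assert set(structure.edges) == {(0, 1), (0, 2)}
        assert structure.root == 0

    def test_matches_exhaustive_enumeration(self, rng):
        # oracle: enumerate all labeled spanning trees (Prüfer sequences)
        for _ in range(100):
            d = int(rng.integers(2, 6))
            w = rng.random((d, d))
            w = np.triu(w, 1) + np.triu(w, 1).T
            tree_weight = sum(w[a, b]
                              for a, b in structure_from_cmi(w).edges)
            best = max(sum(w[a, b] for a, b in tree)
                       for tree in enumerate_spanning_trees(d))
            assert tree_weight == pytest.approx(best, abs=1e-12)

    def test_equal_weights_deterministic_tiebreak(self):
        cmi = np.ones((4, 4)) - np.eye(4)
        s1 = structure_from_cmi(cmi)
        s2 = structure_from_cmi(cmi)
        assert s1.parents == s2.parents
        # lowest index pairs chosen first: star rooted at attribute 0
        assert s1.parents == (None, 0, 0, 0)

    def test_single_attribute(self):
        s = build_tan_structure(np.zeros((10, 1), dtype=int),
                                np.arange(10) % 2)
        assert s.parents == (None,)

    def test_always_a_tree(self, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = r.integers(0, 3, (200, 6))
            y = r.integers(0, 2, 200)
            s = build_tan_structure(X, y)
            assert s.is_tree and len(s.edges) == 5

    def test_cycle_rejected(self):
        with pytest.raises(ValueError):
            TANStructure((1, 0, None))


class TestFit:
    def test_uniform_weights_match_unweighted(self, rng):
        X = rng.normal(size=(200, 4))
        y = rng.integers(0, 2, 200)
        m1 = fit_tan(X, y)
        m2 = fit_tan(X, y, np.ones(200))
        assert np.allclose(m1.class_prior, m2.class_prior)
        assert all(np.allclose(a, b) for a, b in zip(m1.cpts, m2.cpts))

    def test_weight_scale_invariance(self, rng):
        X = rng.normal(size=(200, 4))
        y = rng.integers(0, 2, 200)
        w = rng.random(200)
        m1 = fit_tan(X, y, w)
        m2 = fit_tan(X, y, 3.7 * w)
        assert np.allclose(m1.class_prior, m2.class_prior)
        assert all(np.allclose(a, b) for a, b in zip(m1.cpts, m2.cpts))

    def test_concentrated_weight_drives_prior(self, rng):
        X = rng.normal(size=(50, 2))
        y = np.array([1] + [0] * 49)
        w = np.full(50, 1e-9)
        w[0] = 1.0
        model = fit_tan(X, y, w, smoothing=1e-9)
        assert model.class_prior[1] == pytest.approx(1.0, abs=1e-6)

    def test_single_class_errors(self, rng):
        with pytest.raises(ValueError):
            fit_tan(rng.normal(size=(20, 3)), np.zeros(20, dtype=int))

    def test_cpt_columns_normalized(self, rng):
        X = rng.normal(size=(300, 5))
        y = rng.integers(0, 2, 300)
        model = fit_tan(X, y)
        for table in model.cpts:
            assert np.allclose(table.sum(axis=0), 1.0, atol=1e-9)
            assert np.all(table > 0)


class TestPosterior:
    def test_zero_attribute_model_returns_prior(self):
        model = TANModel(TANStructure(()), np.array([0.7, 0.3]), [],
                         Discretizer([]), 1.0)
        assert np.allclose(model.predict_proba(np.empty((1, 0)))[0],
                           [0.7, 0.3])

    def test_two_attribute_toy_equals_joint_bayes(self):
        # oracle: enumerate the full 8-cell joint table and invert by Bayes
        prior = np.array([0.6, 0.4])
        cpt0 = np.array([[0.8, 0.3], [0.2, 0.7]])        # P(x0 | y)
        cpt1 = np.array([[[0.9, 0.4], [0.5, 0.2]],
                         [[0.1, 0.6], [0.5, 0.8]]])      # P(x1 | x0, y)
        model = TANModel(TANStructure((None, 0)), prior, [cpt0, cpt1],
                         Discretizer([np.array([0.5]), np.array([0.5])]),
                         1.0)
        for x0, x1 in itertools.product((0, 1), repeat=2):
            joint = np.array([prior[c] * cpt0[x0, c] * cpt1[x1, x0, c]
                              for c in (0, 1)])
            expected = joint / joint.sum()
            got = tan_posterior(model, np.array([float(x0), float(x1)]))
            assert np.allclose(got, expected, atol=1e-12)

    def test_posterior_sums_to_one(self, rng):
        X = rng.normal(size=(100, 4))
        y = rng.integers(0, 2, 100)
        model = fit_tan(X, y)
        probs = model.predict_proba(rng.normal(size=(50, 4)))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_schema_mismatch_errors(self, rng):
        model = fit_tan(rng.normal(size=(50, 3)), rng.integers(0, 2, 50))
        with pytest.raises(ValueError):
            tan_posterior(model, np.zeros(5))

    def test_fitted_posterior_tracks_generative_truth(self):
        # data from known tree models: fitted posterior close to exact;
        # averaged over models since one random tree may hold an edge too
        # weak to recover from 5000 samples
        maes = []
        for seed in range(5):
            sampler = make_tree_sampler(6, seed=seed)
            X, y = sampler.sample(5000)
            model = fit_tan(X, y)
            Xt, _ = sampler.sample(1000)
            maes.append(np.mean(np.abs(
                model.predict_proba(Xt)[:, 1]
                - sampler.posterior(Xt.astype(int)))))
        assert np.mean(maes) < 0.05
        assert max(maes) < 0.10


class TestSerialization:
    def test_roundtrip_bit_exact(self, rng):
        X = rng.normal(size=(200, 5))
        y = rng.integers(0, 2, 200)
        model = fit_tan(X, y, feature_names=[f"f{i}" for i in range(5)])
        clone = TANModel.from_json(model.to_json())
        Xt = rng.normal(size=(40, 5))
        assert np.array_equal(model.predict_proba(Xt),
                              clone.predict_proba(Xt))
        assert clone.feature_names == model.feature_names


class TestAgainstNaiveBayes:
    def test_tan_beats_nb_under_attribute_dependence(self):
        # strong pairwise dependence: one-sided sign test over 20 seeds
        wins = ties = 0
        for seed in range(20):
            X, y = make_chain_task(seed=seed)
            n_train = 2000
            tan = fit_tan(X[:n_train], y[:n_train])
            nb = fit_naive_bayes(X[:n_train], y[:n_train])
            acc_tan = np.mean(tan.predict(X[n_train:]) == y[n_train:])
            acc_nb = np.mean(nb.predict(X[n_train:]) == y[n_train:])
            wins += acc_tan > acc_nb
            ties += acc_tan == acc_nb
        # sign test at alpha 0.05: with n = wins + losses trials,
        # P(>= wins | p=0.5) must be small; demand a clear majority
        losses = 20 - wins - ties
        assert wins > losses
        from scipy.stats import binomtest

        assert binomtest(wins, wins + losses,
                         alternative="greater").pvalue < 0.05
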