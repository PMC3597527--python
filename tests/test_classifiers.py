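import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.stats import spearmanr

from fktransfer.classifiers import (
    FeatureBaggedForest,
    L1LogisticNetwork,
    NetworkSVM,
    calibrate_sigmoid,
    rank_genes,
)
from fktransfer.errors import CalibrationError, ConfigurationError
from fktransfer.features import FeatureView
from fktransfer.network import FunctionalNetwork


def separable_data(n=20, d=6, seed=0, margin=2.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    w = rng.normal(size=d)
    y = np.where(X @ w >= 0, 1.0, -1.0)
    X += margin * y[:, None] * w / np.linalg.norm(w)  # push classes apart
    return X, y


class TestLinearSVM:
    def test_two_point_separable(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0]])
        y = np.array([1.0, -1.0])
        clf = NetworkSVM(calibration_folds=2).fit(X, y)
        assert np.all(np.sign(clf.decision_function(X)) == y)

    def test_sign_agreement_with_primal_qp_oracle(self):
        # independent reference: minimize 0.5||w||^2 + C sum xi^2 directly
        X, y = separable_data(seed=3)
        C = 100.0

        def objective(wb):
            w, b = wb[:-1], wb[-1]
            xi = np.maximum(0.0, 1.0 - y * (X @ w + b))
            return 0.5 * w @ w + C * np.sum(xi**2)

        ref = minimize(objective, np.zeros(X.shape[1] + 1), method="BFGS",
                       options={"gtol": 1e-10})
        w_ref, b_ref = ref.x[:-1], ref.x[-1]
        clf = NetworkSVM(C=C, class_weight=None).fit(X, y)
        assert np.all(
            np.sign(X @ w_ref + b_ref) == np.sign(clf.decision_function(X))
        )

    def test_decision_values_invariant_to_example_order(self):
        X, y = separable_data(n=40, seed=5, margin=0.5)
        perm = np.random.default_rng(1).permutation(len(y))
        a = NetworkSVM().fit(X, y).decision_function(X)
        b = NetworkSVM().fit(X[perm], y[perm]).decision_function(X)
        assert np.allclose(a, b, atol=1e-6)

    def test_single_class_rejected(self):
        X = np.ones((5, 2))
        with pytest.raises(ConfigurationError):
            NetworkSVM().fit(X, np.ones(5))

    def test_calibrated_probabilities_in_open_interval(self):
        X, y = separable_data(n=30, seed=7)
        clf = NetworkSVM().fit(X, y)
        p = clf.predict_proba(X)[:, 1]
        assert np.all((p > 0) & (p < 1))


class TestSigmoidCalibration:
    def test_symmetric_scores_balanced_labels_cross_half_at_zero(self):
        scores = np.array([-2.0, -1.0, 1.0, 2.0])
        labels = np.array([-1, -1, 1, 1])
        cal = calibrate_sigmoid(scores, labels)
        assert cal.predict([0.0])[0] == pytest.approx(0.5, abs=1e-4)

    def test_matches_generic_optimizer_oracle(self):
        rng = np.random.default_rng(4)
        scores = np.concatenate([rng.normal(1, 1, 30), rng.normal(-1, 1, 40)])
        labels = np.concatenate([np.ones(30), -np.ones(40)])
        cal = calibrate_sigmoid(scores, labels)
        t = np.where(labels > 0, 31 / 32, 1 / 42)

        def nll(ab):
            z = ab[0] * scores + ab[1]
            return float(np.sum(t * np.logaddexp(0, z) + (1 - t) * np.logaddexp(0, -z)))

        oracle = minimize(nll, [-1.0, 0.0], method="Nelder-Mead",
                          options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        assert nll([cal.A, cal.B]) == pytest.approx(oracle.fun, abs=1e-6)

    def test_monotone_in_score(self):
        cal = calibrate_sigmoid([-1.0, -0.5, 0.5, 1.0], [-1, -1, 1, 1])
        p = cal.predict(np.linspace(-3, 3, 50))
        assert np.all(np.diff(p) >= 0)

    def test_separated_scores_bounded_by_smoothed_targets(self):
        cal = calibrate_sigmoid([-5.0, -4.0, 4.0, 5.0], [-1, -1, 1, 1])
        p = cal.predict([-10.0, 10.0])
        assert 0.0 < p[0] and p[1] < 1.0

    def test_degenerate_scores_raise(self):
        with pytest.raises(CalibrationError):
            calibrate_sigmoid([1.0, 1.0, 1.0, 1.0], [1, -1, 1, -1])

    def test_calibration_preserves_ranking_exactly(self):
        X, y = separable_data(n=50, seed=9, margin=0.3)
        clf = NetworkSVM().fit(X, y)
        scores = clf.decision_function(X)
        probs = clf.predict_proba(X)[:, 1]
        rho, _ = spearmanr(scores, probs)
        assert rho == pytest.approx(1.0, abs=1e-12)


class TestL1Logistic:
    def test_huge_lambda_shrinks_all_weights(self):
        X, y = separable_data(n=40, seed=2)
        clf = L1LogisticNetwork(lam=1e5).fit(X, y)
        assert clf.n_nonzero_ == 0
        prev = (y > 0).mean()
        assert clf.predict_proba(X)[:, 1] == pytest.approx(prev, abs=0.05)

    def test_planted_informative_feature_selected(self):
        rng = np.random.default_rng(6)
        n = 120
        X = rng.normal(size=(n, 30))
        y = np.where(X[:, 7] + 0.2 * rng.normal(size=n) > 0, 1.0, -1.0)
        clf = L1LogisticNetwork(lam=2.0).fit(X, y)
        # coordinate-descent oracle check: liblinear's solution must give the
        # planted coordinate dominant weight, noise coordinates mostly zero
        assert abs(clf.coef_[7]) == np.max(np.abs(clf.coef_))
        assert np.sum(clf.coef_ != 0) <= 8

    def test_small_lambda_fits_separable_data(self):
        X, y = separable_data(n=30, seed=8)
        clf = L1LogisticNetwork(lam=1e-4).fit(X, y)
        assert np.all(clf.predict(X) == y)

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(ConfigurationError):
            L1LogisticNetwork(lam=0.0).fit(np.eye(4), np.array([1, 1, -1, -1]))

    def test_sparsity_weakly_monotone_in_lambda(self):
        # weak monotonicity at well-separated regularization scales (the
        # L1 path is not locally monotone in support size)
        X, y = separable_data(n=60, d=20, seed=12, margin=0.5)
        nz = [L1LogisticNetwork(lam=l).fit(X, y).n_nonzero_ for l in (0.01, 1.0, 100.0)]
        assert nz[2] <= min(nz[0], nz[1])
        assert L1LogisticNetwork(lam=1e5).fit(X, y).n_nonzero_ == 0


class TestForest:
    def test_uniform_labels_vote_constant(self):
        X = np.random.default_rng(0).normal(size=(10, 4))
        clf = FeatureBaggedForest(n_trees=11, random_state=0).fit(X, np.ones(10))
        assert np.all(clf.vote_fraction(X) == 1.0)

    def test_perfectly_separating_feature_recovered(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(80, 10))
        y = np.where(X[:, 4] > 0, 1.0, -1.0)
        clf = FeatureBaggedForest(n_trees=61, random_state=0).fit(X[:60], y[:60])
        assert np.all(clf.predict(X[60:]) == y[60:])

    def test_odd_ensemble_never_votes_half(self):
        X, y = separable_data(n=30, seed=4, margin=0.2)
        clf = FeatureBaggedForest(n_trees=61, random_state=1).fit(X, y)
        votes = clf.vote_fraction(X)
        assert not np.any(votes == 0.5)

    def test_reproducible_under_fixed_seed(self):
        X, y = separable_data(n=30, seed=5, margin=0.2)
        v1 = FeatureBaggedForest(n_trees=21, random_state=9).fit(X, y).vote_fraction(X)
        v2 = FeatureBaggedForest(n_trees=21, random_state=9).fit(X, y).vote_fraction(X)
        assert np.array_equal(v1, v2)

    def test_feature_subsets_are_bootstrap_deduplicated(self):
        X, y = separable_data(n=20, d=15, seed=6)
        clf = FeatureBaggedForest(n_trees=7, random_state=2).fit(X, y)
        for feats in clf.feature_subsets_:
            assert len(feats) == len(set(feats)) <= 15


class TestRankGenes:
    def make_view(self):
        net = FunctionalNetwork.from_edges(
            "org",
            {("a", "b"): 0.9, ("a", "c"): 0.1, ("b", "c"): 0.5, ("a", "d"): 0.9,
             ("b", "d"): 0.9, ("c", "d"): 0.1},
        )
        return FeatureView(net)

    def test_monotone_and_flags(self):
        fv = self.make_view()
        X, y, _ = fv.design(["a", "b"], ["c"])
        clf = NetworkSVM(calibration_folds=2).fit(X, y)
        table = rank_genes(clf, fv, ["a", "b", "c", "d"], training_genes=["a", "b"])
        assert list(table["rank"]) == [1, 2, 3, 4]
        assert np.all(np.diff(table["raw_score"]) <= 1e-12)
        assert set(table[table.in_training == 1]["gene"]) == {"a", "b"}
        assert np.all((table["probability"] > 0) & (table["probability"] < 1))

    def test_ties_broken_lexicographically(self):
        class Constant:
            classes_ = np.array([-1.0, 1.0])

            def decision_function(self, X):
                return np.zeros(len(X))

            def predict_proba(self, X):
                return np.tile([0.5, 0.5], (len(X), 1))

        fv = self.make_view()
        table = rank_genes(Constant(), fv, ["d", "b", "a", "c"])
        assert list(table["gene"]) == ["a", "b", "c", "d"]
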