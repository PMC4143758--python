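"""Dual SVM solver: oracle equivalence, KKT conditions, CV plumbing."""

import numpy as np
import pytest
from scipy.optimize import LinearConstraint, minimize

import triosvm as tv
from triosvm.svm_core import _penalty_search, assign_folds
from triosvm.transmission import ScoreMatrix


def random_instance(rng, n=10, d=3, sigma2=1.0):
    X = rng.normal(size=(n, d))
    y = np.where(rng.random(n) < 0.5, -1, 1)
    if np.ptp(y) == 0:  # force both classes
        y[0] = -y[0]
    return X, y, tv.kernel_matrix(X, sigma2=sigma2)


def qp_oracle_objective(K, y, C):
    """Generic box-constrained QP solve of the SVM dual via SLSQP."""
    Q = np.outer(y, y) * K
    Q = 0.5 * (Q + Q.T)

    def neg_dual(a):
        return 0.5 * a @ Q @ a - a.sum()

    def grad(a):
        return Q @ a - np.ones_like(a)

    res = minimize(
        neg_dual,
        x0=np.full(len(y), min(C, 1.0) / 2),
        jac=grad,
        bounds=[(0.0, C)] * len(y),
        constraints=[LinearConstraint(y.astype(float), 0.0, 0.0)],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-14},
    )
    return -res.fun


class TestGaussianKernel:
    def test_identity(self):
        assert tv.gaussian_kernel([1.0, 2.0], [1.0, 2.0]) == 1.0

    def test_closed_form(self):
        assert tv.gaussian_kernel([0.0, 0.0], [1.0, 1.0], 1.0) == pytest.approx(
            np.exp(-1.0)
        )

    def test_vanishes_at_large_distance(self):
        assert tv.gaussian_kernel([0.0], [50.0]) < 1e-300 or \
            tv.gaussian_kernel([0.0], [50.0]) >= 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            tv.gaussian_kernel([0.0], [0.0, 1.0])

    def test_matrix_symmetric_unit_diagonal_psd(self, rng):
        X = rng.normal(size=(12, 4))
        K = tv.kernel_matrix(X)
        assert np.array_equal(K, K.T)
        assert np.allclose(np.diag(K), 1.0)
        assert np.linalg.eigvalsh(K).min() > -1e-10


class TestSolveDual:
    def test_symmetric_two_point_problem(self):
        X = np.array([[-1.0], [1.0]])
        model = tv.solve_dual(tv.kernel_matrix(X), np.array([-1, 1]), 10.0, rows=X)
        expected = 1.0 / (1.0 - np.exp(-2.0))
        assert model.alphas == pytest.approx([expected, expected], rel=1e-4)
        assert model.offset == pytest.approx(0.0, abs=1e-6)
        assert tv.decision_scores(model, [[0.0]]) == pytest.approx([0.0], abs=1e-9)

    def test_duplicated_opposite_pair_hits_box(self):
        X = np.zeros((2, 1))
        model = tv.solve_dual(tv.kernel_matrix(X), np.array([-1, 1]), 0.5)
        assert model.alphas == pytest.approx([0.5, 0.5], abs=1e-8)

    def test_equality_constraint_holds(self, rng):
        for _ in range(5):
            X, y, K = random_instance(rng)
            model = tv.solve_dual(K, y, 3.0)
            assert abs(model.alphas @ y) < 1e-8

    def test_single_class_rejected(self):
        K = tv.kernel_matrix(np.zeros((3, 1)))
        with pytest.raises(ValueError):
            tv.solve_dual(K, np.array([1, 1, 1]), 1.0)

    def test_iteration_cap_raises_with_gap(self, rng):
        X, y, K = random_instance(rng, n=12)
        with pytest.raises(tv.ConvergenceError) as err:
            tv.solve_dual(K, y, 5.0, max_iter=1)
        assert err.value.gap > 0

    def test_matches_qp_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 13))
            C = float(rng.uniform(0.5, 10.0))
            X, y, K = random_instance(rng, n=n)
            model = tv.solve_dual(K, y, C, tol=1e-7)
            oracle = qp_oracle_objective(K, y, C)
            assert model.dual_objective == pytest.approx(
                oracle, rel=1e-6, abs=1e-6
            )

    def test_kkt_conditions(self, rng):
        for _ in range(5):
            X, y, K = random_instance(rng, n=12)
            C = 2.0
            model = tv.solve_dual(K, y, C, tol=1e-6, rows=X)
            f = tv.decision_scores(model, X)
            margin = y * f
            tol = 1e-4
            free = (model.alphas > tol) & (model.alphas < C - tol)
            assert np.all(margin[model.alphas <= tol] >= 1 - tol)
            assert np.allclose(margin[free], 1.0, atol=tol)
            assert np.all(margin[model.alphas >= C - tol] <= 1 + tol)

    def test_label_flip_antisymmetry(self, rng):
        X, y, K = random_instance(rng, n=10)
        m1 = tv.solve_dual(K, y, 2.0, tol=1e-8, rows=X)
        m2 = tv.solve_dual(K, -y, 2.0, tol=1e-8, rows=X)
        assert m2.offset == pytest.approx(-m1.offset, abs=1e-5)
        s1 = tv.decision_scores(m1, X)
        s2 = tv.decision_scores(m2, X)
        assert np.allclose(s2, -s1, atol=1e-5)

    def test_unbounded_support_vector_scores_its_label(self, rng):
        X, y, K = random_instance(rng, n=10)
        model = tv.solve_dual(K, y, 5.0, tol=1e-8, rows=X)
        free = (model.alphas > 1e-6) & (model.alphas < 5.0 - 1e-6)
        if free.any():
            f = tv.decision_scores(model, X[free])
            assert np.allclose(f, y[free], atol=1e-4)

    def test_batch_scores_match_single(self, rng):
        X, y, K = random_instance(rng, n=8)
        model = tv.solve_dual(K, y, 2.0, rows=X)
        batch = tv.decision_scores(model, X)
        singles = [tv.decision_scores(model, X[i : i + 1])[0] for i in range(len(X))]
        assert np.allclose(batch, singles)

    def test_matches_sklearn_svc(self, rng):
        sklearn = pytest.importorskip("sklearn.svm")
        X, y, K = random_instance(rng, n=30, d=4)
        C = 3.0
        model = tv.solve_dual(K, y, C, tol=1e-8, rows=X)
        clf = sklearn.SVC(C=C, kernel="precomputed", tol=1e-8).fit(K, y)
        ours = tv.decision_scores(model, X)
        theirs = clf.decision_function(K)
        assert np.allclose(ours, theirs, atol=1e-4)


def make_features(rng, n=20, m=4, ids=None):
    values = rng.choice([-1.0, -0.5, 0.0, 0.5, 1.0], size=(n, m))
    values[0] = 1.0  # guarantee column variance
    labels = np.array([-1, 1] * (n // 2))
    ids = ids or [f"F{i}:3" for i in range(n)]
    return ScoreMatrix(values, labels, [f"s{j}" for j in range(m)], ids)


class TestCrossValidation:
    def test_stratified_balanced_folds(self):
        labels = np.array([-1] * 5 + [1] * 5)
        ids = [f"F{i}:3" for i in range(10)]
        folds = assign_folds(ids, labels, 5, seed=1)
        for f in range(5):
            sel = folds == f
            assert (labels[sel] == -1).sum() == 1
            assert (labels[sel] == 1).sum() == 1

    def test_too_few_members_suggests_fewer_folds(self):
        labels = np.array([-1, -1, 1, 1, 1, 1, 1])
        with pytest.raises(ValueError, match="folds"):
            assign_folds([f"F{i}" for i in range(7)], labels, 5, seed=0)

    def test_same_seed_same_scores(self, rng):
        feats = make_features(rng)
        cfg = tv.KernelConfig(folds=5, seed=7)
        s1 = tv.cross_validated_scores(feats, 2.0, cfg)
        s2 = tv.cross_validated_scores(feats, 2.0, cfg)
        assert np.array_equal(s1, s2)

    def test_fold_membership_keyed_to_trio_id(self, rng):
        """Permuting rows (same ids, same seed) permutes scores identically."""
        feats = make_features(rng)
        cfg = tv.KernelConfig(folds=5, seed=3)
        s1 = tv.cross_validated_scores(feats, 2.0, cfg)
        perm = rng.permutation(feats.n)
        shuffled = ScoreMatrix(
            feats.values[perm], feats.labels[perm], feats.site_ids,
            [feats.trio_ids[i] for i in perm],
        )
        s2 = tv.cross_validated_scores(shuffled, 2.0, cfg)
        # same folds by construction; scores agree to solver tolerance
        assert np.allclose(s2, s1[perm], atol=1e-4)

    def test_out_of_fold_scores_in_input_order(self, rng):
        feats = make_features(rng, n=10)
        cfg = tv.KernelConfig(folds=2, seed=0)
        scores = tv.cross_validated_scores(feats, 1.0, cfg)
        assert scores.shape == (10,)
        assert np.isfinite(scores).all()


class TestSelectPenalty:
    def test_singleton_grid(self, rng):
        feats = make_features(rng)
        cfg = tv.KernelConfig(penalty_grid=(1,), folds=2, seed=0)
        best, table = tv.select_penalty(feats, cfg)
        assert best == 1.0 and len(table) == 1

    def test_one_row_per_grid_value(self, rng):
        feats = make_features(rng)
        cfg = tv.KernelConfig(penalty_grid=(1, 3, 5), folds=2, seed=0)
        _, table = tv.select_penalty(feats, cfg)
        assert list(table["penalty"]) == [1.0, 3.0, 5.0]

    def test_ties_broken_toward_smallest(self, rng):
        # duplicated penalty values give identical CV AUC by construction
        feats = make_features(rng)
        cfg = tv.KernelConfig(penalty_grid=(2, 2, 2), folds=2, seed=0)
        best, table = tv.select_penalty(feats, cfg)
        assert best == 2.0
        assert table["cv_auc"].nunique() == 1

    def test_warm_started_grid_matches_cold_solves(self, rng):
        """The chosen-C out-of-fold scores from the grid search equal a direct
        cross-validation at that C (warm starting changes nothing)."""
        feats = make_features(rng, n=24)
        cfg = tv.KernelConfig(penalty_grid=(1, 2, 4, 8), folds=4, seed=5)
        search = _penalty_search(feats, cfg)
        direct = tv.cross_validated_scores(feats, search.chosen_penalty, cfg)
        assert np.allclose(
            search.scores_by_penalty[search.chosen_penalty], direct, atol=1e-4
        )
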