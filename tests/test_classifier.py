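"""Dictionary construction, lasso solver, class residuals, SRC, evaluation."""

import numpy as np
import pytest
from sklearn.base import clone

from leaftooth import (
    SparseRepresentationClassifier,
    build_dictionary,
    class_residuals,
    classify,
    evaluate,
    solve_lasso,
)
from leaftooth.classifier import (
    Dictionary,
    _cd_chunk,
    duality_gap,
    kkt_violation,
    lasso_objective,
    soft_threshold,
)
from leaftooth.features import FeatureScaler


def ista_lasso(D, y, alpha, n_iter=100000, tol=1e-15):
    """Independent oracle: accelerated proximal-gradient (FISTA) lasso solver.

    A different algorithm family from the package's coordinate descent:
    full-gradient steps with the soft-thresholding proximal operator,
    Nesterov momentum and function-value restarts.
    """
    L = np.linalg.norm(D, 2) ** 2  # Lipschitz constant of the data term
    x = np.zeros(D.shape[1])
    z = x.copy()
    t = 1.0
    f_prev = np.inf
    for _ in range(n_iter):
        grad = D.T @ (D @ z - y)
        w = z - grad / L
        x_new = np.sign(w) * np.maximum(np.abs(w) - alpha / L, 0)
        r = y - D @ x_new
        f = 0.5 * r @ r + alpha * np.abs(x_new).sum()
        if f > f_prev:  # restart momentum when the objective rises
            z = x.copy()
            t = 1.0
            f_prev = np.inf
            continue
        t_new = 0.5 * (1 + np.sqrt(1 + 4 * t * t))
        z = x_new + ((t - 1) / t_new) * (x_new - x)
        if np.max(np.abs(x_new - x)) < tol:
            return x_new
        x, t, f_prev = x_new, t_new, f
    return x


def _random_problem(rng, d=4, n=20):
    D = rng.normal(size=(d, n))
    D /= np.linalg.norm(D, axis=0)
    y = rng.normal(size=d)
    return D, y / np.linalg.norm(y)


class TestSolveLasso:
    def test_zero_solution_when_correlations_below_alpha(self):
        rng = np.random.default_rng(0)
        D, y = _random_problem(rng)
        alpha = float(np.abs(D.T @ y).max()) + 1e-6
        assert not solve_lasso(D, y, alpha).any()

    def test_orthonormal_dictionary_soft_threshold_closed_form(self):
        rng = np.random.default_rng(1)
        Q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        y = rng.normal(size=4)
        alpha = 0.1
        x = solve_lasso(Q, y, alpha)
        expected = soft_threshold(Q.T @ y, alpha)
        assert x == pytest.approx(expected, abs=1e-8)

    def test_atom_recovery(self):
        rng = np.random.default_rng(2)
        D, _ = _random_problem(rng, n=12)
        y = D[:, 5].copy()
        x = solve_lasso(D, y, 1e-4)
        assert x[5] > 0.99
        assert np.all(np.abs(np.delete(x, 5)) < 0.05)

    def test_kkt_on_random_problems(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            D, y = _random_problem(rng)
            x = solve_lasso(D, y, 0.05)
            assert kkt_violation(D, y, x, 0.05) <= 1e-6

    def test_objective_matches_ista_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            D, y = _random_problem(rng)
            x_cd = solve_lasso(D, y, 0.05)
            x_ista = ista_lasso(D, y, 0.05)
            f_cd = lasso_objective(D, y, x_cd, 0.05)
            f_ista = lasso_objective(D, y, x_ista, 0.05)
            assert f_cd == pytest.approx(f_ista, rel=1e-8)

    def test_objective_matches_sklearn(self):
        from sklearn.linear_model import Lasso

        rng = np.random.default_rng(5)
        for _ in range(10):
            D, y = _random_problem(rng)
            alpha = 0.05
            x = solve_lasso(D, y, alpha)
            # sklearn minimizes (1/2n)||y-Dx||^2 + a||x||_1
            skl = Lasso(alpha=alpha / len(y), fit_intercept=False, tol=1e-12, max_iter=100000)
            skl.fit(D, y)
            assert lasso_objective(D, y, x, alpha) == pytest.approx(
                lasso_objective(D, y, skl.coef_, alpha), rel=1e-7
            )

    def test_objective_monotone_over_sweeps(self):
        rng = np.random.default_rng(6)
        D, y = _random_problem(rng)
        A = np.ascontiguousarray(D)
        col = (A * A).sum(axis=0)
        x = np.zeros(A.shape[1])
        resid = y.copy()
        objs = []
        for _ in range(50):
            _cd_chunk(A, col, 0.05, x, resid, 1, 0.0)
            objs.append(lasso_objective(A, y, x, 0.05))
        assert all(b <= a + 1e-12 for a, b in zip(objs, objs[1:]))

    def test_alpha_path_limits(self):
        rng = np.random.default_rng(7)
        D, y = _random_problem(rng)
        x_big = solve_lasso(D, y, 10.0)
        assert not x_big.any()
        # y in the span of one atom: residual -> 0 as alpha -> 0+
        y2 = D[:, 3].copy()
        x_small = solve_lasso(D, y2, 1e-8)
        assert np.linalg.norm(y2 - D @ x_small) < 1e-4

    def test_duality_gap_nonnegative_and_small_at_optimum(self):
        rng = np.random.default_rng(8)
        D, y = _random_problem(rng)
        x = solve_lasso(D, y, 0.05)
        gap = duality_gap(D, y, x, 0.05)
        assert 0 <= gap < 1e-7

    def test_alpha_must_be_positive(self):
        with pytest.raises(ValueError):
            solve_lasso(np.eye(4), np.ones(4), 0.0)


class TestDictionary:
    def test_shapes_and_grouping(self):
        X = np.tile(np.eye(2), (3, 2))[:6, :4]
        X = np.abs(np.random.default_rng(0).normal(size=(6, 4))) + 0.1
        labels = ["b", "a", "b", "a", "b", "a"]
        D = build_dictionary(X, labels)
        assert D.atoms.shape == (4, 6)
        assert list(D.classes) == ["a", "b"]
        assert (np.diff(np.searchsorted(D.classes, D.atom_labels)) >= 0).all()

    def test_unit_norm_columns(self):
        X = np.random.default_rng(1).uniform(0.1, 1, (10, 4))
        D = build_dictionary(X, ["s"] * 10)
        assert np.linalg.norm(D.atoms, axis=0) == pytest.approx(np.ones(10), abs=1e-9)

    def test_zero_vector_dropped_with_warning(self):
        X = np.vstack([np.ones((3, 4)), np.zeros((1, 4))])
        with pytest.warns(UserWarning, match="zero"):
            D = build_dictionary(X, ["a", "a", "b", "b"])
        assert D.n_atoms == 3


class TestResiduals:
    def _dict(self, rng, q=3, per=4):
        X = rng.uniform(0.1, 1.0, (q * per, 4))
        labels = np.repeat([f"sp{i}" for i in range(q)], per)
        return build_dictionary(X, labels)

    def test_zero_coefficients_residual_is_norm_y(self):
        D = self._dict(np.random.default_rng(0))
        y = np.random.default_rng(1).normal(size=4)
        y /= np.linalg.norm(y)
        res = class_residuals(D, np.zeros(D.n_atoms), y)
        assert res == pytest.approx(np.ones(len(D.classes)))

    def test_exact_reconstruction_zero_residual(self):
        D = self._dict(np.random.default_rng(2))
        j = 5
        y = D.atoms[:, j].copy()
        x = np.zeros(D.n_atoms)
        x[j] = 1.0
        res = class_residuals(D, x, y)
        m = list(D.classes).index(D.atom_labels[j])
        assert res[m] == pytest.approx(0.0, abs=1e-12)
        assert all(r == pytest.approx(1.0) for i, r in enumerate(res) if i != m)

    def test_matches_direct_norm_computation(self):
        rng = np.random.default_rng(3)
        D = self._dict(rng)
        x = rng.normal(size=D.n_atoms)
        y = rng.normal(size=4)
        res = class_residuals(D, x, y)
        for m, cls in enumerate(D.classes):
            sel = D.atom_labels == cls
            direct = np.sqrt(np.sum((y - D.atoms[:, sel] @ x[sel]) ** 2))
            assert res[m] == pytest.approx(direct, abs=1e-12)


class TestClassify:
    def _scaler(self):
        return FeatureScaler(min_=np.zeros(4), max_=np.ones(4))

    def test_single_species_always_that_species(self):
        rng = np.random.default_rng(0)
        D = build_dictionary(rng.uniform(0.1, 1, (5, 4)), ["only"] * 5)
        code = classify(rng.uniform(0, 1, 4), D, self._scaler(), alpha=0.01)
        assert code.predicted == "only"

    def test_tie_breaks_to_lowest_class_index(self):
        atom = np.array([[0.5, 0.5, 0.5, 0.5]])
        D = build_dictionary(np.vstack([atom, atom]), ["sp2", "sp1"])
        code = classify(atom[0], D, self._scaler(), alpha=0.01)
        assert code.predicted == "sp1"

    def test_nan_features_unclassifiable(self):
        D = build_dictionary(np.random.default_rng(1).uniform(0.1, 1, (4, 4)), ["a", "a", "b", "b"])
        code = classify(np.array([1.0, np.nan, 0.5, 0.2]), D, self._scaler(), alpha=0.01)
        assert code.predicted is None and np.isnan(code.residuals).all()

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0.1, 1.0, (12, 4))
        labels = np.array(["a", "b", "c"] * 4)
        D1 = build_dictionary(X, labels)
        perm = rng.permutation(12)
        D2 = build_dictionary(X[perm], labels[perm])
        for _ in range(10):
            y = rng.uniform(0, 1, 4)
            c1 = classify(y, D1, self._scaler(), alpha=0.01)
            c2 = classify(y, D2, self._scaler(), alpha=0.01)
            assert c1.predicted == c2.predicted
            assert c1.residuals == pytest.approx(c2.residuals, abs=1e-6)


class TestEstimatorAPI:
    def _data(self, rng, n=30):
        X = np.vstack(
            [
                rng.normal([10, 0.01, 60, 1.2], [1, 0.001, 3, 0.1], (n, 4)),
                rng.normal([25, 0.02, 100, 2.5], [1, 0.001, 3, 0.1], (n, 4)),
            ]
        )
        y = np.array(["a"] * n + ["b"] * n)
        return X, y

    def test_fit_predict_separable(self):
        rng = np.random.default_rng(0)
        X, y = self._data(rng)
        clf = SparseRepresentationClassifier(alpha=0.01).fit(X, y)
        assert (clf.predict(X) == y).all()
        assert list(clf.classes_) == ["a", "b"]

    def test_decision_function_is_negative_residual(self):
        rng = np.random.default_rng(1)
        X, y = self._data(rng, n=10)
        clf = SparseRepresentationClassifier().fit(X, y)
        df = clf.decision_function(X[:3])
        res = clf.residuals(X[:3])
        assert df == pytest.approx(-res)

    def test_clone_and_get_params(self):
        clf = SparseRepresentationClassifier(alpha=0.07, max_iter=123)
        params = clf.get_params()
        assert params["alpha"] == 0.07 and params["max_iter"] == 123
        clone(clf)  # sklearn-compatible construction

    def test_works_in_sklearn_cross_validation(self):
        from sklearn.model_selection import cross_val_score

        rng = np.random.default_rng(2)
        X, y = self._data(rng, n=12)
        scores = cross_val_score(SparseRepresentationClassifier(), X, y, cv=3)
        assert scores.mean() > 0.9


class TestEvaluate:
    def test_perfectly_separable_is_always_perfect(self):
        # species must differ in feature *direction*: unit-norm scaling
        # cannot distinguish vectors that differ only by a common factor
        rng = np.random.default_rng(0)
        means = ([10, 0.01, 60, 1.2], [25, 0.02, 100, 2.5], [18, 0.03, 140, 0.8])
        X = np.vstack([rng.normal(m, [0.5, 0.001, 2, 0.05], (10, 4)) for m in means])
        y = np.repeat(["a", "b", "c"], 10)
        rep = evaluate(X, y, n_runs=5, seed=0)
        assert rep.overall_mean == 1.0 and rep.overall_std == 0.0

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 1, (120, 4))
        y = rng.permutation(np.repeat(["a", "b", "c", "d"], 30))
        rep = evaluate(X, y, n_runs=20, seed=2)
        assert 0.10 < rep.overall_mean < 0.40  # chance = 0.25

    def test_seeded_reruns_identical(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, (40, 4))
        y = np.repeat(["a", "b"], 20)
        r1 = evaluate(X, y, n_runs=5, seed=11)
        r2 = evaluate(X, y, n_runs=5, seed=11)
        assert np.array_equal(r1.run_accuracies, r2.run_accuracies)
        assert r1.per_species == r2.per_species

    def test_tiny_species_excluded_with_warning(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0, 1, (21, 4))
        y = np.array(["a"] * 10 + ["b"] * 10 + ["rare"])
        with pytest.warns(UserWarning, match="rare"):
            rep = evaluate(X, y, n_runs=2, seed=0)
        assert "rare" not in rep.per_species
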