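"""Sparse-representation classification (SRC) of leaf-tooth feature vectors.

Training feature vectors, min-max scaled to [0, 1] and then scaled to unit
Euclidean norm, form the columns ("atoms") of an overall dictionary
D = [D_1 D_2 ... D_q] whose label-m block D_m is the species-m
sub-dictionary.  A query y (normalized the same way) is projected onto the
dictionary by solving the lasso

    x* = argmin_x  1/2 ||y - D x||_2^2 + alpha ||x||_1,

and the species is the one whose sub-dictionary reconstructs y best:
Species(y) = argmin_m r_m(y) with r_m(y) = ||y - D_m x_m||_2, where x_m are
the coefficients of D_m's columns.  Ties break to the lowest class index.

The lasso is solved by cyclic coordinate descent with exact per-coordinate
minimization (soft-thresholding); unit-norm atoms make the coordinate update
closed-form.  With 4-dimensional features the dictionary is massively
overcomplete and the lasso solution is not unique, but the class residual
rule remains well-defined.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .errors import SolverError
from .features import FeatureScaler, fit_scaler

log = logging.getLogger(__name__)

__all__ = [
    "Dictionary",
    "SparseCode",
    "soft_threshold",
    "solve_lasso",
    "lasso_objective",
    "kkt_violation",
    "build_dictionary",
    "class_residuals",
    "classify",
    "SparseRepresentationClassifier",
    "evaluate",
    "EvaluationReport",
]


@dataclass
class Dictionary:
    """Labeled atom matrix D with species sub-dictionary blocks.

    ``atoms`` is (d, n) with unit-norm columns; ``atom_labels`` gives the
    class of each column; ``classes`` the ordered distinct labels.
    Classification does not depend on column grouping order.
    """

    atoms: np.ndarray
    atom_labels: np.ndarray
    classes: np.ndarray

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[1]

    def block(self, label) -> np.ndarray:
        return self.atoms[:, self.atom_labels == label]


@dataclass
class SparseCode:
    """Result of coding one query: coefficients, residuals and prediction."""

    x: np.ndarray
    alpha: float
    objective: float
    residuals: np.ndarray
    predicted: object


def soft_threshold(z: np.ndarray | float, t: float):
    return np.sign(z) * np.maximum(np.abs(z) - t, 0.0)


def lasso_objective(D: np.ndarray, y: np.ndarray, x: np.ndarray, alpha: float) -> float:
    r = y - D @ x
    return 0.5 * float(r @ r) + alpha * float(np.abs(x).sum())


def kkt_violation(D: np.ndarray, y: np.ndarray, x: np.ndarray, alpha: float) -> float:
    """Maximum violation of the lasso stationarity conditions.

    For x_j != 0 the correlation d_j^T(y - Dx) must equal alpha*sign(x_j);
    for x_j == 0 its magnitude must not exceed alpha.  Returns the largest
    deviation, 0 for an exact solution.
    """
    corr = D.T @ (y - D @ x)
    active = x != 0
    v_active = np.abs(corr[active] - alpha * np.sign(x[active]))
    v_inactive = np.maximum(np.abs(corr[~active]) - alpha, 0.0)
    vals = np.concatenate([v_active, v_inactive])
    return float(vals.max()) if vals.size else 0.0


try:  # jitted inner loop; plain-Python fallback keeps the package importable
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    def _njit(*a, **k):
        def deco(f):
            return f
        return deco if not a or not callable(a[0]) else a[0]


@_njit(cache=False)
def _cd_chunk(A, col_sq, alpha, x, resid, n_sweeps, tol):  # pragma: no cover
    n = A.shape[1]
    delta = 0.0
    done = 0
    for _ in range(n_sweeps):
        delta = 0.0
        for j in range(n):
            if col_sq[j] == 0.0:
                continue
            old = x[j]
            rho = old * col_sq[j]
            for i in range(A.shape[0]):
                rho += A[i, j] * resid[i]
            if rho > alpha:
                new = (rho - alpha) / col_sq[j]
            elif rho < -alpha:
                new = (rho + alpha) / col_sq[j]
            else:
                new = 0.0
            if new != old:
                for i in range(A.shape[0]):
                    resid[i] += A[i, j] * (old - new)
                x[j] = new
                diff = abs(new - old)
                if diff > delta:
                    delta = diff
        done += 1
        if delta < tol:
            break
    return delta, done


def duality_gap(D: np.ndarray, y: np.ndarray, x: np.ndarray, alpha: float) -> float:
    """Primal-dual gap of the lasso: an upper bound on the suboptimality.

    The dual candidate is the residual rescaled into the feasible set
    {nu : ||D^T nu||_inf <= alpha}; at the optimum the gap is zero.
    """
    r = y - D @ x
    corr_max = float(np.abs(D.T @ r).max())
    s = 1.0 if corr_max <= alpha else alpha / corr_max
    nu = s * r
    primal = 0.5 * float(r @ r) + alpha * float(np.abs(x).sum())
    dual = 0.5 * float(y @ y) - 0.5 * float((nu - y) @ (nu - y))
    return primal - dual


def _active_set_polish(
    A: np.ndarray, y: np.ndarray, alpha: float, x: np.ndarray
) -> np.ndarray | None:
    """Finish a nearly-converged lasso solve exactly on its active set.

    With near-duplicate atoms, coordinate descent identifies the active set
    quickly but then zigzags along a nearly flat valley.  Given the candidate
    active set (atoms at or near the correlation bound), the stationarity
    conditions D_S^T(y - D_S x_S) = alpha * s fix x_S up to the (possibly
    singular) normal system, solved here in the minimum-norm sense; atoms
    whose solved sign contradicts their correlation sign are dropped and the
    system re-solved.  Returns the polished solution, or None if no
    sign-consistent solution emerges.
    """
    corr = A.T @ (y - A @ x)
    S = list(np.where((np.abs(corr) >= alpha * (1.0 - 1e-3)) | (x != 0))[0])
    if not S:
        return None
    signs = {j: (np.sign(x[j]) if x[j] != 0 else (np.sign(corr[j]) or 1.0)) for j in S}
    seen: set[tuple] = set()
    for _ in range(200):
        S.sort()
        state = tuple((j, signs[j]) for j in S)
        if state in seen:
            return None  # cycling on a degenerate face
        seen.add(state)
        Sa = np.array(S)
        s = np.array([signs[j] for j in S])
        As = A[:, Sa]
        G = As.T @ As
        rhs = As.T @ y - alpha * s
        xs, *_ = np.linalg.lstsq(G, rhs, rcond=None)
        incons = np.abs(G @ xs - rhs)
        if incons.max() > 1e-10:
            # linearly dependent atoms cannot all sit at the correlation
            # bound with these signs: retire the worst-violated one
            drop = int(np.argmax(incons))
            signs.pop(S[drop])
            del S[drop]
            if not S:
                return None
            continue
        bad = np.where(xs * s < -1e-12)[0]
        if bad.size:
            drop = int(bad[0])  # Bland's rule: lowest index, prevents cycling
            signs.pop(S[drop])
            del S[drop]
            if not S:
                return None
            continue
        out = np.zeros_like(x)
        out[Sa] = xs
        corr = A.T @ (y - A @ out)
        corr[Sa] = 0.0
        viol = np.where(np.abs(corr) > alpha * (1.0 + 1e-12))[0]
        if viol.size:
            k = int(viol[0])  # Bland's rule again
            S.append(k)
            signs[k] = np.sign(corr[k])
            continue
        return out
    return None


def _dual_qp_lasso(A: np.ndarray, y: np.ndarray, alpha: float) -> np.ndarray | None:
    """Exact lasso solve via the dual least-distance QP.

    The dual of 1/2||y - Dx||^2 + alpha||x||_1 is the projection of y onto
    the polytope {nu : ||D^T nu||_inf <= alpha}.  The dual is strictly
    convex in d dimensions (d = 4 here), so its solution nu* = y - Dx* is
    unique no matter how degenerate the overcomplete dictionary is.  A
    primal active-set iteration solves it exactly; the primal coefficients
    are then recovered by non-negative least squares on the sign-adjusted
    active atoms.  Returns None if the iteration fails to terminate.
    """
    from scipy.optimize import nnls

    d, n = A.shape
    # constraint normals c_i^T nu <= alpha, i < n: +d_i, i >= n: -d_i
    corr0 = A.T @ y
    scale = float(np.abs(corr0).max())
    nu = y if scale <= alpha else y * (alpha / scale)
    W: list[int] = []

    def normal(i: int) -> np.ndarray:
        return A[:, i] if i < n else -A[:, i - n]

    for _ in range(300):
        N = np.column_stack([normal(i) for i in W]) if W else np.zeros((d, 0))
        if W:
            M = N.T @ N
            mu, *_ = np.linalg.lstsq(M, N.T @ y - alpha, rcond=None)
            nu_eq = y - N @ mu
        else:
            mu = np.zeros(0)
            nu_eq = y
        p = nu_eq - nu
        if float(np.hypot(*p) if d == 2 else np.linalg.norm(p)) > 1e-13:
            cp = A.T @ p
            crn = A.T @ nu
            t = 1.0
            blocker = -1
            for i in range(2 * n):
                ci_p = cp[i] if i < n else -cp[i - n]
                if ci_p <= 1e-14 or i in W:
                    continue
                ci_nu = crn[i] if i < n else -crn[i - n]
                ti = (alpha - ci_nu) / ci_p
                if ti < t - 1e-15:
                    t = max(ti, 0.0)
                    blocker = i
            nu = nu + t * p
            if blocker >= 0:
                W.append(blocker)
                if np.linalg.matrix_rank(np.column_stack([normal(i) for i in W])) < len(W):
                    W.pop()  # dependent hyperplane: treat as full step
            continue
        if mu.size and mu.min() < -1e-12:
            W.pop(int(np.argmin(mu)))  # drop most negative multiplier
            continue
        break
    else:
        return None

    corr = A.T @ nu
    active = np.where(np.abs(corr) >= alpha - 1e-9)[0]
    if active.size == 0:
        return np.zeros(n)
    signs = np.sign(corr[active])
    B = A[:, active] * signs
    u, rnorm = nnls(B, y - nu)
    if rnorm > 1e-7:
        return None
    x = np.zeros(n)
    x[active] = signs * u
    return x


def solve_lasso(
    D: np.ndarray | Dictionary,
    y: np.ndarray,
    alpha: float,
    tol: float = 1e-8,
    max_iter: int = 200000,
    gap_tol: float = 1e-12,
) -> np.ndarray:
    """Cyclic coordinate descent for 1/2||y - Dx||^2 + alpha||x||_1.

    Columns need not be unit norm (the update divides by the column's squared
    norm); zero columns keep zero coefficients.  Convergence is declared when
    the largest coordinate change in a sweep falls below ``tol`` or the
    duality gap falls below ``gap_tol`` — with strongly correlated atoms the
    minimizer is not unique and coefficients can keep drifting along the
    near-flat solution set long after the objective has converged, so the
    gap is the principled criterion and the sweep budget is generous.
    Exceeding ``max_iter`` sweeps raises :class:`SolverError` with the final
    KKT gap.
    """
    A = D.atoms if isinstance(D, Dictionary) else np.asarray(D, dtype=float)
    A = np.ascontiguousarray(A, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    col_sq = (A * A).sum(axis=0)
    x = np.zeros(A.shape[1])
    # screening: all-zero solution when no atom correlates beyond alpha
    if np.abs(A.T @ y).max() <= alpha:
        return x
    resid = y.copy()
    chunk = 2000
    sweeps = 0
    while sweeps < max_iter:
        delta, done = _cd_chunk(A, col_sq, alpha, x, resid, min(chunk, max_iter - sweeps), tol)
        sweeps += done
        if delta < tol:
            return x
        if duality_gap(A, y, x, alpha) < gap_tol:
            return x
        # stalled on a degenerate face: try finishing exactly
        polished = _active_set_polish(A, y, alpha, x)
        if polished is not None and kkt_violation(A, y, polished, alpha) <= max(tol, 1e-9):
            return polished
        polished = _dual_qp_lasso(A, y, alpha)
        if polished is not None and kkt_violation(A, y, polished, alpha) <= max(tol, 1e-9):
            return polished
    raise SolverError(
        f"lasso did not converge in {max_iter} sweeps "
        f"(KKT gap {kkt_violation(A, y, x, alpha):.3e})"
    )


def build_dictionary(features: np.ndarray, labels) -> Dictionary:
    """Stack normalized feature vectors as unit-norm dictionary columns.

    ``features`` is (n, d), already min-max normalized; each row becomes a
    column scaled to unit Euclidean norm, grouped by class.  Zero vectors are
    dropped with a warning.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    labels = np.asarray(labels)
    norms = np.linalg.norm(X, axis=1)
    nz = norms > 0
    if not nz.all():
        warnings.warn(f"dropped {int((~nz).sum())} zero feature vector(s) from dictionary")
    X, labels, norms = X[nz], labels[nz], norms[nz]
    classes = np.unique(labels)
    order = np.argsort(labels, kind="stable")
    atoms = (X[order] / norms[order, None]).T
    return Dictionary(atoms=atoms, atom_labels=labels[order], classes=classes)


def class_residuals(D: Dictionary, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-class reconstruction residuals r_m = ||y - D_m x_m||_2."""
    y = np.asarray(y, dtype=float)
    res = np.empty(len(D.classes))
    for m, cls in enumerate(D.classes):
        sel = D.atom_labels == cls
        res[m] = np.linalg.norm(y - D.atoms[:, sel] @ x[sel])
    return res


def _normalize_query(scaler: FeatureScaler, y_raw: np.ndarray) -> np.ndarray:
    y = scaler.transform(np.asarray(y_raw, dtype=float).reshape(1, -1))[0]
    nrm = np.linalg.norm(y)
    if nrm == 0:
        warnings.warn("query scales to the zero vector; residuals degenerate")
        return y
    return y / nrm


def classify(
    y_raw: np.ndarray,
    dictionary: Dictionary,
    scaler: FeatureScaler,
    alpha: float = 0.01,
    tol: float = 1e-8,
    max_iter: int = 10000,
) -> SparseCode:
    """Classify one raw feature vector: scale, unit-normalize, code, argmin.

    A vector containing NaN (unclassifiable leaf, e.g. zero teeth) yields
    ``predicted=None`` with NaN residuals rather than a species.
    """
    y_raw = np.asarray(y_raw, dtype=float)
    if np.isnan(y_raw).any():
        nanres = np.full(len(dictionary.classes), np.nan)
        return SparseCode(x=np.zeros(dictionary.n_atoms), alpha=alpha,
                          objective=float("nan"), residuals=nanres, predicted=None)
    y = _normalize_query(scaler, y_raw)
    x = solve_lasso(dictionary, y, alpha, tol=tol, max_iter=max_iter)
    res = class_residuals(dictionary, x, y)
    pred = dictionary.classes[int(np.argmin(res))]  # first minimum: lowest class index
    return SparseCode(x=x, alpha=alpha, objective=lasso_objective(dictionary.atoms, y, x, alpha),
                      residuals=res, predicted=pred)


class SparseRepresentationClassifier(ClassifierMixin, BaseEstimator):
    """scikit-learn style sparse-representation classifier.

    Parameters
    ----------
    alpha : float, default 0.01
        L1 penalty of the lasso projection (applied after min-max and unit
        normalization).
    tol : float, default 1e-8
        Coordinate-descent convergence tolerance (max coefficient change).
    max_iter : int, default 10000
        Maximum coordinate-descent sweeps.

    Attributes
    ----------
    classes_ : ndarray of sorted class labels.
    dictionary_ : :class:`Dictionary` of unit-norm training atoms.
    scaler_ : :class:`FeatureScaler` with the training min/max.
    """

    def __init__(self, alpha: float = 0.01, tol: float = 1e-8, max_iter: int = 10000):
        self.alpha = alpha
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.scaler_ = fit_scaler(X)
        self.dictionary_ = build_dictionary(self.scaler_.transform(X), y)
        self.classes_ = self.dictionary_.classes
        self.n_features_in_ = X.shape[1]
        return self

    def residuals(self, X) -> np.ndarray:
        """(n_samples, n_classes) matrix of class reconstruction residuals."""
        check_is_fitted(self, "dictionary_")
        X = check_array(X)
        out = np.empty((X.shape[0], len(self.classes_)))
        for i, row in enumerate(X):
            out[i] = classify(
                row, self.dictionary_, self.scaler_, alpha=self.alpha,
                tol=self.tol, max_iter=self.max_iter,
            ).residuals
        return out

    def decision_function(self, X) -> np.ndarray:
        return -self.residuals(X)

    def predict(self, X) -> np.ndarray:
        res = self.residuals(X)
        return self.classes_[np.argmin(res, axis=1)]


@dataclass
class EvaluationReport:
    """Accuracies of the repeated stratified 50/50 train/test protocol."""

    per_species: dict
    overall_mean: float
    overall_std: float
    run_accuracies: np.ndarray
    n_runs: int

    def __str__(self) -> str:
        lines = [f"overall accuracy: {100*self.overall_mean:.1f} +/- {100*self.overall_std:.1f} %"]
        for sp, (m, s) in self.per_species.items():
            lines.append(f"  {sp}: {100*m:.1f} +/- {100*s:.1f} %")
        return "\n".join(lines)


def evaluate(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.01,
    n_runs: int = 5,
    seed: int | None = None,
    train_frac: float = 0.5,
) -> EvaluationReport:
    """Repeated stratified split evaluation of the SRC classifier.

    Per run: a stratified random split assigns ``train_frac`` (default half)
    of each species to training; scaler and dictionary are fit on the
    training half only, and per-species accuracy (fraction of test leaves of
    that species identified correctly) is measured on the held-out half.
    Mean and population standard deviation over ``n_runs`` runs are reported,
    per species and overall (over all test samples).  Species with fewer
    than 2 samples are excluded with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    small = classes[counts < 2]
    if small.size:
        warnings.warn(f"excluding species with < 2 samples: {list(small)}")
        keep = ~np.isin(y, small)
        X, y = X[keep], y[keep]
        classes = classes[counts >= 2]
    splitter = StratifiedShuffleSplit(
        n_splits=n_runs, train_size=train_frac, random_state=seed
    )
    per_run_species = {c: [] for c in classes}
    overall = []
    for train_idx, test_idx in splitter.split(X, y):
        clf = SparseRepresentationClassifier(alpha=alpha).fit(X[train_idx], y[train_idx])
        pred = clf.predict(X[test_idx])
        truth = y[test_idx]
        overall.append(float(np.mean(pred == truth)))
        for c in classes:
            sel = truth == c
            per_run_species[c].append(float(np.mean(pred[sel] == truth[sel])))
    per_species = {
        c: (float(np.mean(v)), float(np.std(v))) for c, v in per_run_species.items()
    }
    runs = np.array(overall)
    return EvaluationReport(
        per_species=per_species,
        overall_mean=float(runs.mean()),
        overall_std=float(runs.std()),
        run_accuracies=runs,
        n_runs=n_runs,
    )
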