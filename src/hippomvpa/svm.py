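"""Linear support vector machine tuned for many tiny training sets.

The nested searchlight procedure fits a linear SVM (fixed C = 1) once per
voxel neighbourhood per leave-one-out fold — millions of fits on problems
of a few dozen trials and at most ~123 features.  General-purpose SVM
wrappers spend roughly a millisecond of per-call overhead, which dominates
at that scale, so this module implements the hinge-loss dual
coordinate-descent solver directly (the same algorithm family as
liblinear, with the intercept carried as an augmented, regularized
constant feature) and compiles it with numba.

Two representations are used:

* feature space (weights ``w``) for one-off fits and prediction of unseen
  data — :func:`_fit_cold` and the :class:`LinearSvm` wrapper;
* dual / Gram space with cached per-trial decision values for the
  exhaustive leave-one-out and leave-two-out tables — there each refit
  warm-starts from the full-data dual solution and coordinates that do
  not move cost O(1), which is what makes the nested searchlight loops
  affordable.

The optimisation is deterministic: coordinates are visited in a fixed
order and there is no randomisation, so identical inputs give identical
models.

Primal problem (labels y_i ∈ {−1, +1}, x̃ = (x, 1)):

    min_w  ½‖w‖² + C Σ_i max(0, 1 − y_i wᵀx̃_i)

solved in the dual (kernel K = XXᵀ + 1) by coordinate descent with the
projected-gradient stopping rule ``max_i |PG_i| < tol``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

DEFAULT_C = 1.0
DEFAULT_TOL = 1e-4
MAX_EPOCHS_COLD = 4000
MAX_EPOCHS_WARM = 100000
CD_BURST = 40
MAX_OUTER = 50


# ---------------------------------------------------------------------------
# feature-space solver (one-off fits, prediction on unseen data)


@njit(cache=True, fastmath=True)
def _fit_cold(X, y, C, tol, max_epochs):
    """Cold dual CD in feature space; returns (w, alpha).

    ``w`` has length d+1, the last entry being the intercept weight of the
    augmented constant feature.
    """
    n, d = X.shape
    w = np.zeros(d + 1)
    alpha = np.zeros(n)
    Q = np.empty(n)
    for i in range(n):
        s = 1.0
        for k in range(d):
            s += X[i, k] * X[i, k]
        Q[i] = s
    for _epoch in range(max_epochs):
        max_pg = 0.0
        for i in range(n):
            s = w[d]
            for k in range(d):
                s += w[k] * X[i, k]
            g = y[i] * s - 1.0
            pg = g
            if alpha[i] <= 0.0 and g > 0.0:
                pg = 0.0
            elif alpha[i] >= C and g < 0.0:
                pg = 0.0
            if pg > max_pg:
                max_pg = pg
            elif -pg > max_pg:
                max_pg = -pg
            if pg != 0.0:
                a_old = alpha[i]
                a_new = a_old - g / Q[i]
                if a_new < 0.0:
                    a_new = 0.0
                elif a_new > C:
                    a_new = C
                alpha[i] = a_new
                da = (a_new - a_old) * y[i]
                for k in range(d):
                    w[k] += da * X[i, k]
                w[d] += da
        if max_pg < tol:
            break
    return w, alpha


# ---------------------------------------------------------------------------
# dual / Gram solver with cached decision values (LOO tables)


@njit(cache=True, fastmath=True)
def _cd_gram(K, y, f, alpha, skip1, skip2, C, tol, max_epochs):
    """Dual CD on a precomputed kernel, updating decision values in place.

    ``f[i]`` caches the decision value Σ_k α_k y_k K[k, i]; a coordinate
    whose α does not move costs O(1).  Samples ``skip1``/``skip2`` are
    excluded from the training set (pass −1 to disable).
    """
    n = K.shape[0]
    for epoch in range(max_epochs):
        max_pg = 0.0
        for i in range(n):
            if i == skip1 or i == skip2:
                continue
            g = y[i] * f[i] - 1.0
            pg = g
            if alpha[i] <= 0.0 and g > 0.0:
                pg = 0.0
            elif alpha[i] >= C and g < 0.0:
                pg = 0.0
            if pg > max_pg:
                max_pg = pg
            elif -pg > max_pg:
                max_pg = -pg
            if pg != 0.0:
                a_old = alpha[i]
                a_new = a_old - g / K[i, i]
                if a_new < 0.0:
                    a_new = 0.0
                elif a_new > C:
                    a_new = C
                alpha[i] = a_new
                da = (a_new - a_old) * y[i]
                for k in range(n):
                    f[k] += da * K[i, k]
        if max_pg < tol:
            return epoch + 1
    return max_epochs


@njit(cache=True, fastmath=True)
def _solve_gram(K, y, f, alpha, skip1, skip2, C, tol):
    """Converge the dual on a precomputed kernel, in place.

    Alternates short CD bursts with an exact solve of the free-support-
    vector subsystem (the coordinates strictly inside the box): CD
    identifies the active set quickly but zigzags on the near-singular
    free subspace when n far exceeds the feature rank, so once the bound
    variables settle, a direct (ridge-stabilised) linear solve plus a box
    line search jumps to the subspace optimum.  CD bursts between solves
    preserve the usual convergence guarantee; the stopping rule is the
    same projected-gradient criterion as :func:`_cd_gram`.
    """
    n = K.shape[0]
    for _outer in range(MAX_OUTER):
        done = _cd_gram(K, y, f, alpha, skip1, skip2, C, tol, CD_BURST)
        if done < CD_BURST:
            return True
        nf = 0
        idx = np.empty(n, dtype=np.int64)
        for i in range(n):
            if i == skip1 or i == skip2:
                continue
            if 0.0 < alpha[i] < C:
                idx[nf] = i
                nf += 1
        if nf == 0:
            continue
        F = idx[:nf]
        Qff = np.empty((nf, nf))
        g = np.empty(nf)
        tr = 0.0
        for a_ in range(nf):
            for b_ in range(nf):
                Qff[a_, b_] = y[F[a_]] * y[F[b_]] * K[F[a_], F[b_]]
            g[a_] = y[F[a_]] * f[F[a_]] - 1.0
            tr += Qff[a_, a_]
        if tr <= 0.0:
            continue
        lam = 1e-10 * tr / nf
        for a_ in range(nf):
            Qff[a_, a_] += lam
        d = np.linalg.solve(Qff, -g)
        gd = 0.0
        for a_ in range(nf):
            gd += g[a_] * d[a_]
        if gd >= 0.0:
            continue
        tmax = 1.0
        for a_ in range(nf):
            i = F[a_]
            if d[a_] > 0.0:
                t = (C - alpha[i]) / d[a_]
            elif d[a_] < 0.0:
                t = -alpha[i] / d[a_]
            else:
                continue
            if t < tmax:
                tmax = t
        if tmax <= 0.0:
            continue
        for a_ in range(nf):
            i = F[a_]
            da = tmax * d[a_]
            if da != 0.0:
                alpha[i] += da
                dd = da * y[i]
                for k in range(n):
                    f[k] += dd * K[i, k]
    return _cd_gram(K, y, f, alpha, skip1, skip2, C, tol, MAX_EPOCHS_WARM) < MAX_EPOCHS_WARM


@njit(cache=True, fastmath=True)
def _solve_gram_active(K, y, f, alpha, skip1, skip2, C, tol):
    """Exact active-set wrapper around :func:`_solve_gram` for warm starts.

    After a warm start only a few coordinates violate the KKT conditions
    or sit strictly inside the box; the dual is solved on that small
    subproblem (the bound, KKT-satisfied coordinates enter only through
    the cached decision values) and the full KKT conditions are re-checked
    afterwards, repeating until no coordinate violates them.  Exactness
    does not depend on the active-set guess — a wrong guess only costs an
    extra pass.
    """
    n = K.shape[0]
    idx = np.empty(n, dtype=np.int64)
    for _pass in range(50):
        na = 0
        max_pg = 0.0
        for i in range(n):
            if i == skip1 or i == skip2:
                continue
            g = y[i] * f[i] - 1.0
            free = 0.0 < alpha[i] < C
            viol = (alpha[i] <= 0.0 and g < 0.0) or (alpha[i] >= C and g > 0.0)
            if free or viol:
                idx[na] = i
                na += 1
            pg = g
            if alpha[i] <= 0.0 and g > 0.0:
                pg = 0.0
            elif alpha[i] >= C and g < 0.0:
                pg = 0.0
            if pg > max_pg:
                max_pg = pg
            elif -pg > max_pg:
                max_pg = -pg
        if max_pg < tol:
            return True
        A = idx[:na]
        Ksub = np.empty((na, na))
        for a_ in range(na):
            for b_ in range(na):
                Ksub[a_, b_] = K[A[a_], A[b_]]
        ysub = np.empty(na)
        fsub = np.empty(na)
        asub = np.empty(na)
        for a_ in range(na):
            ysub[a_] = y[A[a_]]
            fsub[a_] = f[A[a_]]
            asub[a_] = alpha[A[a_]]
        _solve_gram(Ksub, ysub, fsub, asub, -1, -1, C, tol)
        # propagate the subproblem's alpha changes to the full vectors
        for a_ in range(na):
            i = A[a_]
            da = (asub[a_] - alpha[i]) * y[i]
            if da != 0.0:
                alpha[i] = asub[a_]
                for k in range(n):
                    f[k] += da * K[i, k]
    return _solve_gram(K, y, f, alpha, skip1, skip2, C, tol)


@njit(cache=True, fastmath=True)
def _gram(B, cols):
    """K = X Xᵀ + 1 for the feature columns ``cols`` of the beta matrix."""
    n = B.shape[0]
    d = cols.shape[0]
    X = np.empty((n, d))
    for i in range(n):
        for k in range(d):
            X[i, k] = B[i, cols[k]]
    K = X @ X.T
    for i in range(n):
        for j in range(n):
            K[i, j] += 1.0
    return K


@njit(cache=True, fastmath=True)
def pair_loo_correct(B, nb_flat, nb_start, nb_len, y, C, tol):
    """Exhaustive leave-two-out prediction table per searchlight centre.

    For every centre ``c`` with feature columns ``nb_flat[nb_start[c] :
    nb_start[c] + nb_len[c]]`` of the trial × voxel matrix ``B``, and every
    pair ``(i, j)``, fits the SVM on all trials except ``{i, j}`` (one fit
    per unordered pair, warm-started from the full-data dual solution) and
    records whether trial ``j`` is predicted correctly.

    Returns ``correct`` of shape (n_centres, n, n), uint8; the diagonal
    ``correct[c, i, i]`` is the plain leave-one-out entry (model trained
    without ``i`` alone, predicting ``i``).
    """
    ncen = nb_start.shape[0]
    n = B.shape[0]
    correct = np.zeros((ncen, n, n), dtype=np.uint8)
    for c in range(ncen):
        K = _gram(B, nb_flat[nb_start[c] : nb_start[c] + nb_len[c]])
        a_full = np.zeros(n)
        f_full = np.zeros(n)
        _solve_gram(K, y, f_full, a_full, -1, -1, C, tol)
        a = np.empty(n)
        f = np.empty(n)
        for i in range(n):
            for j in range(i, n):
                for k in range(n):
                    a[k] = a_full[k]
                    f[k] = f_full[k]
                if a[i] != 0.0:
                    da = -a[i] * y[i]
                    for k in range(n):
                        f[k] += da * K[i, k]
                    a[i] = 0.0
                if j != i and a[j] != 0.0:
                    da = -a[j] * y[j]
                    for k in range(n):
                        f[k] += da * K[j, k]
                    a[j] = 0.0
                if j == i:
                    _solve_gram_active(K, y, f, a, i, -1, C, tol)
                    pred = 1.0 if f[i] >= 0.0 else -1.0
                    correct[c, i, i] = 1 if pred == y[i] else 0
                else:
                    _solve_gram_active(K, y, f, a, i, j, C, tol)
                    pred_j = 1.0 if f[j] >= 0.0 else -1.0
                    pred_i = 1.0 if f[i] >= 0.0 else -1.0
                    correct[c, i, j] = 1 if pred_j == y[j] else 0
                    correct[c, j, i] = 1 if pred_i == y[i] else 0
    return correct


@njit(cache=True, fastmath=True)
def single_loo_correct(B, nb_flat, nb_start, nb_len, y, C, tol, skip):
    """Leave-one-out prediction table per searchlight centre.

    Returns ``correct`` of shape (n_centres, n): whether trial ``i`` is
    predicted correctly by the model trained on the remaining trials.
    Trial ``skip`` (pass −1 to disable) is excluded from every training
    set and never predicted — used for the inner cross-validation of an
    outer fold, where the held-out trial must not participate at all.
    """
    ncen = nb_start.shape[0]
    n = B.shape[0]
    correct = np.zeros((ncen, n), dtype=np.uint8)
    for c in range(ncen):
        K = _gram(B, nb_flat[nb_start[c] : nb_start[c] + nb_len[c]])
        a_full = np.zeros(n)
        f_full = np.zeros(n)
        _solve_gram(K, y, f_full, a_full, skip, -1, C, tol)
        a = np.empty(n)
        f = np.empty(n)
        for i in range(n):
            if i == skip:
                continue
            for k in range(n):
                a[k] = a_full[k]
                f[k] = f_full[k]
            if a[i] != 0.0:
                da = -a[i] * y[i]
                for k in range(n):
                    f[k] += da * K[i, k]
                a[i] = 0.0
            _solve_gram_active(K, y, f, a, skip, i, C, tol)
            pred = 1.0 if f[i] >= 0.0 else -1.0
            correct[c, i] = 1 if pred == y[i] else 0
    return correct


# ---------------------------------------------------------------------------
# thin object wrapper


class LinearSvm:
    """Linear SVM with the interface fragment the pipeline needs.

    Labels may be any two orderable values; the lexicographically smaller
    class maps to −1.  Decision values ≥ 0 predict the larger class
    (a deterministic tie-break).
    """

    def __init__(self, c: float = DEFAULT_C, tol: float = DEFAULT_TOL):
        if c <= 0:
            raise ValueError("C must be positive")
        if tol <= 0:
            raise ValueError("tol must be positive")
        self.c = float(c)
        self.tol = float(tol)
        self.coef_: np.ndarray | None = None
        self.intercept_: float | None = None
        self.classes_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LinearSvm":
        X = np.ascontiguousarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be 2D (trials × features)")
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y lengths differ")
        self.classes_ = np.unique(y)
        if self.classes_.size > 2:
            raise ValueError(f"binary labels required, got {self.classes_!r}")
        y_signed = np.where(y == self.classes_[0], -1.0, 1.0)
        w, _ = _fit_cold(X, y_signed, self.c, self.tol, MAX_EPOCHS_COLD)
        self.coef_ = w[:-1]
        self.intercept_ = float(w[-1])
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        if self.coef_ is None:
            raise RuntimeError("fit before predicting")
        X = np.asarray(X, dtype=np.float64)
        return X @ self.coef_ + self.intercept_

    def predict(self, X: np.ndarray) -> np.ndarray:
        dec = self.decision_function(X)
        hi = self.classes_[-1]
        lo = self.classes_[0]
        return np.where(dec >= 0.0, hi, lo)
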