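"""Jitted leave-one-out cross-validation kernels for the classifier bank.

The bank members are deliberately hand-rolled, deterministic solvers:

* exact k-nearest-neighbour with Euclidean distance and distance ties broken
  by the smallest training index;
* L2-regularized logistic regression (unpenalized intercept) by damped
  Newton iteration — the objective is strictly convex, so the optimum is
  unique and solver-independent;
* soft-margin hinge-loss linear SVM by dual coordinate descent with the
  bias absorbed as a regularized constant feature (the liblinear
  formulation).

Exhaustive combination screening evaluates millions of tiny fits
(n ≈ 20 samples, d ≤ 3 features), which rules out per-fold estimator
objects; these kernels run one fit in microseconds.  Training-fold
standardization and mean imputation are precomputed outside (see
:mod:`aptascreen.screening`), so each kernel call receives, for every fold,
the full data matrix already standardized with that fold's statistics.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["loocv_bank", "fit_logistic", "fit_linear_svm", "knn_predict"]


@njit(cache=True, fastmath=False)
def _logistic_objective(Xa, y, C, beta, n, da):
    obj = 0.0
    for j in range(da - 1):
        obj += 0.5 * beta[j] * beta[j]
    for i in range(n):
        m = 0.0
        for j in range(da):
            m += Xa[i, j] * beta[j]
        m *= y[i]
        if m < -30.0:
            obj += C * (-m)
        else:
            obj += C * np.log1p(np.exp(-m))
    return obj


@njit(cache=True)
def fit_logistic(X, y, C):
    """L2-penalized logistic regression, intercept unpenalized.

    Minimizes ``0.5 ||w||^2 + C sum_i log(1 + exp(-y_i (w.x_i + b)))`` for
    ``y in {-1, +1}`` by damped Newton with backtracking.  The objective is
    strictly convex, so the optimum is unique.  Returns the (d+1,) vector
    ``[w, b]``.
    """
    n, d = X.shape
    da = d + 1
    Xa = np.empty((n, da))
    Xa[:, :d] = X
    Xa[:, d] = 1.0
    beta = np.zeros(da)
    grad = np.empty(da)
    H = np.empty((da, da))
    cand = np.empty(da)

    obj = _logistic_objective(Xa, y, C, beta, n, da)
    for _ in range(60):
        for j in range(da):
            grad[j] = beta[j] if j < d else 0.0
            for jj in range(da):
                H[j, jj] = 0.0
        for i in range(n):
            m = 0.0
            for j in range(da):
                m += Xa[i, j] * beta[j]
            m *= y[i]
            if m > 30.0:
                s = np.exp(-m)
            elif m < -30.0:
                s = 1.0
            else:
                s = 1.0 / (1.0 + np.exp(m))
            cy = C * s * y[i]
            r = C * s * (1.0 - s)
            for j in range(da):
                grad[j] -= cy * Xa[i, j]
                rj = r * Xa[i, j]
                for jj in range(da):
                    H[j, jj] += rj * Xa[i, jj]
        gmax = 0.0
        for j in range(da):
            if abs(grad[j]) > gmax:
                gmax = abs(grad[j])
        if gmax < 1e-8:
            break
        for j in range(d):
            H[j, j] += 1.0
        for j in range(da):
            H[j, j] += 1e-10
        step = np.linalg.solve(H, grad)
        t = 1.0
        improved = False
        for _ in range(40):
            for j in range(da):
                cand[j] = beta[j] - t * step[j]
            cobj = _logistic_objective(Xa, y, C, cand, n, da)
            if cobj < obj:
                for j in range(da):
                    beta[j] = cand[j]
                obj = cobj
                improved = True
                break
            t *= 0.5
        if not improved:
            break
    return beta


@njit(cache=True)
def fit_linear_svm(X, y, C):
    """Hinge-loss linear SVM by dual coordinate descent.

    Minimizes ``0.5 (||w||^2 + b^2) + C sum_i max(0, 1 - y_i (w.x_i + b))``
    (bias regularized via an augmented constant feature).  Cyclic updates,
    no shuffling: the primal optimum is unique, and a fixed order keeps the
    solver deterministic.  Returns the (d+1,) vector ``[w, b]``.
    """
    n, d = X.shape
    da = d + 1
    Xa = np.empty((n, da))
    Xa[:, :d] = X
    Xa[:, d] = 1.0
    qii = np.empty(n)
    for i in range(n):
        qii[i] = np.dot(Xa[i], Xa[i])
    alpha = np.zeros(n)
    w = np.zeros(da)
    # projected-gradient stop at 1e-6 relative to C: well past sign
    # stability of the decision values (liblinear stops at 1e-4)
    tol = 1e-6 * max(C, 1.0)
    for _ in range(5000):
        max_viol = 0.0
        for i in range(n):
            g = -1.0
            for j in range(da):
                g += w[j] * Xa[i, j] * y[i]
            # projected gradient for the box constraint 0 <= alpha <= C
            if alpha[i] <= 0.0:
                pg = min(g, 0.0)
            elif alpha[i] >= C:
                pg = max(g, 0.0)
            else:
                pg = g
            if abs(pg) > max_viol:
                max_viol = abs(pg)
            if pg != 0.0:
                old = alpha[i]
                new = min(max(old - g / qii[i], 0.0), C)
                if new != old:
                    dy = (new - old) * y[i]
                    for j in range(da):
                        w[j] += dy * Xa[i, j]
                    alpha[i] = new
        if max_viol < tol:
            break
    return w


@njit(cache=True)
def knn_predict(Xtr, ytr, x, k):
    """Majority vote over the k nearest training points (Euclidean).

    Distance ties are broken by the smallest training index: neighbours are
    taken by repeated first-minimum selection, which prefers earlier indices
    at equal distance.  ``ytr`` is in {0, 1}; k is odd so binary votes never
    tie.
    """
    n = Xtr.shape[0]
    d2 = np.empty(n)
    for i in range(n):
        diff = Xtr[i] - x
        d2[i] = np.dot(diff, diff)
    votes = 0
    kk = min(k, n)
    for _ in range(kk):
        best = -1
        bestval = np.inf
        for i in range(n):
            if d2[i] < bestval:  # strict: first index wins ties
                bestval = d2[i]
                best = i
        votes += ytr[best]
        d2[best] = np.inf
    return 1 if 2 * votes > kk else 0


@njit(cache=True)
def loocv_bank(Z, y, knn_ks, svm_cs, lr_cs):
    """LOOCV predictions of every bank member on one feature subset.

    ``Z`` has shape (n, n, d): ``Z[i]`` is the full data matrix standardized
    (and mean-imputed) with fold-i training statistics, so row ``Z[i, i]``
    is the held-out sample as the fold-i model sees it.  ``y`` is the {0, 1}
    class vector.  Classifier order in the output: kNN members, then SVM,
    then logistic, following the input parameter arrays.

    Returns ``(accuracies, predictions)`` with shapes (n_clf,) and
    (n_clf, n).  A training fold containing a single class predicts that
    class for every member.
    """
    n = Z.shape[0]
    d = Z.shape[2]
    n_clf = len(knn_ks) + len(svm_cs) + len(lr_cs)
    preds = np.empty((n_clf, n), dtype=np.int64)
    ys = y.astype(np.float64) * 2.0 - 1.0  # {-1, +1} for margin solvers

    Xtr = np.empty((n - 1, d))
    ytr = np.empty(n - 1, dtype=np.int64)
    ystr = np.empty(n - 1)
    for i in range(n):
        pos = 0
        for s in range(n):
            if s != i:
                Xtr[pos] = Z[i, s]
                ytr[pos] = y[s]
                ystr[pos] = ys[s]
                pos += 1
        x = Z[i, i]
        n1 = int(np.sum(ytr))
        if n1 == 0 or n1 == n - 1:
            # degenerate single-class training fold: majority class
            cls = 1 if n1 > 0 else 0
            for c in range(n_clf):
                preds[c, i] = cls
            continue
        c = 0
        for k in knn_ks:
            preds[c, i] = knn_predict(Xtr, ytr, x, k)
            c += 1
        for C in svm_cs:
            w = fit_linear_svm(Xtr, ystr, C)
            dec = np.dot(w[:d], x) + w[d]
            preds[c, i] = 1 if dec > 0.0 else 0
            c += 1
        for C in lr_cs:
            w = fit_logistic(Xtr, ystr, C)
            dec = np.dot(w[:d], x) + w[d]
            preds[c, i] = 1 if dec > 0.0 else 0
            c += 1

    acc = np.empty(n_clf)
    for c in range(n_clf):
        correct = 0
        for i in range(n):
            if preds[c, i] == y[i]:
                correct += 1
        acc[c] = correct / n
    return acc, preds
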