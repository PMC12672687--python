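"""Compiled cross-validation kernel for the siPLS search.

The exhaustive interval search cross-validates tens of thousands of small
PLS fits; at that size the work is dominated by Python/numpy call overhead,
so the joint-PLS + mean-centring out-of-fold loop is compiled with numba.
The kernel implements exactly the same NIPALS recursion (warm-started at the
dominant singular direction of X'Y, tolerance-checked weight updates,
X-block deflation, sign convention) as :mod:`mvcalib.regression`; agreement
between the two paths is asserted in the test suite.  If numba is
unavailable the caller falls back to the pure-numpy path.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly by the fallback path
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def _nipals_wpq(X, Y, n_lv, tol, max_iter):
    n, p = X.shape
    m = Y.shape[1]
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    Q = np.zeros((m, n_lv))
    Xd = X.copy()
    Yd = Y.copy()
    for a in range(n_lv):
        S = Xd.T @ Yd
        if m == 1:
            w = S[:, 0].copy()
            nw = np.sqrt(np.sum(w * w))
            if nw <= 0.0:
                raise ValueError("PLS component: X residual carries no covariance with Y")
            w = w / nw
        else:
            G = S.T @ S
            if np.sum(np.abs(G)) == 0.0:
                raise ValueError("PLS component: X residual carries no covariance with Y")
            evecs = np.linalg.eigh(G)[1]
            v = evecs[:, m - 1].copy()
            u = Yd @ v
            w = np.zeros(p)
            have_w = False
            converged = False
            for _ in range(max_iter):
                w_new = Xd.T @ u
                nw = np.sqrt(np.sum(w_new * w_new))
                if nw <= 0.0:
                    raise ValueError("PLS component: degenerate weight update")
                w_new = w_new / nw
                if have_w:
                    d = np.sqrt(np.sum((w_new - w) ** 2))
                    if d <= tol:
                        w = w_new
                        converged = True
                        break
                w = w_new
                have_w = True
                t = Xd @ w
                tt = np.sum(t * t)
                q = (Yd.T @ t) / tt
                qq = np.sum(q * q)
                u = (Yd @ q) / qq
            if not converged:
                raise ValueError("PLS component did not converge")
        imax = np.argmax(np.abs(w))
        if w[imax] < 0.0:
            w = -w
        t = Xd @ w
        tt = np.sum(t * t)
        if tt <= 0.0:
            raise ValueError("PLS component: zero-variance score")
        p_load = (Xd.T @ t) / tt
        q_load = (Yd.T @ t) / tt
        Xd -= np.outer(t, p_load)
        Yd -= np.outer(t, q_load)
        W[:, a] = w
        P[:, a] = p_load
        Q[:, a] = q_load
    return W, P, Q


@njit(cache=True)
def pls_oof_mean_center(X, Y, order, fold_bounds, max_lv, tol, max_iter):
    """Out-of-fold joint-PLS predictions with per-fold mean centring.

    ``order`` is a permutation of sample indices and ``fold_bounds[f]`` the
    half-open slice of ``order`` forming fold f's test set.  Returns
    ``(preds, baseline)`` with ``preds`` of shape (max_lv, n, m) in original
    units and ``baseline`` the training-fold-mean (0-LV) prediction.
    """
    n, p = X.shape
    m = Y.shape[1]
    preds = np.empty((max_lv, n, m))
    baseline = np.empty((n, m))
    in_test = np.zeros(n, dtype=np.bool_)
    for f in range(fold_bounds.shape[0]):
        lo, hi = fold_bounds[f, 0], fold_bounds[f, 1]
        test = order[lo:hi]
        for i in test:
            in_test[i] = True
        n_tr = n - (hi - lo)
        train = np.empty(n_tr, dtype=np.int64)
        k = 0
        for i in range(n):
            if not in_test[i]:
                train[k] = i
                k += 1
        for i in test:
            in_test[i] = False
        Xtr = X[train]
        Ytr = Y[train]
        xmean = np.zeros(p)
        ymean = np.zeros(m)
        for i in range(n_tr):
            xmean += Xtr[i]
            ymean += Ytr[i]
        xmean /= n_tr
        ymean /= n_tr
        Xc = Xtr - xmean
        Yc = Ytr - ymean
        W, P, Q = _nipals_wpq(Xc, Yc, max_lv, tol, max_iter)
        Xd = X[test] - xmean
        acc = np.zeros((hi - lo, m))
        for a in range(max_lv):
            t = Xd @ W[:, a]
            acc = acc + np.outer(t, Q[:, a])
            Xd -= np.outer(t, P[:, a])
            for j in range(hi - lo):
                preds[a, test[j]] = acc[j] + ymean
        for j in range(hi - lo):
            baseline[test[j]] = ymean
    return preds, baseline


def folds_to_arrays(folds) -> tuple[np.ndarray, np.ndarray]:
    """Flatten (train, test) folds into the (order, fold_bounds) layout the
    compiled kernel consumes."""
    order = np.concatenate([test for _, test in folds]).astype(np.int64)
    bounds = np.empty((len(folds), 2), dtype=np.int64)
    pos = 0
    for f, (_, test) in enumerate(folds):
        bounds[f, 0] = pos
        pos += test.size
        bounds[f, 1] = pos
    return order, bounds
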