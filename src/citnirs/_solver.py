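"""Low-level SVM solver and cross-validation engine.

Sequential minimal optimization (SMO) on the dual of the L1 soft-margin
SVM with an unregularized bias, specialised for the small dense problems
this package produces (n of order 100, d <= 16).  Working-pair selection
is second order (maximal violating pair refined by the quadratic gain),
which keeps iteration counts low enough that the exhaustive channel-subset
search -- tens of thousands of subsets, each cross-validated on 100 folds
-- runs in minutes on one core.

The engine works entirely in kernel space: per-channel Gram matrices are
precomputed once on the full dataset, a subset's Gram matrix is their sum,
and each fold's training problem is a submatrix view.  Predictions use
kernel rows, so the weight vector is never materialised inside the hot
loop.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# dual feasibility tolerance for the search engine; the public training
# entry point uses a tighter 1e-6 (see svm.train_linear_svm)
ENGINE_TOL = 1e-3
MAX_ITER = 20_000


@njit(cache=True)
def _smo_from(K, y, C, tol, max_iter, alpha, grad):
    """SMO continuation from a dual-feasible (alpha, grad) pair.

    Solves max_a e'a - 0.5 a'Qa, 0 <= a <= C, y'a = 0, Q = yy' * K,
    in place.  Returns (b, n_iter).  b is recovered from the KKT
    conditions on free support vectors (midpoint of the feasible
    interval when none are free).
    """
    n = K.shape[0]
    kdiag = np.empty(n)
    active = np.empty(n, dtype=np.int64)
    for t in range(n):
        kdiag[t] = K[t, t]
        active[t] = t
    n_act = n

    it = 0
    while it < max_iter:
        it += 1
        # i: maximal -y*grad over the "up" set (active variables only)
        gmax = -1e300
        i = -1
        for u in range(n_act):
            t = active[u]
            if (y[t] > 0.0 and alpha[t] < C) or (y[t] < 0.0 and alpha[t] > 0.0):
                v = -y[t] * grad[t]
                if v > gmax:
                    gmax = v
                    i = t
        # j: best second-order gain over the "low" set (division-free
        # comparison); track gmin for the stopping rule
        Ki = K[i if i >= 0 else 0]
        kii = kdiag[i if i >= 0 else 0]
        gmin = 1e300
        j = -1
        bnum = 0.0
        bden = 1.0
        for u in range(n_act):
            t = active[u]
            if (y[t] > 0.0 and alpha[t] > 0.0) or (y[t] < 0.0 and alpha[t] < C):
                v = -y[t] * grad[t]
                if v < gmin:
                    gmin = v
                diff = gmax - v
                if diff > 0.0:
                    a = kii + kdiag[t] - 2.0 * Ki[t]
                    if a < 1e-12:
                        a = 1e-12
                    if diff * diff * bden > bnum * a:
                        bnum = diff * diff
                        bden = a
                        j = t
        if gmax - gmin < tol or j < 0:
            if n_act == n:
                break
            # converged on the shrunk set: verify on the full set
            n_act = n
            for t in range(n):
                active[t] = t
            continue
        if it % 64 == 0 and n_act == n:
            # shrink: drop bound variables that cannot be selected soon
            m = 0
            for t in range(n):
                up = (y[t] > 0.0 and alpha[t] < C) or (y[t] < 0.0 and alpha[t] > 0.0)
                low = (y[t] > 0.0 and alpha[t] > 0.0) or (y[t] < 0.0 and alpha[t] < C)
                v = -y[t] * grad[t]
                keep = True
                if up and not low:
                    keep = v > gmin
                elif low and not up:
                    keep = v < gmax
                if keep:
                    active[m] = t
                    m += 1
            n_act = m

        a = kii + kdiag[j] - 2.0 * Ki[j]
        if a < 1e-12:
            a = 1e-12
        # direction d_i = y_i, d_j = -y_j keeps y'alpha constant
        step = (gmax - (-y[j] * grad[j])) / a
        # box clipping
        if y[i] > 0.0:
            lim = C - alpha[i]
        else:
            lim = alpha[i]
        if step > lim:
            step = lim
        if y[j] > 0.0:
            lim = alpha[j]
        else:
            lim = C - alpha[j]
        if step > lim:
            step = lim

        alpha[i] += y[i] * step
        alpha[j] += -y[j] * step
        Kj = K[j]
        for t in range(n):
            grad[t] += y[t] * step * (Ki[t] - Kj[t])

    # bias from KKT: y_i (f_i + b) = 1 on free SVs, f_i = (K (alpha*y))_i
    nfree = 0
    bsum = 0.0
    ub = 1e300
    lb = -1e300
    for t in range(n):
        v = -y[t] * grad[t]  # equals y_t - f_t
        free = alpha[t] > 0.0 and alpha[t] < C
        if free:
            bsum += v
            nfree += 1
        else:
            up = (y[t] > 0.0 and alpha[t] < C) or (y[t] < 0.0 and alpha[t] > 0.0)
            if up:
                if v > lb:
                    lb = v
            else:
                if v < ub:
                    ub = v
    if nfree > 0:
        b = bsum / nfree
    else:
        if lb <= -1e299:
            lb = ub
        if ub >= 1e299:
            ub = lb
        b = 0.5 * (lb + ub)
    return b, it


@njit(cache=True)
def _smo(K, y, C, tol, max_iter):
    """Cold-start SMO; returns (alpha, b, n_iter)."""
    n = K.shape[0]
    alpha = np.zeros(n)
    grad = np.full(n, -1.0)
    b, it = _smo_from(K, y, C, tol, max_iter, alpha, grad)
    return alpha, b, it


@njit(cache=True)
def _fold_confusion(K, y, alpha, b, tr, te):
    """Confusion counts (TP, FN, FP, TN) on test rows; positive class +1."""
    tp = 0
    fn = 0
    fp = 0
    tn = 0
    for u in range(te.shape[0]):
        r = te[u]
        f = b
        for v in range(tr.shape[0]):
            s = tr[v]
            av = alpha[v]
            if av != 0.0:
                f += av * y[s] * K[r, s]
        pred = 1.0 if f >= 0.0 else -1.0  # exact 0 -> positive class
        if y[r] > 0.0:
            if pred > 0.0:
                tp += 1
            else:
                fn += 1
        else:
            if pred > 0.0:
                fp += 1
            else:
                tn += 1
    return tp, fn, fp, tn


@njit(cache=True)
def _mcc_bacc(tp, fn, fp, tn):
    num = tp * tn - fp * fn
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if den == 0 else num / np.sqrt(den)
    sens = 0.0 if tp + fn == 0 else tp / (tp + fn)
    spec = 0.0 if tn + fp == 0 else tn / (tn + fp)
    return mcc, 0.5 * (sens + spec)


@njit(cache=True)
def _cv_counts(K, y, fold_ids, n_folds, C, tol, max_iter):
    """Confusion counts for every (repeat, fold); fold_ids is (R, n)."""
    R, n = fold_ids.shape
    out = np.zeros((R * n_folds, 4), dtype=np.int64)
    Ktr = np.empty((n, n))
    tr = np.empty(n, dtype=np.int64)
    te = np.empty(n, dtype=np.int64)
    row = 0
    for r in range(R):
        for f in range(n_folds):
            ntr = 0
            nte = 0
            for t in range(n):
                if fold_ids[r, t] == f:
                    te[nte] = t
                    nte += 1
                else:
                    tr[ntr] = t
                    ntr += 1
            for a in range(ntr):
                ia = tr[a]
                for bx in range(ntr):
                    Ktr[a, bx] = K[ia, tr[bx]]
            alpha, b, _ = _smo(Ktr[:ntr, :ntr], y[tr[:ntr]], C, tol, max_iter)
            tp, fn, fp, tn = _fold_confusion(K, y, alpha, b, tr[:ntr], te[:nte])
            out[row, 0] = tp
            out[row, 1] = fn
            out[row, 2] = fp
            out[row, 3] = tn
            row += 1
    return out


@njit(cache=True)
def _search_engine(gram_ch, y, subsets, sizes, fold_ids, n_folds, C, tol, max_iter):
    """Mean fold-level MCC and bACC for every channel subset.

    gram_ch : (n_ch, n, n) per-channel Gram matrices on the full table
    subsets : (S, k_max) channel indices into gram_ch, -1 padded
    fold_ids: (R, n) fold assignment per repeat (shared by all subsets)

    The fold partition is identical for every subset, so each fold's dual
    solution for the previous subset is kept and used as a warm start:
    consecutive subsets in size-then-lexicographic order share most of
    their channels, and the continuation typically needs a handful of
    SMO iterations.
    """
    S = subsets.shape[0]
    R, n = fold_ids.shape
    nf_tot = R * n_folds
    mean_mcc = np.empty(S)
    mean_bacc = np.empty(S)

    # fold memberships are subset-independent: build them once
    tr_all = np.empty((nf_tot, n), dtype=np.int64)
    te_all = np.empty((nf_tot, n), dtype=np.int64)
    ntr_all = np.empty(nf_tot, dtype=np.int64)
    nte_all = np.empty(nf_tot, dtype=np.int64)
    row = 0
    for r in range(R):
        for f in range(n_folds):
            ntr = 0
            nte = 0
            for t in range(n):
                if fold_ids[r, t] == f:
                    te_all[row, nte] = t
                    nte += 1
                else:
                    tr_all[row, ntr] = t
                    ntr += 1
            ntr_all[row] = ntr
            nte_all[row] = nte
            row += 1

    alpha_store = np.zeros((nf_tot, n))
    warm = False
    K = np.zeros_like(gram_ch[0])
    Ktr = np.zeros_like(gram_ch[0])
    alpha = np.empty(n)
    grad = np.empty(n)
    ytr = np.empty(n)
    for s in range(S):
        for a in range(n):
            for bx in range(n):
                K[a, bx] = 0.0
        for q in range(sizes[s]):
            c = subsets[s, q]
            for a in range(n):
                for bx in range(n):
                    K[a, bx] += gram_ch[c, a, bx]
        acc_mcc = 0.0
        acc_bacc = 0.0
        for row in range(nf_tot):
            ntr = ntr_all[row]
            tr = tr_all[row]
            for a in range(ntr):
                ia = tr[a]
                for bx in range(ntr):
                    Ktr[a, bx] = K[ia, tr[bx]]
                ytr[a] = y[ia]
            if warm:
                # continuation: rebuild the gradient for the stored alpha
                for t in range(ntr):
                    alpha[t] = alpha_store[row, t]
                    grad[t] = -1.0
                for si in range(ntr):
                    av = alpha[si]
                    if av != 0.0:
                        coef = av * ytr[si]
                        for t in range(ntr):
                            grad[t] += ytr[t] * coef * Ktr[si, t]
            else:
                for t in range(ntr):
                    alpha[t] = 0.0
                    grad[t] = -1.0
            b, _ = _smo_from(Ktr[:ntr, :ntr], ytr[:ntr], C, tol, max_iter,
                             alpha[:ntr], grad[:ntr])
            for t in range(ntr):
                alpha_store[row, t] = alpha[t]
            tp, fn, fp, tn = _fold_confusion(
                K, y, alpha[:ntr], b, tr[:ntr], te_all[row, :nte_all[row]])
            m, ba = _mcc_bacc(tp, fn, fp, tn)
            acc_mcc += m
            acc_bacc += ba
        warm = True
        mean_mcc[s] = acc_mcc / nf_tot
        mean_bacc[s] = acc_bacc / nf_tot
    return mean_mcc, mean_bacc


def channel_grams(X: np.ndarray) -> np.ndarray:
    """Per-channel Gram matrices, (n_ch, n, n), so K_S = sum over S."""
    n, n_ch = X.shape
    g = np.empty((n_ch, n, n))
    for c in range(n_ch):
        col = X[:, c]
        g[c] = np.outer(col, col)
    return g
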