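"""Batched linear C-SVC for many small decoding problems.

Every decoding step in this package solves thousands of tiny binary
classification problems (typically 8 training pseudo-trials per problem,
one per fold x pair x time point).  Calling a per-problem SVM library has
millisecond-level overhead per fit, which dominates total runtime at that
scale, so the soft-margin C-SVC dual

    min_a  1/2 a'Qa - 1'a   s.t.  0 <= a <= C,  y'a = 0,
    Q_ij = y_i y_j x_i'x_j

is solved here for all problems simultaneously with a vectorized SMO
(maximal-violating-pair working-set selection, exact two-variable updates)
— the same algorithm and stopping rule used by libsvm-style solvers.
Decision values agree with ``sklearn.svm.SVC(kernel="linear")`` to the
solver tolerance; the test suite asserts this agreement problem-by-problem.
"""
from __future__ import annotations

import numpy as np

#: Default cost parameter; the customary library default, kept fixed.
DEFAULT_C = 1.0

_CHUNK = 16384  # problems per solver chunk, bounds peak memory


def _smo_chunk(K: np.ndarray, y: np.ndarray, C: float, tol: float,
               max_iter: int) -> np.ndarray:
    """Solve the C-SVC dual for a chunk of problems sharing label vector y.

    K is (B, n, n) Gram; returns dual coefficients alpha (B, n).
    """
    B, n, _ = K.shape
    yy = y[None, :]
    Q = K * (y[:, None] * y[None, :])[None]
    alpha = np.zeros((B, n))
    grad = -np.ones((B, n))                  # grad = Q @ alpha - 1
    active = np.ones(B, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        a = alpha[idx]
        g = grad[idx]
        m = -yy * g
        up = ((yy > 0) & (a < C - 1e-12)) | ((yy < 0) & (a > 1e-12))
        low = ((yy > 0) & (a > 1e-12)) | ((yy < 0) & (a < C - 1e-12))
        m_up = np.where(up, m, -np.inf)
        m_low = np.where(low, m, np.inf)
        i = m_up.argmax(axis=1)
        j = m_low.argmin(axis=1)
        gap = m_up.max(axis=1) - m_low.min(axis=1)
        conv = gap <= tol
        active[idx[conv]] = False
        keep = ~conv
        if not keep.any():
            continue
        idx, i, j = idx[keep], i[keep], j[keep]
        a, g = alpha[idx], grad[idx]
        Qi = np.take_along_axis(Q[idx], i[:, None, None], axis=2)[:, :, 0]
        Qj = np.take_along_axis(Q[idx], j[:, None, None], axis=2)[:, :, 0]
        yi, yj = y[i], y[j]
        Qii = np.take_along_axis(Qi, i[:, None], axis=1)[:, 0]
        Qjj = np.take_along_axis(Qj, j[:, None], axis=1)[:, 0]
        Qij = np.take_along_axis(Qi, j[:, None], axis=1)[:, 0]
        eta = np.maximum(Qii + Qjj - 2.0 * yi * yj * Qij, 1e-12)
        gi = np.take_along_axis(g, i[:, None], axis=1)[:, 0]
        gj = np.take_along_axis(g, j[:, None], axis=1)[:, 0]
        ai = np.take_along_axis(a, i[:, None], axis=1)[:, 0]
        aj = np.take_along_axis(a, j[:, None], axis=1)[:, 0]
        # feasible step along the (i, j) pair direction
        dmax_i = np.where(yi > 0, C - ai, ai)
        dmax_j = np.where(yj > 0, aj, C - aj)
        delta = np.clip((-yi * gi + yj * gj) / eta, 0.0,
                        np.minimum(dmax_i, dmax_j))
        d_ai = yi * delta
        d_aj = -yj * delta
        np.put_along_axis(a, i[:, None], (ai + d_ai)[:, None], axis=1)
        np.put_along_axis(a, j[:, None], (aj + d_aj)[:, None], axis=1)
        alpha[idx] = a
        grad[idx] = g + Qi * d_ai[:, None] + Qj * d_aj[:, None]
    return alpha


def _intercept(alpha: np.ndarray, K: np.ndarray, y: np.ndarray,
               C: float) -> np.ndarray:
    """KKT-interval midpoint intercept, as in libsvm."""
    coef = alpha * y[None, :]
    f_tr = np.einsum("bij,bj->bi", K, coef)
    tgt = y[None, :] - f_tr
    eps = 1e-8 * C
    at0 = alpha <= eps
    atC = alpha >= C - eps
    free = ~(at0 | atC)
    pos = (y > 0)[None, :]
    lb = np.where((pos & at0) | (~pos & atC) | free, tgt, -np.inf)
    ub = np.where((pos & atC) | (~pos & at0) | free, tgt, np.inf)
    blo = lb.max(axis=1)
    bhi = ub.min(axis=1)
    b = 0.5 * (blo + bhi)
    bad = ~np.isfinite(b)
    if bad.any():
        b[bad] = np.where(np.isfinite(blo[bad]), blo[bad],
                          np.where(np.isfinite(bhi[bad]), bhi[bad], 0.0))
    return b


def batched_linear_svc(Xtr: np.ndarray, y: np.ndarray, Xte: np.ndarray,
                       C: float = DEFAULT_C, tol: float = 1e-4,
                       max_iter: int = 2000) -> np.ndarray:
    """Train one linear C-SVC per problem and return test decision values.

    ``Xtr`` is (B, n_train, d), ``Xte`` (B, n_test, d); ``y`` (n_train,)
    in {-1, +1} is shared by all problems.  Returns (B, n_test) decision
    values; their sign is the predicted label.
    """
    Xtr = np.asarray(Xtr, dtype=float)
    Xte = np.asarray(Xte, dtype=float)
    y = np.asarray(y, dtype=float)
    if Xtr.ndim != 3 or Xte.ndim != 3:
        raise ValueError("expected (B, n, d) training and test arrays")
    if Xtr.shape[2] != Xte.shape[2]:
        raise ValueError("train/test feature dimensionality mismatch")
    if y.shape != (Xtr.shape[1],) or not set(np.unique(y)) <= {-1.0, 1.0}:
        raise ValueError("labels must be a (n_train,) vector of +/-1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in training data")
    B = Xtr.shape[0]
    out = np.empty((B, Xte.shape[1]))
    for s in range(0, B, _CHUNK):
        sl = slice(s, min(s + _CHUNK, B))
        K = Xtr[sl] @ Xtr[sl].transpose(0, 2, 1)
        alpha = _smo_chunk(K, y, C, tol, max_iter)
        b = _intercept(alpha, K, y, C)
        coef = alpha * y[None, :]
        out[sl] = np.einsum("bmd,bnd,bn->bm", Xte[sl], Xtr[sl], coef) \
            + b[:, None]
    return out


def sklearn_linear_svc(Xtr: np.ndarray, y: np.ndarray, Xte: np.ndarray,
                       C: float = DEFAULT_C) -> np.ndarray:
    """Reference engine: per-problem ``sklearn.svm.SVC`` (libsvm) loop.

    Orders of magnitude slower than the batched solver; intended for
    cross-checks and small problems.
    """
    from sklearn.svm import SVC
    Xtr = np.asarray(Xtr, dtype=float)
    Xte = np.asarray(Xte, dtype=float)
    out = np.empty((Xtr.shape[0], Xte.shape[1]))
    for b in range(Xtr.shape[0]):
        clf = SVC(kernel="linear", C=C)
        clf.fit(Xtr[b], y)
        # decision_function is positive for the larger class label (+1)
        out[b] = clf.decision_function(Xte[b])
    return out


ENGINES = {"batched": batched_linear_svc,
           "libsvm": lambda Xtr, y, Xte, C=DEFAULT_C:
               sklearn_linear_svc(Xtr, y, Xte, C)}
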