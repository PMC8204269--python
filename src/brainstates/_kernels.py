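"""Scaled forward-backward and Viterbi recursions.

Pure-numpy reference implementations, JIT-compiled with numba when available.
The forward-backward pass accepts *sub-normalized* transition/initial
parameters in log form (as produced by variational expectations), so the
returned log normalizer is the variational evidence term rather than a true
log-likelihood unless point estimates are passed in.
"""

from __future__ import annotations

import numpy as np


def _forward_backward(loglik, logA, logpi):
    """One segment of scaled forward-backward.

    Parameters
    ----------
    loglik : (T, K) frame log "likelihoods" (may include variational offsets)
    logA   : (K, K) log transition weights (rows need not normalize)
    logpi  : (K,) log initial weights

    Returns
    -------
    gamma : (T, K) posterior state probabilities, rows sum to 1
    xi    : (K, K) summed pairwise transition responsibilities
    logz  : float, log sum over paths of exp(total log weight)
    """
    T, K = loglik.shape
    A = np.exp(logA)
    pi = np.exp(logpi)

    B = np.empty((T, K))
    m = np.empty(T)
    for t in range(T):
        mx = loglik[t, 0]
        for k in range(1, K):
            if loglik[t, k] > mx:
                mx = loglik[t, k]
        m[t] = mx
        for k in range(K):
            B[t, k] = np.exp(loglik[t, k] - mx)

    alpha = np.empty((T, K))
    c = np.empty(T)
    s = 0.0
    for k in range(K):
        alpha[0, k] = pi[k] * B[0, k]
        s += alpha[0, k]
    c[0] = s
    for k in range(K):
        alpha[0, k] /= s
    for t in range(1, T):
        s = 0.0
        for j in range(K):
            a = 0.0
            for i in range(K):
                a += alpha[t - 1, i] * A[i, j]
            a *= B[t, j]
            alpha[t, j] = a
            s += a
        c[t] = s
        for j in range(K):
            alpha[t, j] /= s

    beta = np.ones(K)
    gamma = np.empty((T, K))
    xi = np.zeros((K, K))
    for k in range(K):
        gamma[T - 1, k] = alpha[T - 1, k]
    for t in range(T - 2, -1, -1):
        bb = np.empty(K)
        for j in range(K):
            bb[j] = B[t + 1, j] * beta[j] / c[t + 1]
        for i in range(K):
            acc = 0.0
            for j in range(K):
                w = alpha[t, i] * A[i, j] * bb[j]
                xi[i, j] += w
                acc += A[i, j] * bb[j]
            beta[i] = acc
            gamma[t, i] = alpha[t, i] * acc
        # guard against drift: renormalize gamma row
        s = 0.0
        for i in range(K):
            s += gamma[t, i]
        for i in range(K):
            gamma[t, i] /= s

    logz = 0.0
    for t in range(T):
        logz += np.log(c[t]) + m[t]
    return gamma, xi, logz


def _viterbi(loglik, logA, logpi):
    """Most probable state path; ties broken toward the lower state index."""
    T, K = loglik.shape
    delta = np.empty(K)
    for k in range(K):
        delta[k] = logpi[k] + loglik[0, k]
    psi = np.zeros((T, K), dtype=np.int64)
    for t in range(1, T):
        new = np.empty(K)
        for j in range(K):
            best = delta[0] + logA[0, j]
            arg = 0
            for i in range(1, K):
                v = delta[i] + logA[i, j]
                if v > best:  # strict: first (lowest) index wins ties
                    best = v
                    arg = i
            new[j] = best + loglik[t, j]
            psi[t, j] = arg
        delta = new
    labels = np.empty(T, dtype=np.int64)
    best = delta[0]
    arg = 0
    for k in range(1, K):
        if delta[k] > best:
            best = delta[k]
            arg = k
    labels[T - 1] = arg
    for t in range(T - 2, -1, -1):
        labels[t] = psi[t + 1, labels[t + 1]]
    return labels, best


try:  # pragma: no cover - exercised implicitly when numba is installed
    from numba import njit

    forward_backward = njit(cache=True, fastmath=False)(_forward_backward)
    viterbi_path = njit(cache=True, fastmath=False)(_viterbi)
except ImportError:  # pragma: no cover
    forward_backward = _forward_backward
    viterbi_path = _viterbi
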