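"""Numba-compiled hot loops for the rank-based quality objective.

The optimizer evaluates the quality function tens of thousands of times per
score subset, so the evaluation avoids a full O(N log N) sort of the combined
scores: active scores (few) are sorted, each decoy is located among them by
binary search, and a histogram/suffix-sum gives every active's global rank in
O(D log A + A).  Ties between an active and a decoy are resolved in favour of
the active here (strict comparison); with continuous scores ties have measure
zero, and all *reported* metrics go through the exact, id-tie-broken path in
:mod:`efoscreen.metrics`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["active_ranks", "quality_value", "pattern_search"]


@njit(cache=True)
def active_ranks(s_act: np.ndarray, s_dec: np.ndarray) -> np.ndarray:
    """Global 1-based ranks (descending score) of the active molecules."""
    A = s_act.shape[0]
    D = s_dec.shape[0]
    order = np.argsort(s_act)  # ascending
    sa = s_act[order]
    hist = np.zeros(A + 1, dtype=np.int64)
    for j in range(D):
        # number of actives with score strictly below this decoy
        hist[np.searchsorted(sa, s_dec[j])] += 1
    ranks = np.empty(A, dtype=np.int64)
    above = 0
    for i in range(A - 1, -1, -1):
        above += hist[i + 1]
        # actives above position i: those at ascending positions > i
        ranks[order[i]] = above + (A - 1 - i) + 1
    return ranks


@njit(cache=True)
def quality_value(s_act: np.ndarray, s_dec: np.ndarray, cluster_size: int):
    """Return (actives_in_cluster, mean_active_rank, Q)."""
    ranks = active_ranks(s_act, s_dec)
    A = s_act.shape[0]
    N = A + s_dec.shape[0]
    a_c = 0
    total = 0
    for i in range(A):
        if ranks[i] <= cluster_size:
            a_c += 1
        total += ranks[i]
    mean_rank = total / A
    q = a_c + (1.0 - mean_rank / N)
    return a_c, mean_rank, q


@njit(cache=True)
def _q_of(Za: np.ndarray, Zd: np.ndarray, w: np.ndarray, cluster_size: int) -> float:
    """Fused combine + rank + quality; avoids temporaries in the hot loop."""
    A = Za.shape[0]
    D = Zd.shape[0]
    k = w.shape[0]
    s_act = np.empty(A)
    for i in range(A):
        acc = 0.0
        for j in range(k):
            acc += Za[i, j] * w[j]
        s_act[i] = acc
    sa = np.sort(s_act)
    hist = np.zeros(A + 1, dtype=np.int64)
    for i in range(D):
        acc = 0.0
        for j in range(k):
            acc += Zd[i, j] * w[j]
        # binary search: number of actives with score strictly below acc
        lo = 0
        hi = A
        while lo < hi:
            mid = (lo + hi) >> 1
            if sa[mid] < acc:
                lo = mid + 1
            else:
                hi = mid
        hist[lo] += 1
    n = A + D
    a_c = 0
    total = 0
    above = 0
    for i in range(A - 1, -1, -1):
        above += hist[i + 1]
        rank = above + (A - 1 - i) + 1
        if rank <= cluster_size:
            a_c += 1
        total += rank
    return a_c + (1.0 - (total / A) / n)


@njit(cache=True)
def pattern_search(
    Za: np.ndarray,
    Zd: np.ndarray,
    cluster_size: int,
    w0: np.ndarray,
    sigma0: float,
    max_iter: int,
    rms_tol: float,
    halve_after: int,
    seed: int,
):
    """Accept-if-better Gaussian pattern search on the unit sphere.

    Proposals are w + sigma * g with g ~ N(0, I), renormalized to unit length.
    sigma is halved after ``halve_after`` consecutive rejections; the search
    stops when sigma * sqrt(k) < rms_tol or after ``max_iter`` iterations.
    Returns (w_best, q_best, iterations_used).
    """
    np.random.seed(seed)
    k = w0.shape[0]
    w = w0 / np.sqrt(np.sum(w0 * w0))
    q = _q_of(Za, Zd, w, cluster_size)
    sigma = sigma0
    sqrt_k = np.sqrt(k)
    rejections = 0
    it = 0
    wp = np.empty(k)
    while it < max_iter and sigma * sqrt_k >= rms_tol:
        it += 1
        for i in range(k):
            wp[i] = w[i] + sigma * np.random.normal(0.0, 1.0)
        nrm = np.sqrt(np.sum(wp * wp))
        if nrm > 0.0:
            cand = wp / nrm
            qc = _q_of(Za, Zd, cand, cluster_size)
        else:
            cand = w
            qc = q - 1.0  # degenerate proposal counts as a rejection
        if qc > q:
            w = cand.copy()
            q = qc
            rejections = 0
        else:
            rejections += 1
            if rejections >= halve_after:
                sigma *= 0.5
                rejections = 0
    return w, q, it
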