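"""Independent element-wise loop implementations used as oracles.

These deliberately mirror the written definitions one index at a time and
stay independent of the vectorised production code they check.
"""

from __future__ import annotations

import math

import numpy as np


def gip_loop(a: np.ndarray, raw_bandwidth: float, axis: str) -> np.ndarray:
    """Gaussian interaction-profile kernel by explicit loops.

    axis='disease': profiles are columns of A; axis='mirna': rows.
    """
    profiles = a.T if axis == "disease" else a
    n = profiles.shape[0]
    mean_sq = sum(
        sum(float(x) ** 2 for x in profiles[i]) for i in range(n)
    ) / n
    r = raw_bandwidth / mean_sq
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            sq_dist = sum(
                (float(profiles[i, l]) - float(profiles[j, l])) ** 2
                for l in range(profiles.shape[1])
            )
            out[i, j] = math.exp(-r * sq_dist)
    return out


def hybrid_loop(a: np.ndarray, lam: float) -> np.ndarray:
    """Hybrid spread operator by explicit loops (lam=0 HeatS, lam=1 ProbS)."""
    n_m, n_d = a.shape
    km = [int(a[i].sum()) for i in range(n_m)]
    kd = [int(a[:, l].sum()) for l in range(n_d)]
    w = np.zeros((n_m, n_m))
    for i in range(n_m):
        for j in range(n_m):
            if km[i] == 0 or km[j] == 0:
                continue
            s = sum(
                float(a[i, l]) * float(a[j, l]) / kd[l]
                for l in range(n_d)
                if kd[l] > 0
            )
            w[i, j] = s / (km[i] ** (1.0 - lam) * km[j] ** lam)
    return w


def heats_loop(a: np.ndarray) -> np.ndarray:
    return hybrid_loop(a, 0.0)


def probs_loop(a: np.ndarray) -> np.ndarray:
    return hybrid_loop(a, 1.0)


def restart_loop(a: np.ndarray, lam: float) -> np.ndarray:
    """P_A by per-disease resource spreading: for each disease, the initial
    resource vector is its indicator column of A, redistributed by W."""
    w = hybrid_loop(a, lam)
    n_m, n_d = a.shape
    p = np.zeros((n_m, n_d))
    for j in range(n_d):
        f = [float(a[i, j]) for i in range(n_m)]
        for i in range(n_m):
            p[i, j] = sum(w[i, k] * f[k] for k in range(n_m))
    return p


def walk_loop(
    p0: np.ndarray, m: np.ndarray, d: np.ndarray, alpha: float, r: int, l: int
) -> np.ndarray:
    """Unbalanced bi-random walk by explicit triple loops."""
    n_m, n_d = p0.shape
    p = p0.copy()
    for t in range(1, max(r, l) + 1):
        p_m = np.zeros_like(p)
        for i in range(n_m):
            for j in range(n_d):
                acc = sum(m[i, k] * p[k, j] for k in range(n_m))
                p_m[i, j] = (1.0 - alpha) * acc + alpha * p0[i, j]
        p_d = np.zeros_like(p)
        for i in range(n_m):
            for j in range(n_d):
                acc = sum(p[i, k] * d[k, j] for k in range(n_d))
                p_d[i, j] = (1.0 - alpha) * acc + alpha * p0[i, j]
        if t <= r and t <= l:
            p = (p_m + p_d) / 2.0
        elif t <= r:
            p = p_m
        else:
            p = p_d
    return p


def auc_bruteforce(positive_ranks: list[int], n_candidates: int) -> float:
    """AUC by enumerating every (positive, negative) rank pair."""
    pos = set(positive_ranks)
    neg = [r for r in range(1, n_candidates + 1) if r not in pos]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p < q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
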