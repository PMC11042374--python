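"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check: the dip
oracle solves the minimax fit over unimodal CDFs directly as a linear
program per candidate modal knot, and the HMM oracle enumerates every
diploid ancestry path with its own transition algebra.
"""
from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog
from scipy.stats import binom


# ---------------------------------------------------------------------------
# dip: direct minimax fit over unimodal CDFs


def _ecdf_corners(x: np.ndarray):
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    v, counts = np.unique(x, return_counts=True)
    hi = np.cumsum(counts) / n
    lo = hi - counts / n
    return v, lo, hi


def lp_dip(x) -> float:
    """Minimal sup-distance between the ECDF and any unimodal CDF.

    For each candidate modal knot r, minimize t over piecewise-linear
    nondecreasing G with values g_j in the ECDF corner bands, convex
    through the left limit at v_r, an upward jump allowed at the mode,
    and concave afterwards; r = k adds the fully convex fit (mode above
    all data).
    """
    v, lo, hi = _ecdf_corners(x)
    k = len(v)
    best = np.inf
    nv = k + 2
    iell, it = k, k + 1
    for r in range(k + 1):
        rows, rhs = [], []

        def le(coefs, b):
            row = np.zeros(nv)
            for idx, c in coefs:
                row[idx] += c
            rows.append(row)
            rhs.append(b)

        for j in range(k):
            le([(j, -1.0), (it, -1.0)], -hi[j])  # g_j >= hi_j - t
            if j != r or r == k:
                le([(j, 1.0), (it, -1.0)], lo[j])  # g_j <= lo_j + t
        seq = list(range(min(r, k)))
        if r < k:
            seq += [iell, r]
        seq += list(range(r + 1, k))
        for a, b in zip(seq[:-1], seq[1:]):
            le([(a, 1.0), (b, -1.0)], 0.0)
        if r < k:
            le([(iell, 1.0), (it, -1.0)], lo[r])  # left limit under the band
        cvx = [(v[j], j) for j in range(min(r, k))]
        if r < k:
            cvx.append((v[r], iell))
        for (xa, a), (xb, b), (xc, c) in zip(cvx[:-2], cvx[1:-1], cvx[2:]):
            le([(a, -(xc - xb)), (b, (xc - xb) + (xb - xa)), (c, -(xb - xa))], 0.0)
        ccv = [(v[j], j) for j in range(r, k)]
        for (xa, a), (xb, b), (xc, c) in zip(ccv[:-2], ccv[1:-1], ccv[2:]):
            le([(a, (xc - xb)), (b, -((xc - xb) + (xb - xa))), (c, (xb - xa))], 0.0)
        obj = np.zeros(nv)
        obj[it] = 1.0
        res = linprog(
            obj,
            A_ub=np.array(rows),
            b_ub=np.array(rhs),
            bounds=[(0.0, 1.0)] * k + [(0.0, 1.0), (0.0, 1.0)],
            method="highs",
        )
        if res.status == 0:
            best = min(best, res.fun)
    return float(best)


# ---------------------------------------------------------------------------
# HMM: brute-force path enumeration


def enumerate_posteriors(
    reads_b: np.ndarray,
    reads_c: np.ndarray,
    distances: np.ndarray,
    generations: float,
    p: float,
    error_rate: float,
) -> np.ndarray:
    """Exact diploid ancestry posteriors by summing over all 3^L paths.

    Transitions follow two independent haploid chains that keep their
    ancestry with probability exp(-T d) and otherwise redraw from the
    stationary (1-p, p); emissions are Binomial(depth, q_state) in the
    cortezi read count.
    """
    L = len(reads_b)
    qs = np.array([error_rate, 0.5, 1.0 - error_rate])
    depth = reads_b + reads_c

    def hap(e):
        return np.array(
            [[e + (1 - e) * (1 - p), (1 - e) * p],
             [(1 - e) * (1 - p), e + (1 - e) * p]]
        )

    def dip3(e):
        # two labelled haploid copies; collapse ordered pairs to dosage
        m = hap(e)
        out = np.zeros((3, 3))
        pairs = {0: [(0, 0)], 1: [(0, 1), (1, 0)], 2: [(1, 1)]}
        for dose_from, from_pairs in pairs.items():
            for a, b in from_pairs:
                for a2 in (0, 1):
                    for b2 in (0, 1):
                        out[dose_from, a2 + b2] += (
                            m[a, a2] * m[b, b2] / len(from_pairs)
                        )
        return out

    pi = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    trans = [dip3(np.exp(-generations * d) if np.isfinite(d) else 0.0) for d in distances]
    emis = np.array([[binom.pmf(reads_c[s], depth[s], q) for q in qs] for s in range(L)])

    joint = np.zeros((L, 3))
    total = 0.0
    for path in itertools.product((0, 1, 2), repeat=L):
        w = pi[path[0]] * emis[0, path[0]]
        for s in range(1, L):
            w *= trans[s][path[s - 1], path[s]] * emis[s, path[s]]
        total += w
        for s in range(L):
            joint[s, path[s]] += w
    return joint / total
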