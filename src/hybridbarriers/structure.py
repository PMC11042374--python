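"""Bimodality of genome-wide ancestry and cluster assignment.

Hartigan's dip statistic — the sup-norm distance between the empirical CDF
and the closest unimodal CDF (convex then concave, an atom allowed at the
mode) — is implemented here from scratch, with a uniform-bootstrap
p-value.  Individuals are then assigned to the two ancestry clusters by
exact 1-D two-means, and individuals far from both clusters are flagged
as intermediates (candidate recent cross-cluster offspring).

Dip algorithm
-------------
Collapse the sample to unique knots v_1 < ... < v_k with lower/upper ECDF
corner heights lo_j (mass below v_j) and hi_j (mass through v_j).  A
unimodal CDF G within sup-distance t of the ECDF exists iff for some
modal knot r one can draw a nondecreasing convex function through the
bands [hi_j - t, lo_j + t] at knots j < r (its limit at v_r staying below
lo_r + t), jump at the mode, and continue with a nondecreasing concave
function through the bands at knots j > r that starts above hi_r - t.
The largest convex function under upper corners is the greatest convex
minorant (GCM); band feasibility on a prefix therefore reduces to
2t >= max_j (hi_j - GCM(lo)_j), and symmetrically on suffixes with the
least concave majorant.  The dip is half the minimum over modal knots of
the larger of the two one-sided deviations, computed in one incremental
hull sweep per direction.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import rng_from

__all__ = [
    "DipResult",
    "ClusterAssignment",
    "dip_statistic",
    "dip_test",
    "assign_clusters",
    "TwoClusterAssigner",
]


# ---------------------------------------------------------------------------
# dip statistic


def _collapse(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique sorted knots with lower/upper ECDF corner heights."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    v, counts = np.unique(x, return_counts=True)
    hi = np.cumsum(counts) / n
    lo = hi - counts / n
    return v, lo, hi


def _prefix_deviations(v: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    """Max deviation of upper corners above the prefix GCM of lower corners.

    Returns (dev_incl, dev_excl): for each prefix 1..q (0-based index q),
    the maximum of hi_j - GCM(lo | prefix)_j over j <= q (incl) and over
    j < q (excl).  The hull is maintained incrementally; when a new point
    re-chords a hull segment, only deviations under the new chord need
    rescanning, and deviations over the untouched head of the hull equal
    dev_incl at the hull anchor.
    """
    k = len(v)
    dev_incl = np.empty(k)
    dev_excl = np.empty(k)
    dev_excl[0] = 0.0
    dev_incl[0] = hi[0] - lo[0]
    stack = [0]
    for q in range(1, k):
        while len(stack) >= 2:
            i, j = stack[-2], stack[-1]
            # pop j when it lies on/above the chord i -> q
            if (v[j] - v[i]) * (lo[q] - lo[i]) <= (v[q] - v[i]) * (lo[j] - lo[i]):
                stack.pop()
            else:
                break
        h = stack[-1]
        if q - h > 1:
            xs = v[h + 1 : q]
            chord = lo[h] + (lo[q] - lo[h]) * (xs - v[h]) / (v[q] - v[h])
            span = float(np.max(hi[h + 1 : q] - chord))
        else:
            span = 0.0
        dev_excl[q] = max(dev_incl[h], span)
        dev_incl[q] = max(dev_excl[q], hi[q] - lo[q])
        stack.append(q)
    return dev_incl, dev_excl


from functools import lru_cache


@lru_cache(maxsize=8)
def _masks(k: int) -> tuple[np.ndarray, np.ndarray]:
    """(mask for j >= i, mask for i >= r): entries to disable, cached."""
    tri = np.tril(np.ones((k, k), dtype=bool), -1)
    return ~tri, np.tril(np.ones((k, k), dtype=bool), 0)


def _min_convex_endpoint(v: np.ndarray, lo: np.ndarray, hi: np.ndarray, t: float) -> np.ndarray:
    """Minimal attainable value at each knot r of a nondecreasing convex
    function through the bands [hi_j - t, lo_j + t] at knots j < r.

    By LP duality the minimum is attained by a two-point support chain:
    descend from an upper corner U_j, touch a lower corner A_i, and
    extrapolate straight to v_r, i.e. max_i [A_i + sigma_i (v_r - v_i)]
    with sigma_i the steepest mandatory slope at A_i.  Bands are clipped
    to [0,1] (the fit is part of a CDF).
    """
    k = len(v)
    a = np.maximum(hi - t, 0.0)
    u = np.minimum(lo + t, 1.0)
    not_j_lt_i, not_i_lt_r = _masks(k)
    dv = v[:, None] - v[None, :]  # (i, j)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        slopes = (a[:, None] - u[None, :]) / dv
        slopes[not_j_lt_i] = -np.inf
        sigma = np.maximum(slopes.max(axis=1, initial=0.0), 0.0)
        lines = a[:, None] - sigma[:, None] * dv  # value of line i at knot r
        lines[not_i_lt_r] = -np.inf
    return np.maximum(lines.max(axis=0, initial=0.0), 0.0)


class _DipProblem:
    """Band deviations and feasibility machinery shared by the dip
    statistic and its bootstrap threshold test."""

    def __init__(self, x: np.ndarray):
        v, lo, hi = _collapse(x)
        self.v, self.lo, self.hi = v, lo, hi
        self.k = len(v)
        if self.k == 1:
            self.band = np.zeros(1)
            return
        _, left_excl = _prefix_deviations(v, lo, hi)
        _, m_excl = _prefix_deviations(-v[::-1], 1.0 - hi[::-1], 1.0 - lo[::-1])
        right_excl = m_excl[::-1]  # max_{j>r} (LCM(hi | r..k)_j - lo_j)
        self.band = np.maximum(left_excl, right_excl)

    def _junction_ok(self, t: float) -> np.ndarray:
        """Per modal knot r: can the convex branch end at or below where
        the concave branch can start (the jump at the mode only goes up)?"""
        v, lo, hi = self.v, self.lo, self.hi
        lmin = _min_convex_endpoint(v, lo, hi, t)
        gmax_m = _min_convex_endpoint(-v[::-1], 1.0 - hi[::-1], 1.0 - lo[::-1], t)
        gmax = (1.0 - gmax_m)[::-1]
        return lmin <= gmax + 1e-12

    def feasible(self, t: float) -> bool:
        """Is there a unimodal CDF within sup-distance t of the ECDF?"""
        if self.k == 1:
            return True
        ok = self.band <= 2.0 * t + 1e-12
        return bool((ok & self._junction_ok(t)).any())

    def solve(self) -> float:
        if self.k == 1:
            return 0.0  # point mass: an atom at the mode fits exactly
        t0 = 0.5 * float(self.band.min())
        if self.feasible(t0):
            return t0
        # the two branches cannot meet monotonically at t0: bisect on t
        t_lo, t_hi = t0, 0.25 + 1.0 / self.k
        for _ in range(50):
            t = 0.5 * (t_lo + t_hi)
            if self.feasible(t):
                t_hi = t
            else:
                t_lo = t
        return t_hi


def _validate_sample(values) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 4:
        raise ValueError("need at least 4 values")
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")
    return x


def dip_statistic(values) -> float:
    """Hartigan's dip statistic of a sample (sup-distance to unimodality).

    The empirical CDF is compared against every unimodal CDF — convex up
    to a mode, concave after, an atom allowed at the mode; modal knots
    are enumerated and each candidate checked for band feasibility (via
    prefix GCM / suffix LCM deviations) and for a monotone junction of
    the two branches.  Requires at least 4 finite values.  The statistic
    lies in [1/(2n), 1/4] for samples with distinct values and is
    invariant to monotone affine transforms of the data.
    """
    return _DipProblem(_validate_sample(values)).solve()


@dataclass(frozen=True)
class DipResult:
    """Dip statistic with its uniform-bootstrap p-value."""

    statistic: float
    pvalue: float
    n: int
    n_boot: int


def dip_test(values, n_boot: int = 1000, seed: int | np.random.Generator | None = None) -> DipResult:
    """Dip test of unimodality with a Uniform(0,1) bootstrap null.

    The p-value is the add-one-corrected fraction of uniform samples of
    the same size whose dip reaches the observed one — the Hartigan &
    Hartigan null, which makes the test conservative for lighter-tailed
    unimodal alternatives.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    x = _validate_sample(values)
    d = dip_statistic(x)
    rng = rng_from(seed)
    n = len(x)
    # a bootstrap dip reaches d iff no unimodal CDF sits within d of the
    # bootstrap ECDF — one feasibility evaluation, no bisection needed
    thresh = d * (1.0 - 1e-9)
    exceed = sum(
        not _DipProblem(rng.random(n)).feasible(thresh) for _ in range(n_boot)
    )
    return DipResult(d, (exceed + 1) / (n_boot + 1), n, n_boot)


# ---------------------------------------------------------------------------
# cluster assignment


@dataclass
class ClusterAssignment:
    """Two-cluster labels with intermediates flagged.

    ``labels`` holds 1 (lower-ancestry cluster), 2 (higher cluster) or 0
    for intermediates; summaries exclude intermediates.
    """

    labels: np.ndarray
    means: tuple[float, float]
    sds: tuple[float, float]
    weights: tuple[float, float]
    intermediate_indices: np.ndarray

    def to_dict(self) -> dict:
        return {
            "means": list(self.means),
            "sds": list(self.sds),
            "weights": list(self.weights),
            "n_intermediate": int(len(self.intermediate_indices)),
            "intermediate_indices": self.intermediate_indices.tolist(),
        }


def _two_means_1d(x: np.ndarray) -> np.ndarray:
    """Exact 1-D two-means: best split of the sorted sample by within-SS."""
    order = np.argsort(x)
    xs = x[order]
    n = len(xs)
    csum = np.cumsum(xs)
    csq = np.cumsum(xs**2)
    best_ss, best_m = np.inf, 1
    for m in range(1, n):  # first m points in cluster 1
        s1, q1 = csum[m - 1], csq[m - 1]
        s2, q2 = csum[-1] - s1, csq[-1] - q1
        ss = (q1 - s1**2 / m) + (q2 - s2**2 / (n - m))
        if ss < best_ss - 1e-15:
            best_ss, best_m = ss, m
    labels = np.ones(n, dtype=int)
    labels[best_m:] = 2
    out = np.empty(n, dtype=int)
    out[order] = labels
    return out


def assign_clusters(proportions, intermediate_margin: float = 0.05) -> ClusterAssignment:
    """Assign individuals to the two ancestry clusters, flag intermediates.

    Two-means on the 1-D proportions; an individual is *intermediate*
    when its distance to each cluster mean exceeds
    max(``intermediate_margin``, 5 x that cluster's SD).  Cluster
    summaries are recomputed excluding intermediates.  Raises when the
    sample does not split into two separated clusters.
    """
    x = np.asarray(proportions, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 individuals")
    if np.ptp(x) < 1e-12:
        raise ValueError("degenerate input: all proportions equal")
    labels = _two_means_1d(x)
    m1, m2 = x[labels == 1].mean(), x[labels == 2].mean()
    if m2 - m1 < intermediate_margin:
        raise ValueError(
            "clusters are not separated; sample looks single-cluster "
            f"(means {m1:.3f}, {m2:.3f})"
        )
    for _ in range(2):  # flag intermediates, then refresh summaries once
        s1 = x[labels == 1].std(ddof=1) if (labels == 1).sum() > 1 else 0.0
        s2 = x[labels == 2].std(ddof=1) if (labels == 2).sum() > 1 else 0.0
        far1 = np.abs(x - m1) > max(intermediate_margin, 5.0 * s1)
        far2 = np.abs(x - m2) > max(intermediate_margin, 5.0 * s2)
        inter = far1 & far2
        labels = np.where(inter, 0, np.where(np.abs(x - m1) <= np.abs(x - m2), 1, 2))
        if not (labels == 1).any() or not (labels == 2).any():
            raise ValueError("a cluster emptied after intermediate flagging")
        m1, m2 = x[labels == 1].mean(), x[labels == 2].mean()
    core = labels != 0
    w1 = (labels == 1).sum() / core.sum()
    return ClusterAssignment(
        labels=labels,
        means=(float(m1), float(m2)),
        sds=(float(s1), float(s2)),
        weights=(float(w1), float(1 - w1)),
        intermediate_indices=np.flatnonzero(labels == 0),
    )


class TwoClusterAssigner:
    """sklearn-style clusterer for 1-D ancestry proportions.

    After ``fit``: ``labels_`` (1/2, 0 = intermediate), ``means_``,
    ``sds_``, ``weights_``, ``intermediate_indices_``.
    """

    def __init__(self, intermediate_margin: float = 0.05):
        self.intermediate_margin = intermediate_margin

    def get_params(self, deep: bool = True) -> dict:
        return {"intermediate_margin": self.intermediate_margin}

    def set_params(self, **params) -> "TwoClusterAssigner":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "TwoClusterAssigner":
        X = np.asarray(X, dtype=float).ravel()
        res = assign_clusters(X, self.intermediate_margin)
        self.assignment_ = res
        self.labels_ = res.labels
        self.means_ = res.means
        self.sds_ = res.sds
        self.weights_ = res.weights
        self.intermediate_indices_ = res.intermediate_indices
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_
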