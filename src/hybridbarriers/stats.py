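"""Small bespoke statistics for the worked hybrid-cross examples.

Chi-squared goodness of fit on genotype counts, the minimum-likelihood
two-sided exact binomial test (sex ratios), the strength-of-preference
score from dichotomous mate-choice trials, and an exact tie-aware
Wilcoxon signed-rank test.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GofResult",
    "PreferenceTrial",
    "chi_square_gof",
    "exact_binomial_two_sided",
    "strength_of_preference",
    "wilcoxon_signed_rank_exact",
]


@dataclass(frozen=True)
class GofResult:
    statistic: float
    df: int
    pvalue: float


def chi_square_gof(observed, expected_probs) -> GofResult:
    """Chi-squared goodness of fit of counts against category probabilities.

    At df = 2 (three categories, e.g. the 1:2:1 F2 genotype test) the
    upper-tail P equals exp(-chi2/2) exactly.
    """
    obs = np.asarray(observed, dtype=float)
    p = np.asarray(expected_probs, dtype=float)
    if obs.shape != p.shape or obs.ndim != 1 or len(obs) < 2:
        raise ValueError("observed and expected must be 1-D and equal length")
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("expected probabilities must sum to 1")
    if (p < 0).any() or (obs < 0).any():
        raise ValueError("negative counts or probabilities")
    n = obs.sum()
    if n < 1:
        raise ValueError("need at least one observation")
    if ((p == 0) & (obs > 0)).any():
        raise ValueError("nonzero count in a zero-probability category")
    keep = p > 0
    exp = n * p[keep]
    chi2 = float(((obs[keep] - exp) ** 2 / exp).sum())
    df = int(keep.sum() - 1)
    return GofResult(chi2, df, float(sps.chi2.sf(chi2, df)))


def exact_binomial_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Minimum-likelihood two-sided exact binomial P.

    Sums Binomial(n, p0) probabilities of all outcomes whose point
    probability does not exceed that of k; at p0 = 0.5 this coincides
    with doubling the smaller tail.
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be in (0,1)")
    return float(sps.binomtest(int(k), int(n), p0, alternative="two-sided").pvalue)


@dataclass(frozen=True)
class PreferenceTrial:
    """One dichotomous preference trial.

    ``sop`` = (t_cortezi - t_birchmanni) / (t_cortezi + t_birchmanni),
    in [-1, +1]; positive values indicate preference for the cortezi cue.
    ``side_bias`` flags trials where one side got over 80% of the time
    (excluded from analysis as positional bias).
    """

    t_cortezi: float
    t_birchmanni: float
    sop: float
    side_bias: bool


def strength_of_preference(
    t_cortezi: float, t_birchmanni: float, side_bias_fraction: float = 0.8
) -> PreferenceTrial:
    """Strength-of-preference score of one trial."""
    if t_cortezi < 0 or t_birchmanni < 0:
        raise ValueError("association times must be non-negative")
    total = t_cortezi + t_birchmanni
    if total <= 0:
        raise ValueError("zero total association time")
    sop = (t_cortezi - t_birchmanni) / total
    bias = max(t_cortezi, t_birchmanni) / total > side_bias_fraction
    return PreferenceTrial(t_cortezi, t_birchmanni, float(sop), bool(bias))


def _signed_rank_distribution(ranks2: np.ndarray) -> np.ndarray:
    """Exact distribution of the positive-rank sum over sign flips.

    ``ranks2`` are doubled midranks (integers); returns the pmf of the
    doubled statistic by dynamic programming over all 2^n sign vectors.
    """
    total = int(ranks2.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    return pmf


def wilcoxon_signed_rank_exact(values, mu0: float = 0.0, exact_max_n: int = 25) -> float:
    """Two-sided Wilcoxon signed-rank test against a location ``mu0``.

    Zeros are removed, ties get midranks.  For n <= ``exact_max_n`` the
    exact permutation distribution of the rank sum (2^n sign flips,
    computed by convolution) is used; beyond that, the normal
    approximation with tie correction.
    """
    d = np.asarray(values, dtype=float) - mu0
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        raise ValueError("all values equal mu0")
    ranks = sps.rankdata(np.abs(d))  # midranks for ties
    w_pos = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        ranks2 = np.round(2 * ranks).astype(int)
        pmf = _signed_rank_distribution(ranks2)
        w2 = int(round(2 * w_pos))
        lower = pmf[: w2 + 1].sum()
        upper = pmf[w2:].sum()
        return float(min(1.0, 2.0 * min(lower, upper)))
    mean = n * (n + 1) / 4.0
    tie_term = sum(
        (c**3 - c) for c in np.unique(ranks, return_counts=True)[1]
    )
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0
    z = (w_pos - mean) / np.sqrt(var)
    return float(2.0 * sps.norm.sf(abs(z)))
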