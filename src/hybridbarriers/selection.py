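"""Rejection-ABC inference of selection against *X. birchmanni* ancestry.

At an incompatibility locus the F2 genotype frequencies at fertilization
are Mendelian (1/4, 1/2, 1/4 for CC, BC, BB where C = cortezi and
B = birchmanni ancestry).  Viability selection against birchmanni ancestry
with selection coefficient s and dominance h assigns fitnesses 1, 1-h*s
and 1-s to CC, BC and BB; surviving-adult frequencies are the fitness-
weighted Mendelian frequencies renormalized by the mean fitness

    W = 1/4 + (1/2)(1 - h s) + (1/4)(1 - s).

``SelectionABC`` draws (s, h) from the Uniform(0,1)^2 prior, simulates
genotype counts for N individuals under each draw, and accepts draws whose
summary statistics — the mean birchmanni ancestry at the site and the
numbers of heterozygous and homozygous-birchmanni individuals — fall
within the tolerance of the observed data.  Accepted draws approximate the
posterior; MAP estimates come from a boundary-reflected Gaussian KDE.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._rng import rng_from

__all__ = [
    "SelectionParams",
    "GenotypeCounts",
    "ABCPosterior",
    "hw_post_selection_freqs",
    "simulate_f2_genotypes",
    "abc_infer",
    "SelectionABC",
]


@dataclass(frozen=True)
class SelectionParams:
    """Selection coefficient and dominance against birchmanni ancestry.

    Fitness of the homozygous-birchmanni genotype is 1-s; of the
    heterozygote, 1-h*s.
    """

    s: float
    h: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.s <= 1.0 and 0.0 <= self.h <= 1.0):
            raise ValueError("s and h must lie in [0,1]")


@dataclass(frozen=True)
class GenotypeCounts:
    """Counts of CC / BC / BB individuals at one locus (C = cortezi)."""

    n_cc: int
    n_bc: int
    n_bb: int

    def __post_init__(self) -> None:
        for v in (self.n_cc, self.n_bc, self.n_bb):
            if int(v) != v or v < 0:
                raise ValueError("genotype counts must be non-negative integers")

    @property
    def total(self) -> int:
        return self.n_cc + self.n_bc + self.n_bb

    def mean_birchmanni_ancestry(self) -> float:
        """Mean birchmanni allele dosage at the locus, in [0,1]."""
        return (2 * self.n_bb + self.n_bc) / (2 * self.total)


@dataclass
class ABCPosterior:
    """Accepted draws and posterior summaries of a rejection-ABC run."""

    s_accepted: np.ndarray
    h_accepted: np.ndarray
    s_map: float
    h_map: float
    s_ci: tuple[float, float]
    h_ci: tuple[float, float]
    acceptance_rate: float
    n_draws: int

    def to_dict(self) -> dict:
        return {
            "s_map": self.s_map,
            "h_map": self.h_map,
            "s_ci": list(self.s_ci),
            "h_ci": list(self.h_ci),
            "acceptance_rate": self.acceptance_rate,
            "n_accepted": int(len(self.s_accepted)),
            "n_draws": self.n_draws,
            "caveat": (
                "single-locus viability model; if selection acts only in "
                "combination with another nuclear locus, s is underestimated"
            ),
        }


def hw_post_selection_freqs(params: SelectionParams) -> tuple[float, float, float]:
    """Adult F2 genotype frequencies (f_CC, f_BC, f_BB) after selection."""
    w_bc = 1.0 - params.h * params.s
    w_bb = 1.0 - params.s
    mean_w = 0.25 + 0.5 * w_bc + 0.25 * w_bb
    assert mean_w > 0.0  # CC fitness is 1, so W >= 0.25 always
    return (0.25 / mean_w, 0.5 * w_bc / mean_w, 0.25 * w_bb / mean_w)


def simulate_f2_genotypes(
    params: SelectionParams, n: int, seed: int | np.random.Generator | None = None
) -> GenotypeCounts:
    """Multinomial draw of N adult genotypes from the post-selection frequencies."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = rng_from(seed)
    cc, bc, bb = rng.multinomial(n, hw_post_selection_freqs(params))
    return GenotypeCounts(int(cc), int(bc), int(bb))


def _reflected_kde_density(x: np.ndarray, grid_points: int = 1000):
    """Gaussian KDE with reflection at the [0,1] boundaries, on a grid.

    Reflection prevents the spurious interior modes a plain KDE shows when
    posterior mass piles against a boundary.  Bandwidth is Silverman's rule.
    Returns (grid, density).
    """
    x = np.asarray(x, dtype=float)
    grid = np.linspace(0.0, 1.0, grid_points)
    if len(x) < 2 or np.ptp(x) < 1e-12:
        dens = np.zeros(grid_points)
        dens[np.argmin(np.abs(grid - np.clip(np.mean(x), 0, 1)))] = 1.0
        return grid, dens
    augmented = np.concatenate([x, -x, 2.0 - x])
    sd = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    sigma = min(sd, iqr / 1.349) if iqr > 0 else sd
    bw = max(0.9 * sigma * len(x) ** (-0.2), 1e-3)
    kde = stats.gaussian_kde(augmented, bw_method=bw / augmented.std(ddof=1))
    return grid, kde(grid)


def _map_and_hpd(x: np.ndarray, mass: float = 0.95) -> tuple[float, tuple[float, float]]:
    """MAP and highest-posterior-density interval from the reflected KDE.

    The HPD interval is the smallest density super-level set holding the
    requested mass (reported as its bounding interval); unlike an
    equal-tailed percentile interval it contains the mode by construction
    and reaches a boundary when posterior mass piles against it.
    """
    grid, dens = _reflected_kde_density(x)
    m = float(grid[np.argmax(dens)])
    order = np.argsort(dens)[::-1]
    cum = np.cumsum(dens[order]) / dens.sum()
    keep = order[: int(np.searchsorted(cum, mass)) + 1]
    return m, (float(grid[keep].min()), float(grid[keep].max()))


def abc_infer(
    observed: GenotypeCounts,
    n_draws: int = 200_000,
    tolerance: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> ABCPosterior:
    """Rejection ABC for (s, h) from observed adult genotype counts.

    A draw is accepted when each count statistic (heterozygotes,
    homozygous birchmanni) matches the observation within
    ``tolerance * N`` individuals and the mean birchmanni ancestry matches
    within ``tolerance`` (absolute); all three must pass jointly.
    """
    if observed.total < 1:
        raise ValueError("observed counts must include at least one individual")
    if not 0.0 < tolerance < 1.0:
        raise ValueError("tolerance must be in (0,1)")
    if n_draws < 10:
        raise ValueError("n_draws too small")
    rng = rng_from(seed)
    n = observed.total

    s = rng.uniform(0.0, 1.0, n_draws)
    h = rng.uniform(0.0, 1.0, n_draws)
    w_bc = 1.0 - h * s
    w_bb = 1.0 - s
    mean_w = 0.25 + 0.5 * w_bc + 0.25 * w_bb
    f_cc = 0.25 / mean_w
    f_bc = 0.5 * w_bc / mean_w
    # sequential binomial thinning == multinomial draw
    n_cc = rng.binomial(n, f_cc)
    rest = n - n_cc
    p_bc = np.divide(f_bc, 1.0 - f_cc, out=np.zeros_like(f_bc), where=(1.0 - f_cc) > 0)
    n_bc = rng.binomial(rest, np.clip(p_bc, 0.0, 1.0))
    n_bb = rest - n_bc

    mean_anc = (2.0 * n_bb + n_bc) / (2.0 * n)
    ok = (
        (np.abs(n_bc - observed.n_bc) <= tolerance * n)
        & (np.abs(n_bb - observed.n_bb) <= tolerance * n)
        & (np.abs(mean_anc - observed.mean_birchmanni_ancestry()) <= tolerance)
    )
    if not ok.any():
        raise RuntimeError(
            "no accepted ABC draws; increase n_draws or the tolerance"
        )
    s_acc, h_acc = s[ok], h[ok]
    s_map, s_ci = _map_and_hpd(s_acc)
    h_map, h_ci = _map_and_hpd(h_acc)
    return ABCPosterior(
        s_accepted=s_acc,
        h_accepted=h_acc,
        s_map=s_map,
        h_map=h_map,
        s_ci=s_ci,
        h_ci=h_ci,
        acceptance_rate=float(ok.mean()),
        n_draws=n_draws,
    )


class SelectionABC:
    """sklearn-style estimator wrapper around :func:`abc_infer`.

    Parameters
    ----------
    n_draws : int
        Prior draws from Uniform(0,1)^2.
    tolerance : float
        Joint acceptance tolerance: fraction of N for count statistics,
        absolute for the mean-ancestry statistic.
    random_state : int or None
        Seed for the prior draws and genotype simulations.

    Attributes (after ``fit``)
    --------------------------
    s_map_, h_map_ : float
        Marginal MAP estimates.
    s_ci_, h_ci_ : tuple
        95% highest-posterior-density credible intervals.
    posterior_ : ABCPosterior
    """

    def __init__(self, n_draws: int = 200_000, tolerance: float = 0.05,
                 random_state: int | None = None):
        self.n_draws = n_draws
        self.tolerance = tolerance
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_draws": self.n_draws,
            "tolerance": self.tolerance,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "SelectionABC":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, observed: GenotypeCounts) -> "SelectionABC":
        if not isinstance(observed, GenotypeCounts):
            observed = GenotypeCounts(*observed)
        post = abc_infer(
            observed,
            n_draws=self.n_draws,
            tolerance=self.tolerance,
            seed=self.random_state,
        )
        self.posterior_ = post
        self.s_map_ = post.s_map
        self.h_map_ = post.h_map
        self.s_ci_ = post.s_ci
        self.h_ci_ = post.h_ci
        self.acceptance_rate_ = post.acceptance_rate
        return self
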