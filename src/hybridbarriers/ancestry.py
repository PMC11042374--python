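"""Local ancestry inference from low-coverage AIM read counts.

Low-coverage (~1x) sequencing rarely samples both alleles of a
heterozygous site, but admixture linkage disequilibrium makes ancestry
states correlated along a hybrid chromosome: ancestry switches only at
recombination events accumulated since admixture.  A hidden Markov model
over the three diploid ancestry states (0/1/2 copies of *X. cortezi*
ancestry) therefore recovers local ancestry accurately from sparse counts.

Model
-----
Transitions come from two independent haploid ancestry chains.  Between
consecutive sites at genetic distance d Morgans, each haploid copy retains
its ancestry with probability exp(-T d) (T = generations since admixture)
and otherwise redraws it from the stationary distribution (p cortezi,
1-p birchmanni); the diploid 3-state transition matrix is the induced
two-copy product.  Emissions are Binomial(depth, q) in the cortezi-read
count with q = eps, 1/2, 1-eps for 0, 1, 2 cortezi copies (eps = per-read
error rate).  The forward-backward recursion runs in log space; sites with
zero depth contribute flat emissions.

Posterior triples are converted to hard calls when one state exceeds the
posterior threshold (0.9 by default), else missing — mirroring standard
practice for downstream tabulation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .panel import AIMPanel
from .simulate import ReadCountMatrix

__all__ = [
    "HMMConfig",
    "AncestryPosteriorMatrix",
    "AncestryCalls",
    "AncestryHMM",
    "infer_posteriors",
    "hard_call",
    "ancestry_proportions",
]

MISSING = -1


@dataclass(frozen=True)
class HMMConfig:
    """HMM priors: T (generations since admixture; 50 for natural
    populations, 2 for F2s), stationary cortezi frequency ``admixture_prior``,
    per-read error rate and the hard-call posterior threshold."""

    generations: float = 50.0
    admixture_prior: float = 0.5
    error_rate: float = 0.001
    threshold: float = 0.9

    def __post_init__(self) -> None:
        if self.generations <= 0:
            raise ValueError("generations must be positive")
        if not 0.0 < self.admixture_prior < 1.0:
            raise ValueError("admixture_prior must be in (0,1)")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if not (1.0 / 3.0) < self.threshold <= 1.0:
            raise ValueError("threshold must be in (1/3, 1]")


@dataclass
class AncestryPosteriorMatrix:
    """Posterior P(0/1/2 cortezi copies) per individual x site.

    ``probs`` has shape (n_individuals, n_sites, 3); every triple sums
    to 1.  ``log_likelihood`` holds the per-individual total data
    log-likelihood from the forward pass.
    """

    probs: np.ndarray
    panel: AIMPanel
    log_likelihood: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 3 or p.shape[2] != 3 or p.shape[1] != self.panel.n_sites:
            raise ValueError("probs must have shape (n, n_sites, 3)")
        if not np.allclose(p.sum(axis=2), 1.0, atol=1e-9):
            raise ValueError("posterior triples must sum to 1")
        self.probs = p

    @property
    def n_individuals(self) -> int:
        return self.probs.shape[0]


@dataclass
class AncestryCalls:
    """Hard-called diploid ancestry states (0/1/2, -1 = missing)."""

    states: np.ndarray
    panel: AIMPanel

    def __post_init__(self) -> None:
        s = np.asarray(self.states)
        if s.ndim != 2 or s.shape[1] != self.panel.n_sites:
            raise ValueError("states must be (n, n_sites)")
        if not np.isin(s, (MISSING, 0, 1, 2)).all():
            raise ValueError("states must be 0/1/2 or -1")
        self.states = s.astype(np.int8)

    @property
    def n_individuals(self) -> int:
        return self.states.shape[0]

    def called(self) -> np.ndarray:
        return self.states != MISSING

    def proportions(self) -> np.ndarray:
        """Genome-wide cortezi proportion per individual over called sites.

        NaN when an individual has no called site.
        """
        called = self.called()
        n_called = called.sum(axis=1)
        dose = np.where(called, self.states, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, dose / (2.0 * n_called), np.nan)

    def heterozygosity(self) -> np.ndarray:
        called = self.called()
        n_called = called.sum(axis=1)
        het = (self.states == 1).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, het / n_called, np.nan)

    def to_frame(self) -> pd.DataFrame:
        n, s = self.states.shape
        state = self.states.astype(object).ravel()
        state[state == MISSING] = "NA"
        return pd.DataFrame(
            {
                "individual": np.repeat(np.arange(n), s),
                "chrom": np.tile(self.panel.chrom, n),
                "pos_bp": np.tile(self.panel.pos_bp, n),
                "state": state,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, panel: AIMPanel) -> "AncestryCalls":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=["NA"])
        inds = np.unique(df["individual"].to_numpy())
        out = np.full((len(inds), panel.n_sites), MISSING, dtype=np.int8)
        site_index = {
            (str(ch), int(p)): i
            for i, (ch, p) in enumerate(zip(panel.chrom, panel.pos_bp))
        }
        ind_index = {v: i for i, v in enumerate(inds)}
        for ind, ch, p, st in zip(df["individual"], df["chrom"], df["pos_bp"], df["state"]):
            if pd.isna(st):
                continue
            out[ind_index[ind], site_index[(str(ch), int(p))]] = int(st)
        return cls(out, panel)


# ---------------------------------------------------------------------------
# model internals


def _haploid_transition(e: float, p: float) -> np.ndarray:
    """2x2 haploid matrix, rows from / cols to (birchmanni, cortezi)."""
    u = 1.0 - e
    return np.array([[e + u * (1.0 - p), u * p], [u * (1.0 - p), e + u * p]])


def diploid_transitions(distances: np.ndarray, generations: float, p: float) -> np.ndarray:
    """3x3 diploid transition matrix per inter-site gap.

    ``distances[s]`` is the genetic gap before site s (inf at chromosome
    starts, collapsing the transition to the stationary distribution).
    Entry [s, i, j]: P(state j at s | state i at s-1).
    """
    with np.errstate(over="ignore"):
        e = np.exp(-generations * np.asarray(distances, dtype=float))
    e = np.where(np.isfinite(distances), e, 0.0)
    out = np.empty((len(e), 3, 3))
    for s, es in enumerate(e):
        m = _haploid_transition(es, p)
        out[s, 0] = [m[0, 0] ** 2, 2 * m[0, 0] * m[0, 1], m[0, 1] ** 2]
        out[s, 1] = [
            m[1, 0] * m[0, 0],
            m[1, 1] * m[0, 0] + m[1, 0] * m[0, 1],
            m[1, 1] * m[0, 1],
        ]
        out[s, 2] = [m[1, 0] ** 2, 2 * m[1, 1] * m[1, 0], m[1, 1] ** 2]
    return out


def stationary_prior(p: float) -> np.ndarray:
    return np.array([(1.0 - p) ** 2, 2.0 * p * (1.0 - p), p * p])


def _log_emissions(counts: ReadCountMatrix, error_rate: float) -> np.ndarray:
    """log Binomial(depth, q) pmf of the cortezi read count, per state.

    Shape (n, n_sites, 3).  Zero-depth sites emit log 1 = 0 for all states.
    """
    c = counts.reads_cortezi
    d = counts.depth()
    qs = np.array([error_rate, 0.5, 1.0 - error_rate])
    log_choose = gammaln(d + 1) - gammaln(c + 1) - gammaln(d - c + 1)
    out = np.empty(c.shape + (3,))
    with np.errstate(divide="ignore", invalid="ignore"):
        for k, q in enumerate(qs):
            if q == 0.0 or q == 1.0:
                # degenerate emission: all reads must match
                match = c == (d if q == 1.0 else 0)
                out[:, :, k] = np.where(match, 0.0, -np.inf)
            else:
                out[:, :, k] = log_choose + c * np.log(q) + (d - c) * np.log1p(-q)
    return out


def _forward_backward(
    log_emis: np.ndarray, log_trans: np.ndarray, log_pi: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Log-space forward-backward, vectorized over individuals.

    Returns (posteriors (n,S,3), loglik_forward (n,), loglik_backward (n,)).
    """
    n, n_sites, _ = log_emis.shape
    alpha = np.empty((n, n_sites, 3))
    alpha[:, 0] = log_pi + log_emis[:, 0]
    for s in range(1, n_sites):
        alpha[:, s] = log_emis[:, s] + logsumexp(
            alpha[:, s - 1, :, None] + log_trans[s][None], axis=1
        )
    beta = np.empty_like(alpha)
    beta[:, -1] = 0.0
    for s in range(n_sites - 2, -1, -1):
        beta[:, s] = logsumexp(
            log_trans[s + 1][None] + (log_emis[:, s + 1] + beta[:, s + 1])[:, None, :],
            axis=2,
        )
    loglik_f = logsumexp(alpha[:, -1], axis=1)
    loglik_b = logsumexp(log_pi + log_emis[:, 0] + beta[:, 0], axis=1)
    log_post = alpha + beta - loglik_f[:, None, None]
    return np.exp(log_post), loglik_f, loglik_b


# ---------------------------------------------------------------------------
# operations


def infer_posteriors(
    counts: ReadCountMatrix, config: HMMConfig | None = None
) -> AncestryPosteriorMatrix:
    """Forward-backward posteriors of diploid ancestry at every site."""
    config = config or HMMConfig()
    panel = counts.panel
    d = panel.site_distances()
    with np.errstate(divide="ignore"):
        log_trans = np.log(diploid_transitions(d, config.generations, config.admixture_prior))
        log_pi = np.log(stationary_prior(config.admixture_prior))
    log_emis = _log_emissions(counts, config.error_rate)
    probs, ll_f, ll_b = _forward_backward(log_emis, log_trans, log_pi)
    if not np.allclose(ll_f, ll_b, rtol=1e-6):
        raise AssertionError("forward and backward likelihoods disagree")
    # renormalize away residual float error
    probs /= probs.sum(axis=2, keepdims=True)
    return AncestryPosteriorMatrix(probs, panel, ll_f)


def hard_call(posteriors: AncestryPosteriorMatrix, threshold: float = 0.9) -> AncestryCalls:
    """Convert posteriors to hard calls: a state is called iff its
    posterior strictly exceeds ``threshold``, else the site is missing."""
    if not (1.0 / 3.0) < threshold <= 1.0:
        raise ValueError("threshold must be in (1/3, 1]")
    best = posteriors.probs.argmax(axis=2)
    best_p = posteriors.probs.max(axis=2)
    states = np.where(best_p > threshold, best, MISSING).astype(np.int8)
    return AncestryCalls(states, posteriors.panel)


def ancestry_proportions(calls: AncestryCalls) -> pd.DataFrame:
    """Per-individual genome-wide cortezi proportion over called sites."""
    if calls.n_individuals == 0:
        raise ValueError("empty call matrix")
    props = calls.proportions()
    n_called = calls.called().sum(axis=1)
    return pd.DataFrame(
        {
            "individual": np.arange(calls.n_individuals),
            "proportion": props,
            "n_called": n_called,
            "no_calls": n_called == 0,
        }
    )


class AncestryHMM:
    """sklearn-style estimator for local ancestry inference.

    ``predict_proba`` returns posterior state probabilities,
    ``predict`` hard calls, ``transform`` genome-wide proportions.

    Parameters mirror :class:`HMMConfig`; ``estimate_prior=True`` replaces
    the shared stationary frequency with each individual's raw
    cortezi-read fraction (a light empirical pre-pass).
    """

    def __init__(
        self,
        generations: float = 50.0,
        admixture_prior: float = 0.5,
        error_rate: float = 0.001,
        threshold: float = 0.9,
        estimate_prior: bool = False,
    ):
        self.generations = generations
        self.admixture_prior = admixture_prior
        self.error_rate = error_rate
        self.threshold = threshold
        self.estimate_prior = estimate_prior

    def get_params(self, deep: bool = True) -> dict:
        return {
            "generations": self.generations,
            "admixture_prior": self.admixture_prior,
            "error_rate": self.error_rate,
            "threshold": self.threshold,
            "estimate_prior": self.estimate_prior,
        }

    def set_params(self, **params) -> "AncestryHMM":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _config(self, prior: float | None = None) -> HMMConfig:
        return HMMConfig(
            generations=self.generations,
            admixture_prior=self.admixture_prior if prior is None else prior,
            error_rate=self.error_rate,
            threshold=self.threshold,
        )

    def fit(self, counts: ReadCountMatrix, y=None) -> "AncestryHMM":
        self._config()  # validate parameters
        if self.estimate_prior:
            total = counts.depth().sum(axis=1)
            cortezi = counts.reads_cortezi.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                frac = np.where(total > 0, cortezi / np.maximum(total, 1), 0.5)
            self.individual_priors_ = np.clip(frac, 0.01, 0.99)
        else:
            self.individual_priors_ = None
        self.n_individuals_ = counts.n_individuals
        return self

    def predict_proba(self, counts: ReadCountMatrix) -> AncestryPosteriorMatrix:
        if not hasattr(self, "n_individuals_"):
            self.fit(counts)
        if self.individual_priors_ is None:
            return infer_posteriors(counts, self._config())
        blocks, lls = [], []
        for i, p in enumerate(self.individual_priors_):
            sub = ReadCountMatrix(
                counts.reads_birchmanni[i : i + 1],
                counts.reads_cortezi[i : i + 1],
                counts.panel,
            )
            post = infer_posteriors(sub, self._config(prior=float(p)))
            blocks.append(post.probs)
            lls.append(post.log_likelihood)
        return AncestryPosteriorMatrix(
            np.concatenate(blocks), counts.panel, np.concatenate(lls)
        )

    def predict(self, counts: ReadCountMatrix) -> AncestryCalls:
        return hard_call(self.predict_proba(counts), self.threshold)

    def transform(self, counts: ReadCountMatrix) -> pd.DataFrame:
        return ancestry_proportions(self.predict(counts))
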