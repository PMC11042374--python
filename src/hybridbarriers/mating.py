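"""Assortative-mating inference from mother/embryo ancestry pairs.

Live-bearing swordtails carry broods sired by a single recent mating, so
the genome-wide ancestry of a mother and her embryos reveals the
(unsampled) father's ancestry cluster: an embryo's expected proportion is
the midparent value, so cross-cluster matings shift embryos roughly half
the between-cluster distance away from the mother while within-cluster
matings leave them near her.  This module classifies matings from those
differences, fits the assortment strength a (probability that a mating is
within-cluster) by matched simulation, computes the power to detect rare
cross-cluster mating, and classifies ancestry-intermediate adults into
recent cross-cluster pedigree classes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import rng_from
from .simulate import (
    MotherEmbryoSet,
    PopulationSpec,
    default_blocks,
    segregation_sd,
    simulate_mother_embryo,
)

__all__ = [
    "mother_embryo_differences",
    "classify_matings",
    "fit_assortment",
    "AssortmentModel",
    "detection_power",
    "classify_intermediate",
    "PedigreeClassification",
]

PEDIGREE_CLASSES = ("cluster-1", "cluster-2", "cross-F1", "cross-BC1", "cross-BC2")


def mother_embryo_differences(pairs: MotherEmbryoSet) -> pd.DataFrame:
    """Signed and absolute embryo-minus-mother ancestry differences."""
    rows = []
    for i, brood in enumerate(pairs.embryo_props):
        for e in brood:
            d = e - pairs.mother_props[i]
            rows.append((i, int(pairs.mother_cluster[i]), pairs.mother_props[i], e, d, abs(d)))
    return pd.DataFrame(
        rows,
        columns=["mother", "mother_cluster", "mother_prop", "embryo_prop", "diff", "abs_diff"],
    )


def _difference_threshold(
    population: PopulationSpec,
    n_sim: int,
    rng: np.random.Generator,
    blocks: float | None = None,
    max_overlap: float = 0.05,
) -> float:
    """Midpoint between simulated within- and cross-cluster |difference|
    distributions; raises if they overlap too much to separate."""
    within = mother_embryo_differences(
        simulate_mother_embryo(population, 1.0, n_mothers=n_sim, embryos_per_mother=1,
                               seed=rng, blocks=blocks)
    )["abs_diff"].to_numpy()
    cross = mother_embryo_differences(
        simulate_mother_embryo(population, 0.0, n_mothers=n_sim, embryos_per_mother=1,
                               seed=rng, blocks=blocks)
    )["abs_diff"].to_numpy()
    thr = 0.5 * (within.mean() + cross.mean())
    overlap = max((within > thr).mean(), (cross < thr).mean())
    if overlap > max_overlap:
        raise ValueError(
            f"within- and cross-cluster difference distributions overlap "
            f"({overlap:.1%} misclassified at the midpoint); threshold undefined"
        )
    return float(thr)


def classify_matings(
    pairs: MotherEmbryoSet,
    population: PopulationSpec,
    n_sim: int = 2000,
    seed: int | np.random.Generator | None = None,
    blocks: float | None = None,
) -> pd.DataFrame:
    """Label each embryo within- or cross-cluster by its |difference|.

    The decision threshold is the midpoint between the simulated
    within-cluster and cross-cluster |embryo - mother| distributions for
    the given population.
    """
    rng = rng_from(seed)
    out = mother_embryo_differences(pairs)
    if len(out) == 0:
        out["cross_cluster"] = np.array([], dtype=bool)
        return out
    thr = _difference_threshold(population, n_sim, rng, blocks=blocks)
    out["cross_cluster"] = out["abs_diff"] > thr
    out.attrs["threshold"] = thr
    return out


def _simulate_cross_counts(
    pairs: MotherEmbryoSet,
    population: PopulationSpec,
    a: float,
    n_sim: int,
    threshold: float,
    rng: np.random.Generator,
    blocks: float | None = None,
) -> np.ndarray:
    """Cross-cluster call counts in simulated datasets matched to the
    observed mothers and brood sizes."""
    b = default_blocks() if blocks is None else float(blocks)
    m_prop = pairs.mother_props
    m_cluster = pairs.mother_cluster
    brood = np.array([len(e) for e in pairs.embryo_props])
    counts = np.zeros(n_sim, dtype=int)
    for s in range(n_sim):
        same = rng.random(len(m_prop)) < a
        f_cluster = np.where(same, m_cluster, 3 - m_cluster)
        f_prop = population.draw_proportion(f_cluster, rng)
        sd = segregation_sd(m_prop, f_prop, b)
        mid = 0.5 * (m_prop + f_prop)
        n_cross = 0
        for i in range(len(m_prop)):
            e = np.clip(mid[i] + sd[i] * rng.standard_normal(brood[i]), 0, 1)
            n_cross += int((np.abs(e - m_prop[i]) > threshold).sum())
        counts[s] = n_cross
    return counts


def fit_assortment(
    pairs: MotherEmbryoSet,
    population: PopulationSpec,
    a_grid=None,
    n_sim: int = 500,
    seed: int | np.random.Generator | None = None,
    blocks: float | None = None,
) -> dict:
    """Fit the assortment strength a on a grid by matched simulation.

    For each candidate a, ``n_sim`` replicate datasets matched in mothers
    and brood sizes are simulated; the fit score is the two-sided
    consistency of the observed cross-cluster call count under model a,
    min(P(count <= observed), P(count >= observed)) — for an observed
    count of zero this is simply the probability of reproducing zero
    cross-cluster calls.  The best a maximizes the score, ties broken
    toward larger a (the most assortative model consistent with the
    data).
    """
    rng = rng_from(seed)
    if a_grid is None:
        a_grid = np.round(np.linspace(0.0, 1.0, 11), 3)
    a_grid = np.asarray(a_grid, dtype=float)
    if a_grid.min() < 0 or a_grid.max() > 1:
        raise ValueError("a-grid must lie in [0,1]")
    thr = _difference_threshold(population, max(n_sim, 1000), rng, blocks=blocks)
    diffs = mother_embryo_differences(pairs)
    observed = int((diffs["abs_diff"] > thr).sum())
    scores = np.empty(len(a_grid))
    for idx, a in enumerate(a_grid):
        counts = _simulate_cross_counts(pairs, population, a, n_sim, thr, rng, blocks)
        scores[idx] = min((counts <= observed).mean(), (counts >= observed).mean())
    # ties toward larger a
    best = len(scores) - 1 - int(np.argmax(scores[::-1]))
    return {
        "a": float(a_grid[best]),
        "a_grid": a_grid,
        "scores": scores,
        "observed_cross_calls": observed,
        "threshold": thr,
    }


class AssortmentModel:
    """sklearn-style estimator for the assortment strength.

    After ``fit(pairs)``: ``a_`` (best-fitting assortment strength),
    ``fit_curve_`` (DataFrame of score per candidate a),
    ``observed_cross_calls_``, ``threshold_``.
    """

    def __init__(
        self,
        population: PopulationSpec | None = None,
        a_grid=None,
        n_sim: int = 500,
        random_state: int | None = None,
    ):
        self.population = population
        self.a_grid = a_grid
        self.n_sim = n_sim
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "population": self.population,
            "a_grid": self.a_grid,
            "n_sim": self.n_sim,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "AssortmentModel":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, pairs: MotherEmbryoSet, y=None) -> "AssortmentModel":
        pop = self.population or PopulationSpec()
        res = fit_assortment(
            pairs, pop, a_grid=self.a_grid, n_sim=self.n_sim, seed=self.random_state
        )
        self.a_ = res["a"]
        self.fit_curve_ = pd.DataFrame({"a": res["a_grid"], "score": res["scores"]})
        self.observed_cross_calls_ = res["observed_cross_calls"]
        self.threshold_ = res["threshold"]
        return self


def detection_power(
    rate: float,
    n_mothers: int,
    seed: int | np.random.Generator | None = None,
    n_sim: int = 0,
) -> float:
    """Probability that at least one sampled mother mated cross-cluster.

    Closed form 1 - (1-r)^n; with ``n_sim`` > 0 a Monte-Carlo estimate is
    returned instead (used as a cross-check).
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0,1]")
    if n_mothers < 0:
        raise ValueError("n_mothers must be non-negative")
    if n_sim:
        rng = rng_from(seed)
        hits = rng.random((n_sim, n_mothers)) < rate
        return float(hits.any(axis=1).mean())
    return 1.0 - (1.0 - rate) ** n_mothers


# ---------------------------------------------------------------------------
# pedigree classification of ancestry-intermediate adults


@dataclass
class PedigreeClassification:
    """Best-fitting recent-pedigree class for a candidate individual."""

    best_class: str | None
    log_densities: dict
    unclassified: bool


def _class_samples(
    cls: str, population: PopulationSpec, n_sim: int, rng: np.random.Generator, blocks: float
) -> np.ndarray:
    """Joint (proportion, heterozygosity) draws for one pedigree class.

    Heterozygosity between two parental genomes with cortezi proportions
    p and q is modelled as p(1-q) + q(1-p) (one cortezi and one
    birchmanni allele meet), with finite-genome noise across ~``blocks``
    independently segregating units.
    """
    ones = np.ones(n_sim, dtype=int)
    if cls == "cluster-1" or cls == "cluster-2":
        c = 1 if cls == "cluster-1" else 2
        p = population.draw_proportion(c * ones, rng)
        prop = p
        het_mean = 2.0 * p * (1.0 - p)
    elif cls == "cross-F1":
        p1 = population.draw_proportion(1 * ones, rng)
        p2 = population.draw_proportion(2 * ones, rng)
        prop = 0.5 * (p1 + p2) + segregation_sd(p1, p2, blocks) * rng.standard_normal(n_sim)
        het_mean = p1 * (1.0 - p2) + p2 * (1.0 - p1)
    elif cls in ("cross-BC1", "cross-BC2"):
        p1 = population.draw_proportion(1 * ones, rng)
        p2 = population.draw_proportion(2 * ones, rng)
        f1 = 0.5 * (p1 + p2)
        c = 1 if cls == "cross-BC1" else 2
        p3 = population.draw_proportion(c * ones, rng)
        prop = 0.5 * (f1 + p3) + segregation_sd(f1, p3, blocks) * rng.standard_normal(n_sim)
        het_mean = f1 * (1.0 - p3) + p3 * (1.0 - f1)
    else:
        raise ValueError(f"unknown pedigree class {cls!r}")
    het = het_mean + np.sqrt(np.clip(het_mean * (1 - het_mean), 0, 1) / blocks) * (
        rng.standard_normal(n_sim)
    )
    return np.column_stack([np.clip(prop, 0, 1), np.clip(het, 0, 1)])


def classify_intermediate(
    proportion: float,
    heterozygosity: float,
    population: PopulationSpec,
    n_sim: int = 2000,
    seed: int | np.random.Generator | None = None,
    blocks: float | None = None,
) -> PedigreeClassification:
    """Assign a candidate to the pedigree class whose simulated joint
    (genome-wide proportion, heterozygous-site fraction) density is
    highest at the candidate; unclassified when it falls outside every
    class's simulated support."""
    rng = rng_from(seed)
    b = default_blocks() if blocks is None else float(blocks)
    point = np.array([proportion, heterozygosity])
    log_dens: dict[str, float] = {}
    in_support = False
    for cls in PEDIGREE_CLASSES:
        samp = _class_samples(cls, population, n_sim, rng, b)
        lo = samp.min(axis=0) - 3.0 * samp.std(axis=0)
        hi = samp.max(axis=0) + 3.0 * samp.std(axis=0)
        inside = bool(np.all(point >= lo) and np.all(point <= hi))
        in_support = in_support or inside
        try:
            kde = stats.gaussian_kde(samp.T)
            log_dens[cls] = float(kde.logpdf(point)[0]) if inside else -np.inf
        except np.linalg.LinAlgError:
            # degenerate cluster (zero SD): fall back to distance kernel
            d = np.min(np.linalg.norm(samp - point, axis=1))
            log_dens[cls] = -d * 1e3 if inside else -np.inf
    if not in_support:
        return PedigreeClassification(None, log_dens, True)
    best = max(log_dens, key=log_dens.get)
    return PedigreeClassification(best, log_dens, False)
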