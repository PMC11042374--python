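"""Synthetic-data generation for the hybrid-population pipeline.

Everything downstream consumes (read counts, hard calls, mother/embryo
pairs) can be generated here with the statistical structure the analyses
assume:

* a two-cluster admixed population (a nearly pure *X. birchmanni* cluster
  and an admixed *cortezi*-like cluster) with ancestry tracts laid down by
  a Markov admixture-LD process,
* F2 intercross genomes with Haldane (no-interference) recombination and
  optional post-zygotic viability selection at chosen loci,
* wild mother/embryo pairs under a tunable assortative-mating strength,
* low-coverage read counts at ancestry-informative sites.

Gametes and population haplotypes are simulated as two-state Markov chains
along the marker map — the exact site-level law of exponential tract
lengths (Poisson crossovers under Haldane's model, or switch rate T per
Morgan for a population T generations after admixture).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import rng_from
from .genomes import CORTEZI, AncestryGenomes
from .panel import AIMPanel
from .selection import SelectionParams

__all__ = [
    "PopulationSpec",
    "ReadCountMatrix",
    "MotherEmbryoSet",
    "simulate_f2",
    "simulate_population",
    "emit_reads",
    "simulate_mother_embryo",
    "segregation_sd",
]


# ---------------------------------------------------------------------------
# specs and containers


@dataclass(frozen=True)
class PopulationSpec:
    """Two-cluster admixed population parameters.

    ``mu1``/``mu2`` are the cluster means of the genome-wide cortezi
    ancestry proportion (cluster 1 = *birchmanni* cluster, cluster 2 =
    admixed *cortezi*-like cluster), ``sd1``/``sd2`` the within-cluster
    SDs, ``w1`` the weight of cluster 1, ``n`` the number of individuals
    and ``generations`` the time since initial admixture (sets the
    ancestry-tract switch rate per Morgan).
    """

    mu1: float = 0.019
    sd1: float = 0.006
    mu2: float = 0.757
    sd2: float = 0.017
    w1: float = 0.62
    n: int = 306
    generations: float = 50.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mu1 < self.mu2 <= 1.0):
            raise ValueError("need 0 <= mu1 < mu2 <= 1")
        if self.sd1 < 0 or self.sd2 < 0:
            raise ValueError("cluster SDs must be non-negative")
        if not 0.0 < self.w1 < 1.0:
            raise ValueError("w1 must be in (0,1)")
        if self.n < 1 or self.generations <= 0:
            raise ValueError("n and generations must be positive")

    @property
    def w2(self) -> float:
        return 1.0 - self.w1

    def cluster_mean(self, cluster: int) -> float:
        return self.mu1 if cluster == 1 else self.mu2

    def cluster_sd(self, cluster: int) -> float:
        return self.sd1 if cluster == 1 else self.sd2

    def draw_proportion(self, cluster: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Truncated-normal ancestry proportions for given cluster labels."""
        mu = np.where(cluster == 1, self.mu1, self.mu2)
        sd = np.where(cluster == 1, self.sd1, self.sd2)
        out = np.empty(len(cluster))
        zero = sd == 0
        out[zero] = mu[zero]
        if (~zero).any():
            a = (0.0 - mu[~zero]) / sd[~zero]
            b = (1.0 - mu[~zero]) / sd[~zero]
            out[~zero] = stats.truncnorm.rvs(
                a, b, loc=mu[~zero], scale=sd[~zero], random_state=rng
            )
        return out


@dataclass
class ReadCountMatrix:
    """Per-individual, per-site allele-supporting read counts.

    ``reads_birchmanni``/``reads_cortezi`` are non-negative integer arrays
    of shape (n_individuals, n_sites) aligned to ``panel``.
    """

    reads_birchmanni: np.ndarray
    reads_cortezi: np.ndarray
    panel: AIMPanel

    def __post_init__(self) -> None:
        b = np.asarray(self.reads_birchmanni)
        c = np.asarray(self.reads_cortezi)
        if b.shape != c.shape or b.ndim != 2 or b.shape[1] != self.panel.n_sites:
            raise ValueError("count matrices must be (n, n_sites) and match the panel")
        if (b < 0).any() or (c < 0).any():
            raise ValueError("read counts must be non-negative")
        self.reads_birchmanni = b.astype(np.int64)
        self.reads_cortezi = c.astype(np.int64)

    @property
    def n_individuals(self) -> int:
        return self.reads_birchmanni.shape[0]

    def depth(self) -> np.ndarray:
        return self.reads_birchmanni + self.reads_cortezi

    def to_frame(self) -> pd.DataFrame:
        n, s = self.reads_birchmanni.shape
        return pd.DataFrame(
            {
                "individual": np.repeat(np.arange(n), s),
                "chrom": np.tile(self.panel.chrom, n),
                "pos_bp": np.tile(self.panel.pos_bp, n),
                "reads_birchmanni": self.reads_birchmanni.ravel(),
                "reads_cortezi": self.reads_cortezi.ravel(),
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, panel: AIMPanel) -> "ReadCountMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        need = {"individual", "chrom", "pos_bp", "reads_birchmanni", "reads_cortezi"}
        if need - set(df.columns):
            raise ValueError(f"counts TSV missing columns: {sorted(need - set(df.columns))}")
        inds = np.unique(df["individual"].to_numpy())
        key = pd.MultiIndex.from_arrays(
            [df["individual"], df["chrom"].astype(str), df["pos_bp"]]
        )
        b = df["reads_birchmanni"].to_numpy()
        c = df["reads_cortezi"].to_numpy()
        wide_b = np.zeros((len(inds), panel.n_sites), dtype=np.int64)
        wide_c = np.zeros_like(wide_b)
        site_index = {
            (str(ch), int(p)): i
            for i, (ch, p) in enumerate(zip(panel.chrom, panel.pos_bp))
        }
        ind_index = {v: i for i, v in enumerate(inds)}
        for (ind, ch, p), bi, ci in zip(key, b, c):
            try:
                j = site_index[(ch, int(p))]
            except KeyError as err:
                raise ValueError(f"site {ch}:{p} not in panel") from err
            i = ind_index[ind]
            wide_b[i, j] = bi
            wide_c[i, j] = ci
        return cls(wide_b, wide_c, panel)


@dataclass
class MotherEmbryoSet:
    """Paired genome-wide ancestry of wild-caught mothers and their embryos.

    ``embryo_props[i]`` holds the brood of mother ``i``.  ``father_cluster``
    and the derived ``true_cross_cluster`` flags record the simulation
    truth for plant-and-recover tests; they are absent (None) for sets
    built from real tables.
    """

    mother_props: np.ndarray
    mother_cluster: np.ndarray
    embryo_props: list
    father_cluster: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mother_props = np.asarray(self.mother_props, dtype=float)
        self.mother_cluster = np.asarray(self.mother_cluster, dtype=int)
        self.embryo_props = [np.atleast_1d(np.asarray(e, dtype=float)) for e in self.embryo_props]
        if len(self.embryo_props) != len(self.mother_props):
            raise ValueError("one embryo array per mother required")
        if any(len(e) < 1 for e in self.embryo_props):
            raise ValueError("every mother needs at least one embryo")
        bad = [
            p
            for p in np.concatenate([self.mother_props, *self.embryo_props])
            if not 0.0 <= p <= 1.0
        ]
        if bad:
            raise ValueError("ancestry proportions must lie in [0,1]")

    @property
    def n_mothers(self) -> int:
        return len(self.mother_props)

    @property
    def n_embryos(self) -> int:
        return int(sum(len(e) for e in self.embryo_props))

    def true_cross_cluster(self) -> np.ndarray | None:
        if self.father_cluster is None:
            return None
        return self.father_cluster != self.mother_cluster

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, brood in enumerate(self.embryo_props):
            for e in brood:
                rows.append((i, self.mother_props[i], int(self.mother_cluster[i]), e))
        return pd.DataFrame(rows, columns=["mother", "mother_prop", "mother_cluster", "embryo_prop"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MotherEmbryoSet":
        mothers, clusters, broods = [], [], []
        for _, grp in df.groupby("mother", sort=True):
            mothers.append(grp["mother_prop"].iloc[0])
            clusters.append(grp["mother_cluster"].iloc[0] if "mother_cluster" in grp else 0)
            broods.append(grp["embryo_prop"].to_numpy())
        return cls(np.array(mothers), np.array(clusters), broods)


# ---------------------------------------------------------------------------
# haplotype machinery


def _markov_haplotypes(
    panel: AIMPanel,
    stationary: np.ndarray,
    switch_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate two-state haplotypes along the map.

    ``stationary`` gives, per chain, the stationary cortezi frequency; the
    chain switches to an ancestry redrawn from the stationary distribution
    with probability 1 - exp(-switch_rate * d) between sites at genetic
    distance ``d`` (infinite at chromosome starts, giving independence).

    Returns an int8 array of shape (n_chains, n_sites).
    """
    q = np.asarray(stationary, dtype=float)[:, None]  # (n_chains, 1)
    d = panel.site_distances()
    keep = np.exp(-switch_rate * d)  # 0 at chromosome starts
    u_switch = rng.random((q.shape[0], panel.n_sites))
    u_state = rng.random((q.shape[0], panel.n_sites))
    redraw = u_state < q  # ancestry if redrawn from stationary
    out = np.empty((q.shape[0], panel.n_sites), dtype=np.int8)
    out[:, 0] = redraw[:, 0]
    for s in range(1, panel.n_sites):
        stay = u_switch[:, s] < keep[s]
        out[:, s] = np.where(stay, out[:, s - 1], redraw[:, s])
    return out


def _f1_gametes(panel: AIMPanel, n_gametes: int, rng: np.random.Generator) -> np.ndarray:
    """Gametes of an F1 (heterozygous everywhere) under Haldane recombination.

    Between adjacent sites at distance d the gamete switches grandparental
    origin with the recombination fraction r = (1 - exp(-2d)) / 2; at
    chromosome starts the origin is a fair coin.  This is the exact
    marginal law at marker positions of a Poisson crossover process with
    intensity 1 per Morgan per meiosis.
    """
    d = panel.site_distances()
    r = 0.5 * (1.0 - np.exp(-2.0 * d))
    r[np.isinf(d)] = 0.5
    switch = rng.random((n_gametes, panel.n_sites)) < r
    switch[:, 0] = rng.random(n_gametes) < 0.5
    first = np.zeros(n_gametes, dtype=np.int8)
    # cumulative XOR of switch indicators within each chromosome
    out = np.empty((n_gametes, panel.n_sites), dtype=np.int8)
    for sl in panel.chrom_slices().values():
        block = switch[:, sl].astype(np.int8)
        block[:, 0] ^= first  # chromosome start re-randomized by switch[:,0]
        out[:, sl] = np.cumsum(block, axis=1) % 2
    return out


# ---------------------------------------------------------------------------
# operations


def simulate_f2(
    panel: AIMPanel,
    n_offspring: int,
    selection_loci: list[tuple[int, SelectionParams]] | None = None,
    seed: int | np.random.Generator | None = None,
    max_batches: int = 1000,
) -> AncestryGenomes:
    """Simulate surviving F2 intercross offspring.

    Each candidate offspring is the union of two independent F1 gametes
    (the F1 is heterozygous birchmanni/cortezi everywhere); it survives
    with probability equal to its fitness, the product over selection loci
    of 1, 1-h*s, 1-s for 0, 1, 2 copies of *birchmanni* ancestry at the
    locus.  Candidates are resampled until ``n_offspring`` survive.  All
    offspring carry the cortezi mitochondria (the viable cross direction).
    """
    if n_offspring < 1:
        raise ValueError("n_offspring must be >= 1")
    selection_loci = list(selection_loci or [])
    for site, par in selection_loci:
        if not 0 <= site < panel.n_sites:
            raise ValueError(f"selection locus {site} outside panel")
        if not isinstance(par, SelectionParams):
            raise TypeError("selection loci must carry SelectionParams")
    rng = rng_from(seed)
    kept = []
    n_kept = 0
    batch = max(n_offspring, 64)
    for _ in range(max_batches):
        g1 = _f1_gametes(panel, batch, rng)
        g2 = _f1_gametes(panel, batch, rng)
        hap = np.stack([g1, g2], axis=1)  # (batch, 2, S)
        if selection_loci:
            fitness = np.ones(batch)
            for site, par in selection_loci:
                birch_copies = 2 - hap[:, :, site].sum(axis=1)
                w = np.array([1.0, 1.0 - par.h * par.s, 1.0 - par.s])
                fitness *= w[birch_copies]
            alive = rng.random(batch) < fitness
        else:
            alive = np.ones(batch, dtype=bool)
        if alive.any():
            kept.append(hap[alive])
            n_kept += int(alive.sum())
        if n_kept >= n_offspring:
            hap = np.concatenate(kept, axis=0)[:n_offspring]
            mito = np.full(n_offspring, CORTEZI, dtype=np.int8)
            return AncestryGenomes(hap, mito, panel)
    raise RuntimeError(
        "selection rejected (nearly) all simulated offspring; "
        "check the selection parameters for joint lethality"
    )


def simulate_population(
    spec: PopulationSpec,
    panel: AIMPanel,
    seed: int | np.random.Generator | None = None,
) -> AncestryGenomes:
    """Simulate a two-cluster admixed population on a panel.

    Each individual's target genome-wide proportion is a truncated-normal
    draw from its cluster; haplotypes follow a two-state Markov process
    with switch rate ``spec.generations`` per Morgan and stationary
    frequency equal to the target, so tract lengths are exponential with
    the admixture-LD scale.  Mitochondria follow the cluster (cluster 1
    birchmanni, cluster 2 cortezi).
    """
    rng = rng_from(seed)
    cluster = np.where(rng.random(spec.n) < spec.w1, 1, 2)
    target = spec.draw_proportion(cluster, rng)
    per_copy = np.repeat(target, 2)
    hap = _markov_haplotypes(panel, per_copy, spec.generations, rng)
    hap = hap.reshape(spec.n, 2, panel.n_sites)
    mito = np.where(cluster == 1, 0, 1).astype(np.int8)
    genomes = AncestryGenomes(hap, mito, panel)
    genomes.cluster = cluster  # simulation truth, used by tests
    genomes.target_proportion = target
    return genomes


def emit_reads(
    genomes: AncestryGenomes,
    mean_depth: float = 1.0,
    error_rate: float = 0.001,
    seed: int | np.random.Generator | None = None,
) -> ReadCountMatrix:
    """Low-coverage read counts at panel sites.

    Depth per individual x site is Poisson(``mean_depth``); conditional on
    depth, cortezi-supporting reads are Binomial(depth, q) with q equal to
    ``error_rate``, 0.5 and 1-``error_rate`` for 0, 1 and 2 cortezi
    copies.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    rng = rng_from(seed)
    dos = genomes.dosage()
    depth = rng.poisson(mean_depth, size=dos.shape)
    q = np.array([error_rate, 0.5, 1.0 - error_rate])[dos]
    c = rng.binomial(depth, q)
    return ReadCountMatrix(depth - c, c, genomes.panel)


def segregation_sd(
    p_mother: np.ndarray,
    p_father: np.ndarray,
    blocks: float,
) -> np.ndarray:
    """SD of embryo ancestry around the midparent value.

    sigma = sqrt(H / (4 B)) where H is the expected fraction of loci at
    which exactly one parent is heterozygous for ancestry (heterozygosity
    per parent modelled as 2p(1-p)) and B the effective number of
    independently segregating blocks.
    """
    hm = 2.0 * p_mother * (1.0 - p_mother)
    hf = 2.0 * p_father * (1.0 - p_father)
    h_one = hm * (1.0 - hf) + hf * (1.0 - hm)
    return np.sqrt(h_one / (4.0 * blocks))


def default_blocks(total_morgans: float = 24.0, n_chromosomes: int = 24) -> float:
    """Effective number of independently segregating blocks.

    Twice the expected number of recombination-delimited segments per
    transmitted genome: crossovers (one per Morgan per meiosis) plus
    independently assorting chromosomes, counted over both parental
    meioses.
    """
    return 2.0 * (total_morgans + n_chromosomes)


def simulate_mother_embryo(
    population: PopulationSpec,
    assortment_strength: float,
    n_mothers: int = 49,
    embryos_per_mother: int = 2,
    segregation_sd_model: str | float = "blocks",
    seed: int | np.random.Generator | None = None,
    blocks: float | None = None,
) -> MotherEmbryoSet:
    """Simulate paired mother/embryo genome-wide ancestry.

    Mothers are drawn from the population; the father comes from the
    mother's cluster with probability ``assortment_strength`` and from the
    other cluster otherwise.  Each embryo's proportion is the midparent
    value plus zero-mean segregation noise (``segregation_sd_model`` =
    ``"blocks"`` for the finite-genome model, ``"none"`` for no noise, or
    a float for a constant SD), truncated to [0,1].
    """
    a = float(assortment_strength)
    if not 0.0 <= a <= 1.0:
        raise ValueError("assortment_strength must be in [0,1]")
    if n_mothers < 1:
        raise ValueError("need at least one mother")
    rng = rng_from(seed)
    b = default_blocks() if blocks is None else float(blocks)

    m_cluster = np.where(rng.random(n_mothers) < population.w1, 1, 2)
    m_prop = population.draw_proportion(m_cluster, rng)
    same = rng.random(n_mothers) < a
    f_cluster = np.where(same, m_cluster, 3 - m_cluster)
    f_prop = population.draw_proportion(f_cluster, rng)

    if segregation_sd_model == "blocks":
        sd = segregation_sd(m_prop, f_prop, b)
    elif segregation_sd_model == "none":
        sd = np.zeros(n_mothers)
    else:
        sd = np.full(n_mothers, float(segregation_sd_model))

    if np.isscalar(embryos_per_mother):
        brood_sizes = np.full(n_mothers, int(embryos_per_mother))
    else:
        brood_sizes = np.asarray(embryos_per_mother, dtype=int)
        if len(brood_sizes) != n_mothers:
            raise ValueError("one brood size per mother required")
    if (brood_sizes < 1).any():
        raise ValueError("brood sizes must be >= 1")

    mid = 0.5 * (m_prop + f_prop)
    broods = []
    for i in range(n_mothers):
        e = mid[i] + sd[i] * rng.standard_normal(brood_sizes[i])
        broods.append(np.clip(e, 0.0, 1.0))
    return MotherEmbryoSet(m_prop, m_cluster, broods, father_cluster=f_cluster)
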