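"""Ancestry-informative-marker (AIM) panels.

An AIM panel is an ordered set of genomic sites that are fixed (or nearly
fixed) for different alleles in the two parental species.  Each site carries
a chromosome id, a physical position in bp and a genetic position in
Morgans.  Panels are the coordinate system shared by the synthetic
generator, the ancestry HMM and the segregation-distortion scan.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["AIMPanel", "make_panel"]


@dataclass(frozen=True)
class AIMPanel:
    """Ordered AIM sites across one or more chromosomes.

    Attributes
    ----------
    chrom : array of str, shape (n_sites,)
        Chromosome label per site; sites are grouped by chromosome.
    pos_bp : array of int, shape (n_sites,)
        1-based physical positions, strictly increasing within a chromosome.
    pos_morgans : array of float, shape (n_sites,)
        Genetic positions in Morgans, non-decreasing and co-monotone with
        the physical positions within a chromosome.
    """

    chrom: np.ndarray
    pos_bp: np.ndarray
    pos_morgans: np.ndarray
    _blocks: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        chrom = np.asarray(self.chrom, dtype=object)
        pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        pos_m = np.asarray(self.pos_morgans, dtype=float)
        if not (chrom.shape == pos_bp.shape == pos_m.shape) or chrom.ndim != 1:
            raise ValueError("chrom, pos_bp and pos_morgans must be 1-D and equal length")
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "pos_bp", pos_bp)
        object.__setattr__(self, "pos_morgans", pos_m)
        blocks: dict[str, slice] = {}
        start = 0
        for i in range(1, len(chrom) + 1):
            if i == len(chrom) or chrom[i] != chrom[start]:
                blocks[str(chrom[start])] = slice(start, i)
                start = i
        if len(blocks) != len(set(chrom.tolist())):
            raise ValueError("sites of one chromosome must be contiguous in the panel")
        for sl in blocks.values():
            if sl.stop - sl.start < 2:
                raise ValueError("each chromosome needs at least 2 sites")
            if not np.all(np.diff(pos_bp[sl]) > 0):
                raise ValueError("physical positions must be strictly increasing per chromosome")
            if not np.all(np.diff(pos_m[sl]) >= 0):
                raise ValueError("genetic positions must be non-decreasing per chromosome")
        object.__setattr__(self, "_blocks", blocks)

    @property
    def n_sites(self) -> int:
        return len(self.chrom)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._blocks)

    @property
    def n_chromosomes(self) -> int:
        return len(self._blocks)

    def chrom_slice(self, chrom: str) -> slice:
        """Site-index slice (half-open) covering one chromosome."""
        return self._blocks[str(chrom)]

    def chrom_slices(self) -> dict[str, slice]:
        return dict(self._blocks)

    @property
    def total_morgans(self) -> float:
        """Total map length: sum over chromosomes of the covered interval."""
        return float(
            sum(
                self.pos_morgans[sl.stop - 1] - self.pos_morgans[sl.start]
                for sl in self._blocks.values()
            )
        )

    def site_distances(self) -> np.ndarray:
        """Genetic distance (Morgans) from each site to the previous one.

        The first site of every chromosome gets ``inf`` (no linkage across
        chromosome boundaries).
        """
        d = np.empty(self.n_sites)
        for sl in self._blocks.values():
            d[sl.start] = np.inf
            d[sl.start + 1 : sl.stop] = np.diff(self.pos_morgans[sl])
        return d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "pos_bp": self.pos_bp, "pos_morgans": self.pos_morgans}
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AIMPanel":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        missing = {"chrom", "pos_bp", "pos_morgans"} - set(df.columns)
        if missing:
            raise ValueError(f"panel TSV missing columns: {sorted(missing)}")
        return cls(df["chrom"].to_numpy(dtype=object), df["pos_bp"].to_numpy(),
                   df["pos_morgans"].to_numpy())


def make_panel(
    n_chromosomes: int,
    sites_per_chromosome: int,
    chromosome_length_morgans: float = 1.0,
    seed: int | None = None,
    bp_per_morgan: float = 3.0e7,
) -> AIMPanel:
    """Build a synthetic AIM panel with sites uniformly spaced in genetic distance.

    The published panel holds ~1e6 informative sites genome-wide; synthetic
    panels emulate it at reduced density.  Physical positions are laid down
    proportionally to the genetic map at ``bp_per_morgan``, with seeded
    jitter so positions are not perfectly regular.
    """
    if n_chromosomes <= 0 or sites_per_chromosome <= 0:
        raise ValueError("counts must be positive")
    if sites_per_chromosome < 2:
        raise ValueError("need at least 2 sites per chromosome")
    if chromosome_length_morgans <= 0:
        raise ValueError("chromosome length must be positive")
    rng = np.random.default_rng(seed)
    chroms, bps, morgans = [], [], []
    for c in range(1, n_chromosomes + 1):
        g = np.linspace(0.0, chromosome_length_morgans, sites_per_chromosome)
        # jitter physical spacing only: genetic grid stays exactly uniform
        spacing = chromosome_length_morgans / max(sites_per_chromosome - 1, 1)
        jitter = rng.uniform(0.0, 0.4 * spacing * bp_per_morgan, size=sites_per_chromosome)
        bp = np.round(g * bp_per_morgan + jitter).astype(np.int64) + 1
        bp = np.maximum.accumulate(bp)
        bp += np.arange(sites_per_chromosome)  # enforce strict increase
        chroms.append(np.full(sites_per_chromosome, f"chr{c}", dtype=object))
        bps.append(bp)
        morgans.append(g)
    return AIMPanel(
        np.concatenate(chroms), np.concatenate(bps), np.concatenate(morgans)
    )
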