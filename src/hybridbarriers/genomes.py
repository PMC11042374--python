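"""Diploid ancestry genomes.

Ancestry is coded per haplotype copy as 0 = *X. birchmanni*, 1 = *X. cortezi*
at every panel site; the diploid state at a site is the dosage (number of
cortezi copies, 0/1/2).  Tract representations (start/end site index,
ancestry) are derived views of the site-level haplotypes: runs of constant
ancestry, half-open in site-index space, tiling each chromosome copy by
construction.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import AIMPanel

BIRCHMANNI, CORTEZI = 0, 1

__all__ = ["AncestryGenomes", "BIRCHMANNI", "CORTEZI"]


@dataclass
class AncestryGenomes:
    """A set of diploid genomes on a shared AIM panel.

    Attributes
    ----------
    haplotypes : int8 array, shape (n_individuals, 2, n_sites)
        Per-copy ancestry (0 birchmanni / 1 cortezi) at each panel site.
    mito : int8 array, shape (n_individuals,)
        Mitochondrial ancestry per individual (0 birchmanni / 1 cortezi).
    panel : AIMPanel
    """

    haplotypes: np.ndarray
    mito: np.ndarray
    panel: AIMPanel

    def __post_init__(self) -> None:
        hap = np.asarray(self.haplotypes, dtype=np.int8)
        if hap.ndim != 3 or hap.shape[1] != 2 or hap.shape[2] != self.panel.n_sites:
            raise ValueError("haplotypes must have shape (n, 2, n_sites)")
        if not np.isin(hap, (0, 1)).all():
            raise ValueError("haplotype ancestry must be 0 or 1")
        mito = np.asarray(self.mito, dtype=np.int8)
        if mito.shape != (hap.shape[0],):
            raise ValueError("mito must have one entry per individual")
        self.haplotypes = hap
        self.mito = mito

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0]

    def dosage(self) -> np.ndarray:
        """Number of cortezi copies per individual x site (0/1/2)."""
        return self.haplotypes.sum(axis=1, dtype=np.int8)

    def proportions(self) -> np.ndarray:
        """Genome-wide cortezi ancestry proportion per individual."""
        return self.haplotypes.mean(axis=(1, 2))

    def heterozygosity(self) -> np.ndarray:
        """Fraction of sites heterozygous for ancestry, per individual."""
        return (self.dosage() == 1).mean(axis=1)

    def tracts(self, individual: int) -> list[tuple[str, int, int, int, int]]:
        """Ancestry tracts of one individual.

        Returns tuples ``(chrom, copy, start, end, ancestry)`` with
        half-open [start, end) site-index bounds; tracts tile each
        chromosome copy without gaps or overlaps.
        """
        out = []
        for chrom, sl in self.panel.chrom_slices().items():
            for copy in (0, 1):
                h = self.haplotypes[individual, copy, sl]
                change = np.flatnonzero(np.diff(h)) + 1
                bounds = np.concatenate(([0], change, [len(h)]))
                for a, b in zip(bounds[:-1], bounds[1:]):
                    out.append((chrom, copy, sl.start + int(a), sl.start + int(b),
                                int(h[a])))
        return out

    def truth_calls_frame(self) -> pd.DataFrame:
        """True ancestry as a long-format hard-call table (oracle for tests)."""
        n, s = self.n_individuals, self.panel.n_sites
        dos = self.dosage()
        return pd.DataFrame(
            {
                "individual": np.repeat(np.arange(n), s),
                "chrom": np.tile(self.panel.chrom, n),
                "pos_bp": np.tile(self.panel.pos_bp, n),
                "state": dos.ravel(),
            }
        )
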