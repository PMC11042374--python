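"""Segregation-distortion scan of F2 hard-call matrices.

In an F2 intercross the expected cortezi ancestry at every site is 0.5;
post-zygotic selection against one ancestry pulls the per-site mean away
from it.  Significance is assessed against a simulated Mendelian null
with a family-wise (genome-wide) envelope, and each significant peak is
extended into an interval by ancestry-LD decay (R^2 between the peak and
flanking thinned markers).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import rng_from
from .ancestry import AncestryCalls
from .panel import AIMPanel
from .simulate import simulate_f2

__all__ = [
    "LDConfig",
    "Envelope",
    "ScanResult",
    "scan_mean_ancestry",
    "null_envelope",
    "ld_interval",
    "run_scan",
]


@dataclass(frozen=True)
class LDConfig:
    """Marker thinning window (bp) and the R^2 cutoff delimiting a peak."""

    window_bp: int = 50_000
    r2_threshold: float = 0.8

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window must be positive")
        if not 0.0 < self.r2_threshold < 1.0:
            raise ValueError("R^2 threshold must be in (0,1)")


@dataclass(frozen=True)
class Envelope:
    """Family-wise null band for per-site mean ancestry, symmetric about 0.5."""

    lower: float
    upper: float
    q: float
    n_sim: int

    def __post_init__(self) -> None:
        if not self.lower < 0.5 < self.upper:
            raise ValueError("envelope must bracket the Mendelian expectation 0.5")


@dataclass
class ScanResult:
    """Per-site means with the null envelope and LD-delimited peak intervals."""

    table: pd.DataFrame  # chrom, pos_bp, mean, n_called, significant
    envelope: Envelope
    intervals: pd.DataFrame  # chrom, start_bp, end_bp, peak_pos


def scan_mean_ancestry(calls: AncestryCalls, min_call_fraction: float = 0.5) -> pd.DataFrame:
    """Per-site mean cortezi ancestry over called individuals.

    Sites called in fewer than ``min_call_fraction`` of individuals are
    masked (mean NaN): sparse sites give noisy means that would dominate
    the scan.
    """
    if calls.n_individuals == 0:
        raise ValueError("empty call matrix")
    called = calls.called()
    n_called = called.sum(axis=0)
    dose = np.where(called, calls.states, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = dose / (2.0 * n_called)
    mean = np.where(n_called >= min_call_fraction * calls.n_individuals, mean, np.nan)
    return pd.DataFrame(
        {
            "chrom": calls.panel.chrom,
            "pos_bp": calls.panel.pos_bp,
            "mean": mean,
            "n_called": n_called,
        }
    )


def null_envelope(
    n_f2: int,
    panel: AIMPanel,
    n_sim: int = 500,
    q: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> Envelope:
    """Family-wise envelope from Mendelian F2 simulations.

    Each replicate simulates ``n_f2`` selection-free F2 genomes on the
    panel and records the genome-wide maximum deviation of per-site mean
    ancestry from 0.5; the envelope half-width is the ``q`` quantile of
    those maxima, so a fraction q of whole-genome null scans lie entirely
    inside the band.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    rng = rng_from(seed)
    max_dev = np.empty(n_sim)
    for s in range(n_sim):
        genomes = simulate_f2(panel, n_f2, seed=rng)
        mean = genomes.dosage().mean(axis=0) / 2.0
        max_dev[s] = np.abs(mean - 0.5).max()
    half = float(np.quantile(max_dev, q))
    return Envelope(0.5 - half, 0.5 + half, q, n_sim)


def thin_sites(calls: AncestryCalls, window_bp: int = 50_000) -> np.ndarray:
    """Indices of one site per window: most-called site, ties to lowest position."""
    n_called = calls.called().sum(axis=0)
    panel = calls.panel
    keep = []
    for chrom, sl in panel.chrom_slices().items():
        pos = panel.pos_bp[sl]
        windows = (pos - 1) // window_bp
        for w in np.unique(windows):
            idx = np.flatnonzero(windows == w) + sl.start
            best = idx[np.argmax(n_called[idx])]  # argmax takes first on ties
            keep.append(best)
    return np.array(sorted(keep))


def ld_interval(
    calls: AncestryCalls,
    peak_chrom: str,
    peak_pos: int,
    config: LDConfig | None = None,
) -> tuple[str, int, int]:
    """Delimit a distortion peak by ancestry-LD decay.

    Sites are thinned to one per window; R^2 between the peak marker and
    every thinned marker on the same chromosome is the squared Pearson
    correlation of ancestry dosage (0/1/2) over individuals called at
    both.  The interval is the maximal contiguous run of thinned markers
    around the peak with R^2 >= the threshold, reported as 1-based
    inclusive (chrom, start_bp, end_bp).
    """
    config = config or LDConfig()
    panel = calls.panel
    thinned = thin_sites(calls, config.window_bp)
    chrom_mask = panel.chrom[thinned] == str(peak_chrom)
    chrom_sites = thinned[chrom_mask]
    if len(chrom_sites) == 0:
        raise ValueError(f"no thinned sites on chromosome {peak_chrom}")
    peak_candidates = chrom_sites[panel.pos_bp[chrom_sites] == int(peak_pos)]
    if len(peak_candidates) == 0:
        raise ValueError(
            f"peak {peak_chrom}:{peak_pos} not retained after thinning"
        )
    peak = int(peak_candidates[0])
    states = calls.states
    peak_col = states[:, peak]
    r2 = np.empty(len(chrom_sites))
    for i, s in enumerate(chrom_sites):
        col = states[:, s]
        both = (peak_col >= 0) & (col >= 0)
        if both.sum() < 3 or np.ptp(col[both]) == 0 or np.ptp(peak_col[both]) == 0:
            r2[i] = 1.0 if s == peak else 0.0
            continue
        r = np.corrcoef(peak_col[both], col[both])[0, 1]
        r2[i] = r * r
    k = int(np.flatnonzero(chrom_sites == peak)[0])
    left = k
    while left > 0 and r2[left - 1] >= config.r2_threshold:
        left -= 1
    right = k
    while right < len(chrom_sites) - 1 and r2[right + 1] >= config.r2_threshold:
        right += 1
    start = int(panel.pos_bp[chrom_sites[left]])
    end = int(panel.pos_bp[chrom_sites[right]])
    return (str(peak_chrom), start, end)


def run_scan(
    calls: AncestryCalls,
    n_sim: int = 500,
    q: float = 0.95,
    seed: int | np.random.Generator | None = None,
    ld_config: LDConfig | None = None,
) -> ScanResult:
    """Full scan: per-site means, null envelope, significant sites and
    LD intervals around each significant peak (one per chromosome)."""
    table = scan_mean_ancestry(calls)
    env = null_envelope(calls.n_individuals, calls.panel, n_sim=n_sim, q=q, seed=seed)
    sig = (table["mean"] < env.lower) | (table["mean"] > env.upper)
    table = table.assign(lower=env.lower, upper=env.upper, significant=sig.fillna(False))
    rows = []
    for chrom, grp in table[table["significant"]].groupby("chrom", sort=False):
        peak = grp.loc[(grp["mean"] - 0.5).abs().idxmax()]
        try:
            c, s, e = ld_interval(calls, chrom, int(peak["pos_bp"]), ld_config)
        except ValueError:
            c, s, e = chrom, int(peak["pos_bp"]), int(peak["pos_bp"])
        rows.append((c, s, e, int(peak["pos_bp"])))
    intervals = pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "peak_pos"])
    return ScanResult(table, env, intervals)
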