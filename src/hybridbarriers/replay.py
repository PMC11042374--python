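"""End-to-end pipeline driver on synthetic data.

``replay`` chains the full analysis arc — simulate a two-cluster hybrid
population, mother/embryo pairs and an F2 cross with planted selection
loci; infer local ancestry from low-coverage read counts; test ancestry
bimodality; fit the assortative-mating strength; scan the F2s for
segregation distortion; and estimate (s, h) at each planted locus by
ABC — writing every intermediate table to disk so each stage reads only
the previous stage's files.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._rng import child_seeds
from .ancestry import AncestryCalls, AncestryHMM, ancestry_proportions
from .mating import fit_assortment
from .panel import AIMPanel, make_panel
from .scan import LDConfig, run_scan
from .selection import GenotypeCounts, SelectionParams, abc_infer
from .simulate import (
    MotherEmbryoSet,
    PopulationSpec,
    ReadCountMatrix,
    emit_reads,
    simulate_f2,
    simulate_mother_embryo,
    simulate_population,
)
from .structure import assign_clusters, dip_test

__all__ = ["RunConfig", "replay", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Declarative replay configuration (one block per stage)."""

    seed: int = 1
    outdir: str = "replay_out"
    panel: dict = field(default_factory=lambda: {
        "n_chromosomes": 6, "sites_per_chromosome": 150, "chromosome_length_morgans": 1.0,
    })
    population: dict = field(default_factory=lambda: {
        "mu1": 0.019, "sd1": 0.006, "mu2": 0.757, "sd2": 0.017,
        "w1": 0.62, "n": 306, "generations": 50,
    })
    reads: dict = field(default_factory=lambda: {"mean_depth": 1.0, "error_rate": 0.001})
    hmm: dict = field(default_factory=lambda: {"threshold": 0.9, "error_rate": 0.001})
    dip: dict = field(default_factory=lambda: {"n_boot": 200})
    mating: dict = field(default_factory=lambda: {
        "assortment": 1.0, "n_mothers": 49, "embryos_per_mother": 2, "n_sim": 300,
    })
    f2: dict = field(default_factory=lambda: {
        "n_offspring": 163,
        "selection_loci": [
            {"chrom": 1, "site_in_chrom": 75, "s": 1.0, "h": 0.0},
            {"chrom": 2, "site_in_chrom": 75, "s": 0.531, "h": 0.049},
        ],
    })
    scan: dict = field(default_factory=lambda: {"n_sim": 300, "q": 0.95})
    abc: dict = field(default_factory=lambda: {"n_draws": 50_000, "tolerance": 0.05})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        base = cls()
        for key, value in raw.items():
            if isinstance(value, dict):
                block = dict(getattr(base, key))
                bad = set(value) - set(block)
                if bad:
                    raise ValueError(f"unknown keys in block {key!r}: {sorted(bad)}")
                block.update(value)
                setattr(base, key, block)
            else:
                setattr(base, key, value)
        return base

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def _locus_site_index(panel: AIMPanel, chrom: int, site_in_chrom: int) -> int:
    sl = panel.chrom_slice(f"chr{chrom}")
    idx = sl.start + site_in_chrom
    if not sl.start <= idx < sl.stop:
        raise ValueError(f"site_in_chrom {site_in_chrom} outside chr{chrom}")
    return idx


def replay(config: RunConfig) -> dict:
    """Run the full synthetic pipeline; returns the report dictionary.

    Writes panel/counts/calls/proportions/mother-embryo TSVs plus
    ``report.json`` under ``config.outdir``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = child_seeds(config.seed, 8)
    report: dict = {"seed": config.seed, "stages": {}}

    # --- stage 1: simulate ------------------------------------------------
    stage = "simulate"
    try:
        panel = make_panel(**config.panel, seed=seeds[0])
        panel.to_tsv(out / "panel.tsv")
        pop_spec = PopulationSpec(**config.population)
        population = simulate_population(pop_spec, panel, seed=seeds[1])
        emit_reads(population, **config.reads, seed=seeds[2]).to_tsv(out / "pop_counts.tsv")

        loci = [
            (_locus_site_index(panel, d["chrom"], d["site_in_chrom"]),
             SelectionParams(d["s"], d["h"]))
            for d in config.f2["selection_loci"]
        ]
        f2 = simulate_f2(panel, config.f2["n_offspring"], loci, seed=seeds[3])
        emit_reads(f2, **config.reads, seed=seeds[4]).to_tsv(out / "f2_counts.tsv")

        pairs = simulate_mother_embryo(
            pop_spec,
            config.mating["assortment"],
            n_mothers=config.mating["n_mothers"],
            embryos_per_mother=config.mating["embryos_per_mother"],
            seed=seeds[5],
        )
        pairs.to_frame().to_csv(out / "mother_embryo.tsv", sep="\t", index=False)
        report["stages"][stage] = {
            "n_population": pop_spec.n,
            "n_f2": config.f2["n_offspring"],
            "planted_loci": [
                {"site": s, "s": p.s, "h": p.h} for s, p in loci
            ],
        }
    except Exception as err:  # noqa: BLE001 - stage boundary
        raise StageError(stage, err) from err

    # --- stage 2: ancestry inference -------------------------------------
    stage = "ancestry"
    try:
        panel = AIMPanel.from_tsv(out / "panel.tsv")
        hmm_pop = AncestryHMM(generations=config.population["generations"], **config.hmm)
        pop_counts = ReadCountMatrix.from_tsv(out / "pop_counts.tsv", panel)
        pop_calls = hmm_pop.fit(pop_counts).predict(pop_counts)
        pop_calls.to_tsv(out / "pop_calls.tsv")
        props = ancestry_proportions(pop_calls)
        props.to_csv(out / "pop_proportions.tsv", sep="\t", index=False)

        hmm_f2 = AncestryHMM(generations=2.0, **config.hmm)
        f2_counts = ReadCountMatrix.from_tsv(out / "f2_counts.tsv", panel)
        f2_calls = hmm_f2.fit(f2_counts).predict(f2_counts)
        f2_calls.to_tsv(out / "f2_calls.tsv")
        report["stages"][stage] = {
            "mean_called_fraction_population": float(pop_calls.called().mean()),
            "mean_called_fraction_f2": float(f2_calls.called().mean()),
        }
    except Exception as err:  # noqa: BLE001
        raise StageError(stage, err) from err

    # --- stage 3: bimodality ----------------------------------------------
    stage = "dip"
    try:
        props = pd.read_csv(out / "pop_proportions.tsv", sep="\t")
        values = props.loc[~props["no_calls"], "proportion"].to_numpy()
        dres = dip_test(values, n_boot=config.dip["n_boot"], seed=seeds[6])
        clusters = assign_clusters(values)
        report["stages"][stage] = {
            "dip": dres.statistic,
            "pvalue": dres.pvalue,
            "clusters": clusters.to_dict(),
        }
    except Exception as err:  # noqa: BLE001
        raise StageError(stage, err) from err

    # --- stage 4: assortative mating --------------------------------------
    stage = "mating"
    try:
        pairs = MotherEmbryoSet.from_frame(pd.read_csv(out / "mother_embryo.tsv", sep="\t"))
        pop_spec = PopulationSpec(**config.population)
        fit = fit_assortment(
            pairs, pop_spec, n_sim=config.mating["n_sim"], seed=seeds[7]
        )
        report["stages"][stage] = {
            "best_a": fit["a"],
            "observed_cross_calls": fit["observed_cross_calls"],
            "scores": {f"{a:.2f}": float(s) for a, s in zip(fit["a_grid"], fit["scores"])},
        }
    except Exception as err:  # noqa: BLE001
        raise StageError(stage, err) from err

    # --- stage 5: segregation-distortion scan ------------------------------
    stage = "scan"
    try:
        panel = AIMPanel.from_tsv(out / "panel.tsv")
        f2_calls = AncestryCalls.from_tsv(out / "f2_calls.tsv", panel)
        scan_res = run_scan(
            f2_calls, n_sim=config.scan["n_sim"], q=config.scan["q"], seed=seeds[3] + 1,
            ld_config=LDConfig(),
        )
        scan_res.table.to_csv(out / "scan.tsv", sep="\t", index=False)
        bed = scan_res.intervals.copy()
        if len(bed):
            bed["start_bp"] -= 1  # BED is 0-based half-open
        bed[["chrom", "start_bp", "end_bp"]].to_csv(
            out / "intervals.bed", sep="\t", index=False, header=False
        )
        report["stages"][stage] = {
            "envelope": [scan_res.envelope.lower, scan_res.envelope.upper],
            "n_significant_sites": int(scan_res.table["significant"].sum()),
            "intervals": scan_res.intervals.to_dict("records"),
        }
    except Exception as err:  # noqa: BLE001
        raise StageError(stage, err) from err

    # --- stage 6: ABC at planted loci --------------------------------------
    stage = "abc"
    try:
        abc_out = {}
        for d in config.f2["selection_loci"]:
            site = _locus_site_index(panel, d["chrom"], d["site_in_chrom"])
            states = f2_calls.states[:, site]
            counts = GenotypeCounts(
                int((states == 2).sum()), int((states == 1).sum()), int((states == 0).sum())
            )
            post = abc_infer(
                counts,
                n_draws=config.abc["n_draws"],
                tolerance=config.abc["tolerance"],
                seed=seeds[3] + 2 + site,
            )
            abc_out[f"chr{d['chrom']}:{d['site_in_chrom']}"] = {
                "true_s": d["s"],
                "true_h": d["h"],
                "counts": [counts.n_cc, counts.n_bc, counts.n_bb],
                **post.to_dict(),
            }
        report["stages"][stage] = abc_out
    except Exception as err:  # noqa: BLE001
        raise StageError(stage, err) from err

    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
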