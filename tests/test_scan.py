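"""F2 segregation-distortion scan: means, null envelope, LD intervals."""
import numpy as np
import pytest

from hybridbarriers.ancestry import AncestryCalls
from hybridbarriers.panel import make_panel
from hybridbarriers.scan import (
    LDConfig,
    ld_interval,
    null_envelope,
    run_scan,
    scan_mean_ancestry,
    thin_sites,
)
from hybridbarriers.selection import SelectionParams
from hybridbarriers.simulate import simulate_f2


def perfect_calls(genomes):
    return AncestryCalls(genomes.dosage(), genomes.panel)


class TestMeans:
    def test_all_heterozygous_site(self, small_panel):
        states = np.ones((163, small_panel.n_sites), dtype=np.int8)
        df = scan_mean_ancestry(AncestryCalls(states, small_panel))
        assert np.allclose(df["mean"], 0.5)

    def test_recessive_lethal_hand_arithmetic(self, small_panel):
        # genotype counts CC=54, BC=109, BB=0 -> (2*54+109)/(2*163)
        col = np.concatenate([np.full(54, 2), np.full(109, 1)]).astype(np.int8)
        states = np.tile(col[:, None], (1, small_panel.n_sites))
        df = scan_mean_ancestry(AncestryCalls(states, small_panel))
        assert df["mean"][0] == pytest.approx((2 * 54 + 109) / (2 * 163))

    def test_sparse_sites_masked(self, small_panel):
        states = np.ones((10, small_panel.n_sites), dtype=np.int8)
        states[:6, 0] = -1  # 60% missing at site 0
        df = scan_mean_ancestry(AncestryCalls(states, small_panel))
        assert np.isnan(df["mean"][0]) and df["mean"][1] == 0.5

    def test_empty_matrix_rejected(self, small_panel):
        with pytest.raises(ValueError):
            scan_mean_ancestry(
                AncestryCalls(np.empty((0, small_panel.n_sites), dtype=np.int8),
                              small_panel)
            )


class TestEnvelope:
    def test_symmetric_about_half(self, small_panel):
        env = null_envelope(80, small_panel, n_sim=150, seed=100)
        assert env.lower == pytest.approx(1.0 - env.upper, abs=1e-12)
        assert env.lower < 0.5 < env.upper

    def test_half_width_shrinks_with_sample_size(self, small_panel):
        env40 = null_envelope(40, small_panel, n_sim=150, seed=101)
        env160 = null_envelope(160, small_panel, n_sim=150, seed=102)
        ratio = (env40.upper - 0.5) / (env160.upper - 0.5)
        assert 1.5 < ratio < 2.6  # ~ sqrt(160/40) = 2 up to Monte-Carlo noise

    def test_planted_lethal_locus_breaches_envelope(self, small_panel):
        locus = 20
        f2 = simulate_f2(small_panel, 163, [(locus, SelectionParams(1.0, 0.0))],
                         seed=103)
        df = scan_mean_ancestry(perfect_calls(f2))
        env = null_envelope(163, small_panel, n_sim=200, seed=104)
        assert df["mean"][locus] > env.upper

    def test_family_wise_calibration(self):
        panel = make_panel(3, 40, 1.0, seed=105)
        env = null_envelope(60, panel, n_sim=300, q=0.95, seed=106)
        breaches = 0
        n_rep = 100
        rng = np.random.default_rng(107)
        for _ in range(n_rep):
            f2 = simulate_f2(panel, 60, seed=rng)
            mean = f2.dosage().mean(axis=0) / 2.0
            breaches += bool((mean < env.lower).any() or (mean > env.upper).any())
        # expect ~5 breaches of 100 at q=0.95
        assert breaches <= 15

    def test_requires_enough_simulations(self, small_panel):
        with pytest.raises(ValueError):
            null_envelope(40, small_panel, n_sim=10, seed=1)


class TestLDInterval:
    def test_identical_columns_full_span(self):
        panel = make_panel(1, 10, 0.2, seed=110, bp_per_morgan=3e6)
        col = np.tile(
            np.concatenate([np.full(30, 2), np.full(60, 1), np.full(30, 0)]),
            (panel.n_sites, 1),
        ).T.astype(np.int8)
        calls = AncestryCalls(col, panel)
        cfg = LDConfig(window_bp=1, r2_threshold=0.8)
        peak = int(panel.pos_bp[5])
        c, s, e = ld_interval(calls, "chr1", peak, cfg)
        assert (s, e) == (int(panel.pos_bp[0]), int(panel.pos_bp[-1]))

    def test_interval_shrinks_with_map_distance(self):
        dense = make_panel(1, 21, 0.2, seed=111)   # 1 cM between sites
        sparse = make_panel(1, 21, 4.0, seed=112)  # 20 cM between sites
        spans = {}
        for name, panel in (("dense", dense), ("sparse", sparse)):
            f2 = simulate_f2(panel, 300, seed=113)
            calls = perfect_calls(f2)
            cfg = LDConfig(window_bp=1, r2_threshold=0.8)
            peak = int(panel.pos_bp[10])
            _, s, e = ld_interval(calls, "chr1", peak, cfg)
            idx = np.searchsorted(panel.pos_bp, [s, e])
            spans[name] = idx[1] - idx[0]
        assert spans["dense"] > spans["sparse"]
        assert spans["sparse"] == 0  # adjacent sites at 20 cM are below R^2=0.8

    def test_never_crosses_chromosome_boundary(self):
        panel = make_panel(2, 15, 0.05, seed=114)  # tightly linked chromosomes
        f2 = simulate_f2(panel, 200, seed=115)
        calls = perfect_calls(f2)
        cfg = LDConfig(window_bp=1, r2_threshold=0.5)
        sl = panel.chrom_slice("chr1")
        peak = int(panel.pos_bp[sl.stop - 1])  # last site of chr1
        c, s, e = ld_interval(calls, "chr1", peak, cfg)
        assert e <= int(panel.pos_bp[sl.stop - 1])

    def test_missing_peak_rejected(self, small_panel):
        f2 = simulate_f2(small_panel, 30, seed=116)
        with pytest.raises(ValueError):
            ld_interval(perfect_calls(f2), "chr1", 999_999_999)

    def test_thinning_keeps_one_site_per_window(self):
        panel = make_panel(1, 30, 1.0, seed=117)
        f2 = simulate_f2(panel, 20, seed=118)
        calls = perfect_calls(f2)
        kept = thin_sites(calls, window_bp=5_000_000)
        windows = (panel.pos_bp[kept] - 1) // 5_000_000
        assert len(windows) == len(set(windows.tolist()))


class TestRunScan:
    def test_planted_locus_flagged_with_interval(self, small_panel):
        locus = small_panel.chrom_slice("chr2").start + 20
        f2 = simulate_f2(small_panel, 163, [(locus, SelectionParams(1.0, 0.0))],
                         seed=120)
        res = run_scan(perfect_calls(f2), n_sim=150, seed=121,
                       ld_config=LDConfig(window_bp=1))
        sig = res.table[res.table["significant"]]
        assert (sig["chrom"] == "chr2").any()
        chr2 = res.intervals[res.intervals["chrom"] == "chr2"]
        assert len(chr2) == 1
        row = chr2.iloc[0]
        assert row["start_bp"] <= small_panel.pos_bp[locus] <= row["end_bp"]
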