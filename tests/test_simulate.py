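"""Synthetic-data generator: panels, crosses, populations, reads, broods."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hybridbarriers.genomes import AncestryGenomes
from hybridbarriers.panel import AIMPanel, make_panel
from hybridbarriers.selection import SelectionParams, hw_post_selection_freqs
from hybridbarriers.simulate import (
    MotherEmbryoSet,
    PopulationSpec,
    ReadCountMatrix,
    emit_reads,
    simulate_f2,
    simulate_mother_embryo,
    simulate_population,
)


class TestPanel:
    def test_minimal_panel(self):
        p = make_panel(1, 2, 1.0, seed=1)
        assert p.n_sites == 2
        assert p.pos_morgans[1] - p.pos_morgans[0] == pytest.approx(1.0)

    def test_positions_monotone(self):
        p = make_panel(24, 100, 1.0, seed=7)
        assert p.n_sites == 2400
        for sl in p.chrom_slices().values():
            assert np.all(np.diff(p.pos_bp[sl]) > 0)
            assert np.all(np.diff(p.pos_morgans[sl]) >= 0)

    def test_seed_determinism(self):
        a, b = (make_panel(3, 20, 1.0, seed=5) for _ in range(2))
        assert np.array_equal(a.pos_bp, b.pos_bp)
        assert np.array_equal(a.pos_morgans, b.pos_morgans)

    @pytest.mark.parametrize("bad", [(0, 5), (5, 0), (2, 1)])
    def test_rejects_nonpositive(self, bad):
        with pytest.raises(ValueError):
            make_panel(bad[0], bad[1], 1.0, seed=1)

    @given(
        n_chrom=st.integers(1, 5),
        n_sites=st.integers(2, 30),
        length=st.floats(0.1, 3.0),
        seed=st.integers(0, 1000),
    )
    def test_panel_invariants(self, n_chrom, n_sites, length, seed):
        p = make_panel(n_chrom, n_sites, length, seed=seed)
        assert p.n_chromosomes == n_chrom
        assert p.total_morgans == pytest.approx(n_chrom * length)
        d = p.site_distances()
        starts = [sl.start for sl in p.chrom_slices().values()]
        assert all(np.isinf(d[s]) for s in starts)

    def test_tsv_round_trip(self, small_panel, tmp_path):
        small_panel.to_tsv(tmp_path / "p.tsv")
        back = AIMPanel.from_tsv(tmp_path / "p.tsv")
        assert np.array_equal(back.pos_bp, small_panel.pos_bp)
        assert list(back.chrom) == list(small_panel.chrom)


class TestF2:
    def test_mendelian_means(self, small_panel):
        n = 4000
        f2 = simulate_f2(small_panel, n, seed=3)
        means = f2.dosage().mean(axis=0) / 2.0
        tol = 4.0 * np.sqrt(0.125 / n)
        assert np.all(np.abs(means - 0.5) < tol)

    def test_recessive_lethal_ratios(self, small_panel):
        locus = 10
        f2 = simulate_f2(
            small_panel, 3000, [(locus, SelectionParams(1.0, 0.0))], seed=4
        )
        dose = f2.dosage()[:, locus]
        assert not (dose == 0).any()  # no homozygous-birchmanni survivors
        ratio = (dose == 2).sum() / (dose == 1).sum()
        assert ratio == pytest.approx(0.5, abs=0.07)  # CC : BC = 1 : 2

    def test_lethal_locus_always_distorts_at_n163(self, small_panel):
        f2 = simulate_f2(small_panel, 163, [(5, SelectionParams(1.0, 0.0))], seed=5)
        dose = f2.dosage()[:, 5]
        counts = np.array([(dose == 2).sum(), (dose == 1).sum(), (dose == 0).sum()])
        expected = 163 * np.array([0.25, 0.5, 0.25])
        chi2 = ((counts - expected) ** 2 / expected).sum()
        # the empty BB class alone contributes 163/4 = 40.75 > 5.99
        assert chi2 > 5.99

    def test_selection_arithmetic_matches_closed_form(self):
        panel = make_panel(1, 10, 0.5, seed=2)
        par = SelectionParams(0.5, 0.5)
        f2 = simulate_f2(panel, 30_000, [(4, par)], seed=6)
        dose = f2.dosage()[:, 4]
        emp = np.array([(dose == 2).mean(), (dose == 1).mean(), (dose == 0).mean()])
        assert emp == pytest.approx(hw_post_selection_freqs(par), abs=0.012)

    def test_cortezi_mitochondria_and_tract_tiling(self, small_panel):
        f2 = simulate_f2(small_panel, 5, seed=7)
        assert (f2.mito == 1).all()
        for ind in range(5):
            tracts = f2.tracts(ind)
            for chrom, sl in small_panel.chrom_slices().items():
                for copy in (0, 1):
                    seg = sorted(
                        (t[2], t[3]) for t in tracts if t[0] == chrom and t[1] == copy
                    )
                    assert seg[0][0] == sl.start and seg[-1][1] == sl.stop
                    assert all(a[1] == b[0] for a, b in zip(seg[:-1], seg[1:]))

    def test_invalid_selection_locus(self, small_panel):
        with pytest.raises(ValueError):
            simulate_f2(small_panel, 5, [(10_000, SelectionParams(0.5, 0.5))], seed=1)

    def test_seed_reproducibility(self, small_panel):
        a = simulate_f2(small_panel, 20, seed=9)
        b = simulate_f2(small_panel, 20, seed=9)
        assert np.array_equal(a.haplotypes, b.haplotypes)


class TestPopulation:
    def test_cluster_means_match_spec(self, chapul_spec, small_panel):
        pop = simulate_population(chapul_spec, small_panel, seed=11)
        props = pop.proportions()
        c1 = props[pop.cluster == 1]
        assert c1.mean() == pytest.approx(0.019, abs=0.003)
        c2 = props[pop.cluster == 2]
        assert c2.mean() == pytest.approx(0.757, abs=0.012)

    def test_degenerate_clusters_are_exact(self, small_panel):
        spec = PopulationSpec(mu1=0.2, sd1=0.0, mu2=0.8, sd2=0.0, w1=0.5, n=40)
        pop = simulate_population(spec, small_panel, seed=12)
        assert set(np.round(pop.target_proportion, 10)) <= {0.2, 0.8}

    def test_mitochondria_follow_cluster(self, chapul_spec, small_panel):
        pop = simulate_population(chapul_spec, small_panel, seed=13)
        assert np.array_equal(pop.mito, (pop.cluster == 2).astype(np.int8))

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            PopulationSpec(mu1=0.8, mu2=0.2)
        with pytest.raises(ValueError):
            PopulationSpec(w1=1.0)


class TestReads:
    def test_poisson_zero_fraction_at_depth_one(self, small_panel):
        f2 = simulate_f2(small_panel, 200, seed=14)
        rc = emit_reads(f2, mean_depth=1.0, seed=15)
        zero = (rc.depth() == 0).mean()
        assert zero == pytest.approx(np.exp(-1.0), abs=0.01)

    def test_noiseless_high_depth_limit(self, small_panel):
        f2 = simulate_f2(small_panel, 20, seed=16)
        rc = emit_reads(f2, mean_depth=400.0, error_rate=0.0, seed=17)
        frac = rc.reads_cortezi / rc.depth()
        dose = f2.dosage()
        assert np.allclose(frac[dose == 0], 0.0)
        assert np.allclose(frac[dose == 2], 1.0)
        assert np.abs(frac[dose == 1] - 0.5).max() < 0.15

    def test_determinism_and_round_trip(self, small_panel, tmp_path):
        f2 = simulate_f2(small_panel, 10, seed=18)
        a = emit_reads(f2, 1.0, 0.001, seed=19)
        b = emit_reads(f2, 1.0, 0.001, seed=19)
        assert np.array_equal(a.reads_cortezi, b.reads_cortezi)
        a.to_tsv(tmp_path / "c.tsv")
        back = ReadCountMatrix.from_tsv(tmp_path / "c.tsv", small_panel)
        assert np.array_equal(back.reads_birchmanni, a.reads_birchmanni)

    def test_parameter_validation(self, small_panel):
        f2 = simulate_f2(small_panel, 2, seed=20)
        with pytest.raises(ValueError):
            emit_reads(f2, mean_depth=0.0)
        with pytest.raises(ValueError):
            emit_reads(f2, mean_depth=1.0, error_rate=0.7)


class TestMotherEmbryo:
    def test_complete_assortment_keeps_embryos_near_mothers(self, chapul_spec):
        pairs = simulate_mother_embryo(chapul_spec, 1.0, n_mothers=49,
                                       embryos_per_mother=2, seed=21)
        for i, brood in enumerate(pairs.embryo_props):
            assert np.abs(brood - pairs.mother_props[i]).max() < 0.1

    def test_random_mating_cross_cluster_difference(self, chapul_spec):
        pairs = simulate_mother_embryo(chapul_spec, 0.0, n_mothers=800,
                                       embryos_per_mother=1, seed=22)
        diffs = np.concatenate(
            [b - m for m, b in zip(pairs.mother_props, pairs.embryo_props)]
        )
        # (0.757 - 0.019) / 2 = 0.369 expected cross-cluster shift
        assert np.abs(diffs).mean() == pytest.approx(0.369, abs=0.01)

    def test_noise_off_gives_exact_midparent(self, chapul_spec):
        pairs = simulate_mother_embryo(
            chapul_spec, 1.0, n_mothers=5, embryos_per_mother=3,
            segregation_sd_model="none", seed=23,
        )
        for brood in pairs.embryo_props:
            assert np.ptp(brood) == 0.0  # all siblings identical to midparent

    def test_truth_labels_and_validation(self, chapul_spec):
        pairs = simulate_mother_embryo(chapul_spec, 0.5, n_mothers=30, seed=24)
        truth = pairs.true_cross_cluster()
        assert truth.shape == (30,)
        with pytest.raises(ValueError):
            simulate_mother_embryo(chapul_spec, 1.5, n_mothers=3, seed=1)
        with pytest.raises(ValueError):
            MotherEmbryoSet(np.array([0.5]), np.array([1]), [np.array([])])
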