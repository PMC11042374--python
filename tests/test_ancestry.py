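"""Local ancestry HMM: posteriors, hard calls, proportions."""
import numpy as np
import pytest

from hybridbarriers.ancestry import (
    AncestryCalls,
    AncestryHMM,
    HMMConfig,
    ancestry_proportions,
    hard_call,
    infer_posteriors,
)
from hybridbarriers.panel import AIMPanel, make_panel
from hybridbarriers.simulate import ReadCountMatrix, emit_reads, simulate_f2

from oracles import enumerate_posteriors


def _counts(panel, b, c):
    return ReadCountMatrix(np.asarray(b)[None, :], np.asarray(c)[None, :], panel)


@pytest.fixture(scope="module")
def two_site_panel():
    return AIMPanel(np.array(["chr1", "chr1"], dtype=object),
                    np.array([1, 1_000_000]), np.array([0.0, 0.03]))


class TestPosteriors:
    def test_single_site_bayes_by_hand(self, two_site_panel):
        # 10 birchmanni reads at site 0, site 1 empty; flat stationary prior
        counts = _counts(two_site_panel, [10, 0], [0, 0])
        eps = 0.01
        post = infer_posteriors(counts, HMMConfig(error_rate=eps)).probs[0, 0]
        lik = np.array([(1 - eps) ** 10, 0.5**10, eps**10])
        prior = np.array([0.25, 0.5, 0.25])
        expected = lik * prior / (lik * prior).sum()
        assert post == pytest.approx(expected, abs=1e-10)
        assert post[0] > 0.99

    def test_no_data_returns_stationary_prior(self, two_site_panel):
        counts = _counts(two_site_panel, [0, 0], [0, 0])
        cfg = HMMConfig(admixture_prior=0.3)
        post = infer_posteriors(counts, cfg).probs[0]
        pi = np.array([0.49, 0.42, 0.09])
        assert post == pytest.approx(np.tile(pi, (2, 1)), abs=1e-12)

    def test_normalization_everywhere(self, small_panel, rng):
        f2 = simulate_f2(small_panel, 8, seed=31)
        rc = emit_reads(f2, 1.0, 0.001, seed=32)
        post = infer_posteriors(rc, HMMConfig(generations=2.0))
        assert np.allclose(post.probs.sum(axis=2), 1.0, atol=1e-9)

    @pytest.mark.parametrize("case_seed", range(6))
    def test_matches_brute_force_enumeration(self, case_seed):
        rng = np.random.default_rng(1000 + case_seed)
        n_sites = int(rng.integers(3, 7))
        pos_m = np.sort(rng.uniform(0, 0.2, n_sites))
        pos_m[0] = 0.0
        panel = AIMPanel(
            np.array(["chr1"] * n_sites, dtype=object),
            np.arange(1, n_sites + 1) * 1000,
            pos_m,
        )
        depth = rng.integers(0, 4, n_sites)
        c = np.array([rng.integers(0, d + 1) for d in depth])
        counts = _counts(panel, depth - c, c)
        cfg = HMMConfig(generations=10.0, admixture_prior=0.4, error_rate=0.02)
        post = infer_posteriors(counts, cfg).probs[0]
        oracle = enumerate_posteriors(
            depth - c, c, panel.site_distances(), 10.0, 0.4, 0.02
        )
        assert post == pytest.approx(oracle, abs=1e-8)

    def test_adding_consistent_reads_is_monotone(self, two_site_panel):
        cfg = HMMConfig(error_rate=0.01)
        p0_prev = 0.0
        for n_reads in range(0, 8):
            counts = _counts(two_site_panel, [n_reads, 0], [0, 0])
            p0 = infer_posteriors(counts, cfg).probs[0, 0, 0]
            assert p0 >= p0_prev - 1e-12
            p0_prev = p0

    def test_dimension_mismatch_rejected(self, small_panel, two_site_panel):
        with pytest.raises(ValueError):
            ReadCountMatrix(np.zeros((1, 3)), np.zeros((1, 3)), two_site_panel)


class TestHardCalls:
    def test_threshold_rules(self, two_site_panel):
        from hybridbarriers.ancestry import AncestryPosteriorMatrix

        probs = np.array([[[0.95, 0.04, 0.01], [0.5, 0.4, 0.1]]])
        post = AncestryPosteriorMatrix(probs, two_site_panel, np.zeros(1))
        calls = hard_call(post, 0.9)
        assert calls.states[0, 0] == 0
        assert calls.states[0, 1] == -1  # no state above 0.9

    def test_tie_at_threshold_not_called(self, two_site_panel):
        from hybridbarriers.ancestry import AncestryPosteriorMatrix

        probs = np.array([[[0.9, 0.05, 0.05], [0.91, 0.05, 0.04]]])
        post = AncestryPosteriorMatrix(probs, two_site_panel, np.zeros(1))
        states = hard_call(post, 0.9).states[0]
        assert states[0] == -1 and states[1] == 0

    @pytest.mark.parametrize("bad", [0.2, 1.0001, 1 / 3])
    def test_threshold_validation(self, two_site_panel, bad):
        from hybridbarriers.ancestry import AncestryPosteriorMatrix

        post = AncestryPosteriorMatrix(
            np.full((1, 2, 3), 1 / 3), two_site_panel, np.zeros(1)
        )
        with pytest.raises(ValueError):
            hard_call(post, bad)

    def test_all_heterozygous_proportion_half(self, two_site_panel):
        calls = AncestryCalls(np.ones((3, 2), dtype=np.int8), two_site_panel)
        assert calls.proportions() == pytest.approx([0.5, 0.5, 0.5])


class TestProportions:
    def test_hand_counted_mixture(self):
        panel = make_panel(1, 20, 1.0, seed=40)
        states = np.full((1, 20), -1, dtype=np.int8)
        states[0, :10] = 2
        states[0, 10:15] = 1
        states[0, 15:20] = 0
        calls = AncestryCalls(states, panel)
        df = ancestry_proportions(calls)
        assert df["proportion"][0] == pytest.approx(25 / 40)

    def test_all_cortezi_and_missing_flagged(self):
        panel = make_panel(1, 4, 1.0, seed=41)
        states = np.array([[2, 2, 2, 2], [-1, -1, -1, -1]], dtype=np.int8)
        df = ancestry_proportions(AncestryCalls(states, panel))
        assert df["proportion"][0] == 1.0
        assert bool(df["no_calls"][1]) and np.isnan(df["proportion"][1])

    def test_empty_matrix_rejected(self, two_site_panel):
        calls = AncestryCalls(np.empty((0, 2), dtype=np.int8), two_site_panel)
        with pytest.raises(ValueError):
            ancestry_proportions(calls)


@pytest.fixture(scope="module")
def f2_run():
    panel = make_panel(2, 500, 1.0, seed=50)
    f2 = simulate_f2(panel, 40, seed=51)
    rc = emit_reads(f2, mean_depth=1.0, error_rate=0.001, seed=52)
    hmm = AncestryHMM(generations=2.0)
    post = hmm.fit(rc).predict_proba(rc)
    calls = hard_call(post, 0.9)
    return f2, post, calls


class TestSimulatedAccuracy:
    def test_hard_call_error_below_one_percent(self, f2_run):
        f2, _, calls = f2_run
        truth = f2.dosage()
        called = calls.called()
        assert called.mean() > 0.5
        err = (calls.states[called] != truth[called]).mean()
        assert err < 0.01

    def test_posterior_calibration_in_marginal_band(self, f2_run):
        f2, post, _ = f2_run
        truth = f2.dosage()
        best = post.probs.argmax(axis=2)
        best_p = post.probs.max(axis=2)
        band = (best_p >= 0.9) & (best_p <= 0.95)
        if band.sum() >= 50:
            acc = (best[band] == truth[band]).mean()
            assert acc >= 0.85

    def test_calls_tsv_round_trip(self, f2_run, tmp_path):
        _, _, calls = f2_run
        calls.to_tsv(tmp_path / "calls.tsv")
        back = AncestryCalls.from_tsv(tmp_path / "calls.tsv", calls.panel)
        assert np.array_equal(back.states, calls.states)


class TestEstimatorAPI:
    def test_get_set_params(self):
        hmm = AncestryHMM()
        params = hmm.get_params()
        assert params["threshold"] == 0.9
        hmm.set_params(generations=2.0, estimate_prior=True)
        assert hmm.generations == 2.0
        with pytest.raises(ValueError):
            hmm.set_params(bogus=1)

    def test_estimated_prior_pre_pass(self, small_panel):
        f2 = simulate_f2(small_panel, 4, seed=60)
        rc = emit_reads(f2, 2.0, 0.001, seed=61)
        hmm = AncestryHMM(generations=2.0, estimate_prior=True).fit(rc)
        assert hmm.individual_priors_.shape == (4,)
        calls = hmm.predict(rc)
        assert calls.states.shape == (4, small_panel.n_sites)
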