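"""Discriminatory statistics, panel construction and assignment likelihoods."""

import math

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import beta as beta_dist

from caprapop import panel as pn
from caprapop.io import MISSING
from caprapop.simulate import SimulationConfig, simulate_genotypes
from conftest import make_dataset


def rosenberg_in_oracle(p1, p2):
    """Direct evaluation of the informativeness formula for K=2, biallelic."""
    total = 0.0
    for q1, q2 in ((p1, p2), (1 - p1, 1 - p2)):
        qbar = (q1 + q2) / 2
        term = 0.0 if qbar == 0 else -qbar * math.log(qbar)
        for q in (q1, q2):
            if q > 0:
                term += 0.5 * q * math.log(q)
        total += term
    return total


class TestDeltaAndIn:
    def test_delta_values(self):
        assert pn.delta_stat(0.3, 0.3) == 0
        assert pn.delta_stat(1.0, 0.0) == 1
        assert pn.delta_stat(0.8, 0.3) == pytest.approx(0.5)

    def test_in_zero_for_identical_freqs(self):
        freqs = np.array([[0.3, 0.7], [0.3, 0.7]])
        np.testing.assert_allclose(pn.informativeness_in(freqs), 0.0, atol=1e-12)

    def test_in_fixed_difference_is_ln2(self):
        freqs = np.array([[1.0], [0.0]])
        assert pn.informativeness_in(freqs)[0] == pytest.approx(math.log(2),
                                                                rel=1e-12)

    def test_in_matches_direct_oracle(self):
        assert pn.informativeness_in(np.array([[0.9], [0.5]]))[0] == \
            pytest.approx(rosenberg_in_oracle(0.9, 0.5), rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_in_nonnegative_random_grid(self, seed):
        rng = np.random.default_rng(seed)
        freqs = rng.random((2, 50))
        assert (pn.informativeness_in(freqs) >= 0).all()


class TestPanels:
    def test_percentile_panel_size(self):
        rng = np.random.default_rng(0)
        theta = rng.random(1000)
        ids = [f"m{i}" for i in range(1000)]
        panel, thr = pn.fst_percentile_panel(theta, ids, q=0.995)
        assert len(panel) in (5, 6)
        assert all(theta[int(i[1:])] >= thr for i in panel)

    def test_all_equal_theta_returns_everything(self):
        theta = np.full(300, 0.2)
        ids = [f"m{i}" for i in range(300)]
        panel, thr = pn.fst_percentile_panel(theta, ids)
        assert len(panel) == 300 and thr == pytest.approx(0.2)

    def test_concordant_metrics_intersection_is_top_n(self, two_pop_f02):
        ds, _ = two_pop_f02
        scores = pn.panel_scores(ds).table
        # build per-metric top-200 sets; the tres panel must equal their
        # intersection exactly
        sets = [set(scores.loc[scores[f"rank_{c}"] <= 200, "snp_id"])
                for c in ("delta", "theta", "In")]
        assert pn.tres_panel(ds) == sets[0] & sets[1] & sets[2]

    def test_independent_random_metrics_rarely_intersect(self):
        rng = np.random.default_rng(1)
        m, top = 10_000, 200
        hits = []
        for _ in range(20):
            sets = [set(rng.choice(m, size=top, replace=False)) for _ in range(3)]
            hits.append(len(sets[0] & sets[1] & sets[2]))
        # expectation m*(top/m)^3 = 0.08 << 1
        assert np.mean(hits) < 1.0

    def test_split_deterministic_and_stratified(self, two_pop_f02):
        ds, _ = two_pop_f02
        tr1, te1 = pn.stratified_split(ds, seed=5)
        tr2, te2 = pn.stratified_split(ds, seed=5)
        assert np.array_equal(tr1, tr2) and np.array_equal(te1, te2)
        breeds = ds.breeds
        for b in set(breeds):
            assert (breeds[tr1] == b).sum() >= 2
            assert (breeds[te1] == b).sum() >= 2

    def test_consensus_subset_of_inputs(self):
        a, b, c = {"x", "y", "z"}, {"y", "z", "w"}, {"z", "y"}
        venn = pn.consensus_panel(a, b, c)
        assert venn["consensus"] == {"y", "z"}
        assert venn["consensus"] <= a and venn["consensus"] <= b
        assert venn["three_way"] == 2 and venn["fst_and_tres_all"] == 2

    def test_disjoint_sets_empty(self):
        venn = pn.consensus_panel({"a"}, {"b"}, {"c"})
        assert venn["consensus"] == set()


class TestLikelihoods:
    def test_frequency_single_het_hand_value(self):
        ll = pn.likelihood_frequency(np.array([1], dtype=np.int8),
                                     np.array([0.5]))
        assert ll == pytest.approx(math.log10(0.5), rel=1e-12)

    def test_zero_freq_substitution(self):
        # genotype carries an allele unseen in the breed -> freq floor 0.01
        ll = pn.likelihood_frequency(np.array([2], dtype=np.int8),
                                     np.array([0.0]))
        assert ll == pytest.approx(math.log10(0.01**2), rel=1e-12)

    def test_likelihood_decreases_with_panel_size(self):
        p = np.full(10, 0.5)
        lls = [pn.likelihood_frequency(np.ones(k, dtype=np.int8), p[:k])
               for k in range(1, 11)]
        assert all(b < a for a, b in zip(lls, lls[1:]))

    def test_bayesian_quadrature_oracle(self):
        # counts 3 A, 1 B; genotype BB; Dirichlet(1/2,1/2) prior
        ll = pn.likelihood_bayesian(np.array([2], dtype=np.int8),
                                    counts_b=np.array([1.0]),
                                    counts_total=np.array([4.0]))
        post = beta_dist(1 + 0.5, 3 + 0.5)   # posterior of freq(B)
        want, _ = integrate.quad(lambda q: q**2 * post.pdf(q), 0, 1)
        assert 10**ll == pytest.approx(want, rel=1e-9)
        assert 10**ll == pytest.approx(0.125, rel=1e-12)

    def test_bayesian_smoothing_positive_for_unseen_allele(self):
        ll = pn.likelihood_bayesian(np.array([2], dtype=np.int8),
                                    counts_b=np.array([0.0]),
                                    counts_total=np.array([100.0]))
        assert np.isfinite(ll) and 10**ll > 0

    def test_bayesian_converges_to_frequency_at_large_counts(self):
        n = 10_000
        p = 0.37
        geno = np.array([1, 2, 0], dtype=np.int8)
        nb = np.full(3, p * 2 * n)
        tot = np.full(3, 2.0 * n)
        lb = pn.likelihood_bayesian(geno, nb, tot)
        lf = pn.likelihood_frequency(geno, np.full(3, p))
        assert lb == pytest.approx(lf, abs=1e-3)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            pn.likelihood_frequency(np.array([MISSING], dtype=np.int8),
                                    np.array([0.5]))


class TestExclusionAndAssignment:
    def test_modal_genotype_high_p(self):
        rng = np.random.default_rng(3)
        freqs = rng.uniform(0.05, 0.3, 40)
        modal = (freqs > 0.5).astype(np.int8) * 2  # most likely genotype
        ll = pn.likelihood_frequency(modal, freqs)
        p = pn.monte_carlo_exclusion(ll, freqs, n_sim=500, seed=1)
        assert p > 0.5

    def test_exclusion_p_deterministic(self):
        freqs = np.full(20, 0.3)
        ll = pn.likelihood_frequency(np.ones(20, dtype=np.int8), freqs)
        a = pn.monte_carlo_exclusion(ll, freqs, n_sim=300, seed=7)
        b = pn.monte_carlo_exclusion(ll, freqs, n_sim=300, seed=7)
        assert a == b and 0 < a <= 1

    def test_identical_breeds_probability_half(self):
        rng = np.random.default_rng(4)
        block = rng.binomial(2, 0.5, size=(10, 30)).astype(np.int8)
        d = np.vstack([block, block])
        ds = make_dataset(d, breeds=["B1"] * 10 + ["B2"] * 10)
        recs = pn.assign_and_detect_migrants(ds, leave_one_out=False)
        np.testing.assert_allclose(recs["prob_B1"], 0.5, atol=1e-9)

    def test_migrant_statistic_zero_when_home_is_argmax(self, two_pop_f02):
        ds, _ = two_pop_f02
        pure = ds.subset(sample_idx=np.arange(80))
        recs = pn.assign_and_detect_migrants(pure)
        home_is_max = recs["assigned_breed"] == recs["true_breed"]
        assert (recs.loc[home_is_max, "migrant_statistic"] == 0).all()
        assert (recs["migrant_statistic"] <= 0).all()

    def test_assignment_probs_sum_to_one(self, two_pop_f02):
        ds, _ = two_pop_f02
        sub = ds.subset(sample_idx=np.arange(0, 90, 5),
                        marker_idx=np.arange(100))
        recs = pn.assign_and_detect_migrants(sub, criterion="bayesian")
        np.testing.assert_allclose(recs["prob_POP1"] + recs["prob_POP2"], 1.0,
                                   atol=1e-12)

    def test_accuracy_nondecreasing_in_fst(self):
        accs = []
        for f in (0.01, 0.05, 0.2):
            cfg = SimulationConfig(n_snps=800, samples_per_pop=(30, 30),
                                   target_fst=f, seed=77)
            ds, _ = simulate_genotypes(cfg)
            tt = pn.tres_train_test(ds, seed=7, top_n=100)
            accs.append(tt.test_accuracy)
        assert accs == sorted(accs)
        assert accs[-1] == 1.0
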