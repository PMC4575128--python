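"""Admixture-model Gibbs sampler, ln P(D) estimator, Evanno Delta-K,
run alignment and cluster summaries."""

import math

import numpy as np
import pytest

import ssrdiv as sd
from ssrdiv.admixture import FrequencyModel


def fixed_diff_matrix(n_per_pop=15, n_loci=20):
    """Two populations with fixed allele differences at every locus."""
    calls_a = np.full((n_per_pop, n_loci, 2), 100)
    calls_b = np.full((n_per_pop, n_loci, 2), 104)
    calls = np.vstack([calls_a, calls_b])
    inds = [f"i{k}" for k in range(2 * n_per_pop)]
    return sd.AlleleMatrix(inds, [f"L{k}" for k in range(n_loci)], calls)


class TestGibbsSampler:
    def test_k1_gives_all_ones_ancestry(self, tiny_matrix):
        r = sd.gibbs_admixture(
            tiny_matrix, sd.AdmixtureConfig(K=1, burnin=5, iterations=10, seed=0)
        )
        assert np.array_equal(r.Q, np.ones((2, 1)))

    def test_two_fixed_populations_recovered(self):
        m = fixed_diff_matrix()
        r = sd.gibbs_admixture(
            m, sd.AdmixtureConfig(K=2, burnin=200, iterations=400, seed=1)
        )
        assert r.Q.max(axis=1).mean() >= 0.95
        # members of the same population share their dominant cluster
        assert len(set(r.Q[:15].argmax(axis=1))) == 1
        assert len(set(r.Q[15:].argmax(axis=1))) == 1

    def test_deterministic_given_seed(self, tiny_matrix):
        cfg = sd.AdmixtureConfig(K=2, burnin=10, iterations=20, seed=3)
        r1 = sd.gibbs_admixture(tiny_matrix, cfg)
        r2 = sd.gibbs_admixture(tiny_matrix, cfg)
        assert np.array_equal(r1.Q, r2.Q)
        assert np.array_equal(r1.loglik_trace, r2.loglik_trace)

    def test_q_rows_remain_simplex_valued(self, small_panel):
        m, _, _, _ = small_panel
        r = sd.gibbs_admixture(
            m, sd.AdmixtureConfig(K=3, burnin=20, iterations=50, seed=5)
        )
        assert np.allclose(r.Q.sum(axis=1), 1.0, atol=1e-9)
        assert (r.Q >= 0).all()
        n_alleles = [len(a) for a in r.P.allele_labels]
        for l, na in enumerate(n_alleles):
            assert np.allclose(r.P.probs[:, l, :na].sum(axis=1), 1.0, atol=1e-9)
            assert np.allclose(r.P.probs[:, l, na:], 0.0)

    def test_constant_alpha_unless_update_enabled(self, small_panel):
        m, _, _, _ = small_panel
        r = sd.gibbs_admixture(
            m, sd.AdmixtureConfig(K=2, burnin=10, iterations=20, seed=2)
        )
        assert np.all(r.alpha_trace == r.alpha_trace[0])
        r2 = sd.gibbs_admixture(
            m,
            sd.AdmixtureConfig(
                K=2, burnin=50, iterations=100, update_alpha=True, seed=2
            ),
        )
        assert np.unique(r2.alpha_trace).size > 1

    def test_correlated_frequency_prior_runs(self, small_panel):
        m, _, _, _ = small_panel
        r = sd.gibbs_admixture(
            m,
            sd.AdmixtureConfig(
                K=2, burnin=20, iterations=40, freq_model_f=0.2, seed=4
            ),
        )
        assert np.isfinite(r.lnPD)

    def test_k_larger_than_n_rejected(self, tiny_matrix):
        with pytest.raises(sd.DataError, match="exceed"):
            sd.gibbs_admixture(
                tiny_matrix, sd.AdmixtureConfig(K=5, burnin=2, iterations=2)
            )


class TestLogLikelihood:
    def test_single_locus_homozygote_closed_form(self):
        m = sd.AlleleMatrix(["i1"], ["L1"], np.array([[[100, 100]]]))
        P = FrequencyModel(["L1"], [[100, 104]], np.array([[[0.5, 0.5]]]))
        ll = sd.log_likelihood(m, np.array([[1.0]]), P)
        assert ll == pytest.approx(2 * math.log(0.5))

    def test_matches_brute_force_enumeration(self):
        m = sd.AlleleMatrix(
            ["i1", "i2"],
            ["L1", "L2"],
            np.array([[[100, 104], [200, 200]], [[104, 104], [200, 204]]]),
        )
        rng = np.random.default_rng(0)
        K = 2
        Q = rng.dirichlet([1, 1], size=2)
        probs = np.zeros((K, 2, 2))
        for k in range(K):
            for l in range(2):
                probs[k, l] = rng.dirichlet([1, 1])
        P = FrequencyModel(["L1", "L2"], [[100, 104], [200, 204]], probs)
        labels = {(0, a): i for i, a in enumerate([100, 104])}
        labels |= {(1, a): i for i, a in enumerate([200, 204])}
        brute = 0.0
        for i in range(2):
            for l in range(2):
                for copy in range(2):
                    a = labels[(l, int(m.calls[i, l, copy]))]
                    brute += math.log(
                        sum(Q[i, k] * probs[k, l, a] for k in range(K))
                    )
        assert sd.log_likelihood(m, Q, P) == pytest.approx(brute, abs=1e-12)

    def test_invariant_under_cluster_relabeling(self):
        m = fixed_diff_matrix(n_per_pop=4, n_loci=5)
        rng = np.random.default_rng(1)
        Q = rng.dirichlet([1, 1, 1], size=8)
        probs = rng.dirichlet([1, 1], size=(3, 5))
        P = FrequencyModel(
            [f"L{k}" for k in range(5)], [[100, 104]] * 5, probs
        )
        perm = np.array([2, 0, 1])
        ll1 = sd.log_likelihood(m, Q, P)
        ll2 = sd.log_likelihood(m, Q[:, perm], P.permuted(perm))
        assert ll1 == pytest.approx(ll2, abs=1e-12)

    def test_zero_probability_flags_minus_infinity(self):
        m = sd.AlleleMatrix(["i1"], ["L1"], np.array([[[100, 104]]]))
        P = FrequencyModel(["L1"], [[100, 104]], np.array([[[1.0, 0.0]]]))
        assert sd.log_likelihood(m, np.array([[1.0]]), P) == -np.inf


class TestLnPDEstimator:
    def test_constant_trace_returns_the_constant(self):
        assert sd.estimate_lnPD(np.full(10, -42.0)) == -42.0

    def test_two_point_trace_hand_arithmetic(self):
        assert sd.estimate_lnPD(np.array([-10.0, -12.0])) == pytest.approx(-12.0)

    def test_noise_lowers_the_estimate(self):
        rng = np.random.default_rng(0)
        base = np.full(500, -100.0)
        noisy = base + rng.normal(0, 3.0, size=500)
        assert sd.estimate_lnPD(noisy) < sd.estimate_lnPD(base)

    def test_converges_to_mu_minus_half_variance(self):
        rng = np.random.default_rng(1)
        trace = rng.normal(-50.0, 2.0, size=200_000)
        assert sd.estimate_lnPD(trace) == pytest.approx(-52.0, abs=0.1)

    def test_short_trace_rejected(self):
        with pytest.raises(sd.DataError, match="length"):
            sd.estimate_lnPD(np.array([-1.0]))


class TestEvannoDeltaK:
    def _runs(self, means, sd_=1.0, n=2):
        # symmetric +/- offsets give the exact target mean and sd
        off = sd_ / math.sqrt(2) if n == 2 else sd_
        return {
            k: [mu - off, mu + off] for k, mu in zip(range(1, len(means) + 1), means)
        }

    def test_hand_arithmetic_example(self):
        table = sd.evanno_delta_k(self._runs([-100.0, -80.0, -75.0, -74.0]))
        t = table.set_index("K")
        assert t.loc[2, "delta_k"] == pytest.approx(15.0)
        assert t.loc[3, "delta_k"] == pytest.approx(4.0)
        assert table.attrs["best_k"] == 2

    def test_linear_lnpd_gives_zero_delta_k(self):
        table = sd.evanno_delta_k(self._runs([-100.0, -90.0, -80.0, -70.0]))
        assert np.allclose(table["delta_k"].dropna(), 0.0, atol=1e-9)

    def test_delta_k_scales_inversely_with_sd(self):
        t1 = sd.evanno_delta_k(self._runs([-100.0, -80.0, -75.0, -74.0], sd_=1.0))
        t10 = sd.evanno_delta_k(self._runs([-100.0, -80.0, -75.0, -74.0], sd_=10.0))
        d1 = t1.set_index("K")["delta_k"].dropna()
        d10 = t10.set_index("K")["delta_k"].dropna()
        assert np.allclose(d1.values, 10.0 * d10.values)

    def test_boundary_k_undefined(self):
        table = sd.evanno_delta_k(self._runs([-10.0, -9.0, -8.0])).set_index("K")
        assert math.isnan(table.loc[1, "delta_k"])
        assert math.isnan(table.loc[3, "delta_k"])

    def test_zero_sd_rejected(self):
        runs = {1: [-10.0, -10.0], 2: [-9.0, -9.0], 3: [-8.0, -8.0]}
        with pytest.raises(sd.DataError, match="sd"):
            sd.evanno_delta_k(runs)

    def test_non_consecutive_k_rejected(self):
        runs = {1: [-10.0, -9.0], 3: [-8.0, -7.0], 4: [-6.0, -5.0]}
        with pytest.raises(sd.DataError, match="consecutive"):
            sd.evanno_delta_k(runs)


class TestAlignment:
    def test_permuted_duplicate_realigned_to_identity(self):
        m = fixed_diff_matrix(n_per_pop=6, n_loci=10)
        r = sd.gibbs_admixture(
            m, sd.AdmixtureConfig(K=2, burnin=50, iterations=100, seed=7)
        )
        perm = np.array([1, 0])
        r_perm = sd.AdmixtureResult(
            Q=r.Q[:, perm],
            P=r.P.permuted(perm),
            alpha_trace=r.alpha_trace,
            loglik_trace=r.loglik_trace,
            lnPD=r.lnPD,
            K=r.K,
            seed=r.seed,
            individuals=r.individuals,
        )
        aligned = sd.align_runs([r, r_perm])
        assert np.allclose(aligned[1].Q, r.Q)

    def test_independent_runs_agree_after_alignment(self):
        m = fixed_diff_matrix()
        runs = [
            sd.gibbs_admixture(
                m, sd.AdmixtureConfig(K=2, burnin=150, iterations=300, seed=s)
            )
            for s in range(3)
        ]
        aligned = sd.align_runs(runs)
        for r in aligned[1:]:
            rmse = float(np.sqrt(((r.Q - aligned[0].Q) ** 2).mean()))
            assert rmse < 0.05

    def test_k1_alignment_is_noop(self, tiny_matrix):
        r = sd.gibbs_admixture(
            tiny_matrix, sd.AdmixtureConfig(K=1, burnin=5, iterations=10, seed=0)
        )
        aligned = sd.align_runs([r, r])
        assert np.array_equal(aligned[1].Q, r.Q)

    def test_k_mismatch_rejected(self, tiny_matrix):
        r1 = sd.gibbs_admixture(
            tiny_matrix, sd.AdmixtureConfig(K=1, burnin=5, iterations=10, seed=0)
        )
        r2 = sd.gibbs_admixture(
            tiny_matrix, sd.AdmixtureConfig(K=2, burnin=5, iterations=10, seed=0)
        )
        with pytest.raises(sd.DataError, match="same K"):
            sd.align_runs([r1, r2])


class TestClusterSummaries:
    def test_identical_clusters_have_zero_divergence(self):
        probs = np.tile(np.array([[0.25, 0.75], [0.6, 0.4]]), (2, 1, 1))
        P = FrequencyModel(["L1", "L2"], [[1, 2], [1, 2]], probs)
        assert np.allclose(sd.cluster_divergence(P), 0.0)

    def test_fixed_cluster_has_zero_heterozygosity(self):
        probs = np.array([[[1.0, 0.0], [1.0, 0.0]]])
        P = FrequencyModel(["L1", "L2"], [[1, 2], [1, 2]], probs)
        assert sd.cluster_heterozygosity(P)[0] == 0.0

    def test_matches_brute_force_loops(self):
        rng = np.random.default_rng(5)
        K, L = 3, 6
        probs = rng.dirichlet([1, 1, 1], size=(K, L))
        P = FrequencyModel(
            [f"L{k}" for k in range(L)], [[1, 2, 3]] * L, probs
        )
        div = sd.cluster_divergence(P)
        het = sd.cluster_heterozygosity(P)
        for k in range(K):
            expected_het = np.mean(
                [1.0 - sum(probs[k, l, a] ** 2 for a in range(3)) for l in range(L)]
            )
            assert het[k] == pytest.approx(expected_het, abs=1e-12)
            for l in range(K):
                expected = np.mean(
                    [
                        0.5
                        * sum(
                            (probs[k, j, a] - probs[l, j, a]) ** 2
                            for a in range(3)
                        )
                        for j in range(L)
                    ]
                )
                assert div[k, l] == pytest.approx(expected, abs=1e-12)
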