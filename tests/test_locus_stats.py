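"""Diversity statistics: worked examples, brute-force oracles and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ssrdiv as sd
from ssrdiv.locus_stats import AlleleFrequencies, band_frequencies


def freqs(*p, locus="L", n=200):
    labels = [100 + 4 * i for i in range(len(p))]
    return AlleleFrequencies(locus, dict(zip(labels, p)), n)


@st.composite
def random_freqs(draw):
    k = draw(st.integers(min_value=1, max_value=6))
    raw = draw(
        st.lists(st.floats(0.01, 1.0), min_size=k, max_size=k)
    )
    total = sum(raw)
    return freqs(*[x / total for x in raw])


class TestAlleleFrequencies:
    def test_direct_count(self, tiny_matrix):
        f = sd.allele_frequencies(tiny_matrix, "L1")
        assert f.freqs == {150: 0.75, 156: 0.25}
        assert f.n_gene_copies == 4

    def test_monomorphic(self, tiny_matrix):
        f = sd.allele_frequencies(tiny_matrix, "L2")
        assert f.freqs == {98: 1.0}
        assert f.n_gene_copies == 2  # missing call excluded (pairwise deletion)

    def test_matches_exhaustive_tally(self):
        rng = np.random.default_rng(3)
        calls = rng.choice([100, 104, 108], size=(20, 1, 2))
        calls[rng.random(20) < 0.2] = -1
        m = sd.AlleleMatrix([f"i{k}" for k in range(20)], ["L1"], calls)
        f = sd.allele_frequencies(m, "L1")
        tally: dict[int, int] = {}
        for i in range(20):
            a, b = m.calls[i, 0]
            if a == -1:
                continue
            tally[a] = tally.get(a, 0) + 1
            tally[b] = tally.get(b, 0) + 1
        n = sum(tally.values())
        assert f.n_gene_copies == n
        for a, c in tally.items():
            assert f.freqs[a] == pytest.approx(c / n)

    def test_all_missing_locus_is_an_error(self):
        m = sd.AlleleMatrix(["i1"], ["L1"], np.array([[[-1, -1]]]))
        with pytest.raises(sd.DataError, match="L1"):
            sd.allele_frequencies(m, "L1")


class TestScalarStatistics:
    def test_gene_diversity_worked_examples(self):
        assert sd.nei_gene_diversity(freqs(0.5, 0.5)) == pytest.approx(0.5)
        assert sd.nei_gene_diversity(freqs(1.0)) == 0.0
        assert sd.nei_gene_diversity(freqs(*[0.2] * 5)) == pytest.approx(0.8)

    def test_effective_alleles_worked_examples(self):
        assert sd.effective_alleles(freqs(0.5, 0.5)) == pytest.approx(2.0)
        p, q = sd.biallelic_frequencies_for_he(0.5)
        assert sd.effective_alleles(freqs(p, q)) == pytest.approx(2.0)

    def test_shannon_worked_examples(self):
        assert sd.shannon_index(freqs(0.5, 0.5)) == pytest.approx(math.log(2))
        assert sd.shannon_index(freqs(1.0)) == 0.0
        p, q = sd.biallelic_frequencies_for_he(0.45)
        assert p == pytest.approx(0.65811, abs=1e-5)
        assert sd.round_half_up(sd.shannon_index(freqs(p, q))) == 0.64

    def test_unbiased_gene_diversity(self):
        f = freqs(0.5, 0.5, n=4)  # two diploid individuals
        assert sd.unbiased_gene_diversity(f) == pytest.approx(0.5 * 4 / 3)
        f_big = freqs(0.5, 0.5, n=2 * 10**6)
        assert sd.unbiased_gene_diversity(f_big) == pytest.approx(0.5, abs=1e-6)

    def test_observed_heterozygosity(self, tiny_matrix):
        assert sd.observed_heterozygosity(tiny_matrix, "L1") == 0.5
        assert sd.observed_heterozygosity(tiny_matrix, "L2") == 0.0

    def test_pic_closed_form(self):
        assert sd.pic(freqs(0.5, 0.5)) == pytest.approx(0.375)
        assert sd.pic(freqs(1.0)) == 0.0

    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_pic_matches_brute_force_double_sum(self, k):
        f = freqs(*[1.0 / k] * k)
        p = f.p
        brute = 1.0 - sum(x * x for x in p) - sum(
            2 * p[i] ** 2 * p[j] ** 2
            for i in range(k)
            for j in range(i + 1, k)
        )
        assert sd.pic(f) == pytest.approx(brute, abs=1e-12)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(random_freqs())
    def test_identities_on_random_frequencies(self, f):
        he = sd.nei_gene_diversity(f)
        na = f.n_alleles
        assert sd.effective_alleles(f) == pytest.approx(1.0 / (1.0 - he), abs=1e-12)
        assert 1.0 - 1e-12 <= sd.effective_alleles(f) <= na + 1e-12
        assert sd.pic(f) <= he + 1e-12
        assert he <= (na - 1) / na + 1e-12
        assert sd.shannon_index(f) <= math.log(na) + 1e-9
        assert sd.unbiased_gene_diversity(f) >= he


class TestResolvingPower:
    def _bm(self, cols):
        scores = np.array(cols).T
        bands = [("L1", 100 + 4 * j) for j in range(scores.shape[1])]
        inds = [f"i{k}" for k in range(scores.shape[0])]
        return sd.BandMatrix(inds, bands, scores)

    def test_maximally_informative_band(self):
        b = self._bm([[1, 1, 0, 0]])
        assert sd.resolving_power(b, "L1") == pytest.approx(1.0)

    def test_monomorphic_band(self):
        b = self._bm([[1, 1, 1, 1]])
        assert sd.resolving_power(b, "L1") == pytest.approx(0.0)

    def test_two_band_hand_arithmetic(self):
        b = self._bm([[1, 0, 0, 0], [1, 1, 1, 0]])  # p = 0.25 and p = 0.75
        assert sd.resolving_power(b, "L1") == pytest.approx(1.0)

    def test_all_missing_band_excluded_with_warning(self):
        b = self._bm([[1, 1, 0, 0], [-1, -1, -1, -1]])
        with pytest.warns(UserWarning, match="excluded"):
            assert sd.resolving_power(b, "L1") == pytest.approx(1.0)


class TestSummaryTables:
    def test_synthetic_panel_table_is_consistent(self, default_panel):
        m, b, pm, _ = default_panel
        df = sd.locus_summary_table(m, b, pm)
        assert len(df) == 43
        assert df.attrs["total_Na"] == df["Na"].sum()
        assert df.attrs["mean_Na"] == pytest.approx(df["Na"].mean())
        # spot-check one locus against the scalar operations
        f = sd.allele_frequencies(m, m.loci[0])
        assert df.loc[0, "He"] == pytest.approx(sd.nei_gene_diversity(f))
        assert df.loc[0, "Rp"] == pytest.approx(sd.resolving_power(b, m.loci[0]))

    def test_monomorphic_locus_summary(self):
        m = sd.AlleleMatrix(
            ["i1", "i2"], ["L1"], np.array([[[100, 100]], [[100, 100]]])
        )
        s = sd.locus_summary(m, "L1")
        assert (s.Na, s.Ne, s.I, s.He, s.PIC) == (1, 1.0, 0.0, 0.0, 0.0)

    def test_rp_absent_without_band_matrix(self, tiny_matrix):
        df = sd.locus_summary_table(tiny_matrix)
        assert df["Rp"].isna().all()

    def test_population_of_clones(self):
        calls = np.tile([[100, 100], [200, 200]], (4, 1, 1))[:, :2, :]
        m = sd.AlleleMatrix([f"i{k}" for k in range(4)], ["L1", "L2"], calls)
        pm = sd.PopulationMap({f"i{k}": "p1" for k in range(4)})
        df = sd.population_summary(m, pm)
        assert df.loc[0, "Na"] == 1.0
        assert df.loc[0, "He"] == 0.0

    def test_identical_populations_get_identical_summaries(self, tiny_matrix):
        calls = np.vstack([tiny_matrix.calls, tiny_matrix.calls])
        m = sd.AlleleMatrix(["a1", "a2", "b1", "b2"], tiny_matrix.loci, calls)
        pm = sd.PopulationMap({"a1": "p1", "a2": "p1", "b1": "p2", "b2": "p2"})
        df = sd.population_summary(m, pm).set_index("population")
        for col in ("Na", "Ne", "I", "He"):
            assert df.loc["p1", col] == pytest.approx(df.loc["p2", col])

    def test_more_diverged_and_diverse_population_ranks_higher(self):
        cfg = sd.SimConfig(
            pop_sizes=(20, 20),
            n_loci=30,
            divergence_f=(0.02, 0.8),
            seed=5,
        )
        m, _, pm, _ = sd.simulate(cfg)
        df = sd.population_summary(m, pm).set_index("population")
        # low-F population retains more ancestral diversity -> higher mean Na
        assert df.loc["pop1", "Na"] > df.loc["pop2", "Na"]

    def test_statistics_invariant_to_relabeling_and_order(self, small_panel):
        m, _, _, _ = small_panel
        f = sd.allele_frequencies(m, m.loci[0])
        # relabel alleles by an order-preserving shift; shuffle individuals
        calls = np.where(m.calls > 0, m.calls + 1000, m.calls)
        rng = np.random.default_rng(0)
        order = rng.permutation(m.n_individuals)
        m2 = sd.AlleleMatrix(
            [m.individuals[i] for i in order], m.loci, calls[order]
        )
        f2 = sd.allele_frequencies(m2, m.loci[0])
        assert sorted(f.freqs.values()) == pytest.approx(
            sorted(f2.freqs.values())
        )
        assert sd.nei_gene_diversity(f) == pytest.approx(sd.nei_gene_diversity(f2))
        assert sd.pic(f) == pytest.approx(sd.pic(f2))

    def test_duplicating_an_individual_never_increases_na(self, small_panel):
        m, _, _, _ = small_panel
        calls = np.vstack([m.calls, m.calls[:1]])
        m2 = sd.AlleleMatrix(m.individuals + ["dup"], m.loci, calls)
        for locus in m.loci[:5]:
            na1 = sd.allele_frequencies(m, locus).n_alleles
            na2 = sd.allele_frequencies(m2, locus).n_alleles
            assert na2 == na1
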