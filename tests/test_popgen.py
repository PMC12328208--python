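import numpy as np
import pandas as pd
import pytest

import _oracles as oracles
import hapscan
from hapscan.io import GenotypeLikelihoodMatrix
from hapscan.popgen import (
    diversity_summary,
    estimate_allele_frequencies,
    hard_genotype_heterozygosity,
    hudson_fst,
    mantel_test,
    nucleotide_diversity,
    sample_heterozygosity,
    tajimas_d,
    wattersons_theta,
)

# four haplotypes over ten sites, three segregating: the shared oracle fixture
HAPLOTYPES = np.array(
    [
        [0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
        [1, 0, 0, 0, 0, 0, 0, 0, 0, 0],
        [1, 1, 0, 0, 0, 0, 0, 0, 0, 0],
        [1, 1, 1, 0, 0, 0, 0, 0, 0, 0],
    ]
)


def _certain_glm(genotypes):
    """GL matrix with probability-1 triples from hard genotypes."""
    g = np.asarray(genotypes)
    gl = np.zeros(g.shape + (3,))
    for k in range(3):
        gl[..., k] = g == k
    sites = pd.DataFrame(
        {"chrom": "chr1", "pos": np.arange(1, g.shape[1] + 1), "ref": "A", "alt": "C"}
    )
    return GenotypeLikelihoodMatrix(
        sites, [f"s{i}" for i in range(g.shape[0])], gl, np.zeros(g.shape, dtype=bool)
    )


class TestFrequencyEM:
    def test_counting_with_certain_genotypes(self):
        glm = _certain_glm(np.array([[0], [0], [1], [1], [2], [2]]))
        ft = estimate_allele_frequencies(glm, np.zeros(6, dtype=int))
        assert ft.freq[0, 0] == pytest.approx(0.5, abs=1e-9)
        assert ft.n_chrom[0, 0] == 12

    def test_all_hom_minor(self):
        glm = _certain_glm(np.full((4, 2), 2))
        ft = estimate_allele_frequencies(glm, np.zeros(4, dtype=int))
        np.testing.assert_allclose(ft.freq[0], 1.0, atol=1e-9)

    def test_uninformative_site_flagged(self):
        gl = np.full((3, 1, 3), 1 / 3)
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [1], "ref": "A", "alt": "C"})
        glm = GenotypeLikelihoodMatrix(sites, ["a", "b", "c"], gl, np.zeros((3, 1), bool))
        ft = estimate_allele_frequencies(glm, np.zeros(3, dtype=int))
        assert ft.low_information[0, 0]

    def test_empty_population_rejected(self):
        glm = _certain_glm(np.array([[0], [1]]))
        with pytest.raises(ValueError, match="zero samples"):
            estimate_allele_frequencies(glm, np.zeros(2, dtype=int), ["p0", "p1"])

    def test_em_matches_truth_at_depth(self):
        cfg = hapscan.SimulationConfig(
            n_pops=2, n_samples_per_pop=50,
            contig_lengths={"chr1": 50_000}, n_sites={"chr1": 300},
            coverage=8.0, inversion=None,
        )
        truth, glm, _ = hapscan.simulate_dataset(cfg, 3)
        ft = estimate_allele_frequencies(glm, truth.pop_of_sample)
        sample_freq = np.stack(
            [truth.genotypes[truth.pop_of_sample == j].mean(axis=0) / 2 for j in range(2)]
        )
        assert np.nanmax(np.abs(ft.freq - sample_freq)) < 0.1
        assert np.nanmean(np.abs(ft.freq - sample_freq)) < 0.02


class TestDiversity:
    def test_two_haplotypes_single_difference(self):
        # one pairwise difference over ten sites -> pi = 0.1
        p = np.array([0.5] + [0.0] * 9)  # freq from the two haplotypes
        assert nucleotide_diversity(p, 2, 10) == pytest.approx(0.1)

    def test_monomorphic_pi_zero(self):
        assert nucleotide_diversity(np.zeros(5), 4, 5) == 0.0

    def test_pi_matches_pairwise_oracle(self):
        freq = HAPLOTYPES.mean(axis=0)
        expected = oracles.pairwise_pi(HAPLOTYPES, 10)
        assert nucleotide_diversity(freq, 4, 10) == pytest.approx(expected, abs=1e-10)

    def test_watterson_hand_values(self):
        assert wattersons_theta(1, 2, 10) == pytest.approx(0.1)
        assert wattersons_theta(0, 5, 10) == 0.0
        assert wattersons_theta(3, 4, 100) == pytest.approx(3 / (11 / 6 * 100), abs=1e-12)

    def test_tajima_matches_constants_oracle(self):
        freq = HAPLOTYPES.mean(axis=0)
        pi_total = nucleotide_diversity(freq, 4, 10) * 10
        expected = oracles.tajimas_d_direct(pi_total, 3, 4)
        assert tajimas_d(pi_total, 3, 4) == pytest.approx(expected, abs=1e-10)

    def test_tajima_zero_numerator(self):
        # pi*L == S/a1 -> D = 0
        n, S = 6, 4
        a1 = sum(1 / i for i in range(1, n))
        assert tajimas_d(S / a1, S, n) == pytest.approx(0.0, abs=1e-12)

    def test_tajima_undefined_without_segregating_sites(self):
        assert np.isnan(tajimas_d(0.0, 0, 10))

    def test_summary_consistency(self):
        freq = HAPLOTYPES.mean(axis=0)
        summ = diversity_summary(freq, 4, 10)
        assert summ.n_segregating == 3
        assert summ.pi == pytest.approx(oracles.pairwise_pi(HAPLOTYPES, 10), abs=1e-10)

    def test_scaling_under_window_subdivision(self):
        # aggregating two half-windows reproduces the full-window estimate
        rng = np.random.default_rng(0)
        freq = rng.uniform(0, 1, 50)
        whole = nucleotide_diversity(freq, 8, 50)
        halves = (
            nucleotide_diversity(freq[:25], 8, 25) * 25
            + nucleotide_diversity(freq[25:], 8, 25) * 25
        ) / 50
        assert whole == pytest.approx(halves, abs=1e-12)


class TestHudsonFst:
    P1 = np.array([0.2, 0.5, 0.9])
    P2 = np.array([0.1, 0.5, 0.4])
    N1 = np.array([20.0, 20.0, 20.0])
    N2 = np.array([10.0, 10.0, 10.0])

    def test_matches_hand_computation(self):
        expected = oracles.hudson_fst_direct(self.P1, self.P2, self.N1, self.N2)
        w, _ = hudson_fst(self.P1, self.P2, self.N1, self.N2)
        assert w == pytest.approx(expected, abs=1e-12)

    def test_symmetry(self):
        a = hudson_fst(self.P1, self.P2, self.N1, self.N2)
        b = hudson_fst(self.P2, self.P1, self.N2, self.N1)
        assert a == pytest.approx(b)

    def test_identical_populations_near_zero(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.1, 0.9, 2000)
        w, u = hudson_fst(p, p, 1000, 1000)
        assert abs(w) < 0.01 and abs(u) < 0.01

    def test_fixed_difference_limit(self):
        w, u = hudson_fst(np.array([1.0]), np.array([0.0]), 1e9, 1e9)
        assert w == pytest.approx(1.0, abs=1e-6)
        assert u == pytest.approx(1.0, abs=1e-6)

    def test_self_comparison_resampled_halves(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.05, 0.95, 500)
        n = 400
        p1 = rng.binomial(n, p) / n
        p2 = rng.binomial(n, p) / n
        w, _ = hudson_fst(p1, p2, n, n)
        assert abs(w) < 0.01

    def test_all_zero_denominator_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            hudson_fst(np.zeros(3), np.zeros(3), 10, 10)


class TestMantel:
    @staticmethod
    def _dist(points):
        d = np.abs(points[:, None] - points[None, :]).astype(float)
        return d

    def test_self_correlation(self):
        a = self._dist(np.array([0.0, 1.0, 3.0, 6.0, 10.0, 15.0]))
        r, p = mantel_test(a, a, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        # only a re-drawn identity permutation can tie r = 1
        assert p == pytest.approx(1 / 100, abs=0.02)

    def test_negated_matrix(self):
        a = self._dist(np.array([0.0, 1.0, 3.0, 6.0]))
        b = a.max() - a
        np.fill_diagonal(b, 0)
        r, _ = mantel_test(a, b, n_perm=9, seed=0)
        assert r == pytest.approx(-1.0)

    def test_exhaustive_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        a = self._dist(np.array([0.0, 2.0, 3.0, 7.0]))
        perm = rng.permutation(4)
        b = a[np.ix_(perm, perm)]
        r, p = mantel_test(a, b, method="exhaustive")
        r_exp, p_exp = oracles.mantel_exhaustive(a, b)
        assert r == pytest.approx(r_exp, abs=1e-12)
        assert p == pytest.approx(p_exp, abs=1e-12)

    def test_constant_matrix_rejected(self):
        a = self._dist(np.array([0.0, 1.0, 3.0]))
        b = np.ones_like(a)
        np.fill_diagonal(b, 0)
        with pytest.raises(ValueError, match="constant"):
            mantel_test(a, b)

    def test_too_small_rejected(self):
        a = np.zeros((2, 2))
        with pytest.raises(ValueError, match=">= 3"):
            mantel_test(a, a)


class TestHeterozygosity:
    def test_hard_genotype_extremes(self):
        assert hard_genotype_heterozygosity(np.ones((2, 5)))[0] == 1.0
        assert hard_genotype_heterozygosity(np.full((2, 5), 2.0))[0] == 0.0

    def test_gl_based_tracks_truth_at_depth(self):
        cfg = hapscan.SimulationConfig(
            n_pops=2, n_samples_per_pop=20,
            contig_lengths={"chr1": 50_000}, n_sites={"chr1": 400},
            coverage=30.0, error=0.001, inversion=None,
        )
        truth, glm, _ = hapscan.simulate_dataset(cfg, 7)
        pooled = truth.genotypes.mean(axis=0) / 2
        poly = (pooled > 0) & (pooled < 1)
        site_idx = np.flatnonzero(poly)
        het = sample_heterozygosity(glm, site_idx, pooled[poly])
        truth_het = (truth.genotypes[:, poly] == 1).mean(axis=1)
        assert np.max(np.abs(het - truth_het)) < 0.05

    def test_empty_region_rejected(self):
        glm = _certain_glm(np.array([[1, 1]]))
        with pytest.raises(ValueError, match="no sites"):
            sample_heterozygosity(glm, np.array([], dtype=int), np.array([]))


class TestRelabelingInvariance:
    def test_pi_theta_invariant_to_sample_order(self):
        cfg = hapscan.SimulationConfig(
            n_pops=1, n_samples_per_pop=12,
            contig_lengths={"chr1": 20_000}, n_sites={"chr1": 100},
            coverage=10.0, inversion=None,
        )
        truth, glm, _ = hapscan.simulate_dataset(cfg, 9)
        rng = np.random.default_rng(0)
        perm = rng.permutation(glm.n_samples)
        glm_p = GenotypeLikelihoodMatrix(
            glm.sites, [glm.samples[i] for i in perm], glm.gl[perm], glm.missing[perm]
        )
        a = estimate_allele_frequencies(glm, np.zeros(glm.n_samples, dtype=int))
        b = estimate_allele_frequencies(glm_p, np.zeros(glm.n_samples, dtype=int))
        np.testing.assert_allclose(a.freq, b.freq, atol=1e-9)
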