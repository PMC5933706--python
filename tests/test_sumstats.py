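import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clineselect.io_formats import GeneticMap, HaplotypeMatrix
from clineselect import sumstats as ss


def wc_oracle(n, p, h):
    """Literal transcription of the Weir & Cockerham (1984) a, b, c formulas."""
    n = np.asarray(n, float)
    p = np.asarray(p, float)
    h = np.asarray(h, float)
    r = len(n)
    nbar = n.sum() / r
    nc = (r * nbar - (n ** 2).sum() / (r * nbar)) / (r - 1)
    pbar = (n * p).sum() / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n * h).sum() / (r * nbar)
    a = nbar / nc * (s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


class TestWcFst:
    def test_against_transcription_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            r = rng.integers(2, 6)
            n = rng.integers(5, 200, r)
            dc = np.array([rng.integers(0, 2 * ni + 1) for ni in n])
            het = np.array([rng.integers(0, min(dc_i, 2 * ni - dc_i) + 1)
                            for dc_i, ni in zip(dc, n)])
            comp = ss.wc_fst_site(ss.SiteCounts(n=n, derived_count=dc, het_count=het))
            a, b, c = wc_oracle(n, dc / (2 * n), het / n)
            assert comp.a == pytest.approx(a, abs=1e-12)
            assert comp.b == pytest.approx(b, abs=1e-12)
            assert comp.c == pytest.approx(c, abs=1e-12)

    def test_printed_population_differentiation(self):
        """High- and low-differentiation pairs from published frequencies."""
        assert ss.wc_fst_from_freqs(106 / 122, 6 / 122, 61, 61).theta == pytest.approx(0.805, abs=0.005)
        assert ss.wc_fst_from_freqs(0.06, 0.05, 61, 61).theta == pytest.approx(-0.007, abs=0.003)

    def test_equal_intermediate_frequencies_negative(self):
        # s2 = 0 makes the among-population component negative
        assert ss.wc_fst_from_freqs(0.5, 0.5, 61, 61).theta == pytest.approx(-0.00833, abs=1e-4)

    @given(p=st.floats(0.01, 0.99), n=st.integers(5, 300))
    @settings(max_examples=50, deadline=None)
    def test_identical_counts_give_nonpositive_theta(self, p, n):
        theta = ss.wc_fst_from_freqs(p, p, n, n).theta
        assert theta <= 1e-12

    def test_monomorphic_flagged_undefined(self):
        comp = ss.wc_fst_site(ss.SiteCounts(n=[10, 10], derived_count=[0, 0]))
        assert not comp.defined and math.isnan(comp.theta)

    def test_vectorized_pair_matches_scalar(self):
        rng = np.random.default_rng(1)
        p1, p2 = rng.random(50), rng.random(50)
        a, abc = ss._wc_pair_components_vec(p1, p2, 30, 45)
        for i in range(50):
            comp = ss.wc_fst_from_freqs(p1[i], p2[i], 30, 45)
            assert a[i] == pytest.approx(comp.a, abs=1e-12)
            assert abc[i] == pytest.approx(comp.a + comp.b + comp.c, abs=1e-12)


class TestRatioOfAverages:
    def test_single_site_equals_theta(self):
        comp = ss.wc_fst_from_freqs(0.8, 0.2, 20, 20)
        assert ss.fst_ratio_of_averages([comp]) == pytest.approx(comp.theta)

    def test_not_mean_of_ratios(self):
        comps = [ss.FstComponents(a=1.0, b=0.0, c=0.0),
                 ss.FstComponents(a=0.0, b=1.0, c=1.0)]
        assert ss.fst_ratio_of_averages(comps) == pytest.approx(1 / 3)
        assert np.mean([c.theta for c in comps]) == pytest.approx(0.5)

    def test_balding_nichols_generator_oracle(self):
        """Realized ratio-of-averages is close to the drift parameter F."""
        rng = np.random.default_rng(7)
        F = 0.1
        anc = rng.uniform(0.05, 0.95, 5000)
        a_, b_ = anc * (1 - F) / F, (1 - anc) * (1 - F) / F
        p1, p2 = rng.beta(a_, b_), rng.beta(a_, b_)
        assert ss.fst_ratio_pair(p1, p2, 1000, 1000) == pytest.approx(F, abs=0.02)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            ss.fst_ratio_of_averages([])


class TestFrequencySpectrumStats:
    def test_tajimas_d_zero_when_pi_matches_watterson(self):
        n, S = 24, 12
        a1 = sum(1 / i for i in range(1, n))
        assert ss.tajimas_d(S, S / a1, n) == pytest.approx(0.0, abs=1e-12)

    def test_tajimas_d_formula_oracle(self):
        n, S, pi = 10, 5, 2.0
        a1 = sum(1 / i for i in range(1, n))
        a2 = sum(1 / i ** 2 for i in range(1, n))
        b1 = (n + 1) / (3 * (n - 1)); b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1; c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
        e1, e2 = c1 / a1, c2 / (a1 ** 2 + a2)
        expect = (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
        assert ss.tajimas_d(S, pi, n) == pytest.approx(expect, abs=1e-14)

    def test_tajimas_d_undefined_without_segregating_sites(self):
        assert math.isnan(ss.tajimas_d(0, 0.0, 10))

    def test_fay_wu_h_hand_sum(self):
        # n=4, one singleton: theta_pi = 2*1*1*3/12 = 0.5, theta_H = 2*1*1/12 = 1/6
        assert ss.fay_wu_h([1, 0, 0], 4) == pytest.approx(1 / 3)

    def test_fay_wu_h_empty_and_sign(self):
        assert ss.fay_wu_h([0, 0, 0], 4) == 0.0
        # a high-frequency derived site dominates -> H < 0
        assert ss.fay_wu_h([0, 0, 5], 4) < 0

    def test_fay_wu_h_rejects_wrong_length(self):
        with pytest.raises(ValueError):
            ss.fay_wu_h([1, 2], 4)

    def test_pi_pairs_equals_pi_from_sfs(self):
        rng = np.random.default_rng(5)
        alleles = rng.integers(0, 2, (12, 40)).astype(np.int8)
        n = 12
        sfs = ss.derived_sfs(alleles)
        i = np.arange(1, n)
        pi_sfs = (2 * sfs * i * (n - i)).sum() / (n * (n - 1))
        assert ss.nucleotide_diversity(alleles) == pytest.approx(pi_sfs)


class TestNucleotideDiversity:
    def test_identical_and_simple(self):
        assert ss.nucleotide_diversity(np.zeros((5, 10), dtype=np.int8)) == 0.0
        two = np.zeros((2, 10), dtype=np.int8)
        two[1, [2, 5, 7]] = 1
        assert ss.nucleotide_diversity(two) == 3.0

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        alleles = rng.integers(0, 2, (4, 15)).astype(np.int8)
        total = sum((alleles[i] != alleles[j]).sum()
                    for i in range(4) for j in range(i + 1, 4))
        assert ss.nucleotide_diversity(alleles) == pytest.approx(total / 6)

    def test_needs_two_rows(self):
        with pytest.raises(ValueError):
            ss.nucleotide_diversity(np.zeros((1, 5), dtype=np.int8))


def _matrix_from(alleles, positions, pop="P"):
    alleles = np.asarray(alleles, dtype=np.int8)
    n = alleles.shape[0]
    ids = np.array([f"i{k // 2}" for k in range(n)], dtype=object)
    return HaplotypeMatrix(alleles, np.asarray(positions), ids,
                           np.array([pop] * n, dtype=object))


class TestEhh:
    def test_identical_carriers_full_span(self, flat_map):
        alleles = np.ones((6, 5), dtype=np.int8)
        hm = _matrix_from(alleles, [10_000, 20_000, 30_000, 40_000, 50_000])
        res = ss.ehh_curve(hm, 30_000, 1, flat_map)
        assert np.all(res.ehh_values == 1.0)
        # iHH = total cM span around the core (40 kb at 1 cM/Mb = 0.04 cM)
        assert res.ihh == pytest.approx(0.04)

    def test_two_two_split_drops_to_one_third(self, flat_map):
        alleles = np.ones((4, 2), dtype=np.int8)
        alleles[:2, 1] = 0  # carriers split 2/2 at the flanking site
        hm = _matrix_from(alleles, [10_000, 11_000])
        res = ss.ehh_curve(hm, 10_000, 1, flat_map, cutoff=0.0)
        flank = res.ehh_values[res.ehh_positions == 11_000][0]
        assert flank == pytest.approx(1 / 3)

    def test_core_is_always_one(self, flat_map):
        rng = np.random.default_rng(0)
        alleles = rng.integers(0, 2, (10, 9)).astype(np.int8)
        alleles[:, 4] = [1] * 5 + [0] * 5
        hm = _matrix_from(alleles, np.arange(1, 10) * 1000)
        res = ss.ehh_curve(hm, 5000, 1, flat_map)
        assert res.ehh_values[res.ehh_positions == 5000][0] == 1.0

    def test_single_carrier_flagged(self, flat_map):
        alleles = np.zeros((6, 3), dtype=np.int8)
        alleles[0, 1] = 1
        hm = _matrix_from(alleles, [1000, 2000, 3000])
        res = ss.ehh_curve(hm, 2000, 1, flat_map)
        assert not res.defined and math.isnan(res.ihh)


class TestIhsXpehh:
    def _sweep_like(self, rng, n=20, m=21):
        """Derived carriers share a long identical haplotype; ancestral varies."""
        alleles = rng.integers(0, 2, (n, m)).astype(np.int8)
        alleles[: n // 2] = 0  # carriers identical everywhere
        alleles[: n // 2, m // 2] = 1
        alleles[n // 2:, m // 2] = 0
        return _matrix_from(alleles, np.arange(1, m + 1) * 2000)

    def test_daf_filter(self, flat_map):
        rng = np.random.default_rng(4)
        hm = self._sweep_like(rng)
        core = int(hm.positions[hm.n_sites // 2])
        alleles = hm.alleles.copy()
        alleles[:, hm.n_sites // 2] = 0
        alleles[0, hm.n_sites // 2] = 1  # DAF 0.05 -> outside (0.05, 0.95)
        hm2 = _matrix_from(alleles, hm.positions)
        res = ss.ihs_scan(hm2, flat_map)
        assert math.isnan(res["ihs_unstd"][hm2.site_index(core)])

    def test_symmetric_structure_gives_zero(self, flat_map):
        # derived and ancestral classes have mirror-image haplotype structure
        alleles = np.zeros((8, 5), dtype=np.int8)
        alleles[:4, 2] = 1
        alleles[[0, 1], 0] = 1
        alleles[[4, 5], 0] = 1
        alleles[[0, 1], 4] = 1
        alleles[[4, 5], 4] = 1
        hm = _matrix_from(alleles, [1000, 2000, 3000, 4000, 5000])
        res = ss.ihs_scan(hm, flat_map)
        j = hm.site_index(3000)
        assert res["ihs_unstd"][j] == pytest.approx(0.0, abs=1e-12)

    def test_invariance_to_row_order_and_monomorphic_columns(self, flat_map):
        rng = np.random.default_rng(9)
        hm = self._sweep_like(rng)
        res = ss.ihs_scan(hm, flat_map)
        perm = rng.permutation(hm.n_haplotypes)
        hm2 = hm.subset_rows(perm)
        res2 = ss.ihs_scan(hm2, flat_map)
        np.testing.assert_allclose(res["ihs_unstd"], res2["ihs_unstd"], equal_nan=True)
        # add a monomorphic column
        alleles = np.insert(hm.alleles, 3, 0, axis=1)
        pos = np.insert(hm.positions, 3, int(hm.positions[2]) + 1)
        hm3 = _matrix_from(alleles, pos)
        res3 = ss.ihs_scan(hm3, flat_map)
        keep = np.ones(hm3.n_sites, bool); keep[3] = False
        np.testing.assert_allclose(res["ihs_unstd"], res3["ihs_unstd"][keep], equal_nan=True)

    def test_xpehh_identical_panels_zero(self, flat_map):
        rng = np.random.default_rng(11)
        hm = self._sweep_like(rng)
        res = ss.xpehh_scan(hm, hm, flat_map)
        finite = np.isfinite(res["xpehh_unstd"])
        assert finite.any()
        assert np.allclose(res["xpehh_unstd"][finite], 0.0, atol=1e-12)

    def test_xpehh_daf_filter(self, flat_map):
        rng = np.random.default_rng(12)
        hm = self._sweep_like(rng)
        alleles = hm.alleles.copy()
        j = hm.n_sites // 2
        alleles[:, j] = 0  # test DAF 0 at the core site
        hm_low = _matrix_from(alleles, hm.positions)
        res = ss.xpehh_scan(hm_low, hm, flat_map)
        assert math.isnan(res["xpehh_unstd"][j])


class TestEmpiricalPvalue:
    def test_extremes_and_median(self):
        bg = np.arange(1, 10_001, dtype=float)
        assert ss.empirical_pvalue(20_000.0, bg) == 0.0
        assert ss.empirical_pvalue(np.median(bg), bg) == pytest.approx(0.5, abs=1e-3)

    def test_printed_tail_proportion(self):
        bg = np.concatenate([np.full(9998, 0.1), [0.9, 0.95]])
        assert ss.empirical_pvalue(0.805, bg) == pytest.approx(0.0002)

    def test_null_uniformity(self):
        from scipy.stats import kstest
        rng = np.random.default_rng(13)
        bg = rng.normal(size=10_000)
        vals = rng.normal(size=2_000)
        pvals = [ss.empirical_pvalue(v, bg) for v in vals]
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_empty_background(self):
        with pytest.raises(ValueError):
            ss.empirical_pvalue(1.0, [])
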