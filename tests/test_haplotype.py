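"""Multi-SNP EM haplotype frequencies and haplotype association tests."""

from itertools import product

import numpy as np
import pytest
from scipy import optimize, stats

from candigene import Cohort
from candigene.containers import MISSING
from candigene.haplotype import (OMNIBUS, RARE, HaplotypeAssociation,
                                 HaplotypeFreqs, em_haplotypes,
                                 hap_specific_test, haplotype_scan,
                                 omnibus_test)
from candigene.ld import HaploBlock
from candigene.simulate import RegionSpec, build_haplotype_pool
from conftest import make_cohort, two_region_panel


def _phase_loglik(G, hap_freqs: dict[tuple, float]) -> float:
    """Observed-data log-likelihood by explicit phase enumeration.

    Independent of the EM implementation: enumerates every ordered haplotype
    pair and sums the probabilities compatible with each genotype row.
    """
    m = G.shape[1]
    haps = list(hap_freqs)
    ll = 0.0
    for row in G:
        p = 0.0
        for h1 in haps:
            for h2 in haps:
                if all(h1[j] + h2[j] == row[j] for j in range(m)):
                    p += hap_freqs[h1] * hap_freqs[h2]
        ll += np.log(max(p, 1e-300))
    return ll


def _ml_oracle(G, n_starts=8, seed=0):
    """Maximum likelihood over the full haplotype simplex via optimizer."""
    m = G.shape[1]
    haps = list(product((0, 1), repeat=m))
    rng = np.random.default_rng(seed)

    def neg_ll(theta):
        w = np.exp(theta - theta.max())
        f = w / w.sum()
        return -_phase_loglik(G, dict(zip(haps, f)))

    best = np.inf
    for s in range(n_starts):
        x0 = rng.normal(scale=1.0, size=len(haps)) if s else np.zeros(len(haps))
        res = optimize.minimize(neg_ll, x0, method="Nelder-Mead",
                                options={"maxiter": 4000, "fatol": 1e-10,
                                         "xatol": 1e-8})
        best = min(best, res.fun)
    return -best


class TestEmHaplotypes:
    def test_complete_ld_two_haplotypes(self):
        cohort = make_cohort(200, 600, two_region_panel(ld_level=1.0,
                                                        mafs=(0.3, 0.2)), seed=1)
        G = cohort.genotypes.values[:, :2]
        freqs = em_haplotypes(G, cohort.status)
        assert len(freqs.haplotypes) == 2
        maf = G[:, 0].mean() / 2
        assert sorted(freqs.freq_overall) == pytest.approx(
            sorted([maf, 1 - maf]), abs=1e-6)

    def test_equilibrium_frequencies_factorise(self):
        cohort = make_cohort(400, 1200, two_region_panel(ld_level=0.0,
                                                         mafs=(0.3, 0.25)), seed=2)
        G = cohort.genotypes.values[:, :2]
        freqs = em_haplotypes(G, cohort.status, pool_min=0.0)
        p1, p2 = G[:, 0].mean() / 2, G[:, 1].mean() / 2
        n = 2 * G.shape[0]
        by_name = dict(zip(freqs.haplotypes, freqs.freq_overall))
        counted = dict(zip(freqs.haplotypes,
                           [h.count("1") for h in freqs.haplotypes]))
        for name, f in by_name.items():
            b1 = name[0] == "1"
            b2 = name[1] == "1"
            want = (p1 if b1 else 1 - p1) * (p2 if b2 else 1 - p2)
            se = np.sqrt(want * (1 - want) / n)
            assert abs(f - want) < 3.5 * se + 1e-9

    @pytest.mark.parametrize("m,n,seed", [(2, 12, 0), (2, 20, 1), (3, 15, 2)])
    def test_em_attains_maximum_likelihood(self, m, n, seed):
        """EM log-likelihood matches an independent optimizer within 1e-6."""
        rng = np.random.default_rng(seed)
        G = rng.integers(0, 3, size=(n, m))
        freqs = em_haplotypes(G, np.zeros(n, dtype=int), pool_min=0.0,
                              tol=1e-12, max_iter=20000)
        by_bits = {tuple(int(c) for c in h): f
                   for h, f in zip(freqs.haplotypes, freqs.freq_overall)}
        full = {h: by_bits.get(h, 0.0) for h in product((0, 1), repeat=m)}
        ll_em = _phase_loglik(G, full)
        ll_opt = _ml_oracle(G, seed=seed)
        assert ll_em >= ll_opt - 1e-6

    def test_posterior_counts_sum_to_chromosomes(self):
        cohort = make_cohort(150, 450, two_region_panel(ld_level=0.8), seed=3,
                             missing_rate=0.01)
        G = cohort.genotypes.values[:, :2]
        freqs = em_haplotypes(G, cohort.status)
        complete = (G != MISSING).all(axis=1)
        n_case = int((cohort.status[complete] == 1).sum())
        n_ctrl = int(complete.sum()) - n_case
        assert freqs.expected_cases.sum() == pytest.approx(2 * n_case, abs=1e-3)
        assert freqs.expected_controls.sum() == pytest.approx(2 * n_ctrl, abs=1e-3)
        assert freqs.freq_overall.sum() == pytest.approx(1.0, abs=1e-6)

    def test_invariant_to_sample_order(self):
        cohort = make_cohort(100, 300, two_region_panel(ld_level=0.6), seed=4)
        G = cohort.genotypes.values[:, :2]
        perm = np.random.default_rng(0).permutation(G.shape[0])
        a = em_haplotypes(G, cohort.status, pool_min=0.0)
        b = em_haplotypes(G[perm], cohort.status[perm], pool_min=0.0)
        assert a.haplotypes == b.haplotypes
        np.testing.assert_allclose(a.freq_overall, b.freq_overall, atol=1e-9)

    def test_rare_pooling(self):
        rng = np.random.default_rng(5)
        G = rng.integers(0, 3, size=(500, 3))
        freqs = em_haplotypes(G, np.zeros(500, dtype=int), pool_min=0.08)
        assert all(f >= 0.08 for h, f in zip(freqs.haplotypes, freqs.freq_overall)
                   if h != RARE)

    def test_wide_block_refused(self):
        G = np.zeros((10, 13), dtype=int)
        with pytest.raises(ValueError, match="12"):
            em_haplotypes(G, np.zeros(10, dtype=int))


def _freqs_from_rounded(f_a, f_u, n_case_chrom, n_ctrl_chrom):
    """HaplotypeFreqs built from printed (rounded) frequency pairs."""
    f_a = np.asarray(f_a, dtype=float)
    f_u = np.asarray(f_u, dtype=float)
    names = [f"H{k}" for k in range(f_a.size)]
    overall = (f_a * n_case_chrom + f_u * n_ctrl_chrom) / (n_case_chrom + n_ctrl_chrom)
    return HaplotypeFreqs(
        snp_ids=["s1", "s2"], haplotypes=names, freq_overall=overall,
        freq_cases=f_a, freq_controls=f_u,
        expected_cases=f_a * n_case_chrom, expected_controls=f_u * n_ctrl_chrom,
        log_likelihood=0.0, n_iter=1)


class TestHaplotypeTests:
    def test_published_frequency_pair_chi2_scale(self):
        """F_A=0.058 vs F_U=0.041 at 5036/15042 chromosomes gives chi2 ~ 25."""
        freqs = _freqs_from_rounded([0.058, 0.942], [0.041, 0.959], 5036, 15042)
        res = hap_specific_test(freqs, "H0")
        # independent 2x2 Pearson computation
        table = np.array([[0.058 * 5036, 0.041 * 15042],
                          [0.942 * 5036, 0.959 * 15042]])
        exp = np.outer(table.sum(1), table.sum(0)) / table.sum()
        want = ((table - exp) ** 2 / exp).sum()
        assert res.chi2 == pytest.approx(want, abs=1e-9)
        assert 24.0 < res.chi2 < 26.5
        assert res.p_value < 1e-5

    def test_equal_frequencies_give_zero(self):
        freqs = _freqs_from_rounded([0.3, 0.7], [0.3, 0.7], 1000, 3000)
        res = hap_specific_test(freqs, "H0")
        assert res.chi2 == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_chi2_scales_linearly_with_counts(self):
        a = _freqs_from_rounded([0.1, 0.9], [0.07, 0.93], 1000, 2000)
        b = _freqs_from_rounded([0.1, 0.9], [0.07, 0.93], 2000, 4000)
        ra, rb = hap_specific_test(a, "H0"), hap_specific_test(b, "H0")
        assert rb.chi2 == pytest.approx(2 * ra.chi2, rel=1e-9)

    def test_unknown_haplotype_rejected(self):
        freqs = _freqs_from_rounded([0.5, 0.5], [0.5, 0.5], 100, 100)
        with pytest.raises(ValueError):
            hap_specific_test(freqs, "missing")

    def test_omnibus_null_and_df(self):
        freqs = _freqs_from_rounded([0.2, 0.3, 0.5], [0.2, 0.3, 0.5], 500, 1500)
        res = omnibus_test(freqs)
        assert res.chi2 == pytest.approx(0.0, abs=1e-9)
        assert res.df == 2
        assert res.haplotype == OMNIBUS

    def test_omnibus_single_haplotype_rejected(self):
        freqs = _freqs_from_rounded([1.0], [1.0], 100, 100)
        with pytest.raises(ValueError):
            omnibus_test(freqs)

    def test_omnibus_detects_risk_haplotype(self):
        """A haplotype with log-OR 0.4 at study-scale n is detected."""
        from candigene.simulate import EffectSpec
        regions = two_region_panel(ld_level=1.0, mafs=(0.15, 0.2))
        target = regions[0].snp_records()[0].snp_id
        hits = 0
        n_rep = 10
        for seed in range(n_rep):
            cohort = make_cohort(
                2518, 7521, regions,
                EffectSpec(main_effects={target: 0.4}), seed=seed)
            G = cohort.genotypes.values[:, :2]
            freqs = em_haplotypes(G, cohort.status)
            if omnibus_test(freqs).p_value < 0.001:
                hits += 1
        assert hits >= 0.9 * n_rep


class TestHaplotypeScan:
    def test_table_layout_matches_standard_header(self):
        cohort = make_cohort(150, 450, two_region_panel(ld_level=1.0), seed=6)
        blocks = [HaploBlock("1", 0, 1, 1, 1.0)]
        table = haplotype_scan(blocks, cohort)
        assert list(table.columns) == ["SNPS", "HAPLOTYPE", "F_A", "F_U",
                                       "CHISQ", "P"]
        assert table.iloc[0]["HAPLOTYPE"] == OMNIBUS
        assert (table["P"] <= 1).all() and (table["CHISQ"] >= 0).all()

    def test_null_blocks_not_significant(self):
        sig = 0
        for seed in range(6):
            cohort = make_cohort(200, 600, two_region_panel(ld_level=1.0),
                                 seed=seed + 50)
            blocks = [HaploBlock("1", 0, 1, 1, 1.0), HaploBlock("2", 2, 3, 1, 1.0)]
            table = haplotype_scan(blocks, cohort)
            omni = table[table["HAPLOTYPE"] == OMNIBUS]
            sig += int((omni["P"] < 0.001).any())
        assert sig <= 1

    def test_risk_haplotype_is_most_significant_row(self):
        from candigene.simulate import EffectSpec
        # unequal MAFs in complete LD give a 3-haplotype pool, so the risk
        # haplotype's chi-square is not mirrored by its complement
        regions = [RegionSpec("R1", "1", 2,
                              build_haplotype_pool(2, [0.15, 0.25], 1.0))]
        target = regions[0].snp_records()[0].snp_id
        cohort = make_cohort(2000, 6000, regions,
                             EffectSpec(main_effects={target: 0.35}), seed=9)
        blocks = [HaploBlock("1", 0, 1, 1, 1.0)]
        table = haplotype_scan(blocks, cohort)
        rows = table[(table["HAPLOTYPE"] != OMNIBUS)]
        best = rows.loc[rows["P"].idxmin()]
        # the risk haplotype carries the counted (minor) allele at both SNPs
        counted = "".join(cohort.genotypes.counted_allele[:2])
        assert best["HAPLOTYPE"] == counted
        assert best["F_A"] > best["F_U"]

    def test_model_object_summary(self):
        cohort = make_cohort(100, 300, two_region_panel(ld_level=1.0), seed=10)
        blocks = [HaploBlock("1", 0, 1, 1, 1.0)]
        res = HaplotypeAssociation(cohort, blocks).fit()
        assert "F_A" in res.summary()
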