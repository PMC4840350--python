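"""Cross-chromosome pair enumeration, interaction tests, permutation null."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from candigene import Cohort, SnpRecord
from candigene.epistasis import (EpistasisScan, SnpPair,
                                 enumerate_cross_chrom_pairs,
                                 genotype_combo_summary, interaction_test,
                                 permutation_scan)
from candigene.simulate import (EffectSpec, default_study_config,
                                simulate_cohort)
from conftest import make_cohort, two_region_panel


def _panel(chrom_counts):
    snps = []
    for c, (chrom, n) in enumerate(chrom_counts.items()):
        for k in range(n):
            snps.append(SnpRecord(f"s{c}_{k}", chrom, 1000 + k, "A", "G"))
    return snps


class TestPairEnumeration:
    def test_default_panel_gives_432(self, default_design):
        _, regions, _ = default_design
        snps = [r for region in regions for r in region.snp_records()]
        assert len(enumerate_cross_chrom_pairs(snps)) == 432

    def test_single_chromosome_gives_none(self):
        assert enumerate_cross_chrom_pairs(_panel({"1": 6})) == []

    def test_two_snps_two_chromosomes(self):
        pairs = enumerate_cross_chrom_pairs(_panel({"1": 1, "2": 1}))
        assert len(pairs) == 1
        assert (pairs[0].index_i, pairs[0].index_j) == (0, 1)

    def test_count_matches_closed_form(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            counts = {str(c): int(rng.integers(1, 8))
                      for c in range(rng.integers(2, 5))}
            snps = _panel(counts)
            m = len(snps)
            want = m * (m - 1) // 2 - sum(n * (n - 1) // 2
                                          for n in counts.values())
            assert len(enumerate_cross_chrom_pairs(snps)) == want

    def test_same_chromosome_pair_rejected(self):
        with pytest.raises(ValueError):
            SnpPair(0, 1, "1", "1")


class TestInteractionTest:
    def test_null_interaction_or_near_one(self):
        ors, pvals = [], []
        for seed in range(6):
            cohort = make_cohort(2518, 7521,
                                 two_region_panel(ld_level=0.5,
                                                  mafs=(0.3, 0.3)), seed=seed)
            pair = SnpPair(0, 2, "1", "2")
            r = interaction_test(cohort, pair, adjust=False)
            if r.converged:
                ors.append(r.or_interaction)
                pvals.append(r.p_nominal)
        assert abs(np.mean(np.log(ors))) < 0.05
        assert min(pvals) > 0.001  # no spurious strong signal across seeds

    def test_matches_statsmodels_with_covariates(self):
        sm = pytest.importorskip("statsmodels.api")
        cohort = make_cohort(300, 900, two_region_panel(ld_level=0.5), seed=3)
        pair = SnpPair(0, 2, "1", "2")
        r = interaction_test(cohort, pair, adjust=True)
        g1 = cohort.genotypes.values[:, 0].astype(float)
        g2 = cohort.genotypes.values[:, 2].astype(float)
        X = np.column_stack([np.ones(len(g1)), g1, g2, g1 * g2,
                             cohort.sex, cohort.age])
        ref = sm.Logit(cohort.status.astype(float), X).fit(disp=0)
        assert r.b3 == pytest.approx(ref.params[3], abs=1e-7)
        assert r.se == pytest.approx(ref.bse[3], abs=1e-6)
        assert r.p_nominal == pytest.approx(ref.pvalues[3], rel=1e-5)

    def test_protective_interaction_recovered(self):
        """CI coverage of the generating interaction OR across replicates."""
        regions = two_region_panel(ld_level=0.4, mafs=(0.3, 0.3))
        s1 = regions[0].snp_records()[0].snp_id
        s2 = regions[1].snp_records()[0].snp_id
        effects = EffectSpec(interaction_effects={(s1, s2): np.log(0.5)})
        covered, logs = 0, []
        n_rep = 10
        for seed in range(n_rep):
            cohort = make_cohort(2518, 7521, regions, effects, seed=seed)
            r = interaction_test(cohort, SnpPair(0, 2, "1", "2"))
            lo, hi = r.ci95()
            covered += int(lo <= 0.5 <= hi)
            logs.append(r.b3)
            assert r.p_nominal < 0.05
        assert covered >= 7
        assert abs(np.mean(logs) - np.log(0.5)) < 0.1


class TestPermutationScan:
    def _small_cohort(self, seed=0):
        return make_cohort(100, 300, two_region_panel(ld_level=0.3), seed=seed)

    def test_corrected_p_monotone_in_nominal(self):
        cohort = self._small_cohort(1)
        results, null = permutation_scan(cohort, n_perm=50, seed=2,
                                         adjust=False)
        ok = [r for r in results if r.converged]
        ok.sort(key=lambda r: r.p_nominal)
        perms = [r.p_perm for r in ok]
        assert perms == sorted(perms)

    def test_null_distribution_shape(self):
        cohort = self._small_cohort(2)
        _, null = permutation_scan(cohort, n_perm=25, seed=3, adjust=False)
        assert null.min_p_values.shape == (25,)
        assert ((null.min_p_values > 0) & (null.min_p_values <= 1)).all()

    def test_single_permutation_bounds(self):
        cohort = self._small_cohort(3)
        results, _ = permutation_scan(cohort, n_perm=1, seed=4, adjust=False)
        assert {r.p_perm for r in results if r.converged} <= {0.5, 1.0}

    def test_seed_reproducibility(self):
        cohort = self._small_cohort(4)
        a, na = permutation_scan(cohort, n_perm=20, seed=7, adjust=False)
        b, nb = permutation_scan(cohort, n_perm=20, seed=7, adjust=False)
        np.testing.assert_array_equal(na.min_p_values, nb.min_p_values)
        assert [r.p_perm for r in a] == [r.p_perm for r in b]

    def test_strong_interaction_hits_permutation_floor(self):
        regions = two_region_panel(ld_level=0.3, mafs=(0.35, 0.35))
        s1 = regions[0].snp_records()[0].snp_id
        s2 = regions[1].snp_records()[0].snp_id
        effects = EffectSpec(interaction_effects={(s1, s2): np.log(0.35)})
        cohort = make_cohort(1000, 3000, regions, effects, seed=6)
        results, null = permutation_scan(cohort, n_perm=99, seed=8)
        best = min(results, key=lambda r: r.p_nominal)
        assert (best.pair.index_i, best.pair.index_j) == (0, 2)
        assert best.p_perm == pytest.approx(1 / 100)

    def test_zero_permutations_degraded_mode(self):
        cohort = self._small_cohort(5)
        results, null = permutation_scan(cohort, n_perm=0, seed=0,
                                         adjust=False)
        assert null.n_permutations == 0
        assert all(np.isnan(r.p_perm) for r in results)


class TestGenotypeComboSummary:
    def test_all_controls_all_zero(self):
        cohort = make_cohort(5, 200, two_region_panel(ld_level=0.2), seed=7)
        # keep only controls
        keep = cohort.status == 0
        g = cohort.genotypes
        sub = Cohort([s for s in cohort.snps],
                     [s for s, k in zip(cohort.samples, keep) if k],
                     type(g)(g.values[keep], g.counted_allele, g.other_allele,
                             [sid for sid, k in zip(g.sample_ids, keep) if k],
                             list(g.snp_ids)))
        table = genotype_combo_summary(sub, SnpPair(0, 2, "1", "2"))
        vals = table.to_numpy()
        assert np.nanmax(vals) == 0.0

    def test_overall_cell_is_case_fraction(self):
        cohort = make_cohort(120, 280, two_region_panel(ld_level=0.2), seed=8)
        table = genotype_combo_summary(cohort, SnpPair(0, 2, "1", "2"))
        assert table.loc["all", "all"] == pytest.approx(100 * 120 / 400)

    def test_protective_double_heterozygote_is_minimum(self):
        """Crafted double-heterozygote depletion shows up in the (1,1) cell."""
        rng = np.random.default_rng(9)
        cohort = make_cohort(1500, 3000,
                             two_region_panel(ld_level=0.2, mafs=(0.45, 0.45)),
                             seed=9)
        g = cohort.genotypes
        g1, g2 = g.values[:, 0], g.values[:, 2]
        p = np.where((g1 == 1) & (g2 == 1), 0.03, 0.4)
        status = (rng.random(len(p)) < p).astype(int)
        samples = [type(s)(s.sample_id, int(st), s.sex, s.age)
                   for s, st in zip(cohort.samples, status)]
        crafted = Cohort(cohort.snps, samples, g)
        table = genotype_combo_summary(crafted, SnpPair(0, 2, "1", "2"))
        inner = table.iloc[:3, :3].to_numpy()
        assert table.loc["1", "1"] == pytest.approx(np.nanmin(inner))


def test_scan_model_object_end_to_end():
    spec, regions, effects = default_study_config(seed=14)
    spec.n_cases, spec.n_controls = 150, 450
    snps, samples, matrix = simulate_cohort(spec, regions, effects)
    cohort = Cohort(snps, samples, matrix)
    scan = EpistasisScan(cohort, n_permutations=5, seed=1)
    assert len(scan.pairs) == 432
    res = scan.fit()
    t = res.table
    assert len(t) == 432
    assert "p_perm" in t.columns
    assert "432 pairs" in res.summary()
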