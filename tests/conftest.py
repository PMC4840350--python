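"""Shared fixtures: small simulated cohorts built at import-free test time."""

import numpy as np
import pytest

from candigene import Cohort
from candigene.simulate import (CohortSpec, EffectSpec, RegionSpec,
                                build_haplotype_pool, default_study_config,
                                simulate_cohort)


def make_cohort(n_cases, n_controls, regions, effects=None, seed=0,
                missing_rate=0.0) -> Cohort:
    spec = CohortSpec(n_cases=n_cases, n_controls=n_controls,
                      missing_rate=missing_rate, seed=seed)
    snps, samples, matrix = simulate_cohort(spec, regions, effects or EffectSpec())
    return Cohort(snps, samples, matrix)


def two_region_panel(ld_level=1.0, n_snps=2, mafs=(0.3, 0.2)):
    """Two regions on different chromosomes, one haplotype pool each."""
    return [
        RegionSpec("GENE1", "1", n_snps,
                   build_haplotype_pool(n_snps, mafs[0], ld_level)),
        RegionSpec("GENE2", "2", n_snps,
                   build_haplotype_pool(n_snps, mafs[1], ld_level),
                   start=2_000_000),
    ]


@pytest.fixture(scope="session")
def null_cohort() -> Cohort:
    """Moderate null cohort on the default 35-SNP study design."""
    spec, regions, effects = default_study_config(seed=11)
    spec.n_cases, spec.n_controls = 500, 1500
    snps, samples, matrix = simulate_cohort(spec, regions, effects)
    return Cohort(snps, samples, matrix)


@pytest.fixture(scope="session")
def default_design():
    return default_study_config(seed=0)
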