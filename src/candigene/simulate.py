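"""Synthetic case-control cohort generator.

Emulates a candidate-gene study design: a small tag-SNP panel spread over a
few gene regions on distinct chromosomes, strong within-region LD (so block
construction has something to find), realistic cohort sizes and covariate
distributions, a configurable missing-call rate, and disease status drawn
from a prospective logistic model with per-allele main effects, one or more
pairwise interaction effects, and optional covariate effects.  Sampling
continues until the case and control quotas are both filled, which
preserves the generating odds ratios under case-control ascertainment.

Haplotype pools are built as a first-order Markov chain across the region's
SNPs: each adjacent pair is given the two-locus distribution whose D'
equals the requested LD level (with minor alleles coupled), so realized
per-SNP allele frequencies match their targets exactly in expectation.

All randomness flows from the single integer seed in :class:`CohortSpec`
through ``numpy.random.SeedSequence`` spawning, so each stage (haplotype
draws, covariates, status, missingness) is independently reproducible.

Pool haplotype strings use 'A' for the major and 'B' for the minor allele
at each position; they are mapped to concrete bases when SNP records are
materialised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .containers import MISSING, Cohort, GenotypeMatrix, SampleRecord, SnpRecord

__all__ = [
    "RegionSpec", "EffectSpec", "CohortSpec", "build_haplotype_pool",
    "simulate_cohort", "inject_missingness", "default_study_config",
    "pool_allele_freqs", "InfeasiblePoolError", "QuotaError",
]

_BASE_PAIRS = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))


class InfeasiblePoolError(ValueError):
    """Requested MAF/LD combination admits no valid haplotype distribution."""


class QuotaError(RuntimeError):
    """Case/control quota unreachable; the intercept needs adjustment."""


@dataclass
class RegionSpec:
    """One gene region: a haplotype pool shared by all its SNPs.

    ``haplotypes`` is a list of ``(allele_string, frequency)`` pairs where
    each string has one character per SNP, 'A' = major, 'B' = minor allele.
    """

    gene: str
    chromosome: str
    n_snps: int
    haplotypes: list[tuple[str, float]]
    start: int = 1_000_000
    spacing: int = 5_000

    def __post_init__(self) -> None:
        freqs = np.array([f for _, f in self.haplotypes], dtype=float)
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError(f"{self.gene}: haplotype frequencies sum to {freqs.sum()}")
        if any(len(h) != self.n_snps for h, _ in self.haplotypes):
            raise ValueError(f"{self.gene}: haplotype length != n_snps")
        for j, f in enumerate(pool_allele_freqs(self.haplotypes)):
            maf = min(f, 1.0 - f)
            if maf <= 0.05:
                raise ValueError(f"{self.gene}: SNP {j} implied MAF {maf:.3f} <= 0.05")
            if 2 * f * (1 - f) <= 0.2:
                raise ValueError(f"{self.gene}: SNP {j} heterozygosity <= 0.2")

    def snp_records(self) -> list[SnpRecord]:
        recs = []
        for k in range(self.n_snps):
            major, minor = _BASE_PAIRS[k % len(_BASE_PAIRS)]
            recs.append(SnpRecord(
                snp_id=f"rs_{self.gene}_{k + 1}", chromosome=self.chromosome,
                position=self.start + k * self.spacing,
                allele_a=major, allele_b=minor, gene=self.gene,
            ))
        return recs


@dataclass
class EffectSpec:
    """Coefficients of the generating logistic model (log-odds scale)."""

    main_effects: dict = field(default_factory=dict)          # snp_id -> per-allele log OR
    interaction_effects: dict = field(default_factory=dict)   # (snp_id, snp_id) -> log OR
    sex_effect: float = 0.0
    age_effect: float = 0.0
    intercept: float = float(np.log(2518 / 7521))


@dataclass
class CohortSpec:
    """Study-design constants: sizes, covariates, missingness, seed."""

    n_cases: int = 2518
    n_controls: int = 7521
    missing_rate: float = 0.005
    age_mean: float = 37.6
    age_sd: float = 9.5
    age_min: int = 18
    age_max: int = 51
    female_fraction: float = 0.52
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("n_cases and n_controls must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


def pool_allele_freqs(haplotypes) -> np.ndarray:
    """Per-SNP minor-allele ('B') frequency implied by a haplotype pool."""
    n_snps = len(haplotypes[0][0])
    freqs = np.zeros(n_snps)
    for h, f in haplotypes:
        for j, c in enumerate(h):
            if c == "B":
                freqs[j] += f
    return freqs


def build_haplotype_pool(n_snps: int, target_maf, ld_level: float,
                         seed: int = 0) -> list[tuple[str, float]]:
    """Haplotype pool with given per-SNP MAFs and adjacent-pair D'.

    A Markov chain couples minor alleles of adjacent SNPs at
    ``D = ld_level * D_max``; marginal allele frequencies equal the targets
    exactly and every adjacent pair has D' equal to ``ld_level``.  The
    ``seed`` is accepted for interface uniformity; the construction is
    deterministic.
    """
    mafs = np.broadcast_to(np.asarray(target_maf, dtype=float), (n_snps,))
    if not np.all((mafs > 0.05) & (mafs <= 0.5)):
        raise ValueError("each target MAF must lie in (0.05, 0.5]")
    if not 0.0 <= ld_level <= 1.0:
        raise ValueError("ld_level must lie in [0, 1]")

    # pool[h] = probability of haplotype string h (A=major, B=minor)
    pool = {"A": 1.0 - mafs[0], "B": mafs[0]}
    for j in range(1, n_snps):
        pa, pb = mafs[j - 1], mafs[j]
        d_max = min(pa * (1 - pb), (1 - pa) * pb)
        d = ld_level * d_max
        f_bb = pa * pb + d          # minor-minor haplotype of the adjacent pair
        f_ba = pa - f_bb
        f_ab = pb - f_bb
        f_aa = 1 - pa - pb + f_bb
        if min(f_bb, f_ba, f_ab, f_aa) < -1e-12:
            raise InfeasiblePoolError(
                f"MAFs ({pa}, {pb}) with D'={ld_level} give a negative "
                "haplotype frequency")
        cond = {  # P(next allele | previous allele)
            "B": {"B": f_bb / pa if pa > 0 else 0.0, "A": f_ba / pa if pa > 0 else 1.0},
            "A": {"B": f_ab / (1 - pa), "A": f_aa / (1 - pa)},
        }
        new = {}
        for h, f in pool.items():
            for nxt in ("A", "B"):
                p = f * cond[h[-1]][nxt]
                if p > 1e-12:
                    new[h + nxt] = p
        pool = new
    total = sum(pool.values())
    out = sorted(((h, f / total) for h, f in pool.items()), key=lambda x: -x[1])
    if len(out) < 2:
        raise InfeasiblePoolError("pool collapsed to a single haplotype")
    return out


def _rng_streams(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_cohort(cohort: CohortSpec, regions: list[RegionSpec],
                    effects: EffectSpec, max_batches: int = 200):
    """Draw a case-control cohort under the specified generating model.

    Individuals are formed by sampling two haplotypes per region
    independently; covariates come from a truncated normal (age) and a
    Bernoulli (sex); status is Bernoulli in the logistic model.  Sampling
    batches continue until exactly ``n_cases`` cases and ``n_controls``
    controls are retained.

    Returns ``(snps, samples, genotypes)``; wrap in :class:`Cohort` for the
    analysis models.
    """
    snps: list[SnpRecord] = []
    for region in regions:
        snps.extend(region.snp_records())
    snp_ids = [r.snp_id for r in snps]
    if len(set(snp_ids)) != len(snp_ids):
        raise ValueError("duplicate SNP ids across regions")
    idx = {s: j for j, s in enumerate(snp_ids)}
    for s in effects.main_effects:
        if s not in idx:
            raise ValueError(f"main effect references unknown SNP {s}")
    for a, b in effects.interaction_effects:
        if a not in idx or b not in idx:
            raise ValueError(f"interaction references unknown SNP ({a}, {b})")

    beta = np.zeros(len(snps))
    for s, v in effects.main_effects.items():
        beta[idx[s]] = v
    inter = [(idx[a], idx[b], v) for (a, b), v in effects.interaction_effects.items()]

    rng_hap, rng_age, rng_sex, rng_status, rng_miss = _rng_streams(cohort.seed, 5)
    need_total = cohort.n_cases + cohort.n_controls
    batch = max(2048, need_total)

    kept_g: list[np.ndarray] = []
    kept_sex: list[np.ndarray] = []
    kept_age: list[np.ndarray] = []
    kept_status: list[np.ndarray] = []
    n_case = n_ctrl = 0
    batches_done = 0
    while n_case < cohort.n_cases or n_ctrl < cohort.n_controls:
        if batches_done >= max_batches:
            raise QuotaError(
                f"could not fill quotas ({n_case}/{cohort.n_cases} cases, "
                f"{n_ctrl}/{cohort.n_controls} controls) in {max_batches} "
                "batches; adjust the generating intercept")
        batches_done += 1
        G = np.empty((batch, len(snps)), dtype=np.int8)
        col = 0
        for region in regions:
            haps = np.array(
                [[1 if c == "B" else 0 for c in h] for h, _ in region.haplotypes],
                dtype=np.int8)
            freqs = np.array([f for _, f in region.haplotypes])
            draws = rng_hap.choice(len(freqs), size=(batch, 2), p=freqs)
            G[:, col:col + region.n_snps] = haps[draws[:, 0]] + haps[draws[:, 1]]
            col += region.n_snps

        age = _truncated_normal(rng_age, batch, cohort.age_mean, cohort.age_sd,
                                cohort.age_min, cohort.age_max)
        sex = (rng_sex.random(batch) < cohort.female_fraction).astype(np.int8)
        lp = effects.intercept + G @ beta
        for i, j, v in inter:
            lp = lp + v * (G[:, i].astype(float) * G[:, j])
        lp = lp + effects.sex_effect * sex + effects.age_effect * age
        status = (rng_status.random(batch) < expit(lp)).astype(np.int8)

        take_case = min(cohort.n_cases - n_case, int(status.sum()))
        take_ctrl = min(cohort.n_controls - n_ctrl, int((1 - status).sum()))
        case_rows = np.flatnonzero(status == 1)[:take_case]
        ctrl_rows = np.flatnonzero(status == 0)[:take_ctrl]
        rows = np.sort(np.concatenate([case_rows, ctrl_rows]))
        kept_g.append(G[rows])
        kept_sex.append(sex[rows])
        kept_age.append(age[rows])
        kept_status.append(status[rows])
        n_case += take_case
        n_ctrl += take_ctrl

    G = np.concatenate(kept_g)
    sex = np.concatenate(kept_sex)
    age = np.concatenate(kept_age)
    status = np.concatenate(kept_status)
    width = len(str(need_total))
    samples = [
        SampleRecord(f"S{i + 1:0{width}d}", int(status[i]), int(sex[i]), int(age[i]))
        for i in range(need_total)
    ]
    matrix = GenotypeMatrix(
        G,
        np.array([r.allele_b for r in snps], dtype="U1"),
        np.array([r.allele_a for r in snps], dtype="U1"),
        [s.sample_id for s in samples], snp_ids,
    )
    if cohort.missing_rate > 0:
        matrix = inject_missingness(matrix, cohort.missing_rate,
                                    rng=rng_miss)
    return snps, samples, matrix


def _truncated_normal(rng, n, mean, sd, lo, hi):
    """Integer ages from a normal truncated to [lo, hi] by rejection."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled))
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(draw), n - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return np.rint(out).astype(int).clip(lo, hi)


def inject_missingness(matrix: GenotypeMatrix, rate: float,
                       seed: int | None = None, rng=None) -> GenotypeMatrix:
    """Set each entry missing independently with the given probability."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    out = matrix.copy()
    if rate == 0.0:
        return out
    if rng is None:
        rng = np.random.default_rng(seed)
    mask = rng.random(out.values.shape) < rate
    out.values[mask] = MISSING
    return out


#: Default per-region panel: 8 CACNG-family regions over 4 chromosomes with
#: per-chromosome SNP counts (12, 12, 8, 3) for chr 17, 19, 16, 22 — the
#: split that yields exactly 432 cross-chromosome SNP pairs.
_DEFAULT_REGIONS = (
    ("CACNG1", "17", 4), ("CACNG4", "17", 4), ("CACNG5", "17", 4),
    ("CACNG6", "19", 4), ("CACNG7", "19", 4), ("CACNG8", "19", 4),
    ("CACNG3", "16", 8), ("CACNG2", "22", 3),
)

_DEFAULT_MAFS = (0.12, 0.18, 0.25, 0.32, 0.40, 0.45)


def default_study_config(ld_level: float = 0.95, seed: int = 0):
    """The built-in study design: 35 tag SNPs, 2518 cases / 7521 controls.

    Returns ``(CohortSpec, regions, EffectSpec)`` with zero genetic and
    covariate effects (a null cohort).  MAF targets cycle through a fixed
    grid satisfying MAF > 0.05 and heterozygosity > 0.2.
    """
    regions = []
    counter = 0
    start_by_chrom: dict[str, int] = {}
    for gene, chrom, n in _DEFAULT_REGIONS:
        mafs = [_DEFAULT_MAFS[(counter + k) % len(_DEFAULT_MAFS)] for k in range(n)]
        counter += n
        start = start_by_chrom.get(chrom, 1_000_000)
        start_by_chrom[chrom] = start + 1_000_000
        regions.append(RegionSpec(
            gene=gene, chromosome=chrom, n_snps=n,
            haplotypes=build_haplotype_pool(n, mafs, ld_level), start=start,
        ))
    return CohortSpec(seed=seed), regions, EffectSpec()
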