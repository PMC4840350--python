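"""Exhaustive cross-chromosome two-locus interaction scan.

For every SNP pair on distinct chromosomes, the model

    logit P(Y=1) = b0 + b1*g1 + b2*g2 + b3*g1*g2 (+ sex + age)

is fitted with additive (0/1/2) codings at both loci, and the interaction
is judged by the Wald test on b3.  Family-wise error over the whole family
of pairs is controlled by max-statistic permutation: case-control labels
are shuffled against the joint (genotype, covariate) rows, the scan is
recomputed per shuffle, and the most significant nominal P per replicate
forms the null distribution.  Corrected P values use the add-one estimator
(1 + #{min P <= observed}) / (1 + n_perm), so the smallest attainable value
at 1,000 permutations is just below 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MISSING, Cohort, SnpRecord
from .glm import fit_logistic_batch

__all__ = ["SnpPair", "EpistasisResult", "PermutationNull",
           "enumerate_cross_chrom_pairs", "interaction_test",
           "permutation_scan", "genotype_combo_summary",
           "EpistasisScan", "EpistasisScanResults"]


@dataclass(frozen=True)
class SnpPair:
    index_i: int
    index_j: int
    chrom_i: str
    chrom_j: str

    def __post_init__(self) -> None:
        if self.index_i >= self.index_j:
            raise ValueError("pair indices must satisfy i < j")
        if self.chrom_i == self.chrom_j:
            raise ValueError("epistasis pairs must span two chromosomes")


@dataclass
class EpistasisResult:
    pair: SnpPair
    b3: float
    se: float
    or_interaction: float
    p_nominal: float
    converged: bool
    b1: float = float("nan")
    b2: float = float("nan")
    p_perm: float = float("nan")

    def ci95(self) -> tuple[float, float]:
        z = 1.959964
        return (float(np.exp(self.b3 - z * self.se)),
                float(np.exp(self.b3 + z * self.se)))


@dataclass
class PermutationNull:
    n_permutations: int
    min_p_values: np.ndarray
    seed: int


def enumerate_cross_chrom_pairs(snps: list[SnpRecord]) -> list[SnpPair]:
    """All unordered SNP pairs with distinct chromosome labels."""
    return [
        SnpPair(i, j, snps[i].chromosome, snps[j].chromosome)
        for i, j in combinations(range(len(snps)), 2)
        if snps[i].chromosome != snps[j].chromosome
    ]


def _pair_designs(cohort: Cohort, pairs: list[SnpPair], adjust: bool):
    """Stacked (B, n, k) designs and (B, n) complete-case weights."""
    values = cohort.genotypes.values
    n = values.shape[0]
    k = 6 if adjust else 4
    B = len(pairs)
    Xb = np.zeros((B, n, k))
    W = np.zeros((B, n))
    sex = cohort.sex.astype(float)
    age = cohort.age
    for b, pair in enumerate(pairs):
        g1 = values[:, pair.index_i].astype(float)
        g2 = values[:, pair.index_j].astype(float)
        ok = (values[:, pair.index_i] != MISSING) & (values[:, pair.index_j] != MISSING)
        g1[~ok] = 0.0
        g2[~ok] = 0.0
        Xb[b, :, 0] = 1.0
        Xb[b, :, 1] = g1
        Xb[b, :, 2] = g2
        Xb[b, :, 3] = g1 * g2
        if adjust:
            Xb[b, :, 4] = sex
            Xb[b, :, 5] = age
        W[b] = ok.astype(float)
    return Xb, W


def _scan_nominal(Xb, W, y):
    """(b1, b2, b3, se3, p3, converged) for every stacked pair design."""
    params, bse, conv = fit_logistic_batch(Xb, y, weights=W)
    b3 = params[:, 3]
    se3 = bse[:, 3]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = b3 / se3
    p3 = 2 * stats.norm.sf(np.abs(z))
    return params[:, 1], params[:, 2], b3, se3, p3, conv


def interaction_test(cohort: Cohort, pair: SnpPair,
                     adjust: bool = True) -> EpistasisResult:
    """Wald test on the interaction coefficient b3 for one SNP pair."""
    Xb, W = _pair_designs(cohort, [pair], adjust)
    b1, b2, b3, se3, p3, conv = _scan_nominal(Xb, W, cohort.status.astype(float))
    return EpistasisResult(pair, float(b3[0]), float(se3[0]),
                           float(np.exp(b3[0])), float(p3[0]), bool(conv[0]),
                           float(b1[0]), float(b2[0]))


def permutation_scan(cohort: Cohort, pairs: list[SnpPair] | None = None,
                     n_perm: int = 1000, seed: int = 0, adjust: bool = True):
    """Full epistasis scan with max-statistic permutation correction.

    Returns ``(results, PermutationNull)``.  With ``n_perm = 0`` only
    nominal P values are computed and ``p_perm`` stays NaN.  Status labels
    are shuffled against the joint (genotype, covariate) rows, so the
    case/control totals are preserved exactly in every replicate; fits that
    fail contribute no min-P candidate.
    """
    if pairs is None:
        pairs = enumerate_cross_chrom_pairs(cohort.snps)
    if not pairs:
        raise ValueError("no cross-chromosome pairs to test")
    y = cohort.status.astype(float)
    Xb, W = _pair_designs(cohort, pairs, adjust)
    b1, b2, b3, se3, p3, conv = _scan_nominal(Xb, W, y)
    results = [
        EpistasisResult(pair, float(b3[k]), float(se3[k]), float(np.exp(b3[k])),
                        float(p3[k]), bool(conv[k]), float(b1[k]), float(b2[k]))
        for k, pair in enumerate(pairs)
    ]
    if n_perm < 1:
        return results, PermutationNull(0, np.empty(0), seed)

    rng = np.random.default_rng(seed)
    min_p = np.empty(n_perm)
    for r in range(n_perm):
        y_perm = rng.permutation(y)
        _, _, _, _, p_r, conv_r = _scan_nominal(Xb, W, y_perm)
        valid = conv_r & np.isfinite(p_r)
        min_p[r] = p_r[valid].min() if valid.any() else 1.0

    for res in results:
        if res.converged and np.isfinite(res.p_nominal):
            res.p_perm = float((1 + (min_p <= res.p_nominal).sum()) / (1 + n_perm))
    return results, PermutationNull(n_perm, min_p, seed)


def genotype_combo_summary(cohort: Cohort, pair: SnpPair) -> pd.DataFrame:
    """3x3 table of case percentage per two-locus genotype combination.

    Rows index the first SNP's dosage, columns the second's; margins and
    the overall case percentage are appended.  Empty cells are NaN.
    """
    g1 = cohort.genotypes.values[:, pair.index_i]
    g2 = cohort.genotypes.values[:, pair.index_j]
    y = cohort.status
    ok = (g1 != MISSING) & (g2 != MISSING)
    g1, g2, y = g1[ok], g2[ok], y[ok]
    pct = np.full((4, 4), np.nan)
    for a in range(3):
        for b in range(3):
            sel = (g1 == a) & (g2 == b)
            if sel.any():
                pct[a, b] = 100.0 * y[sel].mean()
        sel = g1 == a
        if sel.any():
            pct[a, 3] = 100.0 * y[sel].mean()
    for b in range(3):
        sel = g2 == b
        if sel.any():
            pct[3, b] = 100.0 * y[sel].mean()
    pct[3, 3] = 100.0 * y.mean()
    labels = ["0", "1", "2", "all"]
    return pd.DataFrame(pct, index=pd.Index(labels, name="dosage_1"),
                        columns=pd.Index(labels, name="dosage_2"))


class EpistasisScan:
    """Model object for the cross-chromosome interaction scan.

    Parameters
    ----------
    cohort : Cohort
    n_permutations : int
        Label-shuffling replicates for the max-statistic null (default 1000).
    adjust : bool
        Include sex and age covariates in every fit (observed and permuted).
    seed : int
        Seed for the permutation stream.
    """

    def __init__(self, cohort: Cohort, n_permutations: int = 1000,
                 adjust: bool = True, seed: int = 0):
        self.cohort = cohort
        self.n_permutations = n_permutations
        self.adjust = adjust
        self.seed = seed
        self.pairs = enumerate_cross_chrom_pairs(cohort.snps)

    def fit(self) -> "EpistasisScanResults":
        results, null = permutation_scan(
            self.cohort, self.pairs, self.n_permutations, self.seed, self.adjust)
        return EpistasisScanResults(self, results, null)


class EpistasisScanResults:
    def __init__(self, model: EpistasisScan, results: list[EpistasisResult],
                 null: PermutationNull):
        self.model = model
        self.results = results
        self.null = null

    @property
    def table(self) -> pd.DataFrame:
        snps = self.model.cohort.snps
        return pd.DataFrame([{
            "snp_i": snps[r.pair.index_i].snp_id,
            "snp_j": snps[r.pair.index_j].snp_id,
            "b3": r.b3, "or_int": r.or_interaction,
            "p_nominal": r.p_nominal, "p_perm": r.p_perm,
            "converged": r.converged,
        } for r in self.results])

    def summary(self) -> str:
        t = self.table.sort_values("p_nominal")
        top = t.head(10)
        return (f"Cross-chromosome epistasis scan: {len(self.results)} pairs, "
                f"{self.null.n_permutations} permutations\n"
                + top.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
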