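"""Pairwise linkage disequilibrium from unphased genotypes and Gabriel blocks.

Haplotype frequencies for a SNP pair are estimated by EM (the double
heterozygote is the single ambiguous class), giving D, D' and r^2.  The 95%
confidence bounds on D' come from the normalized likelihood of the genotype
data evaluated on a D' grid with allele frequencies held at their MLEs — the
Haploview-style approximation.  Pairs are classified per Gabriel et al.:
"strong LD" when the upper bound >= 0.98 and the lower bound >= 0.7,
"recombination" when the upper bound < 0.9, otherwise non-informative.
A block is a contiguous run whose outermost pair is strong LD and in which
at least 95% of informative comparisons are strong LD.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .containers import MISSING, Cohort, SnpRecord

__all__ = ["PairwiseLD", "HaploBlock", "em_two_snp", "dprime_with_ci",
           "classify_pair", "find_blocks", "pairwise_ld_scan",
           "GabrielBlocks", "GabrielBlockResults",
           "STRONG_LD", "RECOMBINATION", "NON_INFORMATIVE"]

STRONG_LD = "strong_ld"
RECOMBINATION = "recombination"
NON_INFORMATIVE = "non_informative"

_GRID = np.round(np.arange(0, 101) * 0.01, 2)


@dataclass
class PairwiseLD:
    snp_i: int
    snp_j: int
    d: float
    d_prime: float
    r2: float
    ci_low: float
    ci_high: float
    classification: str = ""


@dataclass
class HaploBlock:
    """Inclusive SNP-index span of one LD block on a single chromosome."""

    chromosome: str
    start_index: int
    end_index: int
    n_informative: int
    frac_strong: float

    @property
    def indices(self) -> range:
        return range(self.start_index, self.end_index + 1)


def _pair_counts(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """3x3 table of joint dosage counts over complete-case samples."""
    ok = (g1 != MISSING) & (g2 != MISSING)
    a, b = g1[ok].astype(int), g2[ok].astype(int)
    counts = np.zeros((3, 3))
    np.add.at(counts, (a, b), 1.0)
    return counts


def em_two_snp(g1: np.ndarray, g2: np.ndarray, tol: float = 1e-9,
               max_iter: int = 1000) -> np.ndarray:
    """EM haplotype frequencies for one SNP pair from unphased dosages.

    Returns frequencies ``[f_BB, f_Ba, f_bB, f_bb]`` where the first letter
    is SNP 1's allele (B = counted/minor) and the second SNP 2's.  Only the
    double-heterozygote class is phase-ambiguous; the EM starts from linkage
    equilibrium.
    """
    counts = _pair_counts(g1, g2)
    n = counts.sum()
    if n == 0:
        raise ValueError("no complete-case samples")
    p1 = (counts * np.array([0, 1, 2])[:, None]).sum() / (2 * n)
    p2 = (counts * np.array([0, 1, 2])[None, :]).sum() / (2 * n)
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        raise ValueError("monomorphic SNP: D' undefined")

    # known haplotype counts from unambiguous cells; x = count of BB/bb
    # resolution of the n11 double heterozygotes
    f = np.array([p1 * p2, p1 * (1 - p2), (1 - p1) * p2, (1 - p1) * (1 - p2)])
    n_dh = counts[1, 1]
    base = np.array([
        2 * counts[2, 2] + counts[2, 1] + counts[1, 2],   # BB
        2 * counts[2, 0] + counts[2, 1] + counts[1, 0],   # Ba
        2 * counts[0, 2] + counts[0, 1] + counts[1, 2],   # bB
        2 * counts[0, 0] + counts[0, 1] + counts[1, 0],   # bb
    ])
    for _ in range(max_iter):
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        w = cis / (cis + trans) if cis + trans > 0 else 0.5
        hap = base + n_dh * np.array([w, 1 - w, 1 - w, w])
        new = hap / (2 * n)
        if np.max(np.abs(new - f)) < tol:
            f = new
            break
        f = new
    return f


def _dprime_from_freqs(f: np.ndarray) -> tuple[float, float, float]:
    """(D, D', r2) from haplotype frequencies [f_BB, f_Ba, f_bB, f_bb]."""
    pA = f[0] + f[1]
    pB = f[0] + f[2]
    d = f[0] - pA * pB
    if d >= 0:
        d_max = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        d_max = min(pA * pB, (1 - pA) * (1 - pB))
    d_prime = 0.0 if d_max == 0 else abs(d) / d_max
    denom = pA * (1 - pA) * pB * (1 - pB)
    r2 = 0.0 if denom == 0 else d * d / denom
    return float(d), float(min(d_prime, 1.0)), float(min(r2, 1.0))


def _genotype_class_probs(f: np.ndarray) -> np.ndarray:
    """3x3 joint genotype probabilities under random mating from hap freqs."""
    hap_dosage = np.array([[1, 1], [1, 0], [0, 1], [0, 0]])
    probs = np.zeros((3, 3))
    for i in range(4):
        for j in range(4):
            gi = hap_dosage[i, 0] + hap_dosage[j, 0]
            gj = hap_dosage[i, 1] + hap_dosage[j, 1]
            probs[gi, gj] += f[i] * f[j]
    return probs


def dprime_with_ci(freqs: np.ndarray, g1: np.ndarray, g2: np.ndarray,
                   snp_i: int = 0, snp_j: int = 1) -> PairwiseLD:
    """D, D', r^2 and 95% likelihood bounds on D' for one SNP pair.

    The likelihood of the observed two-SNP genotype table is evaluated on a
    D' grid (step 0.01) with allele frequencies fixed at their MLEs and the
    sign of D fixed at its MLE; the normalized cumulative likelihood yields
    the bounds: the lower bound is the largest grid value with at most 5% of
    the mass strictly below it, the upper bound the smallest grid value with
    at least 95% of the mass at or below it.
    """
    counts = _pair_counts(g1, g2)
    d_hat, d_prime, r2 = _dprime_from_freqs(freqs)
    pA = freqs[0] + freqs[1]
    pB = freqs[0] + freqs[2]
    sign = 1.0 if d_hat >= 0 else -1.0
    d_max = (min(pA * (1 - pB), (1 - pA) * pB) if sign > 0
             else min(pA * pB, (1 - pA) * (1 - pB)))

    loglik = np.empty(_GRID.size)
    for k, dp in enumerate(_GRID):
        d = sign * dp * d_max
        f = np.array([pA * pB + d, pA * (1 - pB) - d,
                      (1 - pA) * pB - d, (1 - pA) * (1 - pB) + d])
        f = np.clip(f, 1e-12, None)
        f = f / f.sum()
        probs = np.clip(_genotype_class_probs(f), 1e-300, None)
        loglik[k] = float((counts * np.log(probs)).sum())
    lik = np.exp(loglik - loglik.max())
    lik /= lik.sum()
    cum = np.cumsum(lik)
    below = np.concatenate([[0.0], cum[:-1]])    # mass strictly below grid point
    ci_low = float(_GRID[np.flatnonzero(below <= 0.05)[-1]])
    ci_high = float(_GRID[np.flatnonzero(cum >= 0.95 - 1e-12)[0]])

    ld = PairwiseLD(snp_i, snp_j, d_hat, d_prime, r2, ci_low, ci_high)
    ld.classification = classify_pair(ld)
    return ld


def classify_pair(ld: PairwiseLD) -> str:
    """Gabriel pair classification from the D' confidence bounds."""
    if ld.ci_high >= 0.98 and ld.ci_low >= 0.7:
        return STRONG_LD
    if ld.ci_high < 0.9:
        return RECOMBINATION
    return NON_INFORMATIVE


def pairwise_ld_scan(cohort: Cohort, within_chromosome_only: bool = True
                     ) -> list[PairwiseLD]:
    """All (within-chromosome) pairwise LD estimates over the panel."""
    out = []
    for i, j in combinations(range(len(cohort.snps)), 2):
        if within_chromosome_only and (
                cohort.snps[i].chromosome != cohort.snps[j].chromosome):
            continue
        g1 = cohort.genotypes.values[:, i]
        g2 = cohort.genotypes.values[:, j]
        try:
            f = em_two_snp(g1, g2)
        except ValueError:
            out.append(PairwiseLD(i, j, 0.0, 0.0, 0.0, 0.0, 1.0, NON_INFORMATIVE))
            continue
        out.append(dprime_with_ci(f, g1, g2, i, j))
    return out


def find_blocks(pairs: list[PairwiseLD], snps: list[SnpRecord],
                min_frac_strong: float = 0.95) -> list[HaploBlock]:
    """Gabriel-style LD blocks from classified within-chromosome pairs.

    Candidate spans are contiguous runs (>= 2 SNPs, one chromosome) whose
    outermost pair is strong LD; a span is accepted when it has at least one
    informative comparison and the strong-LD fraction among informative
    comparisons reaches the threshold.  Candidates are taken greedily from
    longest to shortest (ties to the leftmost start) skipping overlaps.
    """
    cls = {(p.snp_i, p.snp_j): p.classification for p in pairs}

    candidates = []
    for i, j in combinations(range(len(snps)), 2):
        if snps[i].chromosome != snps[j].chromosome:
            continue
        span = [k for k in range(i, j + 1)
                if snps[k].chromosome == snps[i].chromosome]
        if cls.get((i, j)) != STRONG_LD:
            continue
        n_strong = n_inform = 0
        for a, b in combinations(span, 2):
            c = cls.get((a, b))
            if c == STRONG_LD:
                n_strong += 1
                n_inform += 1
            elif c == RECOMBINATION:
                n_inform += 1
        if n_inform >= 1 and n_strong / n_inform >= min_frac_strong:
            candidates.append(HaploBlock(snps[i].chromosome, i, j, n_inform,
                                         n_strong / n_inform))

    candidates.sort(key=lambda b: (-(b.end_index - b.start_index), b.start_index))
    chosen: list[HaploBlock] = []
    used: set[int] = set()
    for cand in candidates:
        if any(k in used for k in cand.indices):
            continue
        chosen.append(cand)
        used.update(cand.indices)
    chosen.sort(key=lambda b: b.start_index)
    return chosen


class GabrielBlocks:
    """Model object: estimate pairwise LD and construct haplotype blocks."""

    def __init__(self, cohort: Cohort, min_frac_strong: float = 0.95):
        self.cohort = cohort
        self.min_frac_strong = min_frac_strong

    def fit(self) -> "GabrielBlockResults":
        pairs = pairwise_ld_scan(self.cohort)
        blocks = find_blocks(pairs, self.cohort.snps, self.min_frac_strong)
        return GabrielBlockResults(self, pairs, blocks)


class GabrielBlockResults:
    def __init__(self, model: GabrielBlocks, pairs: list[PairwiseLD],
                 blocks: list[HaploBlock]):
        self.model = model
        self.pairs = pairs
        self.blocks = blocks

    @property
    def pair_table(self) -> pd.DataFrame:
        snps = self.model.cohort.snps
        return pd.DataFrame([{
            "snp_i": snps[p.snp_i].snp_id, "snp_j": snps[p.snp_j].snp_id,
            "d": p.d, "d_prime": p.d_prime, "r2": p.r2,
            "ci_low": p.ci_low, "ci_high": p.ci_high,
            "classification": p.classification,
        } for p in self.pairs])

    @property
    def block_table(self) -> pd.DataFrame:
        snps = self.model.cohort.snps
        return pd.DataFrame([{
            "chromosome": b.chromosome,
            "start_snp": snps[b.start_index].snp_id,
            "end_snp": snps[b.end_index].snp_id,
            "n_snps": b.end_index - b.start_index + 1,
            "frac_strong": b.frac_strong,
        } for b in self.blocks])

    def summary(self) -> str:
        return (f"Gabriel LD blocks: {len(self.blocks)} block(s) from "
                f"{len(self.pairs)} within-chromosome pairs\n"
                + self.block_table.to_string(index=False))
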