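"""EM haplotype frequency estimation within LD blocks and haplotype tests.

Phase within a block is unobserved; the EM iterates over all haplotype-pair
resolutions consistent with each multilocus genotype, initialised at
products of allele frequencies.  Case (F_A) and control (F_U) frequencies
come from posterior-weighted haplotype counts within each status group
under the pooled-sample EM solution.  Association is tested per haplotype
(2x2 chi-square of target vs all others across status) and by an omnibus
H x 2 chi-square with H - 1 degrees of freedom — the layout of a standard
haplotype association table (SNPS, HAPLOTYPE, F_A, F_U, CHISQ, P).

Expected haplotype counts are treated as observed in the chi-square tests,
the standard toolchain convention; the extra EM uncertainty is a documented
approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MISSING, Cohort
from .ld import HaploBlock

__all__ = ["HaplotypeFreqs", "HaplotypeTestResult", "em_haplotypes",
           "hap_specific_test", "omnibus_test", "haplotype_scan",
           "HaplotypeAssociation", "HaplotypeResults", "RARE", "OMNIBUS"]

RARE = "RARE"
OMNIBUS = "OMNIBUS"

_MAX_BLOCK_SNPS = 12


@dataclass
class HaplotypeFreqs:
    """EM haplotype frequencies for one block, overall and by status."""

    snp_ids: list[str]
    haplotypes: list[str]            # allele strings, counted-allele base per site
    freq_overall: np.ndarray
    freq_cases: np.ndarray           # F_A
    freq_controls: np.ndarray        # F_U
    expected_cases: np.ndarray       # expected chromosome counts, cases
    expected_controls: np.ndarray
    log_likelihood: float
    n_iter: int


@dataclass
class HaplotypeTestResult:
    haplotype: str                   # allele string or "OMNIBUS"
    chi2: float
    df: int
    p_value: float
    reliable: bool = True


def _enumerate_pairs(genotype: tuple[int, ...]):
    """All (hap1, hap2) bitmask resolutions of one multilocus dosage vector."""
    het = [j for j, d in enumerate(genotype) if d == 1]
    base = 0
    for j, d in enumerate(genotype):
        if d == 2:
            base |= 1 << j
    if not het:
        return [(base, base)]
    first = het[0]
    pairs = []
    for bits in product((0, 1), repeat=len(het) - 1):
        h1, h2 = base, base
        h1 |= 1 << first
        for j, b in zip(het[1:], bits):
            if b:
                h1 |= 1 << j
            else:
                h2 |= 1 << j
        pairs.append((h1, h2))
    return pairs


def em_haplotypes(block_dosages: np.ndarray, status: np.ndarray,
                  alleles: tuple[np.ndarray, np.ndarray] | None = None,
                  pool_min: float = 0.01, tol: float = 1e-6,
                  max_iter: int = 5000) -> HaplotypeFreqs:
    """Multi-SNP EM haplotype frequencies from unphased block genotypes.

    Parameters
    ----------
    block_dosages : (n_samples, n_snps) dosage array for the block's SNPs.
    status : binary case/control indicator per sample.
    alleles : optional (counted, other) base arrays used to spell haplotypes;
        bitstrings of 1/0 are used otherwise.
    pool_min : haplotypes rarer than this overall are pooled into ``RARE``.

    Individuals missing any member SNP are dropped (complete case per
    block).  Refuses blocks wider than 12 SNPs (phase enumeration bound).
    """
    G = np.asarray(block_dosages)
    m = G.shape[1]
    if m < 2:
        raise ValueError("a block needs at least 2 SNPs")
    if m > _MAX_BLOCK_SNPS:
        raise ValueError(f"block of {m} SNPs exceeds the {_MAX_BLOCK_SNPS}-SNP "
                         "phase-enumeration bound")
    ok = (G != MISSING).all(axis=1)
    G = G[ok].astype(int)
    status = np.asarray(status)[ok]
    n = G.shape[0]
    if n == 0:
        raise ValueError("no complete-case samples for the block")

    # group samples by distinct genotype vector; enumerate resolutions once
    geno_keys, inverse = np.unique(G, axis=0, return_inverse=True)
    group_n = np.bincount(inverse, minlength=len(geno_keys)).astype(float)
    group_case = np.bincount(inverse, weights=(status == 1).astype(float),
                             minlength=len(geno_keys))
    group_ctrl = group_n - group_case
    pair_lists = [_enumerate_pairs(tuple(g)) for g in geno_keys]

    hap_ids = sorted({h for pl in pair_lists for pr in pl for h in pr})
    hap_pos = {h: k for k, h in enumerate(hap_ids)}
    H = len(hap_ids)

    # initialisation: products of per-SNP allele frequencies
    p = G.sum(axis=0) / (2.0 * n)
    freqs = np.array([
        np.prod([p[j] if (h >> j) & 1 else 1 - p[j] for j in range(m)])
        for h in hap_ids])
    freqs = np.clip(freqs, 1e-12, None)
    freqs /= freqs.sum()

    ll = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        counts = np.zeros(H)
        counts_case = np.zeros(H)
        counts_ctrl = np.zeros(H)
        new_ll = 0.0
        for g, pl in enumerate(pair_lists):
            w = np.array([freqs[hap_pos[a]] * freqs[hap_pos[b]] * (2 if a != b else 1)
                          for a, b in pl])
            tot = w.sum()
            if tot <= 0:
                w = np.full(len(pl), 1.0 / len(pl))
                tot = 1.0
            else:
                new_ll += group_n[g] * np.log(tot)
                w = w / tot
            for (a, b), wk in zip(pl, w):
                for h in (a, b):
                    counts[hap_pos[h]] += group_n[g] * wk
                    counts_case[hap_pos[h]] += group_case[g] * wk
                    counts_ctrl[hap_pos[h]] += group_ctrl[g] * wk
        new = counts / (2.0 * n)
        if np.max(np.abs(new - freqs)) < tol:
            freqs, ll = new, new_ll
            break
        freqs, ll = new, new_ll

    n_case = int((status == 1).sum())
    n_ctrl = n - n_case
    f_case = counts_case / (2.0 * n_case) if n_case else np.zeros(H)
    f_ctrl = counts_ctrl / (2.0 * n_ctrl) if n_ctrl else np.zeros(H)

    # spell haplotypes, then pool rare ones
    def spell(h: int) -> str:
        if alleles is None:
            return "".join("1" if (h >> j) & 1 else "0" for j in range(m))
        counted, other = alleles
        return "".join(counted[j] if (h >> j) & 1 else other[j] for j in range(m))

    names = [spell(h) for h in hap_ids]
    live = freqs > 1e-9  # numerically extinct haplotypes are dropped outright
    names = [nm for nm, keep in zip(names, live) if keep]
    freqs = freqs[live]
    counts_case, counts_ctrl = counts_case[live], counts_ctrl[live]
    f_case, f_ctrl = f_case[live], f_ctrl[live]
    common = freqs >= pool_min
    if not common.all():
        rare = ~common
        names = [nm for nm, c in zip(names, common) if c] + [RARE]
        freqs = np.concatenate([freqs[common], [freqs[rare].sum()]])
        counts_case = np.concatenate([counts_case[common], [counts_case[rare].sum()]])
        counts_ctrl = np.concatenate([counts_ctrl[common], [counts_ctrl[rare].sum()]])
        f_case = np.concatenate([f_case[common], [f_case[rare].sum()]])
        f_ctrl = np.concatenate([f_ctrl[common], [f_ctrl[rare].sum()]])

    order = np.argsort(-freqs, kind="stable")
    return HaplotypeFreqs(
        snp_ids=[], haplotypes=[names[k] for k in order],
        freq_overall=freqs[order], freq_cases=f_case[order],
        freq_controls=f_ctrl[order],
        expected_cases=counts_case[order], expected_controls=counts_ctrl[order],
        log_likelihood=float(ll), n_iter=it,
    )


def _pearson_2xk(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square on a k x 2 expected-count table."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    exp = row * col / table.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        cells = np.where(exp > 0, (table - exp) ** 2 / exp, 0.0)
    chi2 = float(cells.sum())
    df = table.shape[0] - 1
    return chi2, df, float(stats.chi2.sf(chi2, df))


def hap_specific_test(freqs: HaplotypeFreqs, target: str) -> HaplotypeTestResult:
    """2x2 chi-square of one haplotype vs all others across status."""
    if target not in freqs.haplotypes:
        raise ValueError(f"haplotype {target!r} not present")
    k = freqs.haplotypes.index(target)
    a = freqs.expected_cases[k]
    b = freqs.expected_cases.sum() - a
    c = freqs.expected_controls[k]
    d = freqs.expected_controls.sum() - c
    table = np.array([[a, c], [b, d]])
    chi2, df, p = _pearson_2xk(table)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    reliable = bool((row * col / table.sum() >= 1).all())
    return HaplotypeTestResult(target, chi2, 1, p, reliable)


def omnibus_test(freqs: HaplotypeFreqs) -> HaplotypeTestResult:
    """H x 2 chi-square comparing the full haplotype profile across status."""
    H = len(freqs.haplotypes)
    if H < 2:
        raise ValueError("omnibus test needs at least 2 haplotypes")
    table = np.column_stack([freqs.expected_cases, freqs.expected_controls])
    chi2, df, p = _pearson_2xk(table)
    return HaplotypeTestResult(OMNIBUS, chi2, df, p)


def haplotype_scan(blocks: list[HaploBlock], cohort: Cohort,
                   pool_min: float = 0.01) -> pd.DataFrame:
    """Per-block EM plus omnibus and per-haplotype tests.

    Returns a table with the standard haplotype-association columns
    ``SNPS, HAPLOTYPE, F_A, F_U, CHISQ, P`` (omnibus row first per block).
    """
    rows = []
    status = cohort.status
    for block in blocks:
        idx = list(block.indices)
        snp_ids = [cohort.snps[j].snp_id for j in idx]
        g = cohort.genotypes
        freqs = em_haplotypes(
            g.values[:, idx], status,
            alleles=(g.counted_allele[idx], g.other_allele[idx]),
            pool_min=pool_min)
        freqs.snp_ids = snp_ids
        label = "-".join(snp_ids)
        omni = omnibus_test(freqs)
        rows.append({"SNPS": label, "HAPLOTYPE": OMNIBUS, "F_A": np.nan,
                     "F_U": np.nan, "CHISQ": omni.chi2, "P": omni.p_value})
        for k, hap in enumerate(freqs.haplotypes):
            t = hap_specific_test(freqs, hap)
            rows.append({"SNPS": "", "HAPLOTYPE": hap,
                         "F_A": freqs.freq_cases[k],
                         "F_U": freqs.freq_controls[k],
                         "CHISQ": t.chi2, "P": t.p_value})
    return pd.DataFrame(rows, columns=["SNPS", "HAPLOTYPE", "F_A", "F_U",
                                       "CHISQ", "P"])


class HaplotypeAssociation:
    """Model object: haplotype association over a set of LD blocks."""

    def __init__(self, cohort: Cohort, blocks: list[HaploBlock],
                 pool_min: float = 0.01):
        self.cohort = cohort
        self.blocks = blocks
        self.pool_min = pool_min

    def fit(self) -> "HaplotypeResults":
        table = haplotype_scan(self.blocks, self.cohort, self.pool_min)
        return HaplotypeResults(self, table)


class HaplotypeResults:
    def __init__(self, model: HaplotypeAssociation, table: pd.DataFrame):
        self.model = model
        self.table = table

    def summary(self) -> str:
        return ("Haplotype-based association (EM frequencies; F_A cases, "
                "F_U controls)\n"
                + self.table.to_string(index=False,
                                       float_format=lambda v: f"{v:.4g}"))
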