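"""Per-SNP quality control: call rate, MAF, and exact Hardy-Weinberg test.

Inclusion follows the usual candidate-gene convention: a SNP passes when its
minor allele frequency exceeds the threshold, its exact HWE P value in
controls is not below the cutoff, and its call rate is adequate.  The HWE
test is the exact conditional test: given the observed allele counts, the
probability of every attainable heterozygote count is computed from the
random-mating distribution, and the P value sums the probabilities of all
configurations no more probable than the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .containers import MISSING, GenotypeMatrix, SampleRecord

__all__ = ["SnpSummary", "minor_allele_freq", "call_rate", "hwe_exact_test",
           "genotype_counts", "apply_qc"]


@dataclass
class SnpSummary:
    snp_id: str
    call_rate: float
    maf: float
    hwe_p: float
    passed: bool


def call_rate(dosages: np.ndarray) -> float:
    """Fraction of non-missing genotype calls in one SNP column."""
    d = np.asarray(dosages)
    return float((d != MISSING).sum()) / d.size


def minor_allele_freq(dosages: np.ndarray) -> float:
    """Minor allele frequency min(p, 1-p) over non-missing calls."""
    d = np.asarray(dosages)
    obs = d != MISSING
    n = int(obs.sum())
    if n == 0:
        raise ValueError("all genotypes missing; MAF undefined")
    p = float(d[obs].sum()) / (2 * n)
    return min(p, 1.0 - p)


def genotype_counts(dosages: np.ndarray) -> tuple[int, int, int]:
    """(n_major_hom, n_het, n_minor_hom) ignoring missing entries."""
    d = np.asarray(dosages)
    return (int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum()))


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test P value.

    Conditions on the observed allele counts and sums, over every attainable
    heterozygote count ``h`` (same parity as the minor-allele total), the
    probabilities of configurations with probability not exceeding the
    observed one.  Probabilities are evaluated in log space so counts in the
    tens of thousands remain stable.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("empty genotype table")
    n_a = n_Aa + 2 * n_aa            # minor allele count
    n_minor = min(n_a, 2 * n - n_a)  # symmetry in homozygote labels
    if n_minor == 0:
        return 1.0

    hs = np.arange(n_minor % 2, n_minor + 1, 2)
    # P(h) ∝ n! / (nAA! nAa! naa!) * 2^h, conditioned on allele counts
    n_aa_h = (n_minor - hs) // 2
    n_AA_h = n - n_aa_h - hs
    logp = (hs * np.log(2.0) - gammaln(hs + 1) - gammaln(n_aa_h + 1)
            - gammaln(n_AA_h + 1))
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    p_obs = p[hs == n_Aa][0]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def apply_qc(matrix: GenotypeMatrix, samples: list[SampleRecord],
             maf_min: float = 0.05, hwe_min: float = 1e-4,
             callrate_min: float = 0.97):
    """Summarise and filter SNPs.

    A SNP passes iff ``maf > maf_min`` and ``hwe_p >= hwe_min`` (computed in
    controls only) and ``call_rate >= callrate_min``.  The filtered matrix
    keeps passing SNPs in their original order; the summary covers every
    input SNP.
    """
    for t in (maf_min, hwe_min, callrate_min):
        if not 0.0 <= t <= 1.0:
            raise ValueError("QC thresholds must lie in [0, 1]")
    status = np.array([s.status for s in samples])
    if (status == 0).sum() == 0:
        raise ValueError("no controls: HWE test undefined")
    controls = status == 0

    summaries: list[SnpSummary] = []
    keep: list[int] = []
    for j in range(matrix.n_snps):
        col = matrix.values[:, j]
        cr = call_rate(col)
        maf = minor_allele_freq(col) if cr > 0 else 0.0
        ctrl = col[controls]
        ctrl = ctrl[ctrl != MISSING]
        hwe = hwe_exact_test(*genotype_counts(ctrl)) if ctrl.size else 1.0
        ok = (maf > maf_min) and (hwe >= hwe_min) and (cr >= callrate_min)
        summaries.append(SnpSummary(matrix.snp_ids[j], cr, maf, hwe, ok))
        if ok:
            keep.append(j)

    filtered = GenotypeMatrix(
        matrix.values[:, keep], matrix.counted_allele[keep],
        matrix.other_allele[keep], list(matrix.sample_ids),
        [matrix.snp_ids[j] for j in keep], matrix.monomorphic[keep],
    )
    return summaries, filtered
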