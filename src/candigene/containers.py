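"""Core in-memory containers for a case-control SNP cohort.

Genotypes are held as a dense ``n_samples x n_snps`` array of counted-allele
dosages in {0, 1, 2}, with :data:`MISSING` (-1) marking no-calls.  Which
allele is counted at each SNP is carried alongside the matrix so that
recoding to the minor allele is a well-defined, idempotent operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: Sentinel for a missing genotype call in dosage arrays (int8).
MISSING = -1

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic SNP marker in the genotyping panel.

    Parameters
    ----------
    snp_id : str
        Marker name, unique within a panel.
    chromosome : str
        Chromosome label, compared by string equality.
    position : int
        1-based physical coordinate.
    allele_a, allele_b : str
        The two observed bases; must differ.
    gene : str
        Gene-region label (e.g. ``"CACNG5"``) or ``""`` for intergenic.
    """

    snp_id: str
    chromosome: str
    position: int
    allele_a: str
    allele_b: str
    gene: str = ""

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise ValueError(f"{self.snp_id}: position must be positive")
        if self.allele_a == self.allele_b:
            raise ValueError(f"{self.snp_id}: alleles must differ")
        for a in (self.allele_a, self.allele_b):
            if a not in _VALID_BASES:
                raise ValueError(f"{self.snp_id}: invalid allele {a!r}")


@dataclass(frozen=True)
class SampleRecord:
    """One study participant: disease status plus the two model covariates.

    ``status`` is 1 for a case and 0 for a control; ``sex`` is a binary code
    (0 = male, 1 = female by the package convention); ``age`` is in years.
    """

    sample_id: str
    status: int
    sex: int
    age: int

    def __post_init__(self) -> None:
        if self.status not in (0, 1):
            raise ValueError(f"{self.sample_id}: status must be 0 or 1")
        if self.sex not in (0, 1):
            raise ValueError(f"{self.sample_id}: sex must be 0 or 1")


@dataclass
class GenotypeMatrix:
    """Dense dosage matrix with per-SNP counted-allele bookkeeping.

    ``values[i, j]`` is the number of copies of ``counted_allele[j]`` carried
    by sample ``i`` at SNP ``j``, or :data:`MISSING`.
    """

    values: np.ndarray
    counted_allele: np.ndarray  # per-SNP base whose copies are counted
    other_allele: np.ndarray    # the complementary base
    sample_ids: list[str]
    snp_ids: list[str]
    monomorphic: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be 2-D")
        n, m = self.values.shape
        if len(self.sample_ids) != n or len(self.snp_ids) != m:
            raise ValueError("dimensions inconsistent with sample/SNP lists")
        self.counted_allele = np.asarray(self.counted_allele, dtype="U1")
        self.other_allele = np.asarray(self.other_allele, dtype="U1")
        if self.counted_allele.shape != (m,) or self.other_allele.shape != (m,):
            raise ValueError("allele arrays must have one entry per SNP")
        ok = (self.values == MISSING) | ((self.values >= 0) & (self.values <= 2))
        if not ok.all():
            raise ValueError("dosages must lie in {0,1,2} or be missing")
        if self.monomorphic is None:
            self.monomorphic = np.zeros(m, dtype=bool)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    @property
    def sample_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.sample_ids)}

    @property
    def snp_index(self) -> dict[str, int]:
        return {s: j for j, s in enumerate(self.snp_ids)}

    def column(self, snp: str | int) -> np.ndarray:
        """Dosage column for one SNP (by id or panel index)."""
        j = snp if isinstance(snp, (int, np.integer)) else self.snp_index[snp]
        return self.values[:, j]

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.values.copy(), self.counted_allele.copy(), self.other_allele.copy(),
            list(self.sample_ids), list(self.snp_ids), self.monomorphic.copy(),
        )


@dataclass
class Cohort:
    """Bundle of panel, samples and genotypes with consistency checks."""

    snps: list[SnpRecord]
    samples: list[SampleRecord]
    genotypes: GenotypeMatrix

    def __post_init__(self) -> None:
        if [s.snp_id for s in self.snps] != list(self.genotypes.snp_ids):
            raise ValueError("SNP records do not match genotype matrix columns")
        if [s.sample_id for s in self.samples] != list(self.genotypes.sample_ids):
            raise ValueError("sample records do not match genotype matrix rows")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP ids in panel")

    @property
    def status(self) -> np.ndarray:
        return np.array([s.status for s in self.samples], dtype=np.int8)

    @property
    def sex(self) -> np.ndarray:
        return np.array([s.sex for s in self.samples], dtype=np.int8)

    @property
    def age(self) -> np.ndarray:
        return np.array([s.age for s in self.samples], dtype=float)

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())

    @property
    def n_controls(self) -> int:
        return len(self.samples) - self.n_cases

    def subset_snps(self, keep: Sequence[int]) -> "Cohort":
        """New cohort restricted to the given SNP panel indices (order kept)."""
        keep = list(keep)
        g = self.genotypes
        new_g = GenotypeMatrix(
            g.values[:, keep], g.counted_allele[keep], g.other_allele[keep],
            list(g.sample_ids), [g.snp_ids[j] for j in keep], g.monomorphic[keep],
        )
        return Cohort([self.snps[j] for j in keep], list(self.samples), new_g)
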