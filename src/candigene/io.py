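"""Readers and writers for cohort genotype/phenotype data.

Supported formats: PLINK-style whitespace-delimited PED/MAP text, VCF v4.2
with GT fields (via cyvcf2), and a phenotype/covariate TSV with header
``sample_id status sex age``.  PED/MAP conventions follow the de facto text
dialect: phenotype 1 = control / 2 = case, sex 1 = male / 2 = female,
missing allele token ``0``.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .containers import MISSING, Cohort, GenotypeMatrix, SampleRecord, SnpRecord

__all__ = [
    "read_plink_text", "write_plink_text", "read_vcf", "write_vcf",
    "read_phenotypes", "write_phenotypes", "recode_to_minor",
    "normalize_chromosome", "ParseError",
]


class ParseError(ValueError):
    """Malformed input file (message names the offending line/record)."""


def normalize_chromosome(label: str, strip_chr: bool = True) -> str:
    """Chromosome labels are opaque strings; optionally strip a 'chr' prefix."""
    if strip_chr and label.lower().startswith("chr"):
        return label[3:]
    return label


# ---------------------------------------------------------------------------
# PED/MAP


def read_plink_text(ped_path, map_path):
    """Read a PED/MAP pair into (snps, samples, GenotypeMatrix).

    The returned matrix counts the whole-sample minor allele at each SNP
    (ties broken toward the lexicographically smaller base).  ``"0 0"``
    genotypes become missing.
    """
    snps: list[SnpRecord] = []
    raw_alleles: list[tuple] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4:
                raise ParseError(f"{map_path}:{lineno}: expected 4 MAP columns, got {len(fields)}")
            chrom, snp_id, _cm, pos = fields
            # alleles are unknown until the PED is read; placeholders patched below
            snps.append((snp_id, chrom, int(pos)))

    m = len(snps)
    samples: list[SampleRecord] = []
    allele_rows: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise ParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} columns, got {len(fields)}"
                )
            _fid, iid, _pat, _mat, sex, pheno = fields[:6]
            if pheno not in ("1", "2"):
                raise ParseError(f"{ped_path}:{lineno}: phenotype must be 1/2, got {pheno!r}")
            if sex not in ("1", "2"):
                raise ParseError(f"{ped_path}:{lineno}: sex must be 1/2, got {sex!r}")
            samples.append(SampleRecord(iid, status=int(pheno) - 1, sex=int(sex) - 1, age=0))
            pairs = []
            toks = fields[6:]
            for j in range(m):
                a1, a2 = toks[2 * j], toks[2 * j + 1]
                for a in (a1, a2):
                    if a not in "ACGT0":
                        raise ParseError(f"{ped_path}:{lineno}: invalid allele token {a!r}")
                pairs.append((a1, a2))
            allele_rows.append(pairs)

    n = len(samples)
    values = np.full((n, m), MISSING, dtype=np.int8)
    counted = np.empty(m, dtype="U1")
    other = np.empty(m, dtype="U1")
    snp_records = []
    for j in range(m):
        observed = sorted({a for row in allele_rows for a in row[j] if a != "0"})
        if len(observed) > 2:
            raise ParseError(f"{map_path}: SNP {snps[j][0]} has >2 alleles: {observed}")
        if len(observed) == 0:
            observed = ["A", "C"]  # all-missing column: arbitrary placeholder alleles
        elif len(observed) == 1:
            observed.append("A" if observed[0] != "A" else "C")
        a, b = observed
        counted[j], other[j] = b, a  # provisional; recode below picks the minor
        snp_id, chrom, pos = snps[j]
        snp_records.append(SnpRecord(snp_id, chrom, pos, a, b))
        for i, row in enumerate(allele_rows):
            a1, a2 = row[j]
            if a1 == "0" or a2 == "0":
                continue
            values[i, j] = (a1 == b) + (a2 == b)

    matrix = GenotypeMatrix(values, counted, other, [s.sample_id for s in samples],
                            [r.snp_id for r in snp_records])
    return snp_records, samples, recode_to_minor(matrix)


def write_plink_text(snps, samples, matrix, ped_path, map_path) -> None:
    """Write PED/MAP text; inverse of :func:`read_plink_text` up to minor recoding."""
    with open(map_path, "w") as fh:
        for rec in snps:
            fh.write(f"{rec.chromosome}\t{rec.snp_id}\t0\t{rec.position}\n")
    values = matrix.values
    with open(ped_path, "w") as fh:
        for i, s in enumerate(samples):
            row = [s.sample_id, s.sample_id, "0", "0", str(s.sex + 1), str(s.status + 1)]
            for j in range(matrix.n_snps):
                d = values[i, j]
                if d == MISSING:
                    row += ["0", "0"]
                else:
                    c, o = matrix.counted_allele[j], matrix.other_allele[j]
                    row += [c] * int(d) + [o] * (2 - int(d))
            fh.write(" ".join(row) + "\n")


# ---------------------------------------------------------------------------
# phenotype TSV

_PHENO_HEADER = ["sample_id", "status", "sex", "age"]


def read_phenotypes(path) -> list[SampleRecord]:
    """Read the phenotype/covariate TSV (header: sample_id, status, sex, age)."""
    with open(path) as fh:
        reader = csv.DictReader(
            (ln for ln in fh if not ln.startswith("#")), delimiter="\t"
        )
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != _PHENO_HEADER:
            raise ParseError(f"{path}: expected header {' '.join(_PHENO_HEADER)}")
        return [
            SampleRecord(row["sample_id"], int(row["status"]), int(row["sex"]),
                         int(row["age"]))
            for row in reader
        ]


def write_phenotypes(samples, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_PHENO_HEADER) + "\n")
        for s in samples:
            fh.write(f"{s.sample_id}\t{s.status}\t{s.sex}\t{s.age}\n")


# ---------------------------------------------------------------------------
# VCF


def read_vcf(vcf_path, pheno_path):
    """Read genotypes from a VCF (GT only) plus a phenotype TSV.

    Dosages count the ALT allele; apply :func:`recode_to_minor` before
    association analysis.  Phase separators are accepted and ignored.
    Multi-allelic records are rejected.
    """
    from cyvcf2 import VCF

    pheno = {s.sample_id: s for s in read_phenotypes(pheno_path)}
    vcf = VCF(str(vcf_path))
    missing_ids = [s for s in vcf.samples if s not in pheno]
    if missing_ids:
        raise ParseError(
            f"{vcf_path}: samples absent from phenotype table: {', '.join(missing_ids)}"
        )
    samples = [pheno[s] for s in vcf.samples]

    snps: list[SnpRecord] = []
    cols: list[np.ndarray] = []
    counted, other = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ParseError(f"{vcf_path}: multi-allelic record at {var.CHROM}:{var.POS}")
        ref, alt = var.REF, var.ALT[0]
        snps.append(SnpRecord(var.ID or f"{var.CHROM}:{var.POS}", var.CHROM, var.POS,
                              ref, alt, gene=""))
        gt = np.asarray(var.genotype.array())[:, :2]
        col = np.where((gt < 0).any(axis=1), MISSING, gt.clip(min=0).sum(axis=1))
        cols.append(col.astype(np.int8))
        counted.append(alt)
        other.append(ref)

    values = (np.column_stack(cols) if cols
              else np.empty((len(samples), 0), dtype=np.int8))
    matrix = GenotypeMatrix(values, np.array(counted, dtype="U1"),
                            np.array(other, dtype="U1"),
                            [s.sample_id for s in samples],
                            [r.snp_id for r in snps])
    return snps, samples, matrix


def write_vcf(snps, samples, matrix, vcf_path) -> None:
    """Write an uncompressed VCF v4.2 with GT fields; ALT is the counted allele."""
    idx = range(len(snps))  # panel order; panels are built coordinate-sorted
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(s.sample_id for s in samples) + "\n")
        gts = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j in idx:
            rec = snps[j]
            ref = matrix.other_allele[j]
            alt = matrix.counted_allele[j]
            row = [rec.chromosome, str(rec.position), rec.snp_id, ref, alt,
                   ".", "PASS", ".", "GT"]
            row += [gts[int(d)] for d in matrix.values[:, j]]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# minor-allele recoding


def recode_to_minor(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Recode every SNP so the counted allele is the whole-sample minor allele.

    A dosage ``d`` becomes ``2 - d`` wherever the counted allele's frequency
    exceeds 0.5; exact ties count the lexicographically smaller base.
    Monomorphic SNPs are flagged, not dropped.  Idempotent.
    """
    out = matrix.copy()
    for j in range(out.n_snps):
        col = out.values[:, j]
        obs = col != MISSING
        n_obs = int(obs.sum())
        if n_obs == 0:
            out.monomorphic[j] = True
            continue
        freq = float(col[obs].sum()) / (2 * n_obs)
        flip = freq > 0.5 or (freq == 0.5 and out.counted_allele[j] > out.other_allele[j])
        if flip:
            out.values[obs, j] = 2 - col[obs]
            out.counted_allele[j], out.other_allele[j] = (
                out.other_allele[j], out.counted_allele[j])
            freq = 1.0 - freq
        out.monomorphic[j] = freq in (0.0, 1.0)
    return out
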