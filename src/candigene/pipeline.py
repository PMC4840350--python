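"""Pipeline orchestration: config, stage chaining, and TSV report writing.

Stages run in the analysis order QC -> single-marker association -> LD
blocks -> haplotype association -> epistasis.  Every output TSV starts with
header comments naming the tool version, the seed and a hash of the
configuration, and each stage writes only declared files so stages can be
re-run individually.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import SingleMarkerAssociation
from .containers import Cohort
from .epistasis import EpistasisScan
from .haplotype import HaplotypeAssociation
from .io import read_phenotypes, read_plink_text, read_vcf, recode_to_minor
from .ld import GabrielBlocks
from .qc import apply_qc
from .simulate import (CohortSpec, EffectSpec, RegionSpec, default_study_config,
                       simulate_cohort)

__all__ = ["PipelineConfig", "run_pipeline", "regional_table", "load_cohort",
           "simulate_from_config", "config_from_yaml"]

log = logging.getLogger("candigene")


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; exactly one input source.

    Either ``vcf``+``phenotypes`` or ``ped``+``map`` point at real data, or
    ``simulate = True`` uses the built-in study design (optionally overridden
    through ``simulation``, a dict with CohortSpec / region / effect fields).
    """

    out_dir: str = "candigene_out"
    seed: int = 0
    simulate: bool = False
    simulation: dict = field(default_factory=dict)
    vcf: str | None = None
    phenotypes: str | None = None
    ped: str | None = None
    map: str | None = None
    maf_min: float = 0.05
    hwe_min: float = 1e-4
    callrate_min: float = 0.97
    models: tuple = ("additive", "dominant", "recessive")
    adjust: bool = True
    alpha: float = 0.05
    n_permutations: int = 1000

    def __post_init__(self) -> None:
        sources = [self.simulate, self.vcf is not None, self.ped is not None]
        if sum(sources) != 1:
            raise ValueError("exactly one of simulate / vcf / ped must be set")

    def digest(self) -> str:
        payload = {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def config_from_yaml(path) -> PipelineConfig:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "models" in data:
        data["models"] = tuple(data["models"])
    return PipelineConfig(**data)


def load_cohort(config: PipelineConfig) -> Cohort:
    """Read (or simulate) the cohort named by the config, minor-recoded."""
    if config.simulate:
        return simulate_from_config(config)
    if config.vcf is not None:
        if config.phenotypes is None:
            raise ValueError("a VCF input needs a phenotype TSV")
        snps, samples, matrix = read_vcf(config.vcf, config.phenotypes)
        matrix = recode_to_minor(matrix)
    else:
        snps, samples, matrix = read_plink_text(config.ped, config.map)
        if config.phenotypes is not None:
            by_id = {s.sample_id: s for s in read_phenotypes(config.phenotypes)}
            samples = [by_id.get(s.sample_id, s) for s in samples]
    return Cohort(snps, samples, matrix)


def simulate_from_config(config: PipelineConfig) -> Cohort:
    cohort_spec, regions, effects = default_study_config(seed=config.seed)
    sim = dict(config.simulation)
    spec_kwargs = {k: sim[k] for k in (
        "n_cases", "n_controls", "missing_rate", "age_mean", "age_sd",
        "age_min", "age_max", "female_fraction") if k in sim}
    if spec_kwargs:
        cohort_spec = CohortSpec(seed=config.seed, **spec_kwargs)
    if "regions" in sim:
        from .simulate import build_haplotype_pool

        regions = []
        for r in sim["regions"]:
            pool = r.get("haplotypes") or build_haplotype_pool(
                r["n_snps"], r.get("maf", 0.3), r.get("ld_level", 0.95))
            regions.append(RegionSpec(
                gene=r["gene"], chromosome=str(r["chromosome"]),
                n_snps=r["n_snps"], haplotypes=[tuple(h) for h in pool],
                start=r.get("start", 1_000_000)))
    if "main_effects" in sim or "interaction_effects" in sim or "intercept" in sim:
        effects = EffectSpec(
            main_effects=dict(sim.get("main_effects", {})),
            interaction_effects={tuple(k.split(",")) if isinstance(k, str) else tuple(k): v
                                 for k, v in sim.get("interaction_effects", {}).items()},
            sex_effect=sim.get("sex_effect", 0.0),
            age_effect=sim.get("age_effect", 0.0),
            intercept=sim.get("intercept", effects.intercept),
        )
    snps, samples, matrix = simulate_cohort(cohort_spec, regions, effects)
    return Cohort(snps, samples, matrix)


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# candigene {__version__}\n")
        fh.write(f"# seed={config.seed} config_hash={config.digest()}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages; returns the output directory of TSV reports."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    log.info("loading cohort (seed=%d)", config.seed)
    cohort = load_cohort(config)
    log.info("cohort: %d samples (%d cases), %d SNPs",
             len(cohort.samples), cohort.n_cases, len(cohort.snps))

    # QC
    summaries, filtered = apply_qc(cohort.genotypes, cohort.samples,
                                   config.maf_min, config.hwe_min,
                                   config.callrate_min)
    qc_df = pd.DataFrame([{
        "snp_id": s.snp_id, "call_rate": s.call_rate, "maf": s.maf,
        "hwe_p": s.hwe_p, "pass": s.passed} for s in summaries])
    _write_tsv(qc_df, out / "qc.tsv", config)
    keep = [j for j, s in enumerate(summaries) if s.passed]
    cohort = cohort.subset_snps(keep)
    log.info("QC: %d/%d SNPs pass", len(keep), len(summaries))

    # single-marker association
    assoc = SingleMarkerAssociation(cohort, config.models, config.adjust,
                                    config.alpha).fit()
    _write_tsv(assoc.table, out / "association.tsv", config)
    log.info("single-marker scan done (%.1fs)", time.time() - t0)

    # LD blocks
    ldres = GabrielBlocks(cohort).fit()
    _write_tsv(ldres.pair_table, out / "ld_pairs.tsv", config)
    _write_tsv(ldres.block_table, out / "blocks.tsv", config)
    log.info("blocks: %d", len(ldres.blocks))

    # haplotype association
    hap = HaplotypeAssociation(cohort, ldres.blocks).fit()
    _write_tsv(hap.table, out / "haplotypes.tsv", config)

    # epistasis
    epi = EpistasisScan(cohort, config.n_permutations, config.adjust,
                        config.seed).fit()
    _write_tsv(epi.table, out / "epistasis.tsv", config)
    if epi.null.n_permutations:
        _write_tsv(pd.DataFrame({"min_p": epi.null.min_p_values}),
                   out / "epistasis_null.tsv", config)
    log.info("pipeline finished in %.1fs", time.time() - t0)
    return out


def regional_table(assoc_table: pd.DataFrame, snps, center_snp: str,
                   window: int = 1_000_000, model: str = "additive"
                   ) -> pd.DataFrame:
    """Position vs -log10 P table for SNPs around a center SNP.

    Rows cover SNPs within ``window/2`` of the center's position on the same
    chromosome, sorted by position; the center SNP is flagged as reference.
    """
    by_id = {r.snp_id: r for r in snps}
    if center_snp not in by_id:
        raise ValueError(f"center SNP {center_snp!r} not in panel")
    center = by_id[center_snp]
    sub = assoc_table[assoc_table["model"] == model]
    rows = []
    for _, r in sub.iterrows():
        rec = by_id.get(r["snp_id"])
        if rec is None or rec.chromosome != center.chromosome:
            continue
        if abs(rec.position - center.position) > window / 2:
            continue
        rows.append({
            "snp_id": rec.snp_id, "chromosome": rec.chromosome,
            "position": rec.position,
            "neg_log10_p": float(-np.log10(r["p_value"])),
            "genotyped": True,
            "reference": rec.snp_id == center_snp,
        })
    return (pd.DataFrame(rows, columns=["snp_id", "chromosome", "position",
                                        "neg_log10_p", "genotyped", "reference"])
            .sort_values("position").reset_index(drop=True))
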