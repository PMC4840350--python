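"""Single-marker case-control association tests.

Each SNP is tested under three genetic codings of the minor-allele dosage —
additive (0/1/2), dominant (carrier vs non-carrier) and recessive (minor
homozygote vs rest) — by covariate-adjusted logistic regression with Wald
tests, plus the unadjusted allele-count chi-square ("allelic") test on the
2x2 allele table.  Family-wise control uses the Bonferroni threshold
alpha / m.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MISSING, Cohort
from .glm import LogisticFit, fit_logistic
from .qc import genotype_counts

__all__ = [
    "CodedGenotype", "AssocResult", "code_genotypes", "allelic_test",
    "single_marker_scan", "bonferroni_threshold", "SingleMarkerAssociation",
    "SingleMarkerResults", "GENETIC_MODELS",
]

GENETIC_MODELS = ("additive", "dominant", "recessive")
_Z95 = 1.959964


@dataclass
class CodedGenotype:
    """Numeric genetic-model coding of a minor-allele dosage column.

    Additive keeps the dosage; dominant maps {1,2} to 1; recessive maps 2 to
    1 and {0,1} to 0.  Missing dosages become NaN.
    """

    model: str
    values: np.ndarray


@dataclass
class AssocResult:
    snp_id: str
    model: str
    odds_ratio: float
    ci95_low: float
    ci95_high: float
    p_value: float
    counts: dict = field(default_factory=dict)
    converged: bool = True
    beta: float = float("nan")
    se: float = float("nan")


def code_genotypes(dosages: np.ndarray, model: str) -> CodedGenotype:
    """Apply one of the three genetic-model codings to a dosage column."""
    d = np.asarray(dosages, dtype=float)
    d = np.where(np.asarray(dosages) == MISSING, np.nan, d)
    if model == "additive":
        v = d
    elif model == "dominant":
        v = np.where(np.isnan(d), np.nan, (d >= 1).astype(float))
    elif model == "recessive":
        v = np.where(np.isnan(d), np.nan, (d == 2).astype(float))
    else:
        raise ValueError(f"unknown genetic model {model!r}")
    return CodedGenotype(model, v)


def allelic_test(case_counts, control_counts):
    """Allele-count chi-square test on the 2x2 allele table.

    Parameters are genotype count triples ``(n_major_hom, n_het,
    n_minor_hom)`` for cases and controls.  Genotypes collapse to allele
    counts (2N chromosomes per group); the test is the 1-df Pearson
    chi-square without continuity correction, and the odds ratio is the
    minor-allele odds in cases over controls (0.5 added to every cell when
    one is empty, flagged via ``corrected``).

    Returns
    -------
    (chi2, p, odds_ratio, corrected)
    """
    (a0, a1, a2), (u0, u1, u2) = case_counts, control_counts
    case_minor = a1 + 2 * a2
    case_major = a1 + 2 * a0
    ctrl_minor = u1 + 2 * u2
    ctrl_major = u1 + 2 * u0
    if case_minor + case_major == 0 or ctrl_minor + ctrl_major == 0:
        raise ValueError("both groups must be non-empty")
    table = np.array([[case_minor, case_major], [ctrl_minor, ctrl_major]], dtype=float)
    if table.sum(axis=0).min() == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    corrected = (table == 0).any()
    t = table + 0.5 if corrected else table
    odds_ratio = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return float(chi2), float(p), float(odds_ratio), bool(corrected)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha / m for m tests."""
    if m < 1:
        raise ValueError("number of tests must be at least 1")
    return alpha / m


def _fit_snp(coded: np.ndarray, y: np.ndarray, covars: np.ndarray | None) -> LogisticFit:
    cols = [np.ones_like(coded), coded]
    if covars is not None:
        cols.extend(covars.T)
    X = np.column_stack(cols)
    ok = ~np.isnan(X).any(axis=1)
    return fit_logistic(X[ok], y[ok])


def single_marker_scan(cohort: Cohort, models=GENETIC_MODELS,
                       adjust: bool = True, allelic: bool = True) -> list[AssocResult]:
    """Per-SNP logistic association under each genetic model.

    With ``adjust`` the design includes sex and age.  Rows missing the SNP's
    genotype are dropped per SNP (complete case).  The unadjusted allelic
    test is emitted alongside unless ``allelic`` is False.  A fit that fails
    to converge is recorded in its result row; the scan continues.
    """
    y = cohort.status.astype(float)
    covars = np.column_stack([cohort.sex, cohort.age]).astype(float) if adjust else None
    cases = y == 1
    out: list[AssocResult] = []
    for j, rec in enumerate(cohort.snps):
        col = cohort.genotypes.values[:, j]
        counts = {
            "cases": genotype_counts(col[cases]),
            "controls": genotype_counts(col[~cases]),
        }
        if allelic:
            chi2, p, orr, corrected = allelic_test(counts["cases"], counts["controls"])
            se = _allelic_log_or_se(counts, corrected)
            out.append(AssocResult(rec.snp_id, "allelic", orr,
                                   float(np.exp(np.log(orr) - _Z95 * se)),
                                   float(np.exp(np.log(orr) + _Z95 * se)),
                                   p, counts, True, float(np.log(orr)), se))
        for model in models:
            coded = code_genotypes(col, model)
            fit = _fit_snp(coded.values, y, covars)
            b, se = float(fit.params[1]), float(fit.bse[1])
            out.append(AssocResult(
                rec.snp_id, model, _safe_exp(b),
                _safe_exp(b - _Z95 * se), _safe_exp(b + _Z95 * se),
                float(fit.pvalues[1]), counts, fit.converged, b, se,
            ))
    return out


def _safe_exp(x: float) -> float:
    return float(np.exp(np.clip(x, -700, 700)))


def _allelic_log_or_se(counts, corrected: bool) -> float:
    (a0, a1, a2) = counts["cases"]
    (u0, u1, u2) = counts["controls"]
    cells = np.array([a1 + 2 * a2, a1 + 2 * a0, u1 + 2 * u2, u1 + 2 * u0], dtype=float)
    if corrected:
        cells += 0.5
    return float(np.sqrt((1.0 / cells).sum()))


def results_table(results: list[AssocResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "snp_id": r.snp_id, "model": r.model, "odds_ratio": r.odds_ratio,
            "ci95_low": r.ci95_low, "ci95_high": r.ci95_high,
            "p_value": r.p_value, "converged": r.converged,
        })
    return pd.DataFrame(rows)


class SingleMarkerAssociation:
    """Model object for the per-SNP association scan.

    Parameters
    ----------
    cohort : Cohort
        QC-passing genotypes plus phenotypes.
    models : sequence of str
        Genetic codings to fit (subset of additive/dominant/recessive).
    adjust : bool
        Include sex and age as covariates in the logistic fits.
    alpha : float
        Family-wise level used for the Bonferroni threshold in the summary.
    """

    def __init__(self, cohort: Cohort, models=GENETIC_MODELS,
                 adjust: bool = True, alpha: float = 0.05):
        unknown = set(models) - set(GENETIC_MODELS)
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")
        self.cohort = cohort
        self.models = tuple(models)
        self.adjust = adjust
        self.alpha = alpha

    def fit(self) -> "SingleMarkerResults":
        res = single_marker_scan(self.cohort, self.models, self.adjust)
        thr = bonferroni_threshold(self.alpha, len(self.cohort.snps))
        return SingleMarkerResults(self, res, thr)


class SingleMarkerResults:
    """Estimates, Wald CIs and P values for every SNP x model combination."""

    def __init__(self, model: SingleMarkerAssociation,
                 results: list[AssocResult], threshold: float):
        self.model = model
        self.results = results
        self.bonferroni = threshold

    @property
    def table(self) -> pd.DataFrame:
        t = results_table(self.results)
        t["significant"] = t["p_value"] < self.bonferroni
        return t

    def summary(self) -> str:
        t = self.table
        lines = [
            "Single-marker case-control association",
            f"  SNPs: {len(self.model.cohort.snps)}   "
            f"cases: {self.model.cohort.n_cases}   "
            f"controls: {self.model.cohort.n_controls}",
            f"  covariate adjustment: {'sex+age' if self.model.adjust else 'none'}",
            f"  Bonferroni threshold: {self.bonferroni:.3g}",
            t.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)
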