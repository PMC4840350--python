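"""Odds-ratio meta-analysis and case-control genetic power calculation.

Meta-analysis pools per-study log odds ratios by inverse-variance weighting
(fixed effect) and by the DerSimonian-Laird moment estimator of the
between-study variance tau^2 (random effects).  Study standard errors may
be given directly or recovered from symmetric 95% CIs on the log scale.

Power for the 1-df allele-count (allelic/trend) test uses the normal
approximation: the case allele frequency is derived from the control MAF
and the per-allele OR through the odds transform, and the detectable
standardized difference is compared with the two-sided critical value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["StudyEffect", "MetaResult", "PowerSpec", "meta_fixed",
           "meta_random", "power_case_control", "MetaAnalysis", "MetaResults"]

_Z95 = 1.959964


@dataclass
class StudyEffect:
    """One study's odds ratio with either a 95% CI or a log-OR SE."""

    label: str
    odds_ratio: float
    ci95_low: float | None = None
    ci95_high: float | None = None
    se_log_or: float | None = None
    n_cases: int | None = None
    n_controls: int | None = None

    def __post_init__(self) -> None:
        if self.odds_ratio <= 0:
            raise ValueError(f"{self.label}: odds ratio must be positive")
        if self.se_log_or is None:
            if self.ci95_low is None or self.ci95_high is None:
                raise ValueError(f"{self.label}: need a CI or an SE")
            if not 0 < self.ci95_low <= self.odds_ratio <= self.ci95_high:
                raise ValueError(f"{self.label}: CI must bracket the OR")
            self.se_log_or = (np.log(self.ci95_high) - np.log(self.ci95_low)) / (2 * _Z95)
        if self.se_log_or <= 0:
            raise ValueError(f"{self.label}: SE must be positive")


@dataclass
class MetaResult:
    pooled_or_fixed: float | None = None
    ci95_fixed: tuple[float, float] | None = None
    pooled_or_random: float | None = None
    ci95_random: tuple[float, float] | None = None
    q_statistic: float = 0.0
    q_pvalue: float = 1.0
    i2: float = 0.0
    tau2: float = 0.0
    k: int = 0


def _fixed_core(effects: list[StudyEffect]):
    logs = np.array([np.log(e.odds_ratio) for e in effects])
    w = np.array([1.0 / e.se_log_or**2 for e in effects])
    pooled = float((w * logs).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    q = float((w * (logs - pooled) ** 2).sum())
    return logs, w, pooled, se, q


def meta_fixed(effects: list[StudyEffect]) -> MetaResult:
    """Inverse-variance fixed-effect pooled odds ratio with heterogeneity."""
    if not effects:
        raise ValueError("at least one study required")
    logs, w, pooled, se, q = _fixed_core(effects)
    k = len(effects)
    i2 = max(0.0, (q - (k - 1)) / q) if q > 0 else 0.0
    return MetaResult(
        pooled_or_fixed=float(np.exp(pooled)),
        ci95_fixed=(float(np.exp(pooled - _Z95 * se)),
                    float(np.exp(pooled + _Z95 * se))),
        q_statistic=q,
        q_pvalue=float(stats.chi2.sf(q, k - 1)) if k > 1 else 1.0,
        i2=i2, tau2=0.0, k=k,
    )


def meta_random(effects: list[StudyEffect]) -> MetaResult:
    """DerSimonian-Laird random-effects pooled odds ratio.

    tau^2 = max(0, (Q - (k-1)) / (sum(w) - sum(w^2)/sum(w))); with tau^2 = 0
    (or a single study) the random-effects estimate equals the fixed one.
    """
    if not effects:
        raise ValueError("at least one study required")
    res = meta_fixed(effects)
    k = len(effects)
    logs, w, pooled_f, _, q = _fixed_core(effects)
    if k == 1:
        tau2 = 0.0
    else:
        c = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0
    w_star = np.array([1.0 / (e.se_log_or**2 + tau2) for e in effects])
    pooled = float((w_star * logs).sum() / w_star.sum())
    se = float(1.0 / np.sqrt(w_star.sum()))
    res.pooled_or_random = float(np.exp(pooled))
    res.ci95_random = (float(np.exp(pooled - _Z95 * se)),
                       float(np.exp(pooled + _Z95 * se)))
    res.tau2 = float(tau2)
    return res


@dataclass
class PowerSpec:
    """Design parameters for the allelic-test power calculation."""

    n_cases: int
    n_controls: int
    maf: float                 # control minor allele frequency
    per_allele_or: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.maf <= 0.5:
            raise ValueError("maf must lie in (0, 0.5]")
        if self.per_allele_or <= 0:
            raise ValueError("per_allele_or must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def power_case_control(spec: PowerSpec) -> float:
    """Analytic power of the two-sided 1-df allele-count test.

    The case allele frequency comes from the odds transform
    ``odds_case = OR * p/(1-p)``; the test statistic's noncentrality uses
    binomial variances at 2N chromosomes per group.  Returns ``alpha``
    (the size) when OR = 1.
    """
    p0 = spec.maf
    if spec.per_allele_or == 1.0:
        return spec.alpha
    odds = spec.per_allele_or * p0 / (1 - p0)
    p1 = odds / (1 + odds)
    se = np.sqrt(p1 * (1 - p1) / (2 * spec.n_cases)
                 + p0 * (1 - p0) / (2 * spec.n_controls))
    z_crit = stats.norm.ppf(1 - spec.alpha / 2)
    return float(stats.norm.cdf(abs(p1 - p0) / se - z_crit))


def simulate_power(spec: PowerSpec, n_sims: int = 5000, seed: int = 0) -> float:
    """Monte-Carlo power: simulate allele-count 2x2 tables and test each."""
    rng = np.random.default_rng(seed)
    p0 = spec.maf
    odds = spec.per_allele_or * p0 / (1 - p0)
    p1 = odds / (1 + odds)
    m_case = 2 * spec.n_cases
    m_ctrl = 2 * spec.n_controls
    x1 = rng.binomial(m_case, p1, size=n_sims)
    x0 = rng.binomial(m_ctrl, p0, size=n_sims)
    # Pearson chi-square on each 2x2 allele table, vectorised
    n = m_case + m_ctrl
    tot_minor = x1 + x0
    tot_major = n - tot_minor
    num = (x1 * (m_ctrl - x0) - x0 * (m_case - x1)).astype(float) ** 2 * n
    den = tot_minor * tot_major * m_case * m_ctrl
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(den > 0, num / den, 0.0)
    crit = stats.chi2.ppf(1 - spec.alpha, 1)
    return float((chi2 > crit).mean())


class MetaAnalysis:
    """Model object pooling study odds ratios under both effect models."""

    def __init__(self, effects: list[StudyEffect]):
        if not effects:
            raise ValueError("at least one study required")
        self.effects = list(effects)

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "MetaAnalysis":
        """Build from a forest-table DataFrame (label, or, ci_low, ci_high)."""
        effects = [
            StudyEffect(str(r["label"]), float(r["or"]),
                        float(r["ci_low"]), float(r["ci_high"]))
            for _, r in table.iterrows()
        ]
        return cls(effects)

    def fit(self) -> "MetaResults":
        return MetaResults(self, meta_random(self.effects))


class MetaResults:
    def __init__(self, model: MetaAnalysis, result: MetaResult):
        self.model = model
        self.result = result

    @property
    def table(self) -> pd.DataFrame:
        """Forest-plot-ready study table plus pooled rows."""
        rows = [{
            "label": e.label, "or": e.odds_ratio,
            "ci_low": float(np.exp(np.log(e.odds_ratio) - _Z95 * e.se_log_or)),
            "ci_high": float(np.exp(np.log(e.odds_ratio) + _Z95 * e.se_log_or)),
            "weight_fixed": 1.0 / e.se_log_or**2,
        } for e in self.model.effects]
        r = self.result
        rows.append({"label": "POOLED_FIXED", "or": r.pooled_or_fixed,
                     "ci_low": r.ci95_fixed[0], "ci_high": r.ci95_fixed[1],
                     "weight_fixed": np.nan})
        rows.append({"label": "POOLED_RANDOM", "or": r.pooled_or_random,
                     "ci_low": r.ci95_random[0], "ci_high": r.ci95_random[1],
                     "weight_fixed": np.nan})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        r = self.result
        return (
            f"Meta-analysis of {r.k} studies\n"
            f"  fixed effect:  OR = {r.pooled_or_fixed:.4f} "
            f"(95% CI {r.ci95_fixed[0]:.4f}-{r.ci95_fixed[1]:.4f})\n"
            f"  random effects: OR = {r.pooled_or_random:.4f} "
            f"(95% CI {r.ci95_random[0]:.4f}-{r.ci95_random[1]:.4f})\n"
            f"  Q = {r.q_statistic:.3f} (P = {r.q_pvalue:.3g}), "
            f"I2 = {100 * r.i2:.1f}%, tau2 = {r.tau2:.4g}"
        )
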