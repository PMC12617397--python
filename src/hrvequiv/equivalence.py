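"""Equivalence testing of High- vs Low-HRV groups by two one-sided tests.

Participants are dichotomized at the sample median of log-RMSSD; the smallest
effect size of interest (SESOI) is ±5% of each outcome's maximum possible
score; the pooled High−Low mixed-model coefficient is tested against those
bounds with two one-sided t tests (TOST), complemented by a 90% confidence
interval.  At alpha = 0.05 the two verdicts (both one-sided p < alpha; 90% CI
inside the bounds) coincide algebraically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .modeling import ModelSpec, PooledMIModel

__all__ = [
    "SesoiSpec",
    "EquivalenceResult",
    "median_split",
    "sesoi_bounds",
    "tost",
    "ci90",
    "run_equivalence_suite",
    "EquivalenceModel",
    "EquivalenceResults",
]

#: Maximum possible score per outcome; the screener total uses the
#: 75-point maximum implied by its published 5% bound of 3.75.
DEFAULT_SCALE_MAX = {
    "ders": 60.0,
    "mmapp_phqa": 27.0,
    "mmapp_gad7": 21.0,
    "mmapp_total": 75.0,
    "dbis": 24.0,
    "false_alarm_pct": 100.0,
    "immediate_reward_pct": 100.0,
}


@dataclass(frozen=True)
class SesoiSpec:
    fraction: float = 0.05
    scale_max: dict = field(default_factory=lambda: dict(DEFAULT_SCALE_MAX))


def sesoi_bounds(outcome: str, spec: SesoiSpec | None = None):
    """Symmetric equivalence bounds (lower, upper) = ±fraction × scale maximum."""
    if spec is None:
        spec = SesoiSpec()
    if outcome not in spec.scale_max:
        raise KeyError(f"no scale maximum configured for outcome {outcome!r}")
    delta = spec.fraction * spec.scale_max[outcome]
    return -delta, delta


def median_split(log_rmssd) -> np.ndarray:
    """Labels "High" for values strictly above the sample median, else "Low"."""
    x = np.asarray(log_rmssd, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("median split needs at least 2 distinct values")
    med = np.median(x)
    return np.where(x > med, "High", "Low")


@dataclass
class EquivalenceResult:
    outcome: str
    b: float
    se: float
    df: float
    delta_lower: float
    delta_upper: float
    t_lower: float
    t_upper: float
    p_lower: float
    p_upper: float
    ci90: tuple
    alpha: float = 0.05

    @property
    def equivalent(self) -> bool:
        return self.p_lower < self.alpha and self.p_upper < self.alpha

    @property
    def verdict(self) -> str:
        return "equivalent" if self.equivalent else "not_equivalent"


def ci90(b: float, se: float, df: float):
    """Two-sided 90% confidence interval B ± t(0.95, df) · SE."""
    if se < 0:
        raise ValueError("SE must be non-negative")
    half = stats.t.ppf(0.95, df) * se
    return (b - half, b + half)


def tost(
    b: float,
    se: float,
    df: float,
    bounds,
    alpha: float = 0.05,
    outcome: str = "",
) -> EquivalenceResult:
    """Two one-sided t tests of B against (delta_lower, delta_upper).

    The lower test rejects "true difference <= delta_lower" when
    t_lower = (B − ΔL)/SE is large; the upper test rejects
    "true difference >= delta_upper" when t_upper = (B − ΔU)/SE is small.
    """
    lo, hi = bounds
    if se <= 0:
        raise ValueError("SE must be positive")
    if df <= 0:
        raise ValueError("df must be positive")
    if not lo < hi:
        raise ValueError("lower bound must be below upper bound")
    t_lower = (b - lo) / se
    t_upper = (b - hi) / se
    return EquivalenceResult(
        outcome=outcome,
        b=b,
        se=se,
        df=df,
        delta_lower=lo,
        delta_upper=hi,
        t_lower=t_lower,
        t_upper=t_upper,
        p_lower=float(stats.t.sf(t_lower, df)),
        p_upper=float(stats.t.cdf(t_upper, df)),
        ci90=ci90(b, se, df),
        alpha=alpha,
    )


@dataclass
class EquivalenceResults:
    """Equivalence verdicts for all requested outcomes."""

    results: list

    def __iter__(self):
        return iter(self.results)

    def summary(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append(
                {
                    "outcome": r.outcome,
                    "B": r.b,
                    "ci90_lo": r.ci90[0],
                    "ci90_hi": r.ci90[1],
                    "SE": r.se,
                    "df": r.df,
                    "delta_lower": r.delta_lower,
                    "delta_upper": r.delta_upper,
                    "tL": r.t_lower,
                    "tU": r.t_upper,
                    "pL": r.p_lower,
                    "pU": r.p_upper,
                    "verdict": r.verdict,
                }
            )
        return pd.DataFrame(rows)


class EquivalenceModel:
    """Median-split group comparison across imputed datasets, TOST per outcome.

    The split is computed once on the (complete) log-RMSSD of the first
    dataset; each outcome is refit with the group factor (reference = Low, so
    B > 0 means higher scores in the High-HRV group), Rubin-pooled, and tested
    against its SESOI bounds.
    """

    def __init__(
        self,
        datasets,
        outcomes=None,
        sesoi: SesoiSpec | None = None,
        base_spec: ModelSpec | None = None,
        alpha: float = 0.05,
    ):
        self.datasets = list(datasets)
        self.sesoi = sesoi or SesoiSpec()
        self.outcomes = list(outcomes) if outcomes is not None else list(
            self.sesoi.scale_max
        )
        self.base_spec = base_spec
        self.alpha = alpha

    def fit(self) -> EquivalenceResults:
        labels = median_split(self.datasets[0]["log_rmssd"].to_numpy(dtype=float))
        datasets = []
        for d in self.datasets:
            d = d.copy()
            d["hrv_group"] = labels
            datasets.append(d)
        results = []
        for outcome in self.outcomes:
            if outcome not in datasets[0].columns:
                continue
            base = self.base_spec or ModelSpec(outcome=outcome)
            spec = ModelSpec(
                outcome=outcome,
                predictor="hrv_group",
                covariates=base.covariates,
                categorical=tuple(set(base.categorical) | {"hrv_group"}),
                cluster=base.cluster,
                reml=base.reml,
                alpha=self.alpha,
                n_tests=base.n_tests,
                treatment_reference="Low",
            )
            usable = [d.dropna(subset=[outcome]) for d in datasets]
            pooled = PooledMIModel(usable, spec).fit()
            est = pooled.estimate("hrv_group")
            results.append(
                tost(
                    est.qbar,
                    est.se,
                    est.df,
                    sesoi_bounds(outcome, self.sesoi),
                    alpha=self.alpha,
                    outcome=outcome,
                )
            )
        return EquivalenceResults(results)


def run_equivalence_suite(
    datasets, outcomes=None, sesoi: SesoiSpec | None = None, base_spec=None, alpha=0.05
) -> pd.DataFrame:
    """Functional wrapper returning the equivalence table."""
    return EquivalenceModel(
        datasets, outcomes=outcomes, sesoi=sesoi, base_spec=base_spec, alpha=alpha
    ).fit().summary()
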