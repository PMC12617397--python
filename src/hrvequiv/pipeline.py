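"""End-to-end orchestration: simulate -> preprocess -> score -> impute ->
model -> equivalence, with descriptive tables and a run manifest.

The pipeline is pure dataflow: each stage consumes the previous stage's
tables and produces new ones, so re-running a late stage from cached inputs
reproduces its outputs bit for bit under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__, equivalence, impute, modeling, scoring, simulate
from .preprocessing import NormReference, preprocess_participant

__all__ = ["AnalysisConfig", "RunManifest", "run_pipeline", "make_descriptives", "PipelineResult"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything one run needs; nested generator settings ride along."""

    seed: int = 0
    alpha: float = 0.05
    m: int = 5
    maxit: int = 10
    cohort: simulate.CohortSimConfig = field(default_factory=simulate.CohortSimConfig)
    norm_reference: NormReference = field(default_factory=NormReference)
    max_artifacts: int = 10
    min_duration_s: float = 240.0
    min_beats: int = 150
    sesoi_fraction: float = 0.05
    outcomes: tuple = scoring.OUTCOME_NAMES
    measure_hrv_from_series: bool = False
    simulate_tasks: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            d["cohort"] = simulate.CohortSimConfig(**d["cohort"])
        if "norm_reference" in d and isinstance(d["norm_reference"], dict):
            d["norm_reference"] = NormReference(**d["norm_reference"])
        if "outcomes" in d:
            d["outcomes"] = tuple(d["outcomes"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stage_counts: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


@dataclass
class PipelineResult:
    config: AnalysisConfig
    cohort: pd.DataFrame
    features: pd.DataFrame | None
    imputed: impute.ImputedDatasets
    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    country_tables: dict
    manifest: RunManifest


def _config_hash(config: AnalysisConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _measure_hrv(cohort: pd.DataFrame, config: AnalysisConfig, manifest: RunManifest):
    """Replace drawn RMSSD with values measured from simulated tachograms."""
    logs = simulate.simulate_hp_logs(cohort, seed=config.seed + 1)
    rows, kept = [], []
    for pid, series in logs.items():
        features, report = preprocess_participant(
            series,
            config.norm_reference,
            max_artifacts=config.max_artifacts,
            min_duration_s=config.min_duration_s,
            min_beats=config.min_beats,
        )
        rec = {
            "participant_id": pid,
            "n_artifacts": report.n_artifacts,
            "excluded": report.excluded,
            "reason": report.exclusion_reason,
        }
        if features is not None:
            rec.update(
                rmssd=features.rmssd,
                log_rmssd=features.log_rmssd,
                mean_hr=features.mean_hr,
            )
            kept.append(pid)
        rows.append(rec)
    features_df = pd.DataFrame(rows)
    manifest.stage_counts["hrv_excluded"] = int(features_df["excluded"].sum())
    cohort = cohort[cohort["participant_id"].isin(kept)].copy()
    merged = features_df.set_index("participant_id")
    cohort["rmssd"] = cohort["participant_id"].map(merged["rmssd"])
    cohort["log_rmssd"] = cohort["participant_id"].map(merged["log_rmssd"])
    return cohort, features_df


def run_pipeline(config: AnalysisConfig) -> PipelineResult:
    manifest = RunManifest(config_hash=_config_hash(config), version=__version__)
    t0 = time.time()

    cohort = simulate.simulate_cohort(config.cohort)
    manifest.stage_counts["simulated"] = len(cohort)
    manifest.timings_s["simulate"] = round(time.time() - t0, 3)

    features = None
    if config.measure_hrv_from_series:
        t = time.time()
        cohort, features = _measure_hrv(cohort, config, manifest)
        manifest.stage_counts["hrv_retained"] = len(cohort)
        manifest.timings_s["hrv"] = round(time.time() - t, 3)

    if config.simulate_tasks:
        t = time.time()
        egng, ddt = simulate.simulate_task_logs(cohort, seed=config.seed + 2)
        fa = egng.groupby("participant_id").apply(
            scoring.score_egng, include_groups=False
        )
        imm = ddt.groupby("participant_id").apply(
            scoring.score_ddt, include_groups=False
        )
        cohort["false_alarm_pct"] = cohort["participant_id"].map(fa)
        cohort["immediate_reward_pct"] = cohort["participant_id"].map(imm)
        manifest.timings_s["score_tasks"] = round(time.time() - t, 3)

    t = time.time()
    imp_cfg = impute.ImputationConfig(
        m=config.m, maxit=config.maxit, seed=config.seed + 3
    )
    imputed = impute.chained_impute(cohort, imp_cfg)
    manifest.stage_counts["imputed_datasets"] = imputed.m
    manifest.timings_s["impute"] = round(time.time() - t, 3)

    t = time.time()
    table1 = make_descriptives(impute.passive_derive(imputed.complete(0)))
    rows = []
    country_tables = {}
    spec0 = None
    for outcome in config.outcomes:
        if outcome not in imputed.complete(0).columns:
            manifest.warnings.append(f"outcome {outcome} absent; skipped")
            continue
        spec = modeling.ModelSpec(outcome=outcome, alpha=config.alpha)
        spec0 = spec0 or spec
        usable = [d.dropna(subset=[outcome]) for d in imputed.datasets]
        res = modeling.PooledMIModel(usable, spec).fit()
        est = res.estimate(spec.predictor)
        rows.append(
            {
                "outcome": outcome,
                "B": est.qbar,
                "SE": est.se,
                "t": est.t,
                "df": est.df,
                "p": est.p,
                "r2_conditional": res.mean_r2_conditional,
                "icc": res.mean_icc,
            }
        )
    table2 = pd.DataFrame(rows)
    if not table2.empty:
        table2["p_bonferroni"] = modeling.bonferroni_adjust(
            table2["p"].to_numpy(), len(table2)
        )
    manifest.timings_s["model"] = round(time.time() - t, 3)

    for country in config.cohort.countries:
        ctabs = {}
        sub0 = imputed.complete(0)
        for outcome in config.outcomes:
            if outcome not in sub0.columns:
                continue
            sub = sub0[sub0["country"] == country].dropna(subset=[outcome])
            if sub.empty or sub[outcome].isna().all():
                continue
            spec = modeling.ModelSpec(outcome=outcome, alpha=config.alpha)
            ctabs[outcome] = modeling.fit_country_glm(sub0.dropna(subset=[outcome]), country, spec)
        country_tables[country] = ctabs

    t = time.time()
    sesoi = equivalence.SesoiSpec(fraction=config.sesoi_fraction)
    table3 = equivalence.run_equivalence_suite(
        [d for d in imputed.datasets],
        outcomes=[o for o in config.outcomes],
        sesoi=sesoi,
        alpha=config.alpha,
    )
    manifest.timings_s["equivalence"] = round(time.time() - t, 3)
    manifest.stage_counts["table2_rows"] = len(table2)
    manifest.stage_counts["table3_rows"] = len(table3)

    return PipelineResult(
        config=config,
        cohort=cohort,
        features=features,
        imputed=imputed,
        table1=table1,
        table2=table2,
        table3=table3,
        country_tables=country_tables,
        manifest=manifest,
    )


def _tukey_fence(x: np.ndarray):
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    return q1 - 1.5 * iqr, q3 + 1.5 * iqr


def make_descriptives(records: pd.DataFrame, continuous=None) -> pd.DataFrame:
    """Per-country descriptive table: mean (SD) for continuous variables,
    percentage (SE) for gender, plus a Tukey-fence range column."""
    if continuous is None:
        continuous = [
            c
            for c in (
                "age", "height_m", "weight_kg", "bmi", "rmssd", "mean_hr",
            ) + scoring.OUTCOME_NAMES
            if c in records.columns
        ]
    countries = sorted(records["country"].unique())
    rows = []
    if "gender" in records.columns:
        for level in sorted(records["gender"].dropna().unique()):
            row = {"outcome": f"gender_{level}", "range_tukey": "",
                   "tukey_lo": np.nan, "tukey_hi": np.nan}
            for c in countries:
                g = records.loc[records["country"] == c, "gender"].dropna()
                if g.empty:
                    row[c] = ""
                    continue
                p = float((g == level).mean())
                se = float(np.sqrt(p * (1 - p) / len(g)) * 100.0)
                row[c] = f"{p * 100:.2f}% ({se:.2f})"
            rows.append(row)
    for var in continuous:
        x = pd.to_numeric(records[var], errors="coerce").dropna().to_numpy()
        if x.size == 0:
            continue
        lo, hi = _tukey_fence(x)
        lo = max(lo, float(np.min(x)))
        hi = min(hi, float(np.max(x)))
        row = {"outcome": var, "range_tukey": f"{lo:.2f}-{hi:.2f}",
               "tukey_lo": lo, "tukey_hi": hi}
        for c in countries:
            g = pd.to_numeric(
                records.loc[records["country"] == c, var], errors="coerce"
            ).dropna()
            row[c] = f"{g.mean():.2f} ({g.std():.2f})" if len(g) else ""
        rows.append(row)
    return pd.DataFrame(rows)
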