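"""Synthetic data generators emulating the study's data structure.

Three layers:

* heart-period series — resting 5-min tachograms built from a mean heart
  period, a sinusoidal respiratory modulation (respiratory sinus arrhythmia)
  and AR(1) Gaussian beat noise, with optional injected beat artifacts
  (spikes, missed beats, extra beats) carrying ground-truth indices;
* a three-country adolescent cohort — per-country random intercepts, realistic
  demographics, lognormal RMSSD calibrated to adolescent norms, a configurable
  linear effect of log-RMSSD on a latent outcome (default zero), ordinal
  questionnaire items drawn from the latent trait through shared
  proportional-odds cutpoints, and go/no-go + delay-discounting trial logs;
* missingness — MCAR or MAR (driven by an observed auxiliary) cell deletion
  with categorical missing codes and a ground-truth mask.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import scoring
from .preprocessing import HeartPeriodSeries

__all__ = [
    "HPSimConfig",
    "ArtifactSpec",
    "CohortSimConfig",
    "simulate_hp_series",
    "inject_artifacts",
    "simulate_cohort",
    "simulate_task_logs",
    "simulate_hp_logs",
    "impose_missingness",
    "hp_config_for_rmssd",
]

COUNTRIES = ("Colombia", "Nepal", "South Africa")

# Per-country demographic profiles (means/SDs follow the cohort's descriptives).
_DEMOGRAPHICS = {
    "Colombia": dict(age_mu=13.83, height=(1.60, 0.08), weight=(52.2, 8.7), p_ecg=1.00),
    "Nepal": dict(age_mu=13.87, height=(1.56, 0.07), weight=(47.0, 8.1), p_ecg=0.35),
    "South Africa": dict(age_mu=14.21, height=(1.64, 0.11), weight=(56.1, 14.9), p_ecg=0.22),
}

#: Default proportional-odds cutpoints per instrument (shared within
#: instrument), on the latent-trait + standard-logistic scale.
DEFAULT_ITEM_THRESHOLDS = {
    "mmapp": (-0.4, 1.0, 2.2),
    "ders": (-1.5, -0.3, 0.9, 2.1),
    "dbis": (0.2, 1.5, 2.8),
}


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class HPSimConfig:
    """Resting tachogram generator settings.

    ``mean_hp`` (ms) sets mean heart period; ``rsa_amplitude`` (ms) the
    respiratory modulation at ``resp_freq`` (Hz); ``noise_sd`` (ms) the
    marginal SD of the AR(1) beat noise with lag-1 coefficient ``ar_coef``.
    """

    mean_hp: float = 900.0
    rsa_amplitude: float = 40.0
    resp_freq: float = 0.25
    noise_sd: float = 25.0
    ar_coef: float = 0.3
    duration: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        _check(300.0 < self.mean_hp < 2000.0, "mean_hp must be in (300, 2000) ms")
        _check(self.duration > 0, "duration must be positive")
        _check(self.noise_sd >= 0, "noise_sd must be non-negative")
        _check(self.rsa_amplitude >= 0, "rsa_amplitude must be non-negative")
        _check(0.0 <= self.ar_coef < 1.0, "ar_coef must be in [0, 1)")


def simulate_hp_series(config: HPSimConfig, participant_id: str = "sim", device: str = "ECG_chest") -> HeartPeriodSeries:
    """Generate a heart-period series truncated to ``config.duration`` seconds."""
    rng = np.random.default_rng(config.seed)
    innov_sd = config.noise_sd * np.sqrt(1.0 - config.ar_coef**2)
    hps, times = [], []
    t = 0.0  # seconds, time at which the current beat interval ends
    e = rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
    while True:
        hp = config.mean_hp + config.rsa_amplitude * np.sin(
            2.0 * np.pi * config.resp_freq * t
        ) + e
        hp = max(hp, 1.0)  # keep intervals physical under extreme noise draws
        t_next = t + hp / 1000.0
        if t_next > config.duration:
            break
        t = t_next
        hps.append(hp)
        times.append(t * 1000.0)
        e = config.ar_coef * e + (rng.normal(0.0, innov_sd) if innov_sd > 0 else 0.0)
    return HeartPeriodSeries(participant_id, np.array(hps), np.array(times), device)


@dataclass(frozen=True)
class ArtifactSpec:
    """Beat corruptions to inject: multiplicative spikes, merged ("missed")
    beats, and split ("extra") beats."""

    n_spikes: int = 0
    n_missed: int = 0
    n_extra: int = 0
    spike_factor: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        _check(min(self.n_spikes, self.n_missed, self.n_extra) >= 0, "counts must be >= 0")
        _check(self.spike_factor > 0, "spike_factor must be positive")


def inject_artifacts(series: HeartPeriodSeries, spec: ArtifactSpec):
    """Corrupt a clean series; returns ``(corrupted, truth_indices)``.

    Target beats are chosen pairwise non-adjacent (isolated artifacts).  A
    spike multiplies one interval by ``spike_factor``; a missed beat merges
    two adjacent intervals into their sum; an extra beat splits one interval
    in two (total duration preserved for merges/splits).  ``truth_indices``
    are positions of corrupted beats in the *returned* series (both halves of
    a split).
    """
    n = len(series)
    total = spec.n_spikes + spec.n_missed + spec.n_extra
    # merges consume two source beats; require room with isolation gaps
    if 3 * total + 1 >= n:
        raise ValueError("more corruptions requested than the series can hold")
    rng = np.random.default_rng(spec.seed)

    # choose isolated source positions (no two adjacent, merges need i and i+1)
    chosen: list[int] = []
    kinds = ["spike"] * spec.n_spikes + ["missed"] * spec.n_missed + ["extra"] * spec.n_extra
    rng.shuffle(kinds)
    occupied = set()
    for kind in kinds:
        width = 2 if kind == "missed" else 1
        for _ in range(10000):
            i = int(rng.integers(1, n - width - 1))
            span = set(range(i - 1, i + width + 1))
            if not (span & occupied):
                occupied |= span
                chosen.append(i)
                break
        else:  # pragma: no cover - practically unreachable given the size check
            raise ValueError("could not place isolated artifacts")

    plan = sorted(zip(chosen, kinds))
    out: list[float] = []
    truth: list[int] = []
    i = 0
    k = 0
    while i < n:
        if k < len(plan) and plan[k][0] == i:
            kind = plan[k][1]
            k += 1
            if kind == "spike":
                truth.append(len(out))
                out.append(series.hp[i] * spec.spike_factor)
                i += 1
            elif kind == "missed":
                truth.append(len(out))
                out.append(series.hp[i] + series.hp[i + 1])
                i += 2
            else:  # extra: split into two fractions of the original interval
                frac = rng.uniform(0.4, 0.6)
                truth.extend([len(out), len(out) + 1])
                out.extend([series.hp[i] * frac, series.hp[i] * (1.0 - frac)])
                i += 1
        else:
            out.append(series.hp[i])
            i += 1
    return series.with_hp(np.array(out)), frozenset(truth)


@dataclass(frozen=True)
class CohortSimConfig:
    """Three-country cohort generator settings.

    The latent outcome for participant *p* in country *c* is

        y_p = intercept + u_c + beta_logrmssd * logRMSSD_p
              + sum_k covariate_effects[k] * x_pk + N(0, residual_sd^2),

    with u_c ~ N(0, country_intercept_sd^2).  log-RMSSD is Gaussian with
    ``logrmssd_mean``/``logrmssd_sd`` chosen so raw RMSSD has mean ~43 ms and
    SD ~13 ms, matching the adolescent norm reference used for the artifact
    thresholds.  Ordinal items are drawn from the standardized latent trait
    through shared proportional-odds cutpoints.
    """

    n_per_country: int = 369
    countries: tuple = COUNTRIES
    intercept: float = 24.0
    country_intercept_sd: float = 1.4
    beta_logrmssd: float = 0.0
    covariate_effects: dict = field(default_factory=dict)
    residual_sd: float = 9.5
    logrmssd_mean: float = 3.7175
    logrmssd_sd: float = 0.2958
    item_thresholds: dict = field(default_factory=lambda: dict(DEFAULT_ITEM_THRESHOLDS))
    item_loading: float = 0.7
    missing_rate: float = 0.0
    missing_mechanism: str = "MCAR"
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.n_per_country >= 2, "n_per_country must be >= 2")
        _check(self.residual_sd > 0, "residual_sd must be positive")
        _check(0.0 <= self.missing_rate < 1.0, "missing_rate must be in [0, 1)")
        _check(self.missing_mechanism in ("MCAR", "MAR"), "mechanism must be MCAR or MAR")
        for name, cuts in self.item_thresholds.items():
            if list(cuts) != sorted(set(cuts)):
                raise ValueError(f"degenerate cutpoints for {name}")


def _draw_items(rng, trait, cutpoints, prefix_names):
    """Proportional-odds draws: y = #{cutpoints crossed by trait + logistic}."""
    cuts = np.asarray(cutpoints, dtype=float)
    cols = {}
    for name in prefix_names:
        e = rng.logistic(0.0, 1.0, size=trait.size)
        cols[name] = (trait[:, None] + e[:, None] > cuts[None, :]).sum(axis=1)
    return cols


def simulate_cohort(config: CohortSimConfig) -> pd.DataFrame:
    """Generate one participant-per-row cohort table.

    Columns: identifiers, demographics, device, ``log_rmssd``/``rmssd``, the
    continuous latent ``outcome``, and all ordinal instrument items.  The true
    generating parameters are stored in ``df.attrs["truth"]`` for recovery
    tests.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    country_effects = {
        c: rng.normal(0.0, config.country_intercept_sd) if config.country_intercept_sd > 0 else 0.0
        for c in config.countries
    }
    for country in config.countries:
        demo = _DEMOGRAPHICS.get(country, _DEMOGRAPHICS["Colombia"])
        n = config.n_per_country
        age = np.clip(rng.normal(demo["age_mu"], 0.75, n), 13.0, 15.99)
        height = np.clip(rng.normal(*demo["height"], size=n), 1.30, 1.95)
        weight = np.clip(rng.normal(*demo["weight"], size=n), 25.0, 120.0)
        gender = rng.choice(
            ["female", "male", "nonbinary"], size=n, p=[0.57, 0.426, 0.004]
        )
        device = np.where(
            rng.random(n) < demo["p_ecg"], "ECG_chest", "PPG_ear"
        )
        log_rmssd = rng.normal(config.logrmssd_mean, config.logrmssd_sd, n)
        rows.append(
            pd.DataFrame(
                {
                    "country": country,
                    "age": age,
                    "gender": gender,
                    "height_m": height,
                    "weight_kg": weight,
                    "device": device,
                    "log_rmssd": log_rmssd,
                }
            )
        )
    df = pd.concat(rows, ignore_index=True)
    df.insert(0, "participant_id", [f"p{i:04d}" for i in range(len(df))])
    df["bmi"] = df["weight_kg"] / df["height_m"] ** 2
    df["rmssd"] = np.exp(df["log_rmssd"])

    linpred = config.intercept + config.beta_logrmssd * df["log_rmssd"].to_numpy()
    linpred = linpred + df["country"].map(country_effects).to_numpy()
    for name, slope in config.covariate_effects.items():
        linpred = linpred + slope * df[name].to_numpy(dtype=float)
    outcome = linpred + rng.normal(0.0, config.residual_sd, len(df))
    df["outcome"] = outcome

    z = (outcome - outcome.mean()) / outcome.std()
    lam = config.item_loading
    for instrument, names in (
        ("mmapp", scoring.MMAPP_ITEMS),
        ("ders", scoring.DERS_ITEMS),
        ("dbis", scoring.DBIS_ITEMS),
    ):
        u = rng.normal(0.0, 1.0, len(df))
        trait = lam * z + np.sqrt(1.0 - lam**2) * u
        df = pd.concat(
            [df, pd.DataFrame(_draw_items(rng, trait, config.item_thresholds[instrument], names), index=df.index)],
            axis=1,
        )

    if config.missing_rate > 0:
        df, mask = impose_missingness(
            df,
            rate=config.missing_rate,
            mechanism=config.missing_mechanism,
            seed=int(rng.integers(2**31)),
        )
        df.attrs["missing_mask"] = mask

    df.attrs["truth"] = {
        "beta_logrmssd": config.beta_logrmssd,
        "intercept": config.intercept,
        "country_effects": country_effects,
        "residual_sd": config.residual_sd,
        "covariate_effects": dict(config.covariate_effects),
    }
    return df


def simulate_task_logs(cohort: pd.DataFrame, seed: int = 0):
    """Trial-level logs for the go/no-go and delay-discounting tasks.

    The go/no-go task (4 blocks x 30 trials, 20 go + 10 no-go, plus 20
    practice trials) is generated only for Colombia and South Africa, matching
    the study design; the discounting task (30 self-paced trials) for all
    countries.  Returns ``(egng, ddt)`` trial-per-row frames.
    """
    rng = np.random.default_rng(seed)
    egng_rows, ddt_rows = [], []
    for _, row in cohort.iterrows():
        pid = row["participant_id"]
        if row["country"] in ("Colombia", "South Africa"):
            p_fa = float(np.clip(rng.normal(0.17, 0.08), 0.01, 0.6))
            for block in range(-1, 4):  # block -1 = practice
                practice = block < 0
                n_go, n_nogo = (10, 10) if practice else (20, 10)
                stim = np.array(["go"] * n_go + ["no_go"] * n_nogo)
                rng.shuffle(stim)
                resp = np.where(
                    stim == "go", rng.random(stim.size) < 0.95, rng.random(stim.size) < p_fa
                )
                for s, r in zip(stim, resp):
                    egng_rows.append((pid, block, s, bool(r), practice))
        p_imm = float(rng.beta(2.0, 3.0))
        for trial in range(30):
            if rng.random() < 0.99:
                choice = "immediate" if rng.random() < p_imm else "delayed"
            else:
                choice = "none"
            ddt_rows.append((pid, trial, choice, False))
    egng = pd.DataFrame(
        egng_rows, columns=["participant_id", "block", "stimulus", "response", "practice"]
    )
    ddt = pd.DataFrame(ddt_rows, columns=["participant_id", "trial", "choice", "practice"])
    return egng, ddt


def hp_config_for_rmssd(
    target_rmssd: float, mean_hp: float = 900.0, ar_coef: float = 0.3, seed: int = 0
) -> HPSimConfig:
    """Tachogram settings whose expected RMSSD approximates ``target_rmssd``.

    The respiratory component contributes RMSSD of about
    ``A * 2 * sin(pi * f * mean_hp / 1000)`` and the AR(1) noise
    ``sigma * sqrt(2 (1 - ar))``; the respiratory amplitude is fixed at 40% of
    the target and the noise SD solves for the remainder.
    """
    rsa = 0.4 * target_rmssd
    f = 0.25
    rsa_rmssd = rsa * 2.0 * abs(np.sin(np.pi * f * mean_hp / 1000.0))
    rem = max(target_rmssd**2 - rsa_rmssd**2, 0.0)
    noise_sd = float(np.sqrt(rem / (2.0 * (1.0 - ar_coef))))
    return HPSimConfig(
        mean_hp=mean_hp, rsa_amplitude=rsa, noise_sd=noise_sd, ar_coef=ar_coef, seed=seed
    )


def simulate_hp_logs(cohort: pd.DataFrame, seed: int = 0) -> dict:
    """One heart-period series per participant, calibrated to the cohort's
    drawn RMSSD values.  Returns ``{participant_id: HeartPeriodSeries}``."""
    ss = np.random.SeedSequence(seed)
    out = {}
    for (_, row), child in zip(cohort.iterrows(), ss.spawn(len(cohort))):
        cfg = hp_config_for_rmssd(
            row["rmssd"], seed=int(child.generate_state(1)[0] % 2**31)
        )
        out[row["participant_id"]] = simulate_hp_series(
            cfg, participant_id=row["participant_id"], device=row["device"]
        )
    return out


def impose_missingness(
    table: pd.DataFrame,
    rate: float,
    mechanism: str = "MCAR",
    seed: int = 0,
    columns=None,
    auxiliary: str = "age",
):
    """Delete cells, writing categorical missing codes; returns ``(table, mask)``.

    MCAR deletes uniformly at ``rate``; MAR scales per-row deletion
    probability with the standardized auxiliary (logistic link, slope 1) while
    preserving the overall expected rate.  ``mask`` is a boolean frame over
    the affected columns marking deleted cells (the imputation ground truth).
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    if mechanism not in ("MCAR", "MAR"):
        raise ValueError("mechanism must be MCAR or MAR")
    if columns is None:
        items = [
            c
            for c in table.columns
            if c in scoring.MMAPP_ITEMS + scoring.DERS_ITEMS + scoring.DBIS_ITEMS
        ]
        columns = items + [c for c in ("height_m", "weight_kg") if c in table.columns]
    table = table.copy()
    rng = np.random.default_rng(seed)
    if rate == 0 or not columns:
        return table, pd.DataFrame(False, index=table.index, columns=list(columns))

    if mechanism == "MCAR":
        p_row = np.full(len(table), rate)
    else:
        aux = table[auxiliary].to_numpy(dtype=float)
        z = (aux - aux.mean()) / (aux.std() or 1.0)
        w = 1.0 / (1.0 + np.exp(-z))
        p_row = np.clip(rate * w / w.mean(), 0.0, 0.95)

    mask = pd.DataFrame(
        rng.random((len(table), len(columns))) < p_row[:, None],
        index=table.index,
        columns=list(columns),
    )
    codes = sorted(scoring.MISSING_CODES - {""})
    for c in columns:
        idx = mask.index[mask[c]]
        if len(idx):
            col = table[c].astype(object)
            col.loc[idx] = rng.choice(codes, size=len(idx))
            table[c] = col
    return table, mask
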