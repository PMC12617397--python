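"""Heart-period (RR-interval) preprocessing and time-domain HRV features.

The cleaning pipeline mirrors standard practice for short resting recordings
collected with consumer-grade beat detectors: absolute physiological bounds,
an iterative local-mean (Karlsson-style) deviation filter whose threshold is
personalised by the participant's HRV-norm category, linear interpolation of
flagged beats, and quality gates on artifact count, recording span and beat
count.  Features are RMSSD, its natural log, mean heart rate, minute-wise
RMSSD and optional high-frequency spectral power.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, signal

__all__ = [
    "HeartPeriodSeries",
    "NormReference",
    "ArtifactReport",
    "HRVFeatures",
    "FormatError",
    "QualityError",
    "read_hp_log",
    "write_hp_log",
    "flag_absolute_bounds",
    "assign_norm_category",
    "detect_karlsson",
    "detect_karlsson_bruteforce",
    "correct_artifacts",
    "apply_quality_gate",
    "compute_rmssd",
    "compute_mean_hr",
    "compute_minutewise_rmssd",
    "compute_hf_power",
    "preprocess_participant",
]


class FormatError(ValueError):
    """Malformed heart-period log file."""


class QualityError(ValueError):
    """Series too short or too degraded for the requested operation."""


@dataclass(frozen=True)
class HeartPeriodSeries:
    """Ordered interbeat intervals (ms) with cumulative timestamps (ms).

    ``timestamp[i]`` is the time at which beat interval ``hp[i]`` ends.
    """

    participant_id: str
    hp: np.ndarray
    timestamp: np.ndarray
    device: str = "ECG_chest"

    def __post_init__(self) -> None:
        hp = np.asarray(self.hp, dtype=float)
        ts = np.asarray(self.timestamp, dtype=float)
        object.__setattr__(self, "hp", hp)
        object.__setattr__(self, "timestamp", ts)
        if hp.size == 0:
            raise FormatError("heart-period series is empty")
        if hp.shape != ts.shape:
            raise FormatError("hp and timestamp lengths differ")
        if not np.all(np.isfinite(hp)) or np.any(hp <= 0):
            raise FormatError("heart periods must be finite and positive")
        if np.any(np.diff(ts) <= 0):
            raise FormatError("timestamps must be strictly increasing")

    @classmethod
    def from_intervals(
        cls, hp, participant_id: str = "p0", device: str = "ECG_chest", t0: float = 0.0
    ) -> "HeartPeriodSeries":
        hp = np.asarray(hp, dtype=float)
        return cls(participant_id, hp, t0 + np.cumsum(hp), device)

    def __len__(self) -> int:
        return int(self.hp.size)

    @property
    def span_ms(self) -> float:
        """Elapsed time from start of first beat to end of last beat."""
        return float(self.timestamp[-1] - (self.timestamp[0] - self.hp[0]))

    def with_hp(self, hp: np.ndarray) -> "HeartPeriodSeries":
        """Same identity/device, new intervals; timestamps recomputed."""
        hp = np.asarray(hp, dtype=float)
        t0 = self.timestamp[0] - self.hp[0]
        return HeartPeriodSeries(self.participant_id, hp, t0 + np.cumsum(hp), self.device)


#: Deviation thresholds per HRV-norm category.
DEFAULT_CATEGORY_THRESHOLDS = {
    "very_low": 0.40,
    "low": 0.40,
    "normal": 0.40,
    "high": 0.45,
    "very_high": 0.50,
}


@dataclass(frozen=True)
class NormReference:
    """Adolescent resting RMSSD norms used to personalise the deviation threshold."""

    norm_mean: float = 42.9
    norm_sd: float = 13.4
    category_thresholds: dict = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_THRESHOLDS)
    )

    def __post_init__(self) -> None:
        if self.norm_sd <= 0:
            raise ValueError("norm_sd must be positive")

    def cutoffs(self) -> np.ndarray:
        """Category cutoffs at mean + k*SD for k in (-2, -1, +1, +2)."""
        k = np.array([-2.0, -1.0, 1.0, 2.0])
        return self.norm_mean + k * self.norm_sd


@dataclass
class ArtifactReport:
    participant_id: str = ""
    flagged_bounds: frozenset = frozenset()
    flagged_karlsson: frozenset = frozenset()
    category: str = "normal"
    threshold_used: float = 0.40
    excluded: bool = False
    exclusion_reason: str = "none"

    @property
    def n_artifacts(self) -> int:
        return len(set(self.flagged_bounds) | set(self.flagged_karlsson))


@dataclass
class HRVFeatures:
    participant_id: str
    rmssd: float
    log_rmssd: float
    mean_hr: float
    minutewise_rmssd: list
    n_artifacts: int
    hf_power: float = float("nan")


def read_hp_log(path) -> HeartPeriodSeries:
    """Read a two-column CSV heart-period log (header ``timestamp_ms,rr_ms``)."""
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # includes EmptyDataError
        raise FormatError(f"unparseable heart-period log {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected columns timestamp_ms,rr_ms")
    ts_col, rr_col = df.columns[0], df.columns[1]
    ts = pd.to_numeric(df[ts_col], errors="coerce")
    rr = pd.to_numeric(df[rr_col], errors="coerce")
    bad = np.where(ts.isna() | rr.isna())[0]
    if bad.size:
        raise FormatError(f"{path}: nonnumeric cell at data row {bad[0]}")
    ts = ts.to_numpy(float)
    if np.any(np.diff(ts) <= 0):
        row = int(np.where(np.diff(ts) <= 0)[0][0]) + 1
        raise FormatError(f"{path}: nonmonotone timestamp at data row {row}")
    pid = os.path.splitext(os.path.basename(path))[0]
    return HeartPeriodSeries(pid, rr.to_numpy(float), ts)


def write_hp_log(series: HeartPeriodSeries, path) -> None:
    pd.DataFrame({"timestamp_ms": series.timestamp, "rr_ms": series.hp}).to_csv(
        path, index=False
    )


def flag_absolute_bounds(
    series: HeartPeriodSeries, lower: float = 300.0, upper: float = 2000.0
) -> frozenset:
    """Indices of beats strictly below ``lower`` or strictly above ``upper`` ms."""
    hp = series.hp
    return frozenset(np.where((hp < lower) | (hp > upper))[0].tolist())


def assign_norm_category(preliminary_rmssd: float, ref: NormReference | None = None):
    """Map a preliminary RMSSD to its norm category and Karlsson threshold.

    Intervals are left-closed: a value exactly at a cutoff takes the higher
    category.
    """
    if ref is None:
        ref = NormReference()
    if not np.isfinite(preliminary_rmssd) or preliminary_rmssd < 0:
        raise ValueError("preliminary RMSSD must be finite and non-negative")
    c = ref.cutoffs()
    names = ["very_low", "low", "normal", "high", "very_high"]
    category = names[int(np.searchsorted(c, preliminary_rmssd, side="right"))]
    return category, ref.category_thresholds[category]


def _local_mean(hp: np.ndarray, i: int, flagged: set) -> float | None:
    """Mean of nearest non-flagged preceding and subsequent beats (one each)."""
    prev_val = next_val = None
    j = i - 1
    while j >= 0:
        if j not in flagged:
            prev_val = hp[j]
            break
        j -= 1
    j = i + 1
    while j < hp.size:
        if j not in flagged:
            next_val = hp[j]
            break
        j += 1
    vals = [v for v in (prev_val, next_val) if v is not None]
    if not vals:
        return None
    return float(np.mean(vals))


def detect_karlsson(series: HeartPeriodSeries, threshold: float) -> frozenset:
    """Iterative local-mean deviation filter.

    A beat is flagged when its relative deviation from the mean of its nearest
    non-flagged neighbours exceeds ``threshold``.  Flags found in one pass are
    applied synchronously before the next pass; passes repeat to fixed point.
    Endpoints are compared against their single available neighbour.
    """
    hp = series.hp
    n = hp.size
    if n < 3:
        raise QualityError("Karlsson detection needs at least 3 beats")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")

    flagged: set[int] = set()
    # prev_clean[i]/next_clean[i]: nearest non-flagged index before/after i
    while True:
        new: set[int] = set()
        for i in range(n):
            if i in flagged:
                continue
            local = _local_mean(hp, i, flagged)
            if local is None or local == 0:
                continue
            if abs(hp[i] - local) / local > threshold:
                new.add(i)
        if not new:
            return frozenset(flagged)
        flagged |= new


def detect_karlsson_bruteforce(series: HeartPeriodSeries, threshold: float) -> frozenset:
    """Naive reference: rescan the entire series each iteration.

    Kept deliberately simple and independent of :func:`detect_karlsson` as a
    cross-check; identical semantics, quadratic neighbour search.
    """
    hp = list(series.hp)
    n = len(hp)
    if n < 3:
        raise QualityError("Karlsson detection needs at least 3 beats")
    flagged: set[int] = set()
    changed = True
    while changed:
        changed = False
        newly = []
        for i in range(n):
            if i in flagged:
                continue
            neigh = []
            for j in range(i - 1, -1, -1):
                if j not in flagged:
                    neigh.append(hp[j])
                    break
            for j in range(i + 1, n):
                if j not in flagged:
                    neigh.append(hp[j])
                    break
            if not neigh:
                continue
            local = sum(neigh) / len(neigh)
            if local != 0 and abs(hp[i] - local) / local > threshold:
                newly.append(i)
        if newly:
            changed = True
            flagged.update(newly)
    return frozenset(flagged)


def correct_artifacts(series: HeartPeriodSeries, flagged) -> HeartPeriodSeries:
    """Replace flagged beats by linear interpolation between clean neighbours.

    Interpolation runs in beat-index coordinates; flagged runs at either end
    take the value of the nearest clean beat.  Length is unchanged and
    timestamps are recomputed from the corrected intervals.
    """
    flagged = set(int(i) for i in flagged)
    if not flagged:
        return series
    n = len(series)
    if any(i < 0 or i >= n for i in flagged):
        raise ValueError("flagged index out of range")
    clean = np.array(sorted(set(range(n)) - flagged))
    if clean.size < 2:
        raise QualityError("fewer than 2 clean beats; cannot interpolate")
    hp = series.hp.copy()
    bad = np.array(sorted(flagged))
    # np.interp clamps outside the clean range, giving the nearest-clean end rule
    hp[bad] = np.interp(bad, clean, hp[clean])
    return series.with_hp(hp)


def apply_quality_gate(
    report: ArtifactReport,
    series: HeartPeriodSeries,
    max_artifacts: int = 10,
    min_duration_s: float = 240.0,
    min_beats: int = 150,
) -> ArtifactReport:
    """Exclusion verdict: too many artifacts, too short, or too few beats."""
    report = dataclasses.replace(report)
    if report.n_artifacts > max_artifacts:
        report.excluded, report.exclusion_reason = True, "too_many_artifacts"
    elif series.span_ms < min_duration_s * 1000.0:
        report.excluded, report.exclusion_reason = True, "too_short"
    elif len(series) < min_beats:
        report.excluded, report.exclusion_reason = True, "implausible_beat_count"
    else:
        report.excluded, report.exclusion_reason = False, "none"
    return report


def _as_hp(series) -> np.ndarray:
    return series.hp if isinstance(series, HeartPeriodSeries) else np.asarray(series, float)


def compute_rmssd(series) -> float:
    """Root mean square of successive differences, over the N-1 differences."""
    hp = _as_hp(series)
    if hp.size < 2:
        raise QualityError("RMSSD needs at least 2 beats")
    d = np.diff(hp)
    return float(np.sqrt(np.mean(d * d)))


def compute_mean_hr(series) -> float:
    """Mean heart rate in bpm: 60000 / mean heart period (ms)."""
    hp = _as_hp(series)
    if hp.size < 1:
        raise QualityError("mean HR needs at least 1 beat")
    return float(60000.0 / np.mean(hp))


def compute_minutewise_rmssd(
    series: HeartPeriodSeries, n_windows: int = 5, window_s: float = 60.0
) -> list:
    """RMSSD per consecutive 60-s window; beats assigned by end-of-beat time.

    Windows with fewer than 2 beats yield NaN; if the recording covers fewer
    than ``n_windows`` full windows, the trailing values are NaN.
    """
    t0 = series.timestamp[0] - series.hp[0]
    rel = series.timestamp - t0
    out = []
    for w in range(n_windows):
        lo, hi = w * window_s * 1000.0, (w + 1) * window_s * 1000.0
        mask = (rel > lo) & (rel <= hi)
        hp_w = series.hp[mask]
        out.append(compute_rmssd(hp_w) if hp_w.size >= 2 else float("nan"))
    return out


def compute_hf_power(
    series: HeartPeriodSeries,
    band: tuple = (0.15, 0.40),
    fs: float = 4.0,
    min_duration_s: float = 120.0,
) -> float:
    """High-frequency spectral power (ms^2) of the tachogram.

    The interval series is cubically resampled on an even ``fs`` Hz grid,
    mean-centered, and a Welch-averaged periodogram is integrated over the
    respiratory band.
    """
    if series.span_ms < min_duration_s * 1000.0:
        raise QualityError("HF power needs at least 2 min of data")
    t = series.timestamp / 1000.0
    f_interp = interpolate.CubicSpline(t, series.hp)
    grid = np.arange(t[0], t[-1], 1.0 / fs)
    x = f_interp(grid)
    x = x - np.mean(x)
    nperseg = min(256, x.size)
    freqs, psd = signal.welch(x, fs=fs, nperseg=nperseg)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    return float(np.trapezoid(psd[mask], freqs[mask]))


def preprocess_participant(
    series: HeartPeriodSeries,
    ref: NormReference | None = None,
    max_artifacts: int = 10,
    min_duration_s: float = 240.0,
    min_beats: int = 150,
    with_hf: bool = False,
):
    """Full per-participant cleaning and feature extraction.

    Order of operations: (1) flag and interpolate absolute-bound violations;
    (2) preliminary RMSSD on the bounds-cleaned series; (3) norm category and
    personalised threshold; (4) iterative local-mean detection; (5) interpolate
    those flags; (6) quality gate; (7) features on the corrected series.
    Excluded participants yield ``(None, report)``.
    """
    if ref is None:
        ref = NormReference()
    bounds = flag_absolute_bounds(series)
    bounds_cleaned = correct_artifacts(series, bounds)
    prelim = compute_rmssd(bounds_cleaned)
    category, threshold = assign_norm_category(prelim, ref)
    karlsson = detect_karlsson(bounds_cleaned, threshold)
    corrected = correct_artifacts(bounds_cleaned, karlsson)
    report = ArtifactReport(
        participant_id=series.participant_id,
        flagged_bounds=frozenset(bounds),
        flagged_karlsson=frozenset(karlsson),
        category=category,
        threshold_used=threshold,
    )
    report = apply_quality_gate(
        report, corrected, max_artifacts=max_artifacts,
        min_duration_s=min_duration_s, min_beats=min_beats,
    )
    if report.excluded:
        return None, report
    rmssd = compute_rmssd(corrected)
    features = HRVFeatures(
        participant_id=series.participant_id,
        rmssd=rmssd,
        log_rmssd=float(np.log(rmssd)) if rmssd > 0 else float("nan"),
        mean_hr=compute_mean_hr(corrected),
        minutewise_rmssd=compute_minutewise_rmssd(corrected),
        n_artifacts=report.n_artifacts,
        hf_power=compute_hf_power(corrected) if with_hf else float("nan"),
    )
    return features, report
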