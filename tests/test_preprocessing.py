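"""Heart-period cleaning and HRV feature extraction."""

import numpy as np
import pytest

from hrvequiv import simulate
from hrvequiv.preprocessing import (
    FormatError,
    HeartPeriodSeries,
    NormReference,
    QualityError,
    apply_quality_gate,
    assign_norm_category,
    compute_hf_power,
    compute_mean_hr,
    compute_minutewise_rmssd,
    compute_rmssd,
    correct_artifacts,
    detect_karlsson,
    detect_karlsson_bruteforce,
    flag_absolute_bounds,
    preprocess_participant,
    read_hp_log,
    write_hp_log,
    ArtifactReport,
)


class TestSeriesIO:
    def test_roundtrip_is_lossless(self, tmp_path, clean_series):
        path = tmp_path / "p1.csv"
        write_hp_log(clean_series, path)
        back = read_hp_log(path)
        np.testing.assert_allclose(back.hp, clean_series.hp)
        np.testing.assert_allclose(back.timestamp, clean_series.timestamp)

    def test_small_file_parses(self, tmp_path):
        path = tmp_path / "p2.csv"
        path.write_text("timestamp_ms,rr_ms\n1000,1000\n2010,1010\n3000,990\n")
        series = read_hp_log(path)
        assert len(series) == 3

    @pytest.mark.parametrize(
        "content",
        [
            "",
            "timestamp_ms,rr_ms\n1000,abc\n",
            "timestamp_ms,rr_ms\n2000,800\n1000,810\n",
        ],
        ids=["empty", "nonnumeric", "nonmonotone"],
    )
    def test_malformed_files_raise_format_error(self, tmp_path, content):
        path = tmp_path / "bad.csv"
        path.write_text(content)
        with pytest.raises(FormatError):
            read_hp_log(path)

    def test_invalid_interval_values_rejected(self):
        with pytest.raises(FormatError):
            HeartPeriodSeries.from_intervals([800.0, -5.0, 700.0])


class TestAbsoluteBounds:
    def test_low_beat_flagged(self):
        s = HeartPeriodSeries.from_intervals([800, 250, 800])
        assert flag_absolute_bounds(s) == {1}

    def test_boundary_values_not_flagged(self):
        s = HeartPeriodSeries.from_intervals([300, 2000])
        assert flag_absolute_bounds(s) == frozenset()

    def test_clean_range_unflagged(self):
        rng = np.random.default_rng(0)
        s = HeartPeriodSeries.from_intervals(rng.uniform(600, 1200, 200))
        assert flag_absolute_bounds(s) == frozenset()


class TestNormCategories:
    @pytest.mark.parametrize(
        "rmssd, category, threshold",
        [
            (42.9, "normal", 0.40),
            (60.0, "high", 0.45),
            (75.0, "very_high", 0.50),
            (20.0, "low", 0.40),
            (10.0, "very_low", 0.40),
        ],
    )
    def test_category_assignment(self, rmssd, category, threshold):
        cat, thr = assign_norm_category(rmssd, NormReference())
        assert (cat, thr) == (category, threshold)

    def test_threshold_monotone_in_rmssd(self):
        grid = np.linspace(0, 120, 400)
        thresholds = [assign_norm_category(v)[1] for v in grid]
        assert all(a <= b for a, b in zip(thresholds, thresholds[1:]))
        assert set(thresholds) <= {0.40, 0.45, 0.50}

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            assign_norm_category(-1.0)


class TestKarlssonDetection:
    def test_constant_series_unflagged(self, constant_series):
        assert detect_karlsson(constant_series, 0.40) == frozenset()

    def test_single_spike_hand_example(self):
        s = HeartPeriodSeries.from_intervals([800, 800, 1600, 800, 800])
        # deviation |1600 - 800| / 800 = 1.0 > 0.4
        assert detect_karlsson(s, 0.40) == {2}

    def test_matches_bruteforce_on_random_corruptions(self):
        rng = np.random.default_rng(5)
        for rep in range(25):
            n = int(rng.integers(50, 400))
            cfg = simulate.HPSimConfig(
                noise_sd=float(rng.uniform(10, 50)), seed=int(rng.integers(2**31)),
                duration=n,
            )
            s = simulate.simulate_hp_series(cfg)
            spec = simulate.ArtifactSpec(
                n_spikes=int(rng.integers(0, 5)),
                n_missed=int(rng.integers(0, 3)),
                n_extra=int(rng.integers(0, 3)),
                spike_factor=float(rng.uniform(1.5, 3.0)),
                seed=int(rng.integers(2**31)),
            )
            corrupted, _ = simulate.inject_artifacts(s, spec)
            thr = float(rng.uniform(0.40, 0.50))
            assert detect_karlsson(corrupted, thr) == detect_karlsson_bruteforce(
                corrupted, thr
            )

    def test_too_short_series_rejected(self):
        with pytest.raises(QualityError):
            detect_karlsson(HeartPeriodSeries.from_intervals([800, 810]), 0.4)


class TestCorrection:
    def test_interior_flag_interpolated_to_midpoint(self):
        s = HeartPeriodSeries.from_intervals([800, 1600, 820])
        out = correct_artifacts(s, {1})
        np.testing.assert_allclose(out.hp, [800, 810, 820])

    def test_empty_flag_set_is_identity(self, clean_series):
        assert correct_artifacts(clean_series, set()) is clean_series

    def test_end_flag_copies_nearest_clean(self):
        s = HeartPeriodSeries.from_intervals([2500, 800, 820])
        out = correct_artifacts(s, {0})
        np.testing.assert_allclose(out.hp, [800, 800, 820])

    def test_unflagged_beats_untouched_and_length_kept(self, clean_series):
        flagged = {10, 50, 51, 200}
        out = correct_artifacts(clean_series, flagged)
        assert len(out) == len(clean_series)
        keep = sorted(set(range(len(clean_series))) - flagged)
        np.testing.assert_array_equal(out.hp[keep], clean_series.hp[keep])

    def test_all_but_one_flagged_rejected(self):
        s = HeartPeriodSeries.from_intervals([800, 810, 820])
        with pytest.raises(QualityError):
            correct_artifacts(s, {0, 1})


class TestQualityGate:
    def _report(self, n_flags):
        return ArtifactReport(flagged_karlsson=frozenset(range(n_flags)))

    def test_ten_artifacts_kept(self, clean_series):
        rep = apply_quality_gate(self._report(10), clean_series)
        assert not rep.excluded

    def test_eleven_artifacts_excluded(self, clean_series):
        rep = apply_quality_gate(self._report(11), clean_series)
        assert rep.excluded and rep.exclusion_reason == "too_many_artifacts"

    def test_short_recording_excluded(self):
        s = simulate.simulate_hp_series(simulate.HPSimConfig(duration=200, seed=1))
        rep = apply_quality_gate(self._report(0), s)
        assert rep.excluded and rep.exclusion_reason == "too_short"

    def test_sparse_recording_excluded(self):
        s = simulate.simulate_hp_series(
            simulate.HPSimConfig(mean_hp=1900, noise_sd=0, rsa_amplitude=0, seed=1)
        )
        rep = apply_quality_gate(self._report(0), s, min_beats=200)
        assert rep.excluded and rep.exclusion_reason == "implausible_beat_count"


class TestTimeDomainFeatures:
    def test_rmssd_constant_series_zero(self, constant_series):
        assert compute_rmssd(constant_series) == 0.0

    def test_rmssd_hand_example(self):
        # sqrt((10^2 + 20^2) / 2) = sqrt(250)
        assert compute_rmssd([800, 810, 790]) == pytest.approx(np.sqrt(250))

    def test_rmssd_matches_bruteforce(self, clean_series, rmssd_oracle):
        assert compute_rmssd(clean_series) == pytest.approx(
            rmssd_oracle(clean_series.hp), rel=1e-12
        )

    def test_rmssd_time_reversal_invariant(self, clean_series):
        forward = compute_rmssd(clean_series.hp)
        backward = compute_rmssd(clean_series.hp[::-1])
        assert forward == pytest.approx(backward, rel=1e-12)

    @pytest.mark.parametrize(
        "hp, expected", [([1000] * 10, 60.0), ([800] * 5, 75.0), ([600, 1200], 60000 / 900)]
    )
    def test_mean_hr(self, hp, expected):
        assert compute_mean_hr(hp) == pytest.approx(expected)

    def test_minutewise_constant_series_all_zero(self, constant_series):
        vals = compute_minutewise_rmssd(constant_series)
        assert vals == [0.0] * 5

    def test_minutewise_stationary_series_near_global(self, clean_series):
        total = compute_rmssd(clean_series)
        vals = compute_minutewise_rmssd(clean_series)
        assert len(vals) == 5
        for v in vals:
            assert abs(v - total) / total < 0.35  # sampling error per 60-s window

    def test_short_recording_yields_nan_windows(self):
        s = simulate.simulate_hp_series(simulate.HPSimConfig(duration=150, seed=3))
        vals = compute_minutewise_rmssd(s)
        assert np.isfinite(vals[0]) and np.isfinite(vals[1]) and np.isnan(vals[-1])


class TestHFPower:
    def test_pure_respiratory_modulation_concentrates_in_band(self):
        cfg = simulate.HPSimConfig(rsa_amplitude=40, noise_sd=0, seed=0)
        s = simulate.simulate_hp_series(cfg)
        hf = compute_hf_power(s)
        total = compute_hf_power(s, band=(0.01, 2.0))
        assert hf / total >= 0.90

    def test_constant_series_zero_power(self, constant_series):
        assert compute_hf_power(constant_series) == pytest.approx(0.0, abs=1e-8)

    def test_power_scales_with_amplitude_squared(self):
        lo = compute_hf_power(
            simulate.simulate_hp_series(simulate.HPSimConfig(rsa_amplitude=20, noise_sd=0, seed=0))
        )
        hi = compute_hf_power(
            simulate.simulate_hp_series(simulate.HPSimConfig(rsa_amplitude=40, noise_sd=0, seed=0))
        )
        assert hi / lo == pytest.approx(4.0, rel=0.15)

    def test_short_series_rejected(self):
        s = simulate.simulate_hp_series(simulate.HPSimConfig(duration=60, seed=0))
        with pytest.raises(QualityError):
            compute_hf_power(s)


class TestFullPreprocessing:
    def test_clean_series_passes_with_no_artifacts(self, clean_series):
        features, report = preprocess_participant(clean_series)
        assert report.n_artifacts == 0
        assert not report.excluded
        assert np.isfinite(features.rmssd) and np.isfinite(features.log_rmssd)
        assert features.log_rmssd == pytest.approx(np.log(features.rmssd))

    def test_many_spikes_trigger_exclusion(self, clean_series):
        corrupted, _ = simulate.inject_artifacts(
            clean_series, simulate.ArtifactSpec(n_spikes=12, seed=1)
        )
        features, report = preprocess_participant(corrupted)
        assert features is None
        assert report.excluded and report.exclusion_reason == "too_many_artifacts"

    def test_few_spikes_recovered_and_rmssd_restored(self, clean_series):
        corrupted, truth = simulate.inject_artifacts(
            clean_series, simulate.ArtifactSpec(n_spikes=3, spike_factor=2.0, seed=2)
        )
        features, report = preprocess_participant(corrupted)
        flagged = set(report.flagged_bounds) | set(report.flagged_karlsson)
        assert truth <= flagged
        pristine = compute_rmssd(clean_series)
        assert abs(features.rmssd - pristine) / pristine < 0.05
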