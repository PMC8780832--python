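import datetime as dt
import math

import numpy as np
import pytest

from actisphere.metrics import (
    acceleration_asymmetry_index,
    activity_amplitude,
    cmw_spectrogram,
    cohens_d,
    compute_report,
    detect_sleep,
    detect_transitions,
    higher_acceleration_fraction,
    time_zone_of,
)
from actisphere.synth import generate_pulse_train
from tests.conftest import DAY_START, make_recording


def _daytime_rec(accel, fs=100.0):
    return make_recording(accel, fs=fs, start_clock=DAY_START)


def _polar_cap_accel(n, magnitude=1.0, x_sign=0.0):
    """n samples pointing near the south pole with given |a| and x lean."""
    a = np.tile([0.1 * x_sign, -1.0, 0.0], (n, 1))
    a /= np.linalg.norm(a[0])
    return a * magnitude


class TestHigherAccelerationFraction:
    def test_one_percent_above_two_g_gives_minus_two(self):
        accel = np.concatenate(
            [_polar_cap_accel(990, 1.0), _polar_cap_accel(10, 2.5)]
        )
        assert higher_acceleration_fraction(_daytime_rec(accel)) == pytest.approx(-2.0)

    def test_none_above_threshold_returns_sentinel_not_inf(self):
        rec = _daytime_rec(_polar_cap_accel(100, 1.0))
        assert math.isnan(higher_acceleration_fraction(rec))

    def test_all_above_threshold_gives_zero(self):
        rec = _daytime_rec(_polar_cap_accel(100, 2.5))
        assert higher_acceleration_fraction(rec) == 0.0

    def test_empty_selection_raises(self):
        rec = _daytime_rec(np.tile([1.0, 0.0, 0.0], (100, 1)))  # equator
        with pytest.raises(ValueError):
            higher_acceleration_fraction(rec)

    def test_haf_is_never_positive(self, short_daytime_recording):
        haf = higher_acceleration_fraction(short_daytime_recording)
        assert math.isnan(haf) or haf <= 0.0


class TestAAI:
    def test_balanced_sides_give_zero(self):
        accel = np.concatenate(
            [_polar_cap_accel(50, 2.5, x_sign=+1), _polar_cap_accel(50, 2.5, x_sign=-1)]
        )
        res = acceleration_asymmetry_index(_daytime_rec(accel))
        assert res.aai == pytest.approx(0.0)
        assert (res.n_left, res.n_right) == (50, 50)

    def test_two_to_one_ratio_gives_log10_two(self):
        accel = np.concatenate(
            [_polar_cap_accel(200, 2.5, x_sign=-1), _polar_cap_accel(100, 2.5, x_sign=+1)]
        )
        res = acceleration_asymmetry_index(_daytime_rec(accel))
        assert res.aai == pytest.approx(math.log10(2.0))
        assert res.signed == pytest.approx(math.log10(2.0))

    def test_one_sided_counts_give_sentinel_with_counts(self):
        accel = _polar_cap_accel(100, 2.5, x_sign=-1)
        res = acceleration_asymmetry_index(_daytime_rec(accel))
        assert math.isnan(res.aai)
        assert res.n_right == 100 and res.n_left == 0

    def test_mirror_invariance_of_absolute_aai(self, short_daytime_recording):
        rec = short_daytime_recording
        res = acceleration_asymmetry_index(rec)
        mirrored = make_recording(
            rec.accel * np.array([-1.0, 1.0, 1.0]),
            fs=rec.sample_rate_hz,
            start_clock=rec.start_clock,
        )
        res_m = acceleration_asymmetry_index(mirrored)
        assert res_m.aai == pytest.approx(res.aai)
        assert res_m.signed == pytest.approx(-res.signed)
        assert (res_m.n_left, res_m.n_right) == (res.n_right, res.n_left)


class TestSleepDetection:
    def test_supine_stillness_is_sleep(self):
        rec = make_recording(np.tile([0.0, 0.0, -1.0], (500, 1)))
        mask, hours = detect_sleep(rec)
        assert mask.all()
        assert hours == pytest.approx(5.0 / 3600)

    def test_upright_standing_is_not_sleep(self, still_standing):
        mask, hours = detect_sleep(still_standing)
        assert not mask.any() and hours == 0.0

    def test_planted_supine_epoch_recovered_within_one_percent(self):
        rng = np.random.default_rng(0)
        fs = 100.0
        hours = 6.0
        n_sleep = int(hours * 3600 * fs)
        n_wake = int(0.5 * 3600 * fs)
        supine = np.tile([0.0, 0.0, -1.0], (n_sleep, 1))
        upright = np.tile([0.0, -1.0, 0.0], (n_wake, 1))
        accel = np.concatenate([upright, supine, upright])
        accel += rng.normal(0, 0.01, accel.shape)
        rec = make_recording(accel, fs=fs)
        _, detected = detect_sleep(rec)
        assert detected == pytest.approx(hours, rel=0.01)

    def test_sleep_hours_additive_over_disjoint_epochs(self):
        fs = 100.0
        supine = np.tile([0.0, 0.0, -1.0], (int(120 * fs), 1))
        upright = np.tile([0.0, -1.0, 0.0], (int(60 * fs), 1))
        accel = np.concatenate([supine, upright, supine])
        _, hours = detect_sleep(make_recording(accel, fs=fs))
        assert hours == pytest.approx(240 / 3600.0)


class TestActivityAmplitude:
    def test_constant_unit_magnitude_gives_zero(self, still_standing):
        report = activity_amplitude(still_standing)
        assert all(v == 0.0 for v in report.by_band.values())
        assert report.n_epochs == 0

    def test_rectangular_epoch_integral(self):
        fs = 100.0
        accel = np.tile([0.0, -1.0, 0.0], (int(30 * fs), 1))
        accel[1000:2000, 1] = -1.2  # 10 s at |a| = 1.2 g
        report = activity_amplitude(make_recording(accel, fs=fs))
        assert report.by_band["medium"] == pytest.approx(2.0, rel=1e-6)
        assert report.by_band["low"] == 0.0 and report.by_band["high"] == 0.0

    def test_epoch_credited_to_start_time_zone(self):
        accel = np.tile([0.0, -1.0, 0.0], (3000, 1))
        accel[1000:2000, 1] = -1.5
        rec = make_recording(accel, start_clock=dt.datetime(2022, 1, 10, 3, 0))
        report = activity_amplitude(rec)
        assert report.by_zone[1] > 0
        assert report.by_zone[2] == report.by_zone[3] == report.by_zone[4] == 0.0

    @pytest.mark.parametrize(
        "hour,zone", [(0, 1), (5.99, 1), (6, 2), (11.99, 2), (12, 3), (18, 4), (23.99, 4)]
    )
    def test_time_zone_boundaries(self, hour, zone):
        assert time_zone_of(hour * 3600.0) == zone

    def test_band_totals_shrink_when_cut_rises(self, short_daytime_recording):
        lo = activity_amplitude(short_daytime_recording, band_thresholds=(0.1, 0.3))
        hi = activity_amplitude(short_daytime_recording, band_thresholds=(0.15, 0.3))
        assert hi.by_band["low"] >= lo.by_band["low"]
        assert hi.by_band["medium"] <= lo.by_band["medium"]

    def test_amplitude_is_rotation_invariant(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(1)
        accel = np.tile([0.0, -1.0, 0.0], (6000, 1))
        accel[1000:2000, 1] -= 0.4 * np.sin(np.linspace(0, 12 * np.pi, 1000))
        rot = Rotation.from_euler("zyx", [15, 70, 40], degrees=True)
        a_rot = rot.apply(accel)
        r1 = activity_amplitude(make_recording(accel))
        r2 = activity_amplitude(make_recording(a_rot))
        for band in r1.by_band:
            assert r2.by_band[band] == pytest.approx(r1.by_band[band], abs=1e-9)

    def test_bad_thresholds_rejected(self, still_standing):
        with pytest.raises(ValueError):
            activity_amplitude(still_standing, band_thresholds=(0.3, 0.1))


class TestTransitions:
    def test_flat_signal_has_no_transitions(self, still_standing):
        assert detect_transitions(still_standing) == []

    def test_single_pulse_statistics(self):
        rec = generate_pulse_train(1, pulse_amp_g=0.5, pulse_s=2.0)
        trans = detect_transitions(rec)
        assert len(trans) == 1
        t = trans[0]
        assert t.max == pytest.approx(1.5)
        assert t.range == pytest.approx(0.5)
        assert t.duration_s == pytest.approx(2.0, abs=0.05)
        assert t.min == pytest.approx(1.0, abs=0.02)
        assert 1.0 < t.rms < 1.5

    @pytest.mark.parametrize("k", [1, 2, 5, 10])
    def test_pulse_train_count_recovered_exactly(self, k):
        rec = generate_pulse_train(k)
        assert len(detect_transitions(rec)) == k

    def test_sustained_oscillation_is_not_a_transition(self):
        fs = 100.0
        n = int(60 * fs)
        t = np.arange(n) / fs
        accel = np.tile([0.0, -1.0, 0.0], (n, 1))
        accel[:, 1] -= 0.4 * np.sin(2 * np.pi * 1.8 * t)
        rec = make_recording(accel, fs=fs)
        assert detect_transitions(rec) == []


class TestCMWSpectrogram:
    def _sine_rec(self, f, n_s=30, fs=100.0):
        t = np.arange(int(n_s * fs)) / fs
        accel = np.tile([0.0, -1.0, 0.0], (t.size, 1))
        accel[:, 1] -= 0.3 * np.sin(2 * np.pi * f * t)
        return make_recording(accel, fs=fs)

    def test_pure_tone_frequency_recovered(self):
        rec = self._sine_rec(2.0)
        freqs = np.linspace(0.5, 5.0, 10)
        power = cmw_spectrogram(rec, freqs)
        mid = power[:, power.shape[1] // 2]
        assert freqs[np.argmax(mid)] == pytest.approx(2.0)

    def test_dc_signal_has_negligible_power(self, still_standing):
        power = cmw_spectrogram(still_standing, [1.0, 2.0], cycles=3)
        assert power.max() < 1e-20

    def test_chirp_ridge_increases_monotonically(self):
        from scipy.signal import chirp

        fs = 100.0
        t = np.arange(int(120 * fs)) / fs
        accel = np.tile([0.0, -1.0, 0.0], (t.size, 1))
        accel[:, 1] -= 0.3 * chirp(t, f0=0.5, f1=5.0, t1=t[-1])
        rec = make_recording(accel, fs=fs)
        freqs = np.linspace(0.4, 5.5, 24)
        power = cmw_spectrogram(rec, freqs)
        interior = slice(int(10 * fs), int(110 * fs))
        ridge = freqs[np.argmax(power[:, interior], axis=0)]
        # down-sample the ridge and require monotone increase
        coarse = ridge[:: int(10 * fs)]
        assert np.all(np.diff(coarse) > 0)

    def test_out_of_band_frequency_rejected(self, still_standing):
        with pytest.raises(ValueError):
            cmw_spectrogram(still_standing, [80.0])


class TestCohensD:
    def test_identical_groups_give_zero(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_unit_difference_at_unit_sd(self):
        rng = np.random.default_rng(0)
        a = rng.normal(1.0, 1.0, 200_000)
        b = rng.normal(0.0, 1.0, 200_000)
        assert cohens_d(a, b) == pytest.approx(1.0, abs=0.01)

    def test_simulated_small_effect_recovered(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.28, 1.0, 100_000)
        b = rng.normal(0.0, 1.0, 100_000)
        assert cohens_d(a, b) == pytest.approx(0.28, abs=0.01)

    def test_degenerate_pooled_sd_gives_sentinel(self):
        assert math.isnan(cohens_d([1.0, 1.0], [2.0, 2.0]))


class TestMetricReport:
    def test_report_serializes_and_has_consistent_counts(self, short_daytime_recording):
        report = compute_report(short_daytime_recording)
        text = report.to_json()
        assert '"haf"' in text
        assert report.sleep_hours >= 0
        assert all(v >= 0 for v in report.activity_amplitude.values())
        # side counts match the AAI recomputation
        res = acceleration_asymmetry_index(short_daytime_recording)
        assert (report.n_left, report.n_right) == (res.n_left, res.n_right)
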