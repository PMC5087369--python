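"""Tests for signal averaging, filtering, QRS bounds and VLP parameters."""

import numpy as np
import pytest

from aiqp import (
    BeatEnsemble,
    EmptyEnsembleError,
    InvalidInputError,
    InvalidParameterError,
    NoQRSDetectedError,
    bandpass_filter,
    detect_qrs_bounds,
    signal_average,
    vector_magnitude,
    vlp_params,
)


def _pulse(p=400, center=200, width=20, amp=500.0):
    n = np.arange(p)
    return amp * np.exp(-((n - center) ** 2) / (2.0 * width**2))


class TestSignalAverage:
    def test_identical_beats_average_to_the_beat(self):
        beat = _pulse()
        ens = BeatEnsemble(beats=[beat] * 5, fs=2000.0)
        avg = signal_average(ens)
        np.testing.assert_allclose(avg.samples, beat)

    def test_known_shifts_recovered(self):
        beat = _pulse()
        shifts_in = [0, 3, -5, 8]
        ens = BeatEnsemble(beats=[np.roll(beat, s) for s in shifts_in], fs=2000.0)
        avg, info = signal_average(ens, align=True, return_info=True)
        # aligning undoes the applied shift
        assert info.shifts.tolist() == [-s for s in shifts_in]
        assert info.kept.all()
        np.testing.assert_allclose(avg.samples, beat, atol=1e-9)

    def test_noise_suppression_follows_sqrt_n_law(self):
        rng = np.random.default_rng(8)
        beat = _pulse(p=512, center=256)
        sigma_n = 30.0
        beats = [beat + sigma_n * rng.standard_normal(512) for _ in range(64)]
        avg = signal_average(BeatEnsemble(beats=beats, fs=2000.0), align=False)
        resid_rms = np.sqrt(np.mean((avg.samples - beat) ** 2))
        assert resid_rms == pytest.approx(sigma_n / 8.0, rel=0.30)

    def test_uncorrelated_beat_rejected(self):
        rng = np.random.default_rng(1)
        beat = _pulse()
        junk = rng.standard_normal(beat.size) * 100
        ens = BeatEnsemble(beats=[beat, beat, junk], fs=2000.0)
        _, info = signal_average(ens, return_info=True)
        assert info.kept.tolist() == [True, True, False]

    def test_all_rejected_raises(self):
        ens = BeatEnsemble(beats=[_pulse()] * 3, fs=2000.0)
        with pytest.raises(EmptyEnsembleError):
            signal_average(ens, reject_correlation_below=1.5)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(InvalidInputError):
            BeatEnsemble(beats=[np.zeros(10), np.zeros(11)])


class TestBandpassFilter:
    fs = 2000.0

    def _sine(self, freq, seconds=8.0):
        t = np.arange(int(seconds * self.fs)) / self.fs
        return np.sin(2 * np.pi * freq * t)

    def _tail_amplitude(self, x):
        tail = x[x.size // 2 :]
        return np.sqrt(2.0) * np.sqrt(np.mean(tail**2))

    def test_midband_gain_near_unity(self):
        x = self._sine(100.0)
        y = bandpass_filter(x, 40.0, 250.0, fs=self.fs, zero_phase=False)
        assert self._tail_amplitude(y) == pytest.approx(1.0, rel=0.05)

    @pytest.mark.parametrize("edge", [40.0, 250.0])
    def test_edge_gain_forward_and_zero_phase(self, edge):
        x = self._sine(edge)
        fwd = bandpass_filter(x, 40.0, 250.0, fs=self.fs, zero_phase=False)
        zp = bandpass_filter(x, 40.0, 250.0, fs=self.fs, zero_phase=True)
        assert self._tail_amplitude(fwd) == pytest.approx(2**-0.5, rel=0.02)
        assert self._tail_amplitude(zp) == pytest.approx(0.5, rel=0.02)

    def test_dc_rejected(self):
        x = np.ones(4000)
        y = bandpass_filter(x, 40.0, 250.0, fs=self.fs, zero_phase=False)
        assert np.abs(y[2000:]).max() < 1e-3

    def test_zero_phase_preserves_pulse_peak(self):
        x = _pulse(p=2000, center=1000, width=8)
        y = bandpass_filter(x, 40.0, 250.0, fs=self.fs, zero_phase=True)
        assert abs(int(np.argmax(y)) - 1000) <= 1

    def test_segmented_mode_runs_and_keeps_shape(self):
        x = _pulse(p=1000, center=500, width=10)
        y = bandpass_filter(x, 40.0, 250.0, fs=self.fs, mode="segmented")
        assert y.shape == x.shape
        assert np.all(np.isfinite(y))

    def test_invalid_band_rejected(self):
        with pytest.raises(InvalidParameterError):
            bandpass_filter(np.zeros(100), 250.0, 40.0, fs=self.fs)
        with pytest.raises(InvalidParameterError):
            bandpass_filter(np.zeros(100), 40.0, 1100.0, fs=self.fs)


class TestVectorMagnitude:
    def test_three_four_zero_gives_five(self):
        vm = vector_magnitude([3.0, 0.0], [4.0, 0.0], [0.0, 0.0])
        assert vm[0] == 5.0

    def test_zero_leads_give_zero(self):
        np.testing.assert_array_equal(
            vector_magnitude(np.zeros(5), np.zeros(5), np.zeros(5)), 0.0
        )

    def test_sign_invariance(self, rng):
        x, y, z = rng.normal(size=(3, 40))
        np.testing.assert_allclose(
            vector_magnitude(x, y, z), vector_magnitude(-x, -y, -z)
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            vector_magnitude(np.zeros(4), np.zeros(5), np.zeros(4))


def _vm_with_pulse(shift=0, p=1000, amp=100.0, start=400, stop=600, noise_amp=0.5):
    rng = np.random.default_rng(17)
    vm = noise_amp * np.abs(rng.standard_normal(p))
    vm[start + shift : stop + shift] += amp
    return vm


class TestDetectQRSBounds:
    def test_pulse_edges_found_within_sustain_window(self):
        vm = _vm_with_pulse()
        onset, offset, noise_rms = detect_qrs_bounds(vm, (0, 200), fs=2000.0)
        run = int(round(5.0 * 2000.0 / 1000.0))
        assert abs(onset - 400) <= run
        assert abs(offset - 599) <= run
        assert noise_rms < 1.0

    def test_translation_equivariance(self):
        for s in (0, 37):
            vm = _vm_with_pulse(shift=s)
            onset, offset, _ = detect_qrs_bounds(vm, (0, 200), fs=2000.0)
            if s == 0:
                base = (onset, offset)
            else:
                assert (onset - s, offset - s) == base

    def test_no_crossing_raises(self):
        rng = np.random.default_rng(3)
        vm = np.abs(rng.standard_normal(500))
        with pytest.raises(NoQRSDetectedError):
            detect_qrs_bounds(vm, (0, 500), k_sigma=50.0, fs=2000.0)

    def test_invalid_noise_window_rejected(self):
        with pytest.raises(InvalidParameterError):
            detect_qrs_bounds(np.ones(100), (50, 200), fs=2000.0)


class TestVLPParams:
    fs = 2000.0

    def test_constant_plateau(self):
        # constant 100 uV, onset..offset spanning exactly 100 ms
        vm = np.full(300, 100.0)
        params = vlp_params(vm, 50, 250, fs=self.fs)
        assert params.fqrsd_ms == pytest.approx(100.0)
        assert params.rms40_uV == pytest.approx(100.0)
        assert params.las40_ms == 0.0

    def test_piecewise_terminal_low_amplitude(self):
        # 100 uV until 30 ms before offset, then 10 uV: RMS40 mixes 10 ms of
        # 100 with 30 ms of 10; LAS40 = 30 ms
        vm = np.full(200, 100.0)
        vm[140:] = 10.0  # samples 140..199, i.e. the last 30 ms
        params = vlp_params(vm, 0, 199, fs=self.fs)
        expect_rms40 = np.sqrt((20 * 100.0**2 + 60 * 10.0**2) / 80)
        assert params.rms40_uV == pytest.approx(expect_rms40)
        assert params.las40_ms == pytest.approx(30.0)

    def test_everywhere_below_threshold_gives_las40_equal_fqrsd(self):
        vm = np.full(200, 10.0)
        params = vlp_params(vm, 0, 199, fs=self.fs)
        assert params.las40_ms == pytest.approx(params.fqrsd_ms)

    def test_rms40_scales_linearly_las40_flips_at_threshold(self):
        vm = np.full(200, 100.0)
        vm[140:] = 10.0
        base = vlp_params(vm, 0, 199, fs=self.fs)
        up = vlp_params(5.0 * vm, 0, 199, fs=self.fs)  # 10 -> 50 > 40 uV
        down = vlp_params(0.3 * vm, 0, 199, fs=self.fs)  # 100 -> 30 < 40 uV
        assert up.rms40_uV == pytest.approx(5.0 * base.rms40_uV)
        assert up.las40_ms == 0.0
        assert down.las40_ms == pytest.approx(down.fqrsd_ms)

    def test_parameters_invariant_under_record_shift(self):
        vm = np.full(400, 1.0)
        vm[100:300] = 100.0
        vm[260:300] = 10.0
        a = vlp_params(vm, 100, 299, fs=self.fs)
        b = vlp_params(np.roll(vm, 50), 150, 349, fs=self.fs)
        assert a.fqrsd_ms == b.fqrsd_ms
        assert a.rms40_uV == pytest.approx(b.rms40_uV)
        assert a.las40_ms == pytest.approx(b.las40_ms)

    def test_window_shorter_than_40ms_rejected(self):
        with pytest.raises(InvalidInputError):
            vlp_params(np.ones(60), 0, 50, fs=self.fs)

    def test_bad_bounds_rejected(self):
        with pytest.raises(InvalidInputError):
            vlp_params(np.ones(100), 50, 50, fs=self.fs)
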