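"""Tests for EEG synthesis, coherent averaging and the neighbour-bin SNR."""

import numpy as np
import pytest

from binsum.model import tagged_response
from binsum.ssaep import (
    EEGTrialSet,
    SpectrumEstimate,
    WaveformSpec,
    am_waveform,
    calibrate_gains,
    coherent_average,
    noise_floor_amplitude,
    snr_at_frequency,
    synth_trial_set,
)
from binsum.stimuli import F35, F40, eeg_arrangement


class TestAmWaveform:
    def test_zero_at_time_zero_for_any_depth(self):
        for m in (0.0, 0.3, 1.0):
            assert am_waveform(WaveformSpec(m=m), 0.0) == 0.0

    def test_unmodulated_is_half_amplitude_carrier(self):
        t = np.linspace(0, 0.1, 4001)
        w = am_waveform(WaveformSpec(m=0.0), t)
        assert np.max(np.abs(w)) == pytest.approx(0.5, abs=1e-3)

    def test_envelope_bound_and_onset_minimum(self):
        spec = WaveformSpec(m=0.8)
        t = np.linspace(0, 0.5, 22051)
        w = am_waveform(spec, t)
        assert np.all(np.abs(w) <= 0.5 * (1 + spec.m) + 1e-12)
        # phase pi puts the envelope minimum at t=0: nearby extremes small
        assert np.max(np.abs(w[:20])) < 0.5 * (1 - spec.m) + 0.01

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            WaveformSpec(m=1.2)
        with pytest.raises(ValueError):
            WaveformSpec(m=0.5, f_m=600.0, fs=1000.0)


class TestSynthTrials:
    def test_noiseless_trial_is_a_pure_line(self, p6d):
        rng = np.random.default_rng(0)
        ts = synth_trial_set("bin", 100.0, p6d, gain=2.0, noise_sd=0.0,
                             rng=rng, n_reps=3)
        spec = coherent_average(ts)
        amp = spec.amplitude()
        left, right = eeg_arrangement("bin", 100.0)
        expect = 2.0 * tagged_response(left, right, F40, p6d)
        i40 = int(round(40.0 / spec.df))
        assert amp[i40] == pytest.approx(expect, rel=1e-9)
        others = np.delete(amp, i40)
        assert np.max(others) < 1e-9 * expect

    def test_divide_guard_on_exactly_zero_neighbours(self):
        coeffs = np.zeros(5001, dtype=complex)
        coeffs[400] = 10.0
        spec = SpectrumEstimate(coeffs=coeffs, fs=1000.0, n=10000)
        with pytest.raises(ZeroDivisionError):
            snr_at_frequency(spec, 40.0)

    def test_depth_zero_no_masker_is_pure_noise(self, p6d):
        rng = np.random.default_rng(1)
        ts = synth_trial_set("mon", 0.0, p6d, gain=1.0, noise_sd=1.0,
                             rng=rng, n_reps=2)
        # remove noise by regenerating with the same seed and zero signal:
        rng2 = np.random.default_rng(1)
        for _ in range(2):
            rng2.uniform(0, 2 * np.pi)  # the two signal phases drawn first
        noise = rng2.normal(0.0, 1.0, ts.trials.shape)
        assert np.allclose(ts.trials, noise)

    def test_seeded_synthesis_reproducible(self, p6d):
        a = synth_trial_set("dich", 25.0, p6d, 1.0, 0.5,
                            np.random.default_rng(7), n_reps=2)
        b = synth_trial_set("dich", 25.0, p6d, 1.0, 0.5,
                            np.random.default_rng(7), n_reps=2)
        assert np.array_equal(a.trials, b.trials)

    def test_doubling_gain_doubles_line_and_raises_snr(self, p6d):
        phases = {F40: 1.0, F35: 2.0}
        kw = dict(noise_sd=0.8, n_reps=4, signal_phases=phases)
        s1 = coherent_average(
            synth_trial_set("bin", 50.0, p6d, 1.0, rng=np.random.default_rng(3), **kw)
        )
        s2 = coherent_average(
            synth_trial_set("bin", 50.0, p6d, 2.0, rng=np.random.default_rng(3), **kw)
        )
        i40 = int(round(40.0 / s1.df))
        # identical noise seed: the signal component doubles exactly
        left, right = eeg_arrangement("bin", 50.0)
        a = tagged_response(left, right, F40, p6d)
        line1, line2 = s1.amplitude()[i40], s2.amplitude()[i40]
        assert line2 - line1 == pytest.approx(a, rel=1e-3)
        assert snr_at_frequency(s2, 40.0) > snr_at_frequency(s1, 40.0)


class TestCoherentAverage:
    def test_identical_repetitions_change_nothing(self):
        rng = np.random.default_rng(2)
        one = rng.normal(0, 1, 11000)
        ts = EEGTrialSet(np.tile(one, (5, 1)))
        single = coherent_average(EEGTrialSet(one[None, :]))
        avg = coherent_average(ts)
        assert np.allclose(avg.coeffs, single.coeffs)

    def test_antiphase_component_cancels(self):
        t = np.arange(11000) / 1000.0
        s = np.sin(2 * np.pi * 40 * t)
        ts = EEGTrialSet(np.stack([s, -s]))
        spec = coherent_average(ts)
        assert np.max(np.abs(spec.coeffs)) < 1e-9

    def test_onset_discard_window(self):
        # a transient confined to the first second must not reach the spectrum
        x = np.zeros((1, 11000))
        x[0, :1000] = 100.0
        spec = coherent_average(EEGTrialSet(x))
        assert spec.n == 10000
        assert np.max(np.abs(spec.coeffs)) == 0.0

    def test_noise_floor_halves_from_4_to_16_reps(self):
        floors = {4: [], 16: []}
        for seed in range(10):
            rng = np.random.default_rng(seed)
            for n in floors:
                ts = EEGTrialSet(rng.normal(0, 1, (n, 11000)))
                amp = coherent_average(ts).amplitude()
                floors[n].append(np.mean(amp[1:]))
        ratio = np.mean(floors[4]) / np.mean(floors[16])
        assert ratio == pytest.approx(2.0, rel=0.1)

    def test_predicted_noise_floor_amplitude(self):
        rng = np.random.default_rng(11)
        sd, reps = 2.0, 8
        ts = EEGTrialSet(rng.normal(0, sd, (reps, 11000)))
        amp = coherent_average(ts).amplitude()
        assert np.mean(amp[1:]) == pytest.approx(
            noise_floor_amplitude(sd, reps, 10000), rel=0.05
        )

    def test_parseval_energy_identity(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, (1, 11000))
        spec = coherent_average(EEGTrialSet(x))
        direct = float(np.sum(x[0, 1000:] ** 2))
        assert spec.total_energy() == pytest.approx(direct, rel=1e-9)


class TestSnrAtFrequency:
    def _flat_spectrum(self, centre_amp, flat_amp, i=400, n=10000):
        coeffs = np.full(n // 2 + 1, flat_amp, dtype=complex)
        coeffs[i] = centre_amp
        return SpectrumEstimate(coeffs=coeffs, fs=1000.0, n=n)

    def test_flat_spectrum_arithmetic(self):
        # amplitude 10 at the tag over a flat floor of 2 -> SNR 5
        assert snr_at_frequency(self._flat_spectrum(10.0, 2.0), 40.0) == 5.0

    def test_tag_bins_fall_on_grid(self):
        spec = self._flat_spectrum(4.0, 2.0)
        assert spec.df == pytest.approx(0.1)
        assert int(round(40.0 / spec.df)) == 400
        assert snr_at_frequency(spec, 35.0) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            snr_at_frequency(spec, 40.05)

    def test_location_invariant_for_white_noise(self):
        snrs = {F35: [], F40: []}
        for seed in range(60):
            rng = np.random.default_rng(seed)
            spec = coherent_average(EEGTrialSet(rng.normal(0, 1, (2, 11000))))
            for f in snrs:
                snrs[f].append(snr_at_frequency(spec, f))
        m35, m40 = np.mean(snrs[F35]), np.mean(snrs[F40])
        assert m35 == pytest.approx(m40, abs=0.15)
        assert m35 == pytest.approx(1.0, abs=0.15)


def test_raw_trial_hdf5_round_trip(tmp_path, p6d):
    rng = np.random.default_rng(9)
    ts = synth_trial_set("bin", 25.0, p6d, 1.0, 0.5, rng, n_reps=2)
    path = tmp_path / "trials.h5"
    ts.to_hdf5(path)
    back = EEGTrialSet.from_hdf5(path)
    assert np.array_equal(back.trials, ts.trials)
    assert back.condition == "bin" and back.depth == 25.0 and back.fs == ts.fs


def test_calibrated_gain_scales_inversely_with_sigma(p6d):
    gains = calibrate_gains(p6d, noise_sd=1.0)
    assert gains[F40] / gains[F35] == pytest.approx(
        p6d.sigma35 / p6d.sigma40, rel=1e-12
    )
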