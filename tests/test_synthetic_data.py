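"""Synthetic recording generators and sweep averaging."""

import numpy as np
import pytest

from cochlenv import (AllSweepsRejectedError, BoltzmannParams, ContractError,
                      NoiseModel, PhaseSweepResult, PopulationConfig,
                      SweepSet, amplitude_spectrum,
                      average_with_artifact_rejection, component_amplitude,
                      correct_electrode_filter_time, generate_bm_recording,
                      generate_ooc_recording, generate_rw_recording,
                      generate_sweep_set, simulate_receptor_current,
                      synthesize_noise, synthesize_three_tone, tip_to_tail)
from cochlenv.timeseries import TimeSeries

QUIET = NoiseModel(floor=0.0)


class TestBmGenerator:
    def test_noiseless_trace_is_just_the_primaries(self, short_stim):
        bm = generate_bm_recording(short_stim, {}, QUIET, seed=0)
        ref = synthesize_three_tone(short_stim, units="nm")
        np.testing.assert_allclose(bm.samples, ref.samples, atol=1e-12)

    def test_envelope_frequency_request_rejected(self, short_stim):
        with pytest.raises(ContractError):
            generate_bm_recording(short_stim, {"fe": -20.0}, QUIET)

    def test_zero_deterministic_envelope_energy(self, short_stim):
        bm = generate_bm_recording(
            short_stim, {"2f3-f2": -13.0, "2f1-f2": -20.0}, QUIET, seed=1)
        spec = amplitude_spectrum(bm)
        assert component_amplitude(spec, short_stim.f_e) < 1e-12
        assert component_amplitude(spec, 2 * short_stim.f_e) < 1e-12

    def test_requested_distortion_level_round_trips(self, short_stim):
        bm = generate_bm_recording(short_stim, {"2f3-f2": -13.0}, QUIET,
                                   seed=2)
        spec = amplitude_spectrum(bm)
        f = 2 * short_stim.f3 - short_stim.f2
        level = 20 * np.log10(component_amplitude(spec, f)
                              / component_amplitude(spec, short_stim.f1))
        assert level == pytest.approx(-13.0, abs=0.1)

    def test_noisy_fe_component_stays_at_noise_floor(self, short_stim):
        noise = NoiseModel(floor=1e-3, lf_corner=200.0, lf_slope=6.0)
        bm = generate_bm_recording(short_stim, {}, noise, seed=3)
        spec = amplitude_spectrum(bm)
        from cochlenv import estimate_noise_floor
        floor = estimate_noise_floor(spec, short_stim.f_e)
        assert component_amplitude(spec, short_stim.f_e) < 5 * floor


class TestOocGenerator:
    def test_cutoff_range_enforced(self, short_stim):
        with pytest.raises(Exception):
            generate_ooc_recording(short_stim, electrode_cutoff=100.0)

    def test_prominent_envelope_peaks(self, short_stim, channel):
        ooc = generate_ooc_recording(short_stim, channel, 3000.0,
                                     NoiseModel(floor=1e-6), seed=4)
        spec = amplitude_spectrum(ooc)
        fe = short_stim.f_e
        a1, a2, a3 = (component_amplitude(spec, k * fe) for k in (1, 2, 3))
        assert a1 > a2 > a3 > 0  # f_e dominates, harmonics decay

    def test_corrected_spectrum_matches_unfiltered_current(self, short_stim,
                                                           channel):
        cutoff = 2000.0
        ooc = generate_ooc_recording(short_stim, channel, cutoff, QUIET,
                                     seed=5)
        restored = correct_electrode_filter_time(ooc, cutoff)
        raw = simulate_receptor_current(
            synthesize_three_tone(short_stim, units="nm"), channel)
        s_rest = amplitude_spectrum(restored)
        s_raw = amplitude_spectrum(raw)
        below_cap = s_raw.freqs <= 10 * cutoff
        keep = below_cap & (s_raw.amps > 1e-9)
        np.testing.assert_allclose(s_rest.amps[keep], s_raw.amps[keep],
                                   rtol=1e-3)


class TestRwGenerator:
    def test_single_cell_degenerate_population(self, short_stim, channel):
        pop = PopulationConfig(n_cells=1, x0_sd=0.0, gain_sd=0.0,
                               neural_gain=0.0)
        rw = generate_rw_recording(short_stim, pop, channel, QUIET, seed=6)
        single = simulate_receptor_current(
            synthesize_three_tone(short_stim, units="nm"), channel)
        np.testing.assert_allclose(rw.samples, single.samples, rtol=1e-9)

    def test_seed_reproducibility(self, short_stim, channel):
        pop = PopulationConfig(n_cells=8, neural_gain=0.02)
        a = generate_rw_recording(short_stim, pop, channel,
                                  NoiseModel(floor=1e-4), seed=7)
        b = generate_rw_recording(short_stim, pop, channel,
                                  NoiseModel(floor=1e-4), seed=7)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_cell_order_invariance_of_fe_level(self, short_stim, channel):
        # the population signal is a plain sum: permuting cells must not
        # move the f_e level by more than float noise (< 0.1 dB)
        rng = np.random.default_rng(11)
        x = synthesize_three_tone(short_stim, units="nm")
        x0s = rng.normal(5.5, 1.0, 16)
        gains = np.exp(rng.normal(0.0, 0.2, 16))
        from cochlenv import boltzmann_current

        def total(order):
            out = np.zeros(x.n)
            for i in order:
                out += gains[i] * boltzmann_current(
                    x.samples, channel.with_x0(x0s[i]))
            return out

        s1 = amplitude_spectrum(TimeSeries(total(range(16)), x.sample_rate, "uV"))
        s2 = amplitude_spectrum(TimeSeries(total(rng.permutation(16)),
                                           x.sample_rate, "uV"))
        a1 = component_amplitude(s1, short_stim.f_e)
        a2 = component_amplitude(s2, short_stim.f_e)
        assert abs(20 * np.log10(a1 / a2)) < 0.1

    def test_phase_sweep_is_v_shaped(self, short_stim, channel):
        pop = PopulationConfig(n_cells=10, seed=None)
        levels = []
        for phi in (0.0, 45.0, 90.0, 135.0, 180.0):
            rw = generate_rw_recording(short_stim.with_phi(phi), pop,
                                       channel, NoiseModel(floor=1e-6),
                                       seed=8)
            spec = amplitude_spectrum(rw)
            levels.append(component_amplitude(spec, short_stim.f_e))
        levels = np.array(levels)
        assert np.argmin(levels) == 2  # minimum at 90 degrees
        assert levels[0] / levels[2] > 10

    def test_ttx_flag_removes_only_the_neural_component(self, short_stim,
                                                        channel):
        phases = np.array([0.0, 90.0, 180.0])
        ratios = {}
        for ttx in (False, True):
            pop = PopulationConfig(n_cells=10, neural_gain=0.005, ttx=ttx)
            amps = []
            for phi in phases:
                rw = generate_rw_recording(short_stim.with_phi(phi), pop,
                                           channel, QUIET, seed=9)
                amps.append(component_amplitude(
                    amplitude_spectrum(rw), short_stim.f_e))
            sweep = PhaseSweepResult(phases, {"fe": np.array(amps)})
            ratios[ttx] = tip_to_tail(sweep, "fe")
        assert abs(ratios[True] - ratios[False]) < 1.0


class TestNoiseSynthesis:
    def test_low_frequency_rise(self):
        noise = NoiseModel(floor=1.0, lf_corner=400.0, lf_slope=6.0)
        # one octave below the corner the density rises by 6 dB
        assert noise.density(np.array([200.0]))[0] == pytest.approx(
            10 ** (6 / 20), rel=1e-9)
        assert noise.density(np.array([800.0]))[0] == 1.0

    def test_density_calibration(self):
        noise = NoiseModel(floor=0.01, lf_corner=1.0, lf_slope=0.0)
        rng = np.random.default_rng(12)
        n, sr = 8192, 64_000.0
        df = sr / n
        amps = []
        for _ in range(40):
            x = synthesize_noise(n, sr, noise, rng)
            spec = amplitude_spectrum(TimeSeries(x, sr, "nm"))
            amps.append(np.mean(spec.amps[100:3000] ** 2))
        # mean squared bin amplitude ~ 2 * density^2 * df
        assert np.mean(amps) == pytest.approx(2 * 0.01 ** 2 * df, rel=0.1)


class TestAveraging:
    def _clean_set(self, n_sweeps=4):
        sr, n = 64_000.0, 6400
        t = np.arange(n) / sr
        base = np.sin(2 * np.pi * 1000.0 * t)
        sweeps = [TimeSeries(base.copy(), sr, "uV") for _ in range(n_sweeps)]
        return SweepSet(sweeps, np.zeros(n_sweeps, bool))

    def test_identical_sweeps_average_to_themselves(self):
        sset = self._clean_set()
        avg, report = average_with_artifact_rejection(sset)
        np.testing.assert_allclose(avg.samples, sset.sweeps[0].samples)
        assert report == {"n_used": 4, "n_rejected": 0,
                          "rejected_indices": []}

    def test_contaminated_sweeps_rejected(self, model_stim, channel):
        sset = generate_sweep_set(
            model_stim, n_sweeps=20, artifact_sweeps=(3, 11, 17),
            artifact_amp=5.0, artifact_freq=20.0, seed=13, met=channel,
            electrode_cutoff=3000.0, noise=NoiseModel(floor=1e-4))
        avg, report = average_with_artifact_rejection(sset, reject_k=3.0)
        assert report["rejected_indices"] == [3, 11, 17]
        assert report["n_used"] == 17
        assert np.array_equal(np.flatnonzero(sset.artifact_flags),
                              report["rejected_indices"])

    def test_all_rejected_raises(self):
        sr, n = 64_000.0, 6400
        t = np.arange(n) / sr
        # every sweep has a different huge low-frequency drift; one clean
        # reference drags the median down so all drifting sweeps fail
        sweeps = [TimeSeries(np.sin(2 * np.pi * 10.0 * t) * (i + 1) * 100,
                             sr, "uV") for i in range(4)]
        sset = SweepSet(sweeps, np.ones(4, bool))
        with pytest.raises(AllSweepsRejectedError):
            average_with_artifact_rejection(sset, reject_k=0.001)

    def test_sqrt_n_noise_reduction(self):
        sr, n, n_sweeps = 64_000.0, 4096, 16
        noise = NoiseModel(floor=0.01, lf_corner=1.0, lf_slope=0.0)
        rng = np.random.default_rng(14)
        single, averaged = [], []
        for _ in range(10):
            sweeps = [TimeSeries(synthesize_noise(n, sr, noise, rng), sr, "uV")
                      for _ in range(n_sweeps)]
            sset = SweepSet(sweeps, np.zeros(n_sweeps, bool))
            avg, _ = average_with_artifact_rejection(sset, reject_k=10.0)
            band = slice(200, 1800)
            single.append(np.mean(
                amplitude_spectrum(sweeps[0]).amps[band] ** 2))
            averaged.append(np.mean(amplitude_spectrum(avg).amps[band] ** 2))
        ratio = np.sqrt(np.mean(single) / np.mean(averaged))
        assert ratio == pytest.approx(np.sqrt(n_sweeps), rel=0.1)
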