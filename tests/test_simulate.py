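import numpy as np
import pytest

from hairbundle import (CouplingConfig, EfferentDrive, StimulusProtocol,
                        adaptation_rate_for_frequency, default_params,
                        efferent_waveform, null_ensemble, simulate_bundles)
from hairbundle.simulate import OscillatorParams

from _oracles import zero_crossing_frequency

FS = 500.0


class TestEfferentWaveform:
    def test_step_is_constant_inside_the_during_window(self):
        t = np.arange(0, 30, 0.001)
        s = efferent_waveform(EfferentDrive(kind="step", intensity=150.0), t)
        assert np.all(s[t < 10] == 0)
        assert np.all(s[(t >= 10) & (t < 20)] == 150.0)
        assert np.all(s[t >= 20] == 0)

    def test_none_kind_is_identically_zero(self):
        t = np.arange(0, 30, 0.01)
        assert np.all(efferent_waveform(EfferentDrive(), t) == 0)

    def test_pulse_40hz_half_duty_square_wave_structure_at_1khz(self):
        t = np.arange(30_000) / 1000.0
        drv = EfferentDrive(kind="pulse_train", frequency=40.0,
                            duty_cycle=0.5, intensity=100.0)
        s = efferent_waveform(drv, t)
        inside = s[(t >= 10) & (t < 20)]
        # 25-sample period (25 ms) at 50% duty: 12-13 consecutive high
        # samples alternating with 12-13 low, half the samples high overall
        assert set(np.unique(inside)) == {0.0, 100.0}
        high = inside == 100.0
        assert abs(high.mean() - 0.5) < 0.01
        runs = np.diff(np.flatnonzero(np.diff(high.astype(int)) != 0))
        assert set(runs) <= {12, 13}
        period = inside[:25]
        assert np.all(period[:12] == 100.0)
        assert np.all(period[13:] == 0.0)

    def test_pulse_without_frequency_is_a_configuration_error(self):
        with pytest.raises(ValueError, match="frequency"):
            EfferentDrive(kind="pulse_train", intensity=100.0)


class TestSimulateBundles:
    def test_fixed_seed_is_bit_identical(self):
        par = default_params(3, seed=1)
        cpl = CouplingConfig.uniform(3)
        a = simulate_bundles(par, cpl, EfferentDrive(), FS, 5.0, seed=9,
                             protocol=StimulusProtocol(5, 0, 0))
        b = simulate_bundles(par, cpl, EfferentDrive(), FS, 5.0, seed=9,
                             protocol=StimulusProtocol(5, 0, 0))
        assert np.array_equal(a.traces, b.traces)
        assert np.array_equal(a.membrane_trace, b.membrane_trace)

    def test_rigid_plate_is_weighted_average_of_attached_cells(
            self, coupled_ensemble):
        out = coupled_ensemble
        k = np.array([0.35] * 6)
        expected = (k[:, None] * out.traces).sum(0) / k.sum()
        assert np.allclose(out.membrane_trace, expected, atol=1e-9)

    def test_noiseless_cell_reaches_a_stable_limit_cycle(self):
        p = OscillatorParams(natural_frequency_target=20.0,
                             noise_intensity=0.0)
        c = CouplingConfig.uniform(1, k=0.0, attached=[False])
        out = simulate_bundles([p], c, EfferentDrive(), fs=1000,
                               duration=10, seed=0,
                               protocol=StimulusProtocol(10, 0, 0))
        x = out.traces[0, 2000:]
        # peak-to-peak amplitude of consecutive cycles is constant
        period = int(round(1000 / 20.0))
        cycles = x[: (x.size // period) * period].reshape(-1, period)
        ptp = cycles.max(axis=1) - cycles.min(axis=1)
        # windows drift slowly through the (slightly incommensurate) cycle
        assert ptp.std() / ptp.mean() < 5e-3

    def test_frequency_calibration_across_the_band(self):
        for target in (8.0, 20.0, 45.0, 90.0):
            p = OscillatorParams(natural_frequency_target=target,
                                 noise_intensity=0.0)
            c = CouplingConfig.uniform(1, k=0.0, attached=[False])
            out = simulate_bundles([p], c, EfferentDrive(), fs=1000,
                                   duration=10, seed=0,
                                   protocol=StimulusProtocol(10, 0, 0))
            f = zero_crossing_frequency(out.traces[0, 1000:], 1000)
            assert f == pytest.approx(target, rel=0.1)

    def test_divergence_aborts_with_cell_diagnostic(self):
        p = OscillatorParams(noise_intensity=1e12)
        c = CouplingConfig.uniform(1, k=0.0, attached=[False])
        with pytest.raises(FloatingPointError, match="cell 0"):
            simulate_bundles([p], c, EfferentDrive(), FS, 2.0, seed=0,
                             protocol=StimulusProtocol(2, 0, 0))

    def test_pulse_drive_entrains_coupled_group(self):
        from hairbundle import mean_instantaneous_frequency
        par = default_params(6, seed=5)
        cpl = CouplingConfig.uniform(6, k=0.35)
        drv = EfferentDrive(kind="pulse_train", frequency=40.0,
                            intensity=100.0)
        out = simulate_bundles(par, cpl, drv, FS, 30.0, seed=5)
        during = out.traces[:, 5000:10000]
        freqs = [mean_instantaneous_frequency(tr - tr.mean(), FS).mean_hz
                 for tr in during]
        assert np.mean(freqs) == pytest.approx(40.0, rel=0.1)


class TestNullEnsemble:
    def test_uncoupled_pairs_stay_below_threshold(self):
        from hairbundle import correlation_matrix
        traces = null_ensemble(100, fs=FS, duration=10, seed=3)
        m = correlation_matrix(traces)
        assert np.abs(m.pair_values()).max() < 0.2

    def test_pair_count_reaches_request(self):
        traces = null_ensemble(100, fs=FS, duration=5, seed=0)
        n = traces.shape[0]
        assert n * (n - 1) // 2 >= 100

    def test_identical_seeds_give_unit_correlation(self):
        from hairbundle import cross_correlation
        a = null_ensemble(100, fs=FS, duration=5, seed=12)
        b = null_ensemble(100, fs=FS, duration=5, seed=12)
        assert cross_correlation(a[0], b[0]) == pytest.approx(1.0)

    def test_null_spread_reproducible_across_seeds(self):
        from hairbundle import correlation_matrix
        sds = []
        for seed in (1, 2):
            m = correlation_matrix(null_ensemble(150, fs=FS, duration=10,
                                                 seed=seed))
            sds.append(m.pair_values().std())
        assert abs(sds[0] - sds[1]) / sds[0] < 0.35


class TestStochasticTrends:
    def test_step_intensity_lowers_amplitude_and_raises_frequency(self):
        # averaged over seeds: monotone trends of the during-segment
        from hairbundle import detrend, segment
        from hairbundle.oscillation import position_density, amplitude
        amps = {i: [] for i in (0.0, 100.0, 200.0)}
        freqs = {i: [] for i in (0.0, 100.0, 200.0)}
        for seed in range(6):
            for inten in (0.0, 100.0, 200.0):
                par = default_params(4, seed=seed)
                cpl = CouplingConfig.uniform(4, k=0.35)
                drv = EfferentDrive(kind="step", intensity=inten)
                out = simulate_bundles(par, cpl, drv, FS, 30.0, seed=seed)
                for tr in out.traces:
                    seg = segment(detrend(tr, FS), out.protocol).during
                    freqs[inten].append(
                        zero_crossing_frequency(seg.samples, FS))
                    dens = position_density(seg.samples)
                    if dens.modes.size == 2:
                        amps[inten].append(amplitude(dens))
        a = [np.mean(amps[i]) for i in (0.0, 100.0, 200.0)]
        f = [np.mean(freqs[i]) for i in (0.0, 100.0, 200.0)]
        assert a[0] >= a[1] >= a[2]
        assert f[0] <= f[1] <= f[2]

    def test_group_statistics_stable_across_system_size(self):
        # sweeping the patch size changes group means by less than the
        # across-seed spread of the smallest patch
        from hairbundle import correlation_matrix
        means = {}
        spread_ref = None
        for n in (3, 8, 13):
            ccs, fqs = [], []
            for seed in range(4):
                par = [OscillatorParams(natural_frequency_target=20.0)
                       for _ in range(n)]
                cpl = CouplingConfig.uniform(n, k=0.35)
                out = simulate_bundles(par, cpl, EfferentDrive(), FS, 10.0,
                                       seed=seed,
                                       protocol=StimulusProtocol(10, 0, 0))
                m = correlation_matrix(out.traces)
                ccs.append(m.pair_values().mean())
                fqs.append(np.mean([zero_crossing_frequency(t, FS)
                                    for t in out.traces]))
            means[n] = (np.mean(ccs), np.mean(fqs))
            if n == 3:
                spread_ref = (np.std(ccs, ddof=1), np.std(fqs, ddof=1))
        for key in (0, 1):
            vals = [means[n][key] for n in (3, 8, 13)]
            assert max(vals) - min(vals) <= 3 * spread_ref[key] + 1e-9
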