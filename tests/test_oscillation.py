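import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hairbundle import (amplitude, classify_oscillatory, dip_pvalue,
                        dip_statistic, mean_instantaneous_frequency,
                        open_probability, position_density)
from hairbundle.oscillation import PositionDensity

from _oracles import dip_lp, zero_crossing_frequency

FS = 500.0


class TestPositionDensity:
    def test_symmetric_two_gaussian_mixture(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(-40, 4, 3000),
                            rng.normal(40, 4, 3000)])
        d = position_density(x)
        assert d.modes.size == 2
        assert abs(d.modes[0] + 40) < 2 and abs(d.modes[1] - 40) < 2
        assert d.antimode is not None and abs(d.antimode) < 5
        assert np.all(d.density >= 0)
        assert abs(np.trapezoid(d.density, d.grid) - 1) < 1e-6

    def test_single_gaussian_is_unimodal(self):
        rng = np.random.default_rng(1)
        d = position_density(rng.normal(0, 10, 5000))
        assert d.modes.size == 1
        assert d.antimode is None

    def test_simulated_bundle_is_bimodal(self, free_running_cell):
        d = position_density(free_running_cell)
        assert d.modes.size == 2 and d.antimode is not None

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            position_density(np.zeros(1000))
        with pytest.raises(ValueError):
            position_density(np.arange(50.0))


class TestDipStatistic:
    def test_two_equal_point_masses(self):
        assert dip_statistic([0, 0, 0, 0, 1, 1, 1, 1]) == pytest.approx(
            0.25, abs=1e-12)

    @pytest.mark.parametrize("n", [4, 6, 8, 12, 16])
    def test_discrete_uniform(self, n):
        assert dip_statistic(np.arange(n)) == pytest.approx(1 / (2 * n),
                                                            abs=1e-12)

    def test_gaussian_sample_below_oscillatory_threshold(self):
        rng = np.random.default_rng(2)
        assert dip_statistic(rng.normal(size=20000)) < 0.01

    def test_too_few_samples_raise(self):
        with pytest.raises(ValueError):
            dip_statistic([1.0, 2.0, 3.0])

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-100, 100), min_size=4, max_size=40))
    def test_bounds_and_affine_invariance(self, xs):
        # coarse rounding keeps ties while avoiding sub-resolution spacings
        # that a float affine map would merge
        x = np.round(np.asarray(xs), 3)
        d = dip_statistic(x)
        assert 0.0 <= d <= 0.25 + 1e-12
        # positive affine maps rescale the x-axis of both CDFs identically
        assert dip_statistic(2.5 * x + 7.0) == pytest.approx(d, abs=1e-8)

    def test_matches_lp_oracle_on_random_samples(self):
        rng = np.random.default_rng(3)
        for rep in range(60):
            n = int(rng.integers(4, 25))
            if rep % 3 == 0:
                x = rng.integers(0, 4, size=n).astype(float)
            elif rep % 3 == 1:
                x = rng.normal(size=n)
            else:
                x = np.concatenate([rng.normal(-2, 0.3, n // 2),
                                    rng.normal(2, 0.3, n - n // 2)])
            assert dip_statistic(x) == pytest.approx(dip_lp(x), abs=1e-9)


class TestDipPvalue:
    def test_maximal_dip_has_zero_pvalue(self):
        assert dip_pvalue(0.25, 50) == 0.0

    def test_zero_dip_has_unit_pvalue(self):
        assert dip_pvalue(0.0, 50) == 1.0

    def test_bimodal_trace_is_significant(self, free_running_cell):
        d = dip_statistic(free_running_cell)
        p = dip_pvalue(d, free_running_cell.size, n_boot=2000, seed=0)
        assert p < 0.001

    def test_reproducible_for_fixed_seed(self):
        a = dip_pvalue(0.012, 1500, n_boot=1000, seed=5)
        b = dip_pvalue(0.012, 1500, n_boot=1000, seed=5)
        assert a == b


class TestAmplitudeAndOpenProbability:
    def _density(self, modes, antimode=None):
        g = np.linspace(-100, 100, 512)
        return PositionDensity(grid=g, density=np.ones_like(g) / 200,
                               bandwidth=1.0,
                               modes=np.asarray(modes, float),
                               antimode=antimode)

    def test_amplitude_is_half_mode_distance(self):
        assert amplitude(self._density([-30, 50])) == pytest.approx(40.0)

    def test_amplitude_requires_two_modes(self):
        with pytest.raises(ValueError):
            amplitude(self._density([10.0]))

    def test_symmetric_mixture_amplitude_and_p_open(self):
        rng = np.random.default_rng(4)
        a = 40.0
        x = np.concatenate([rng.normal(-a, 4, 4000), rng.normal(a, 4, 4000)])
        d = position_density(x)
        assert amplitude(d) == pytest.approx(a, rel=0.05)
        assert open_probability(d) == pytest.approx(0.5, abs=0.01)

    def test_asymmetric_mixture_mass_fraction(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(-40, 4, 3000),
                            rng.normal(40, 4, 7000)])
        d = position_density(x)
        assert open_probability(d) == pytest.approx(0.70, abs=0.02)

    def test_invariance_under_constant_offset(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(-35, 4, 3000),
                            rng.normal(35, 4, 3000)])
        d0 = position_density(x)
        d1 = position_density(x + 123.4)
        assert amplitude(d1) == pytest.approx(amplitude(d0), rel=1e-6)
        assert open_probability(d1) == pytest.approx(open_probability(d0),
                                                     abs=1e-3)

    def test_open_and_closed_fractions_sum_to_one(self, free_running_cell):
        d = position_density(free_running_cell)
        p = open_probability(d)
        flipped = position_density(-free_running_cell)
        q = open_probability(flipped)
        assert 0 < p < 1
        assert p + q == pytest.approx(1.0, abs=0.02)

    def test_missing_antimode_raises(self):
        with pytest.raises(ValueError):
            open_probability(self._density([-30, 50], antimode=None))


class TestClassifyOscillatory:
    def test_simulated_bundle_is_oscillatory(self, free_running_cell):
        flag, dens = classify_oscillatory(free_running_cell)
        assert flag
        assert dens.modes.size == 2

    def test_white_noise_is_not(self):
        rng = np.random.default_rng(7)
        flag, _ = classify_oscillatory(rng.normal(size=5000))
        assert not flag

    def test_constant_trace_is_not_and_does_not_raise(self):
        flag, dens = classify_oscillatory(np.zeros(5000))
        assert not flag and dens is None

    def test_flag_equals_conjunction_of_criteria(self):
        # audit the three conditions explicitly on borderline noisy traces
        rng = np.random.default_rng(8)
        for rep in range(8):
            sep = rng.uniform(0.3, 1.6)
            x = np.concatenate([rng.normal(-sep, 1, 600),
                                rng.normal(sep, 1, 600)])
            flag, dens = classify_oscillatory(x, seed=1)
            d = dip_statistic(x)
            p = dip_pvalue(d, x.size, seed=1)
            manual = (d > 0.01 and p < 0.001 and dens is not None
                      and dens.modes.size == 2 and dens.antimode is not None)
            assert flag == manual


class TestMeanInstantaneousFrequency:
    def test_pure_tone(self):
        t = np.arange(10 * int(FS)) / FS
        r = mean_instantaneous_frequency(np.sin(2 * np.pi * 25 * t), FS)
        assert r.mean_hz == pytest.approx(25.0, abs=0.1)
        assert r.slip_fraction == 0.0

    def test_linear_chirp_averages_midpoint(self):
        t = np.arange(20 * int(FS)) / FS
        # instantaneous frequency ramps 10 -> 20 Hz
        phase = 2 * np.pi * (10 * t + 0.25 * t ** 2 / t[-1] * 20)
        r = mean_instantaneous_frequency(np.sin(phase), FS)
        assert r.mean_hz == pytest.approx(15.0, rel=0.03)

    def test_matches_cycle_counting_on_relaxation_trace(self):
        # square-ish 30 Hz relaxation oscillation at moderate noise
        from hairbundle import (CouplingConfig, EfferentDrive,
                                StimulusProtocol, simulate_bundles)
        from hairbundle.simulate import OscillatorParams
        p = OscillatorParams(natural_frequency_target=30.0,
                             noise_intensity=100.0)
        c = CouplingConfig.uniform(1, k=0.0, attached=[False])
        out = simulate_bundles([p], c, EfferentDrive(), fs=FS, duration=10,
                               seed=3, protocol=StimulusProtocol(10, 0, 0))
        x = out.traces[0]
        r = mean_instantaneous_frequency(x, FS)
        zc = zero_crossing_frequency(x, FS)
        assert r.mean_hz == pytest.approx(zc, rel=0.05)

    def test_invariant_under_amplitude_rescaling(self, free_running_cell):
        a = mean_instantaneous_frequency(free_running_cell, FS)
        b = mean_instantaneous_frequency(17.3 * free_running_cell, FS)
        assert a.mean_hz == pytest.approx(b.mean_hz, rel=1e-12)

    def test_short_trace_raises(self):
        with pytest.raises(ValueError):
            mean_instantaneous_frequency(np.sin(np.arange(400) / 10), FS)
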