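"""Input-signal generation: rate programs and Poisson sampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from resonet.rates import (RateProgram, SpikeRaster, background_drive,
                           draw_poisson_spikes, make_rate_program)


class TestRateProgram:
    @pytest.mark.parametrize("f_inp,amp", [(25.0, 4000.0), (20.0, 5000.0)])
    def test_fixed_mean_pulse_amplitude(self, f_inp, amp):
        # amplitude = r_inp / (f_inp * delta_inp) with delta in seconds
        prog = make_rate_program("square_fixed_mean", r_inp=1000.0,
                                 f_inp=f_inp, delta_inp=10.0)
        assert prog.pulse_amplitude == pytest.approx(amp)
        assert prog.values.max() == pytest.approx(amp)

    def test_duty_cycle_one_degenerates_to_constant(self):
        prog = make_rate_program("square_fixed_mean", r_inp=1000.0,
                                 f_inp=50.0, delta_inp=20.0)
        on = prog.times >= prog.onset
        assert np.allclose(prog.values[on], 1000.0)

    def test_duty_cycle_above_one_rejected(self):
        with pytest.raises(ValueError, match="duty cycle"):
            make_rate_program("square_fixed_mean", r_inp=1000.0, f_inp=50.0,
                              delta_inp=25.0)

    @pytest.mark.parametrize("kw", [
        dict(kind="asynchronous", r_inp=-1.0),
        dict(kind="sine", r_inp=100.0, f_inp=0.0),
        dict(kind="square_fixed_amplitude", r_inp=100.0, f_inp=10.0,
             delta_inp=5.0, r_p=-4.0),
        dict(kind="blip", r_inp=1.0),
    ])
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            make_rate_program(**kw)

    def test_sine_formula_extremes(self):
        # lambda(t) = r (1 + sin(2 pi f t)) / 2: crest r_inp, trough 0
        prog = make_rate_program("sine", r_inp=1000.0, f_inp=10.0, dt=0.01)
        assert prog.values.max() == pytest.approx(1000.0, rel=1e-3)
        assert prog.values.min() == pytest.approx(0.0, abs=1e-6)

    def test_sine_mean_matched_average(self):
        prog = make_rate_program("sine", r_inp=1000.0, f_inp=10.0,
                                 duration=1000.0, normalization="mean_matched")
        assert prog.mean_rate() == pytest.approx(1000.0, rel=1e-3)

    def test_onset_gates_the_signal(self):
        prog = make_rate_program("square_fixed_mean", r_inp=1000.0,
                                 f_inp=25.0, delta_inp=10.0, onset=400.0,
                                 duration=1000.0)
        assert np.all(prog.values[prog.times < 400.0] == 0.0)
        # first pulse begins at onset
        i0 = np.searchsorted(prog.times, 400.0)
        assert prog.values[i0] == pytest.approx(prog.pulse_amplitude)

    @given(f_inp=st.sampled_from([10.0, 20.0, 25.0, 40.0]),
           delta=st.sampled_from([1.0, 5.0, 10.0]))
    @settings(deadline=None, max_examples=12, derandomize=True)
    def test_fixed_mean_is_frequency_invariant(self, f_inp, delta):
        # whole-period average equals r_inp regardless of f_inp
        prog = make_rate_program("square_fixed_mean", r_inp=1000.0,
                                 f_inp=f_inp, delta_inp=delta,
                                 duration=round(5000.0 / f_inp / 0.05) * 0.05,
                                 dt=0.05)
        n_per = int(1000.0 / f_inp / 0.05)
        k = (len(prog.values) - 1) // n_per
        lam = prog.values[:k * n_per]
        assert lam.mean() == pytest.approx(1000.0, rel=0.02)

    def test_fixed_amplitude_mean_grows_with_frequency(self):
        means = []
        for f in (10.0, 20.0, 40.0):
            prog = make_rate_program("square_fixed_amplitude", r_inp=1000.0,
                                     f_inp=f, delta_inp=10.0, r_p=4000.0,
                                     duration=1000.0, dt=0.05)
            means.append(prog.mean_rate())
            assert prog.values.max() == pytest.approx(4000.0)
        assert means[0] < means[1] < means[2]
        # mean ~ r_p * f * delta
        assert means[1] == pytest.approx(4000.0 * 20.0 * 0.010, rel=0.05)

    def test_json_roundtrip(self):
        prog = make_rate_program("sine", r_inp=500.0, f_inp=7.0, onset=100.0)
        again = RateProgram.from_json(prog.to_json())
        assert np.allclose(again.values, prog.values)


class TestPoissonSampling:
    def test_zero_rate_gives_empty_raster(self):
        prog = make_rate_program("asynchronous", r_inp=0.0, duration=500.0)
        raster = draw_poisson_spikes(prog, n_sources=3, seed=0)
        assert raster.n_spikes == 0

    def test_seed_determinism(self):
        prog = make_rate_program("asynchronous", r_inp=500.0, duration=500.0)
        a = draw_poisson_spikes(prog, 4, seed=11)
        b = draw_poisson_spikes(prog, 4, seed=11)
        for x, y in zip(a.trains, b.trains):
            assert np.array_equal(x, y)
        c = draw_poisson_spikes(prog, 4, seed=12)
        assert a.n_spikes != c.n_spikes or not all(
            np.array_equal(x, y) for x, y in zip(a.trains, c.trains))

    def test_constant_rate_count_distribution(self):
        # counts over >= 100 seeds agree with the Poisson CDF oracle
        prog = make_rate_program("asynchronous", r_inp=1000.0,
                                 duration=1000.0, dt=0.05)
        counts = [draw_poisson_spikes(prog, 1, seed=s).n_spikes
                  for s in range(120)]
        assert abs(np.mean(counts) - 1000) < 3 * np.sqrt(1000)
        cdf = stats.poisson(1000).cdf
        u = cdf(np.asarray(counts))
        d, p = stats.kstest(u, "uniform")
        assert p > 1e-3

    def test_empirical_rate_tracks_lambda(self):
        # relative error < 5% once >= 1e4 spikes are expected
        prog = make_rate_program("sine", r_inp=2000.0, f_inp=10.0,
                                 duration=5000.0, dt=0.05)
        raster = draw_poisson_spikes(prog, 1, seed=3)
        expected = prog.mean_rate() * 5.0  # spikes over 5 s
        assert abs(raster.n_spikes - expected) / expected < 0.05

    def test_spike_times_strictly_increasing_within_window(self):
        prog = make_rate_program("square_fixed_mean", r_inp=2000.0,
                                 f_inp=20.0, delta_inp=5.0, duration=1000.0)
        raster = draw_poisson_spikes(prog, 5, seed=9)
        for tr in raster.trains:
            assert np.all(np.diff(tr) > 0)
            if len(tr):
                assert tr[0] >= 0 and tr[-1] <= 1000.0


class TestBackgroundDrive:
    def test_expected_total_count(self):
        raster = background_drive(duration=1000.0, seed=21, dt=0.05)
        assert raster.n_sources == 100
        assert abs(raster.n_spikes - 100) < 3 * 10

    def test_zero_cells_empty(self):
        raster = background_drive(duration=500.0, seed=1, n_cells=0)
        assert raster.n_sources == 0 and raster.n_spikes == 0

    def test_superposition_matches_aggregate_process(self):
        # 100 cells at 1 sp/s pooled ~ one source at 100 sp/s
        counts_multi = [background_drive(2000.0, seed=s, dt=0.05).n_spikes
                        for s in range(40)]
        prog = make_rate_program("asynchronous", r_inp=100.0,
                                 duration=2000.0, dt=0.05)
        counts_single = [draw_poisson_spikes(prog, 1, seed=s).n_spikes
                         for s in range(40)]
        t, p = stats.mannwhitneyu(counts_multi, counts_single)
        assert p > 1e-3


class TestSpikeRaster:
    def test_rejects_out_of_window_times(self):
        with pytest.raises(ValueError):
            SpikeRaster(trains=(np.array([10.0, 1500.0]),),
                        window=(0.0, 1000.0))

    def test_csv_roundtrip(self, tmp_path):
        prog = make_rate_program("asynchronous", r_inp=200.0, duration=500.0)
        raster = draw_poisson_spikes(prog, 3, seed=2)
        path = tmp_path / "raster.csv"
        raster.to_csv(path)
        again = SpikeRaster.from_csv(path, window=(0.0, 500.0))
        for x, y in zip(raster.trains, again.trains):
            assert np.allclose(x, y)
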