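"""Network assembly and trial-level contracts."""

import numpy as np
import pytest
from dataclasses import replace

from resonet.network import (NetworkSpec, build_network, competition_network,
                             control_network, lif_network, run_trial,
                             single_pc)
from resonet.rates import draw_poisson_spikes, make_rate_program


class TestAssembly:
    def test_control_synapse_count(self):
        # 20 PC -> 5 IN plus 5 IN -> 20 PC, all-to-all
        assert control_network().n_synapses == 200

    def test_competition_network_shares_the_in_pool(self):
        sim = build_network(competition_network())
        # every IN receives from every PC of both populations...
        assert np.all(sim.W_in_pc > 0)
        # ...and every PC of both populations is inhibited by every IN
        assert np.all(sim.W_pc_in > 0)
        assert sim.W_in_pc.shape == (5, 40)

    def test_lif_preset_sizes(self):
        spec = lif_network()
        assert spec.pc_pops == (25,) and spec.n_in == 5

    def test_per_population_normalization(self):
        sim = build_network(control_network())
        assert np.allclose(sim.W_in_pc, 1.0 / 20)
        assert np.allclose(sim.W_pc_in, 0.1 / 5)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            NetworkSpec(model="izh")
        with pytest.raises(ValueError):
            NetworkSpec(pc_pops=(20, 20))  # names must match


class TestTrials:
    def test_same_seed_bit_identical(self):
        spec = control_network()
        prog = make_rate_program("asynchronous", r_inp=1000.0, onset=200.0,
                                 duration=700.0)
        a = run_trial(spec, [prog], seed=5, duration=700.0, onset=200.0)
        b = run_trial(spec, [prog], seed=5, duration=700.0, onset=200.0)
        for pop in ("PC", "IN"):
            for x, y in zip(a.rasters[pop].trains, b.rasters[pop].trains):
                assert np.array_equal(x, y)
            assert np.array_equal(a.v[pop], b.v[pop])

    def test_different_seeds_distinct(self):
        spec = control_network()
        prog = make_rate_program("asynchronous", r_inp=1000.0, onset=200.0,
                                 duration=700.0)
        a = run_trial(spec, [prog], seed=1, duration=700.0, onset=200.0)
        b = run_trial(spec, [prog], seed=2, duration=700.0, onset=200.0)
        assert not np.array_equal(a.v["PC"], b.v["PC"])

    def test_quiescent_before_onset_without_background(self):
        spec = replace(control_network(), background=False, init_jitter=0.5)
        prog = make_rate_program("asynchronous", r_inp=1500.0, onset=400.0,
                                 duration=900.0)
        res = run_trial(spec, [prog], seed=3, duration=900.0, onset=400.0)
        all_spikes = res.rasters["PC"].all_times()
        assert len(all_spikes) > 0
        assert all_spikes.min() > 400.0

    def test_raster_matches_voltage_threshold_crossings(self):
        spec = control_network()
        prog = make_rate_program("asynchronous", r_inp=1000.0, onset=200.0,
                                 duration=900.0)
        res = run_trial(spec, [prog], seed=4, duration=900.0, onset=200.0)
        v = res.v["PC"]
        for i, train in enumerate(res.rasters["PC"].trains):
            for t in train:
                j = int(round(t / res.v_dt))
                assert v[i, max(0, j - 2):j + 3].max() > -10.0

    def test_analysis_window_excludes_first_500ms_of_response(self):
        spec = control_network()
        prog = make_rate_program("asynchronous", r_inp=800.0, onset=400.0,
                                 duration=1200.0)
        res = run_trial(spec, [prog], seed=1, duration=1200.0, onset=400.0)
        assert res.analysis_window == (900.0, 1200.0)

    def test_raster_input_requires_matching_sources(self):
        spec = control_network()
        prog = make_rate_program("asynchronous", r_inp=500.0, duration=500.0)
        raster = draw_poisson_spikes(prog, 3, seed=1)  # wrong count
        with pytest.raises(ValueError, match="one train per target cell"):
            run_trial(spec, [raster], seed=1, duration=500.0, onset=100.0)

    def test_program_grid_must_match_trial_grid(self):
        spec = control_network()
        prog = make_rate_program("asynchronous", r_inp=500.0, duration=400.0)
        with pytest.raises(ValueError, match="grid"):
            run_trial(spec, [prog], seed=1, duration=700.0, onset=100.0)


class TestOscillation:
    def test_strong_inhibition_produces_volleys_weak_does_not(self):
        """With strong feedback inhibition the PC population emits
        periodic spike volleys separated by silence; removing inhibition
        leaves asynchronous spiking with a much flatter iFR."""
        from resonet.measures import compute_ifr

        prog = make_rate_program("asynchronous", r_inp=1000.0, onset=400.0,
                                 duration=1500.0)
        strong = control_network()
        weak = replace(strong, gaba=replace(strong.gaba, g_syn=0.0))
        gaps = {}
        for label, spec in (("strong", strong), ("weak", weak)):
            res = run_trial(spec, [prog], seed=2, duration=1500.0,
                            onset=400.0)
            tr = compute_ifr(res.rasters["PC"], 20, 2.0,
                             res.analysis_window)
            # fraction of time the population is (nearly) silent: volleys
            # separated by inhibition leave long gaps at zero rate
            gaps[label] = float(np.mean(tr.rate < 0.05 * tr.rate.mean()))
        assert gaps["strong"] > 2.0 * gaps["weak"]
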