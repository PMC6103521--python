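"""Cell and synapse dynamics against closed-form oracles."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from resonet import engine
from resonet.cells import (GABA_IN_TO_PC, INParams, LIFParams, PCParams,
                           H, in_rest_state, in_rhs, pc_rest_state, pc_rhs,
                           syn_current, syn_gate_rhs)
from resonet.network import NetworkSpec, run_trial, single_pc
from resonet.rates import make_rate_program


class TestSynapticGate:
    def test_open_rate_at_zero_mv(self):
        # H(0) = 1, so ds/dt = (1-s)/tau_r = 1/0.4 = 2.5 /ms at s=0
        assert syn_gate_rhs(0.0, 0.0, 0.4, 2.0) == pytest.approx(2.5)

    def test_closed_at_hyperpolarized_presynapse(self):
        # H(-80) ~ 0: pure decay at rate s/tau_d
        s0 = 0.6
        assert syn_gate_rhs(s0, -80.0, 0.4, 2.0) == pytest.approx(
            -s0 / 2.0, rel=1e-6)

    def test_equilibrium_under_sustained_drive(self):
        # ds/dt = 0 at s* = H tau_d / (H tau_d + tau_r); H = 2 when V >> 0
        s_star = 2.0 * 2.0 / (2.0 * 2.0 + 0.4)
        assert syn_gate_rhs(s_star, 100.0, 0.4, 2.0) == pytest.approx(
            0.0, abs=1e-9)
        assert s_star == pytest.approx(4.0 / 4.4)

    @given(st.floats(-100, 60))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_gate_stays_in_unit_interval(self, v_pre):
        # Euler integration from any start stays inside [0, 1)
        s = 0.5
        for _ in range(2000):
            s += 0.01 * syn_gate_rhs(s, v_pre, 0.4, 5.0)
            assert 0.0 <= s < 1.0


class TestSynapticCurrent:
    @pytest.mark.parametrize("s,v,g,e,expected", [
        (0.0, -60.0, 1.0, 0.0, 0.0),
        (0.7, -75.0, 0.1, -75.0, 0.0),          # at reversal potential
        (0.5, -75.0, 1.0, 0.0, -37.5),
    ])
    def test_examples(self, s, v, g, e, expected):
        assert syn_current(s, v, g, e) == pytest.approx(expected)


class TestMembraneEquation:
    def test_all_currents_zero_gives_zero_derivative(self):
        p = PCParams(g_NaF=0, g_KDR=0, g_NaP=0, g_Ks=0, g_Ca=0, g_KCa=0,
                     g_l_soma=0, g_l_dend=0, g_c=0)
        d = pc_rhs(np.array([-65.0, -65.0, 0.5, 0.5, 0.5, 1.0]), p)
        assert d[0] == pytest.approx(0.0) and d[1] == pytest.approx(0.0)

    def test_sign_convention_dv_equals_minus_current(self):
        # C dV/dt = -(I_inp + ...): a positive applied current depolarizes
        p = PCParams(g_NaF=0, g_KDR=0, g_NaP=0, g_Ks=0, g_Ca=0, g_KCa=0,
                     g_l_soma=0, g_l_dend=0, g_c=0)
        d = pc_rhs(np.array([-65.0, -65.0, 0.5, 0.5, 0.5, 1.0]), p,
                   I_app_soma=2.0)
        assert d[0] == pytest.approx(2.0)  # C_m = 1

    def test_passive_relaxation_matches_rc_solution(self):
        # leak-only membrane: V(t) = E_l + (V0-E_l) exp(-t g_l / C)
        p = PCParams(g_NaF=0, g_KDR=0, g_NaP=0, g_Ks=0, g_Ca=0, g_KCa=0,
                     g_l_soma=0.05, g_l_dend=0.05, g_c=0, E_l=-70.0)
        state = np.array([-55.0, -70.0, 0.5, 0.5, 0.5, 1.0])
        dt, T = 0.01, 40.0
        for _ in range(int(T / dt)):
            state = state + dt * pc_rhs(state, p)
        tau = p.C_m / p.g_l_soma
        expected = -70.0 + 15.0 * np.exp(-T / tau)
        assert state[0] == pytest.approx(expected, abs=0.05)

    def test_full_knockout_reduces_to_passive_membrane(self):
        p = PCParams().with_knockout("NaF", "KDR", "NaP", "Ks", "Ca", "KCa")
        passive = PCParams(g_NaF=0, g_KDR=0, g_NaP=0, g_Ks=0, g_Ca=0,
                           g_KCa=0)
        state = np.array([-60.0, -64.0, 0.5, 0.5, 0.5, 1.0])
        assert np.allclose(pc_rhs(state, p)[:2], pc_rhs(state, passive)[:2])

    def test_nonfinite_state_aborts(self):
        with pytest.raises(FloatingPointError):
            pc_rhs(np.array([np.nan, -65, 0.5, 0.5, 0.5, 1.0]), PCParams())

    def test_engine_matches_reference_rhs(self):
        """The numba kernel computes the same derivatives as the
        documented reference implementation."""
        p = PCParams()
        q = INParams()
        rng = np.random.default_rng(0)
        for _ in range(20):
            pc_state = np.array([rng.uniform(-80, 20), rng.uniform(-80, 0),
                                 rng.uniform(0, 1), rng.uniform(0, 1),
                                 rng.uniform(0, 1), rng.uniform(0, 30)])
            in_state = np.array([rng.uniform(-80, 20), rng.uniform(0, 1),
                                 rng.uniform(0, 1)])
            g_exc, g_gaba = rng.uniform(0, 0.05), rng.uniform(0, 0.2)
            y = np.zeros(engine.PC_NSTATE + engine.IN_NSTATE)
            y[:6] = pc_state
            y[6] = 0.3
            y[7:10] = in_state
            y[10] = 0.2
            dy = np.zeros_like(y)
            engine._hh_deriv(
                y, dy, 1, 1, np.tile(p.conductances(), (1, 1)),
                engine.pack_pc_params(p), np.tile(q.conductances(), (1, 1)),
                engine.pack_in_params(q),
                np.zeros((1, 1)), np.full((1, 1), g_gaba / 0.2),
                np.full(1, g_exc), np.zeros(1),
                np.zeros(1), np.zeros(1), np.zeros(1),
                0.4, 2.0, 0.4, 5.0, 0.0, -75.0)
            ref = pc_rhs(pc_state, p, g_exc_dend=g_exc, g_gaba_soma=g_gaba)
            assert np.allclose(dy[:6], ref, rtol=1e-10, atol=1e-10)
            ref_in = in_rhs(in_state, q)
            assert np.allclose(dy[7:10], ref_in, rtol=1e-10, atol=1e-10)


class TestCellPhenotypes:
    def _rates(self, spec_kw, i_app_kw, windows):
        spec = NetworkSpec(background=False, **spec_kw, **i_app_kw)
        res = run_trial(spec, [None] * len(spec.pc_pops), seed=1,
                        duration=900.0, onset=100.0)
        pop = spec.pc_names[0] if spec.n_pc else "IN"
        tr = res.rasters[pop].trains[0]
        return [np.sum((tr >= a) & (tr < b)) / ((b - a) * 1e-3)
                for a, b in windows]

    def test_interneuron_is_fast_spiking_and_non_adapting(self):
        """Sustained tonic drive holds the IN above 100 sp/s with no
        spike-frequency adaptation (the fast-spiking phenotype)."""
        early, late = self._rates(dict(pc_pops=(), pc_names=(), n_in=1),
                                  dict(I_app_in=5.0),
                                  [(150.0, 450.0), (600.0, 900.0)])
        assert early > 100.0
        assert abs(early - late) / early < 0.15

    def test_pc_is_regular_spiking_with_adaptation(self):
        """The PC's slow K currents make its rate adapt downward over
        the first hundreds of milliseconds of tonic dendritic drive."""
        early, late = self._rates(dict(pc_pops=(1,), n_in=0),
                                  dict(I_app_dend=0.3),
                                  [(150.0, 450.0), (600.0, 900.0)])
        assert early > 0.0
        assert late < early

    def test_zero_input_cell_stays_at_rest(self):
        spec = single_pc()
        res = run_trial(spec, [None], seed=1, duration=800.0, onset=100.0)
        assert res.rasters["PC"].n_spikes == 0
        v = res.v["PC"][0]
        assert np.std(v[len(v) // 2:]) < 1.0


class TestLIF:
    def test_reset_and_refractory_clamp(self):
        """Threshold crossing resets the voltage to -65 mV and holds it
        for 3 ms, ignoring inputs."""
        lp = LIFParams()
        spec = NetworkSpec(model="lif", pc_pops=(1,), n_in=0,
                           lif_params=lp, g_inp=0.5, background=False)
        prog = make_rate_program("asynchronous", r_inp=2000.0, onset=50.0,
                                 duration=400.0)
        res = run_trial(spec, [prog], seed=3, duration=400.0, onset=50.0,
                        rec_stride=10)
        train = res.rasters["PC"].trains[0]
        assert len(train) > 0
        v, tv = res.v["PC"][0], res.v_times()
        t0 = train[0]
        clamp = v[(tv > t0 + 0.2) & (tv < t0 + 2.8)]
        assert np.allclose(clamp, lp.V_reset, atol=1e-6)
        # refractory: no spikes closer than t_ref
        if len(train) > 1:
            assert np.diff(train).min() >= lp.t_ref - 1e-9

    def test_leak_decay_toward_rest(self):
        lp = LIFParams()
        spec = NetworkSpec(model="lif", pc_pops=(1,), n_in=0,
                           lif_params=lp, background=False, init_jitter=0.0)
        res = run_trial(spec, [None], seed=1, duration=300.0, onset=50.0)
        v = res.v["PC"][0]
        assert abs(v[-1] - lp.E_l) < 0.5

    def test_invalid_threshold_ordering_rejected(self):
        with pytest.raises(ValueError):
            LIFParams(V_thresh=-70.0)


class TestKnockoutMask:
    def test_knockout_zeroes_only_that_conductance(self):
        p = PCParams().with_knockout("Ks")
        g = p.conductances()
        base = PCParams().conductances()
        assert g[3] == 0.0
        mask = np.ones(6, dtype=bool)
        mask[3] = False
        assert np.allclose(g[mask], base[mask])

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValueError, match="unknown PC channel"):
            PCParams(knockout=("HCN",))
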