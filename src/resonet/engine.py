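"""Fixed-step integration kernels.

The Hodgkin-Huxley network is integrated with a classical 4th-order
Runge-Kutta scheme at a fixed step (default 0.01 ms).  Exogenous Poisson
input is pre-integrated into synaptic-gate conductance traces on the
same grid before the loop (the drive is exogenous, so this keeps the ODE
system autonomous within each step); stage values at half steps use the
midpoint of adjacent grid samples.

The leaky integrate-and-fire variant uses a grid-aligned event update in
the same kind of loop: forward integration of the linear subthreshold
dynamics with exact exponential decay of the double-exponential synaptic
gates, threshold/reset/refractory handling at grid points.

State packing for the HH kernel: each PC occupies 7 slots
(Vs, Vd, h, n, w, ca, s_out) and each IN 4 slots (V, h, n, s_out) in a
flat vector; PCs first.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.signal import lfilter

PC_NSTATE = 7
IN_NSTATE = 4

# pcp parameter-vector layout (see cells.PCParams)
# 0 C_m, 1 E_Na, 2 E_K, 3 E_Ca, 4 E_l, 5 gl_s, 6 gl_d, 7 g_c, 8 kappa,
# 9 tau_Ks, 10 ks_vhalf, 11 ks_slope, 12 nap_vhalf, 13 nap_slope,
# 14 ca_vhalf, 15 ca_slope, 16 kca_kd, 17 ca_gain, 18 tau_Ca, 19 ca_spike,
# 20 h_phi
# inp layout: 0 C_m, 1 E_Na, 2 E_K, 3 E_l, 4 g_l, 5 phi


def pack_pc_params(p) -> np.ndarray:
    return np.array([p.C_m, p.E_Na, p.E_K, p.E_Ca, p.E_l, p.g_l_soma,
                     p.g_l_dend, p.g_c, p.kappa, p.tau_Ks, p.ks_vhalf,
                     p.ks_slope, p.nap_vhalf, p.nap_slope, p.ca_vhalf,
                     p.ca_slope, p.kca_kd, p.ca_gain, p.tau_Ca, p.ca_spike,
                     p.h_phi])


def pack_in_params(p) -> np.ndarray:
    return np.array([p.C_m, p.E_Na, p.E_K, p.E_l, p.g_l, p.phi])


def double_exp_traces(counts: np.ndarray, tau_r: float, tau_d: float,
                      dt: float) -> np.ndarray:
    """Unit-peak double-exponential filtering of binned spike counts.

    ``counts`` has shape (n_sources, n_bins); returns gate traces of the
    same shape.  Each spike contributes
    ``(exp(-t/tau_d) - exp(-t/tau_r)) / peak`` so a single spike drives
    the gate to a maximum of exactly 1.
    """
    counts = np.atleast_2d(counts)
    dr = np.exp(-dt / tau_r)
    dd = np.exp(-dt / tau_d)
    # peak of the continuous kernel, used for unit normalization
    tpk = (tau_d * tau_r / (tau_d - tau_r)) * np.log(tau_d / tau_r)
    peak = np.exp(-tpk / tau_d) - np.exp(-tpk / tau_r)
    a = lfilter([1.0], [1.0, -dr], counts, axis=-1)
    b = lfilter([1.0], [1.0, -dd], counts, axis=-1)
    return (b - a) / peak


def bin_spike_counts(raster, dt: float, n_bins: int) -> np.ndarray:
    """Bin a SpikeRaster's trains onto the simulation grid."""
    out = np.zeros((raster.n_sources, n_bins))
    for i, tr in enumerate(raster.trains):
        if len(tr) == 0:
            continue
        idx = np.minimum((np.asarray(tr) / dt).astype(np.int64), n_bins - 1)
        np.add.at(out[i], idx, 1.0)
    return out


@njit(cache=True, fastmath=True)
def _hh_deriv(y, dy, n_pc, n_in, pc_g, pcp, in_g, inp,
              W_in_pc, W_pc_in, gexc_pc, gexc_in,
              iapp_pc_s, iapp_pc_d, iapp_in,
              tr_ampa, td_ampa, tr_gaba, td_gaba, E_ampa, E_gaba):
    # population-summed synaptic conductances
    off_in = n_pc * PC_NSTATE
    # GABA conductance onto each PC soma
    for i in range(n_pc):
        g_gaba = 0.0
        for j in range(n_in):
            g_gaba += W_pc_in[i, j] * y[off_in + j * IN_NSTATE + 3]
        b = i * PC_NSTATE
        Vs = y[b]
        Vd = y[b + 1]
        h = y[b + 2]
        n = y[b + 3]
        w = y[b + 4]
        ca = y[b + 5]
        s = y[b + 6]

        # soma: NaF (m instantaneous), KDR, Ks, Ca, KCa, leak, coupling, GABA
        x = Vs + 54.0
        am = 0.32 * (x / (1.0 - np.exp(-x / 4.0))) if abs(x) > 1e-6 else 0.32 * 4.0
        x = -(Vs + 27.0)
        bm = 0.28 * (x / (1.0 - np.exp(-x / 5.0))) if abs(x) > 1e-6 else 0.28 * 5.0
        minf = am / (am + bm)
        I_NaF = pc_g[i, 0] * minf * minf * minf * h * (Vs - pcp[1])
        I_KDR = pc_g[i, 1] * n * n * n * n * (Vs - pcp[2])
        I_Ks = pc_g[i, 3] * w * (Vs - pcp[2])
        cinf = 1.0 / (1.0 + np.exp(-(Vs - pcp[14]) / pcp[15]))
        I_Ca = pc_g[i, 4] * cinf * cinf * (Vs - pcp[3])
        I_KCa = pc_g[i, 5] * (ca / (ca + pcp[16])) * (Vs - pcp[2])
        I_ls = pcp[5] * (Vs - pcp[4])
        I_cs = pcp[7] * (Vs - Vd)
        I_gaba = g_gaba * (Vs - E_gaba)

        # dendrite: NaP, leak, coupling, external input
        pinf = 1.0 / (1.0 + np.exp(-(Vd - pcp[12]) / pcp[13]))
        I_NaP = pc_g[i, 2] * pinf * (Vd - pcp[1])
        I_ld = pcp[6] * (Vd - pcp[4])
        I_cd = pcp[7] * pcp[8] * (Vd - Vs)
        I_inp = gexc_pc[i] * (Vd - E_ampa)

        dy[b] = (-(I_NaF + I_KDR + I_Ks + I_Ca + I_KCa + I_ls + I_cs + I_gaba)
                 + iapp_pc_s[i]) / pcp[0]
        dy[b + 1] = (-(I_NaP + I_ld + I_cd + I_inp) + iapp_pc_d[i]) / pcp[0]
        ah = 0.128 * np.exp(-(Vs + 50.0) / 18.0)
        bh = 4.0 / (1.0 + np.exp(-(Vs + 27.0) / 5.0))
        dy[b + 2] = pcp[20] * (ah * (1.0 - h) - bh * h)
        x = Vs + 52.0
        an = 0.032 * (x / (1.0 - np.exp(-x / 5.0))) if abs(x) > 1e-6 else 0.032 * 5.0
        bn = 0.5 * np.exp(-(Vs + 57.0) / 40.0)
        dy[b + 3] = an * (1.0 - n) - bn * n
        winf = 1.0 / (1.0 + np.exp(-(Vs - pcp[10]) / pcp[11]))
        dy[b + 4] = (winf - w) / pcp[9]
        dy[b + 5] = -pcp[17] * I_Ca - ca / pcp[18]
        Hs = 1.0 + np.tanh(Vs / 4.0)
        dy[b + 6] = Hs * (1.0 - s) / tr_ampa - s / td_ampa

    for j in range(n_in):
        g_ampa = 0.0
        for i in range(n_pc):
            g_ampa += W_in_pc[j, i] * y[i * PC_NSTATE + 6]
        b = off_in + j * IN_NSTATE
        V = y[b]
        h = y[b + 1]
        n = y[b + 2]
        s = y[b + 3]
        phi = inp[5]
        x = V + 35.0
        am = 0.1 * (x / (1.0 - np.exp(-x / 10.0))) if abs(x) > 1e-6 else 0.1 * 10.0
        bm = 4.0 * np.exp(-(V + 60.0) / 18.0)
        minf = am / (am + bm)
        I_NaF = in_g[j, 0] * minf * minf * minf * h * (V - inp[1])
        I_KDR = in_g[j, 1] * n * n * n * n * (V - inp[2])
        I_l = inp[4] * (V - inp[3])
        I_exc = (g_ampa + gexc_in[j]) * (V - E_ampa)
        dy[b] = (-(I_NaF + I_KDR + I_l + I_exc) + iapp_in[j]) / inp[0]
        ah = phi * 0.07 * np.exp(-(V + 58.0) / 20.0)
        bh = phi / (1.0 + np.exp(-(V + 28.0) / 10.0))
        dy[b + 1] = ah * (1.0 - h) - bh * h
        x = V + 34.0
        an = (phi * 0.01 * (x / (1.0 - np.exp(-x / 10.0)))
              if abs(x) > 1e-6 else phi * 0.01 * 10.0)
        bn = phi * 0.125 * np.exp(-(V + 44.0) / 80.0)
        dy[b + 2] = an * (1.0 - n) - bn * n
        Hv = 1.0 + np.tanh(V / 4.0)
        dy[b + 3] = Hv * (1.0 - s) / tr_gaba - s / td_gaba


@njit(cache=True, fastmath=True)
def run_hh(y0, dt, n_steps, n_pc, n_in, pc_g, pcp, in_g, inp,
           W_in_pc, W_pc_in, gexc_pc, gexc_in,
           iapp_pc_s, iapp_pc_d, iapp_in,
           tr_ampa, td_ampa, tr_gaba, td_gaba, E_ampa, E_gaba,
           rec_stride, spike_cap):
    """RK4 integration of the PC/IN network.

    Returns (spike_times, spike_counts, v_rec, status) where status is
    0 = ok, 1 = divergence (|V| > 200 mV), 2 = spike capacity exceeded.
    Spike detection: upward crossing of 0 mV at the soma with a 2 ms
    minimum inter-detection interval.
    """
    nstate = y0.shape[0]
    y = y0.copy()
    k1 = np.empty(nstate)
    k2 = np.empty(nstate)
    k3 = np.empty(nstate)
    k4 = np.empty(nstate)
    yt = np.empty(nstate)
    n_cells = n_pc + n_in
    spikes = np.zeros((n_cells, spike_cap))
    counts = np.zeros(n_cells, dtype=np.int64)
    last_spike = np.full(n_cells, -1e9)
    n_rec = n_steps // rec_stride + 1
    v_rec = np.zeros((n_cells, n_rec))
    g_half_pc = np.empty(n_pc)
    g_half_in = np.empty(n_in)
    off_in = n_pc * PC_NSTATE
    status = 0

    for i in range(n_pc):
        v_rec[i, 0] = y[i * PC_NSTATE]
    for j in range(n_in):
        v_rec[n_pc + j, 0] = y[off_in + j * IN_NSTATE]

    for k in range(n_steps):
        for i in range(n_pc):
            g_half_pc[i] = 0.5 * (gexc_pc[i, k] + gexc_pc[i, k + 1])
        for j in range(n_in):
            g_half_in[j] = 0.5 * (gexc_in[j, k] + gexc_in[j, k + 1])

        _hh_deriv(y, k1, n_pc, n_in, pc_g, pcp, in_g, inp, W_in_pc, W_pc_in,
                  gexc_pc[:, k], gexc_in[:, k], iapp_pc_s, iapp_pc_d, iapp_in,
                  tr_ampa, td_ampa, tr_gaba, td_gaba, E_ampa, E_gaba)
        for m in range(nstate):
            yt[m] = y[m] + 0.5 * dt * k1[m]
        _hh_deriv(yt, k2, n_pc, n_in, pc_g, pcp, in_g, inp, W_in_pc, W_pc_in,
                  g_half_pc, g_half_in, iapp_pc_s, iapp_pc_d, iapp_in,
                  tr_ampa, td_ampa, tr_gaba, td_gaba, E_ampa, E_gaba)
        for m in range(nstate):
            yt[m] = y[m] + 0.5 * dt * k2[m]
        _hh_deriv(yt, k3, n_pc, n_in, pc_g, pcp, in_g, inp, W_in_pc, W_pc_in,
                  g_half_pc, g_half_in, iapp_pc_s, iapp_pc_d, iapp_in,
                  tr_ampa, td_ampa, tr_gaba, td_gaba, E_ampa, E_gaba)
        for m in range(nstate):
            yt[m] = y[m] + dt * k3[m]
        _hh_deriv(yt, k4, n_pc, n_in, pc_g, pcp, in_g, inp, W_in_pc, W_pc_in,
                  gexc_pc[:, k + 1], gexc_in[:, k + 1], iapp_pc_s, iapp_pc_d,
                  iapp_in, tr_ampa, td_ampa, tr_gaba, td_gaba, E_ampa, E_gaba)

        t_next = (k + 1) * dt
        for i in range(n_pc):
            b = i * PC_NSTATE
            v_prev = y[b]
            for m in range(PC_NSTATE):
                y[b + m] += dt / 6.0 * (k1[b + m] + 2.0 * k2[b + m]
                                        + 2.0 * k3[b + m] + k4[b + m])
            v_new = y[b]
            if v_prev < 0.0 and v_new >= 0.0 and t_next - last_spike[i] >= 2.0:
                if counts[i] >= spike_cap:
                    status = 2
                else:
                    spikes[i, counts[i]] = t_next
                    counts[i] += 1
                    last_spike[i] = t_next
                    y[b + 5] += pcp[19]  # per-spike calcium influx
            if abs(v_new) > 200.0 or abs(y[b + 1]) > 200.0:
                status = 1
        for j in range(n_in):
            b = off_in + j * IN_NSTATE
            v_prev = y[b]
            for m in range(IN_NSTATE):
                y[b + m] += dt / 6.0 * (k1[b + m] + 2.0 * k2[b + m]
                                        + 2.0 * k3[b + m] + k4[b + m])
            v_new = y[b]
            c = n_pc + j
            if v_prev < 0.0 and v_new >= 0.0 and t_next - last_spike[c] >= 2.0:
                if counts[c] >= spike_cap:
                    status = 2
                else:
                    spikes[c, counts[c]] = t_next
                    counts[c] += 1
                    last_spike[c] = t_next
            if abs(v_new) > 200.0:
                status = 1
        if status == 1:
            break
        if (k + 1) % rec_stride == 0:
            r = (k + 1) // rec_stride
            for i in range(n_pc):
                v_rec[i, r] = y[i * PC_NSTATE]
            for j in range(n_in):
                v_rec[n_pc + j, r] = y[off_in + j * IN_NSTATE]

    return spikes, counts, v_rec, status


@njit(cache=True, fastmath=True)
def run_lif(dt, n_steps, n_pc, n_in,
            g_l, E_l, V_thresh, V_reset, t_ref,
            W_in_pc, W_pc_in,
            tr_on_in, td_on_in, tr_on_pc, td_on_pc,
            E_syn_in, E_syn_pc,
            gexc_pc, gexc_in, V0,
            rec_stride, spike_cap):
    """Grid-aligned leaky integrate-and-fire network loop.

    Synaptic conductances are unit-peak double exponentials updated with
    exact per-step decay; the membrane equation is advanced with an
    explicit step at the integration dt.  On threshold crossing the cell
    spikes, is reset, and is clamped (inputs ignored) for ``t_ref`` ms.
    """
    n_cells = n_pc + n_in
    V = V0.copy()
    refrac = np.zeros(n_cells)
    # output gates: PCs drive synapses onto INs, INs drive synapses onto PCs
    a_pc = np.zeros(n_pc)
    b_pc = np.zeros(n_pc)
    a_in = np.zeros(n_in)
    b_in = np.zeros(n_in)
    dr_pc = np.exp(-dt / tr_on_in)
    dd_pc = np.exp(-dt / td_on_in)
    tpk = (td_on_in * tr_on_in / (td_on_in - tr_on_in)) * np.log(td_on_in / tr_on_in)
    peak_pc = np.exp(-tpk / td_on_in) - np.exp(-tpk / tr_on_in)
    dr_in = np.exp(-dt / tr_on_pc)
    dd_in = np.exp(-dt / td_on_pc)
    tpk = (td_on_pc * tr_on_pc / (td_on_pc - tr_on_pc)) * np.log(td_on_pc / tr_on_pc)
    peak_in = np.exp(-tpk / td_on_pc) - np.exp(-tpk / tr_on_pc)

    spikes = np.zeros((n_cells, spike_cap))
    counts = np.zeros(n_cells, dtype=np.int64)
    n_rec = n_steps // rec_stride + 1
    v_rec = np.zeros((n_cells, n_rec))
    for c in range(n_cells):
        v_rec[c, 0] = V[c]
    status = 0

    for k in range(n_steps):
        t_next = (k + 1) * dt
        # PC update
        for i in range(n_pc):
            if refrac[i] > 0.0:
                refrac[i] -= dt
                V[i] = V_reset
                continue
            g_syn = 0.0
            for j in range(n_in):
                g_syn += W_pc_in[i, j] * (b_in[j] - a_in[j]) / peak_in
            dV = (-gexc_pc[i, k] * V[i] - g_l * (V[i] - E_l)
                  - g_syn * (V[i] - E_syn_pc))
            V[i] += dt * dV
        # IN update
        for j in range(n_in):
            c = n_pc + j
            if refrac[c] > 0.0:
                refrac[c] -= dt
                V[c] = V_reset
                continue
            g_syn = 0.0
            for i in range(n_pc):
                g_syn += W_in_pc[j, i] * (b_pc[i] - a_pc[i]) / peak_pc
            dV = (-gexc_in[j, k] * V[c] - g_l * (V[c] - E_l)
                  - g_syn * (V[c] - E_syn_in))
            V[c] += dt * dV
        # decay gates, then add impulses from this step's spikes
        for i in range(n_pc):
            a_pc[i] *= dr_pc
            b_pc[i] *= dd_pc
        for j in range(n_in):
            a_in[j] *= dr_in
            b_in[j] *= dd_in
        for c in range(n_cells):
            if refrac[c] <= 0.0 and V[c] >= V_thresh:
                if counts[c] >= spike_cap:
                    status = 2
                else:
                    spikes[c, counts[c]] = t_next
                    counts[c] += 1
                V[c] = V_reset
                refrac[c] = t_ref
                if c < n_pc:
                    a_pc[c] += 1.0
                    b_pc[c] += 1.0
                else:
                    a_in[c - n_pc] += 1.0
                    b_in[c - n_pc] += 1.0
        if (k + 1) % rec_stride == 0:
            r = (k + 1) // rec_stride
            for c in range(n_cells):
                v_rec[c, r] = V[c]

    return spikes, counts, v_rec, status
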