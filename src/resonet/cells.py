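"""Cell and synapse dynamics.

Two cell models are provided:

* a two-compartment (soma + dendrite) Hodgkin-Huxley-type principal cell
  (PC) carrying fast spike-generating currents (NaF, KDR) and slow
  modulatory currents (NaP, Ks, Ca, KCa) in the style of deep-layer
  prefrontal pyramidal cells -- regular spiking, ~2 Hz subthreshold
  resonance from the interplay of the slow K currents and the persistent
  sodium current;
* a single-compartment fast-spiking interneuron (IN) with NaF/KDR
  kinetics that are faster and more hyperpolarized than the PC's, giving
  a much higher maximal firing rate.

Kinetic parameter sets live in a named registry (``KINETICS``) so they
can be swapped wholesale; the defaults are calibrated against the
qualitative behaviour the study requires (regular-spiking PC with
delta-band subthreshold resonance, fast-spiking IN) rather than any one
published constant set.

Synapses follow first-order kinetics
``ds/dt = H(V_pre) (1 - s)/tau_r - s/tau_d`` with
``H(V) = 1 + tanh(V/4)``, and currents ``I = g s (V_post - E)``.

Units: mV, ms, mS/cm^2, uA/cm^2, uM (calcium).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Tuple

import numpy as np

__all__ = [
    "H",
    "syn_gate_rhs",
    "syn_current",
    "SynapseParams",
    "PCParams",
    "INParams",
    "LIFParams",
    "KINETICS",
    "AMPA_PC_TO_IN",
    "GABA_IN_TO_PC",
    "pc_rhs",
    "in_rhs",
    "pc_rest_state",
    "in_rest_state",
    "PC_CHANNELS",
    "IN_CHANNELS",
]

# Channel key used for knockouts (NaF = fast sodium, KDR = delayed
# rectifier K, NaP = persistent sodium, Ks = slow M-type K, Ca =
# high-threshold calcium, KCa = calcium-dependent K).
PC_CHANNELS = ("NaF", "KDR", "NaP", "Ks", "Ca", "KCa")
IN_CHANNELS = ("NaF", "KDR")


def H(V):
    """Sigmoidal approximation to the Heaviside function, H(V) = 1 + tanh(V/4)."""
    return 1.0 + np.tanh(V / 4.0)


def syn_gate_rhs(s, V_pre, tau_r, tau_d):
    """First-order synaptic gating kinetics ds/dt."""
    return H(V_pre) * (1.0 - s) / tau_r - s / tau_d


def syn_current(s, V_post, g_syn, E_syn):
    """Postsynaptic current g * s * (V - E) in uA/cm^2."""
    return g_syn * s * (V_post - E_syn)


@dataclass(frozen=True)
class SynapseParams:
    g_syn: float          # maximal conductance, mS/cm^2 (normalized per source)
    E_syn: float          # reversal potential, mV
    tau_r: float = 0.4    # rise time constant, ms
    tau_d: float = 2.0    # decay time constant, ms

    def __post_init__(self):
        if self.tau_r <= 0 or self.tau_d <= 0:
            raise ValueError("synaptic time constants must be positive")
        if self.g_syn < 0:
            raise ValueError("synaptic conductance must be >= 0")


# The two network synapse classes: fast AMPA excitation of INs and
# strong, slower GABA_A feedback inhibition onto PC somata.
AMPA_PC_TO_IN = SynapseParams(g_syn=1.0, E_syn=0.0, tau_r=0.4, tau_d=2.0)
GABA_IN_TO_PC = SynapseParams(g_syn=0.1, E_syn=-75.0, tau_r=0.4, tau_d=5.0)


# -- rate functions (vtrap-safe) ---------------------------------------------

def _vtrap(x, y):
    """x / (1 - exp(-x/y)), stable near x = 0."""
    x = np.asarray(x, dtype=float)
    out = np.where(np.abs(x / y) < 1e-6, y * (1.0 + x / (2.0 * y)),
                   x / (1.0 - np.exp(-np.clip(x / y, -500, 500))))
    return out


# PC fast sodium / delayed rectifier (Traub-Miles-style kinetics)

def pc_am(V):
    return 0.32 * _vtrap(V + 54.0, 4.0)


def pc_bm(V):
    return 0.28 * _vtrap(-(V + 27.0), 5.0)


def pc_ah(V):
    return 0.128 * np.exp(-np.clip((V + 50.0) / 18.0, -500, 500))


def pc_bh(V):
    return 4.0 / (1.0 + np.exp(-np.clip((V + 27.0) / 5.0, -500, 500)))


def pc_an(V):
    return 0.032 * _vtrap(V + 52.0, 5.0)


def pc_bn(V):
    return 0.5 * np.exp(-np.clip((V + 57.0) / 40.0, -500, 500))


# IN fast-spiking kinetics (Wang-Buzsaki-style, temperature factor phi)

def in_am(V):
    return 0.1 * _vtrap(V + 35.0, 10.0)


def in_bm(V):
    return 4.0 * np.exp(-(V + 60.0) / 18.0)


def in_ah(V, phi=5.0):
    return phi * 0.07 * np.exp(-(V + 58.0) / 20.0)


def in_bh(V, phi=5.0):
    return phi / (1.0 + np.exp(-(V + 28.0) / 10.0))


def in_an(V, phi=5.0):
    return phi * 0.01 * _vtrap(V + 34.0, 10.0)


def in_bn(V, phi=5.0):
    return phi * 0.125 * np.exp(-(V + 44.0) / 80.0)


@dataclass(frozen=True)
class PCParams:
    """Two-compartment principal cell.

    The dendrite carries the input synapses and the persistent-sodium
    amplifier; the soma carries the spike-generating currents (NaF,
    KDR), the slow M-type K current, the high-threshold Ca current that
    boosts the final approach to spike threshold, and the Ca-gated K
    afterhyperpolarization current fed by per-spike calcium influx.
    Conductances are per unit membrane area of the respective
    compartment; ``kappa`` is the soma/dendrite area ratio entering the
    coupling current seen by the dendrite.
    """

    C_m: float = 1.0
    E_Na: float = 55.0
    E_K: float = -80.0
    E_Ca: float = 120.0
    E_l: float = -72.0
    g_l_soma: float = 0.012
    g_l_dend: float = 0.012
    g_c: float = 0.2          # soma-dendrite coupling, mS/cm^2
    kappa: float = 1.0        # soma/dendrite area ratio
    g_NaF: float = 100.0
    g_KDR: float = 80.0
    h_phi: float = 2.0        # rate factor on NaF inactivation kinetics
    g_Ks: float = 0.06        # slow M-type K (soma)
    tau_Ks: float = 300.0     # ms, weakly V-dependent in vivo; constant here
    ks_vhalf: float = -68.0
    ks_slope: float = 5.0
    g_NaP: float = 0.015      # persistent sodium (dendrite)
    nap_vhalf: float = -50.0
    nap_slope: float = 5.0
    g_Ca: float = 0.0096      # high-threshold Ca, near-saturated at rest
    ca_vhalf: float = -76.0
    ca_slope: float = 5.0
    g_KCa: float = 0.15       # Ca-dependent K (soma)
    kca_kd: float = 10.0      # uM half-activation of KCa
    ca_gain: float = 0.1      # uM cm^2 / (ms uA): Ca influx per unit I_Ca
    ca_spike: float = 0.0     # uM per-spike calcium increment (AP influx)
    tau_Ca: float = 60.0      # ms, calcium clearance
    knockout: Tuple[str, ...] = ()

    def __post_init__(self):
        for name in self.knockout:
            if name not in PC_CHANNELS:
                raise ValueError(f"unknown PC channel {name!r}; "
                                 f"expected one of {PC_CHANNELS}")

    def conductances(self) -> np.ndarray:
        """(g_NaF, g_KDR, g_NaP, g_Ks, g_Ca, g_KCa) with knockouts zeroed."""
        g = {"NaF": self.g_NaF, "KDR": self.g_KDR, "NaP": self.g_NaP,
             "Ks": self.g_Ks, "Ca": self.g_Ca, "KCa": self.g_KCa}
        for name in self.knockout:
            g[name] = 0.0
        return np.array([g[c] for c in ("NaF", "KDR", "NaP", "Ks", "Ca", "KCa")])

    def with_knockout(self, *names: str) -> "PCParams":
        return replace(self, knockout=tuple(names))


@dataclass(frozen=True)
class INParams:
    """Single-compartment fast-spiking interneuron."""

    C_m: float = 1.6
    E_Na: float = 55.0
    E_K: float = -90.0
    E_l: float = -65.0
    g_l: float = 0.25
    g_NaF: float = 35.0
    g_KDR: float = 9.0
    phi: float = 5.0
    knockout: Tuple[str, ...] = ()

    def __post_init__(self):
        for name in self.knockout:
            if name not in IN_CHANNELS:
                raise ValueError(f"unknown IN channel {name!r}")

    def conductances(self) -> np.ndarray:
        g = {"NaF": self.g_NaF, "KDR": self.g_KDR}
        for name in self.knockout:
            g[name] = 0.0
        return np.array([g["NaF"], g["KDR"]])


@dataclass(frozen=True)
class LIFParams:
    """Leaky integrate-and-fire variant (control model).

    Voltage is reset and clamped at ``V_reset`` for ``t_ref`` ms after
    reaching ``V_thresh``; synaptic conductances are unit-peak double
    exponentials.  Because all excitatory reversal potentials are 0 mV,
    a conductance-driven cell asymptotes below 0 mV; the spike-initiation
    threshold therefore sits near -57 mV (configurable).
    """

    g_l: float = 0.1
    E_l: float = -65.0
    V_thresh: float = -57.0
    V_reset: float = -65.0
    t_ref: float = 3.0
    # synapses onto PCs (inhibitory) and onto INs (excitatory)
    g_syn_pc: float = 0.1
    E_syn_pc: float = -80.0
    tau_d_pc: float = 2.0
    tau_r_pc: float = 0.4
    g_syn_in: float = 0.03
    E_syn_in: float = 0.0
    tau_d_in: float = 10.0
    tau_r_in: float = 0.2
    g_inp: float = 0.00375
    g_noise: float = 0.0056

    def __post_init__(self):
        if not (self.V_reset <= self.E_l < self.V_thresh):
            raise ValueError("require V_reset <= E_l < V_thresh")


#: Named, swappable kinetic parameter sets.
KINETICS: Dict[str, dict] = {
    "pfc_deep_default": {"pc": PCParams(), "in": INParams(), "lif": LIFParams()},
}


# -- reference right-hand sides (used by tests and as documentation of the
#    model; the numba engine implements the same equations) -----------------

def pc_rhs(state, p: PCParams, g_exc_dend=0.0, g_gaba_soma=0.0,
           I_app_soma=0.0, I_app_dend=0.0, E_exc=0.0, E_gaba=-75.0):
    """Time derivative of the PC state.

    ``state`` is (Vs, Vd, h, n, w, ca).  Fast activation gates (NaF m,
    NaP p, Ca c) are taken at their voltage-dependent steady states.
    Returns the 6-vector of derivatives.
    """
    Vs, Vd, h, n, w, ca = state
    if not np.all(np.isfinite(state)):
        raise FloatingPointError("non-finite PC state")
    gNaF, gKDR, gNaP, gKs, gCa, gKCa = p.conductances()

    am, bm = pc_am(Vs), pc_bm(Vs)
    minf = am / (am + bm)
    I_NaF = gNaF * minf ** 3 * h * (Vs - p.E_Na)
    I_KDR = gKDR * n ** 4 * (Vs - p.E_K)
    winf = 1.0 / (1.0 + np.exp(-(Vs - p.ks_vhalf) / p.ks_slope))
    I_Ks = gKs * w * (Vs - p.E_K)
    cinf = 1.0 / (1.0 + np.exp(-(Vs - p.ca_vhalf) / p.ca_slope))
    I_Ca = gCa * cinf ** 2 * (Vs - p.E_Ca)
    I_KCa = gKCa * (ca / (ca + p.kca_kd)) * (Vs - p.E_K)
    I_l_s = p.g_l_soma * (Vs - p.E_l)
    I_c_s = p.g_c * (Vs - Vd)
    I_gaba = g_gaba_soma * (Vs - E_gaba)

    pinf = 1.0 / (1.0 + np.exp(-(Vd - p.nap_vhalf) / p.nap_slope))
    I_NaP = gNaP * pinf * (Vd - p.E_Na)
    I_l_d = p.g_l_dend * (Vd - p.E_l)
    I_c_d = p.g_c * p.kappa * (Vd - Vs)
    I_inp = g_exc_dend * (Vd - E_exc)

    dVs = (-(I_NaF + I_KDR + I_Ks + I_Ca + I_KCa + I_l_s + I_c_s + I_gaba)
           + I_app_soma) / p.C_m
    dVd = (-(I_NaP + I_l_d + I_c_d + I_inp) + I_app_dend) / p.C_m
    dh = p.h_phi * (pc_ah(Vs) * (1.0 - h) - pc_bh(Vs) * h)
    dn = pc_an(Vs) * (1.0 - n) - pc_bn(Vs) * n
    dw = (winf - w) / p.tau_Ks
    dca = -p.ca_gain * I_Ca - ca / p.tau_Ca
    return np.array([dVs, dVd, dh, dn, dw, dca])


def in_rhs(state, p: INParams, g_exc=0.0, I_app=0.0, E_exc=0.0):
    """Time derivative of the IN state (V, h, n)."""
    V, h, n = state
    if not np.all(np.isfinite(state)):
        raise FloatingPointError("non-finite IN state")
    gNaF, gKDR = p.conductances()
    am, bm = in_am(V), in_bm(V)
    minf = am / (am + bm)
    I_NaF = gNaF * minf ** 3 * h * (V - p.E_Na)
    I_KDR = gKDR * n ** 4 * (V - p.E_K)
    I_l = p.g_l * (V - p.E_l)
    I_exc = g_exc * (V - E_exc)
    dV = (-(I_NaF + I_KDR + I_l + I_exc) + I_app) / p.C_m
    dh = in_ah(V, p.phi) * (1.0 - h) - in_bh(V, p.phi) * h
    dn = in_an(V, p.phi) * (1.0 - n) - in_bn(V, p.phi) * n
    return np.array([dV, dh, dn])


def _pc_slow_steady(p: PCParams, V: float):
    """Steady-state values of the slow variables (Ks gate, Ca pool)."""
    w = 1.0 / (1.0 + np.exp(-(V - p.ks_vhalf) / p.ks_slope))
    gCa = 0.0 if "Ca" in p.knockout else p.g_Ca
    cinf = 1.0 / (1.0 + np.exp(-(V - p.ca_vhalf) / p.ca_slope))
    i_ca = gCa * cinf ** 2 * (V - p.E_Ca)
    ca = max(-p.ca_gain * i_ca * p.tau_Ca, 0.0)
    return float(w), float(ca)


def pc_equilibrium_v(p: PCParams, lo: float = -90.0, hi: float = -58.0
                     ) -> float:
    """Resting potential: zero of the steady-state current-voltage curve
    with both compartments at a common voltage and every gate (and the
    calcium pool) at its steady state."""
    def i_ss(V):
        st = np.array([V, V, pc_ah(V) / (pc_ah(V) + pc_bh(V)),
                       pc_an(V) / (pc_an(V) + pc_bn(V)),
                       *_pc_slow_steady(p, V)])
        d = pc_rhs(st, p)
        return d[0] + d[1]          # net depolarizing drive, both compartments

    if i_ss(lo) <= 0:
        return lo
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if i_ss(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def pc_rest_state(p: PCParams, V0: float = None) -> np.ndarray:
    """Resting state for trial initialization.

    The fast gates follow the (possibly jittered) starting voltage
    ``V0``; the slow variables (Ks gate, calcium pool) are set at the
    steady state of the cell's true resting potential -- initializing
    them at a jittered voltage puts the cell off its slow manifold and
    fires spurious startup spikes over the slow time constants.
    """
    V_eq = pc_equilibrium_v(p)
    V = V_eq if V0 is None else V0
    h = pc_ah(V) / (pc_ah(V) + pc_bh(V))
    n = pc_an(V) / (pc_an(V) + pc_bn(V))
    w, ca = _pc_slow_steady(p, V_eq)
    return np.array([V, V, h, n, w, ca])


def in_rest_state(p: INParams, V0: float = None) -> np.ndarray:
    V = p.E_l if V0 is None else V0
    h = in_ah(V, p.phi) / (in_ah(V, p.phi) + in_bh(V, p.phi))
    n = in_an(V, p.phi) / (in_an(V, p.phi) + in_bn(V, p.phi))
    return np.array([V, h, n])
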