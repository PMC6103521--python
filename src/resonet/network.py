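"""Network assembly and trial execution.

A :class:`NetworkSpec` describes one of the study's network
configurations: the control network (20 PCs reciprocally connected to
5 INs, all-to-all), the two-pathway competition network (two PC
populations sharing one IN pool), the minimal 1-PC/1-IN network, the
single isolated PC, and the leaky integrate-and-fire control.

Connectivity is all-to-all with maximal synaptic conductances normalized
by the number of presynaptic cells in the source population, so network
size can be changed without retuning synaptic strengths (the 100-PC /
37-IN variant reproduces the control network's resonances for this
reason).

A trial runs for ``duration`` ms with external signals switched on at
``onset`` (default 400 ms, leaving a settling period); the first 500 ms
after onset are excluded from analysis downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

from . import engine
from .cells import (AMPA_PC_TO_IN, GABA_IN_TO_PC, INParams, LIFParams,
                    PCParams, SynapseParams, in_rest_state, pc_rest_state)
from .rates import RateProgram, SpikeRaster, make_rate_program

__all__ = [
    "NetworkSpec",
    "SimResult",
    "NetworkSimulator",
    "build_network",
    "run_trial",
    "control_network",
    "competition_network",
    "minimal_network",
    "single_pc",
    "lif_network",
]

#: total background rate per PC: 100 uncorrelated cells at 1 sp/s
BACKGROUND_RATE = 100.0


@dataclass(frozen=True)
class NetworkSpec:
    """Populations, connectivity, input coupling and neuromodulation."""

    model: str = "hh"                      # "hh" or "lif"
    pc_pops: Tuple[int, ...] = (20,)       # PC population sizes (pathways)
    pc_names: Tuple[str, ...] = ("PC",)
    n_in: int = 5
    pc_params: PCParams = field(default_factory=PCParams)
    in_params: INParams = field(default_factory=INParams)
    lif_params: LIFParams = field(default_factory=LIFParams)
    ampa: SynapseParams = AMPA_PC_TO_IN    # PC -> IN
    gaba: SynapseParams = GABA_IN_TO_PC    # IN -> PC
    g_inp: float = 0.0015                  # signal synapse conductance, mS/cm^2
    g_noise: Optional[float] = 0.0005      # background synapse, mS/cm^2
    background: bool = True
    I_app_soma: float = 0.0
    I_app_dend: float = 0.0
    I_app_in: float = 0.0
    init_jitter: float = 2.0               # mV, uniform initial-V jitter

    def __post_init__(self):
        if self.model not in ("hh", "lif"):
            raise ValueError("model must be 'hh' or 'lif'")
        if len(self.pc_names) != len(self.pc_pops):
            raise ValueError("pc_names must match pc_pops")
        if any(n < 0 for n in self.pc_pops) or self.n_in < 0:
            raise ValueError("population sizes must be >= 0")
        if self.g_inp < 0:
            raise ValueError("input conductance must be >= 0")

    @property
    def n_pc(self) -> int:
        return int(sum(self.pc_pops))

    @property
    def n_synapses(self) -> int:
        """Directed synapse count over all all-to-all blocks."""
        return int(sum(n * self.n_in + self.n_in * n for n in self.pc_pops))

    @property
    def g_noise_value(self) -> float:
        if self.model == "lif":
            return self.lif_params.g_noise
        return self.g_noise if self.g_noise is not None else self.g_inp

    def knockout(self, *names: str) -> "NetworkSpec":
        return replace(self, pc_params=self.pc_params.with_knockout(*names))

    def fingerprint(self) -> str:
        """Short stable hash of the full configuration, logged with every
        trial so aggregated results can be traced to their spec."""
        import hashlib

        return hashlib.sha1(repr(self).encode()).hexdigest()[:12]


@dataclass
class SimResult:
    """Output of one trial."""

    rasters: dict                 # population name -> SpikeRaster
    v: dict                       # population name -> (n_cells, n_rec) mV
    v_dt: float                   # recording step, ms
    dt: float
    duration: float
    onset: float
    seed: int
    status: int                   # 0 ok, 1 divergence, 2 spike overflow
    spec_fingerprint: str = ""    # hash of the generating NetworkSpec

    @property
    def analysis_window(self) -> Tuple[float, float]:
        """Window excluding the settling period and the first 500 ms of response."""
        return (self.onset + 500.0, self.duration)

    def v_times(self) -> np.ndarray:
        n = next(iter(self.v.values())).shape[1]
        return np.arange(n) * self.v_dt


def _spawn_seeds(master_seed: int, n: int) -> list:
    """Deterministic child seeds from one master seed."""
    return [int(s) for s in
            np.random.SeedSequence(master_seed).generate_state(n)]


class NetworkSimulator:
    """Assembled network: weight matrices, parameter vectors, state layout."""

    def __init__(self, spec: NetworkSpec):
        self.spec = spec
        n_pc, n_in = spec.n_pc, spec.n_in
        # block all-to-all weights normalized per presynaptic population
        W_in_pc = np.zeros((n_in, n_pc))
        W_pc_in = np.zeros((n_pc, n_in))
        # HH synapses are normalized per presynaptic population (size
        # invariance); LIF synapses use the per-synapse conductances as is.
        if spec.model == "hh":
            col = 0
            for size in spec.pc_pops:
                if size > 0:
                    W_in_pc[:, col:col + size] = spec.ampa.g_syn / size
                col += size
            if n_in > 0:
                W_pc_in[:, :] = spec.gaba.g_syn / n_in
        else:
            W_in_pc[:, :] = spec.lif_params.g_syn_in
            W_pc_in[:, :] = spec.lif_params.g_syn_pc
        self.W_in_pc = W_in_pc
        self.W_pc_in = W_pc_in

    # -- inputs --------------------------------------------------------------

    def _input_conductance(self, programs, duration, dt, onset, seed):
        """Per-PC exogenous conductance trace g_inp*s_signal + g_noise*s_noise."""
        spec = self.spec
        n_pc = spec.n_pc
        n_steps = round(duration / dt)
        gexc = np.zeros((max(n_pc, 1), n_steps + 1), dtype=np.float32)
        seeds = _spawn_seeds(seed, 2 * len(spec.pc_pops) + 2)
        col = 0
        input_rasters = {}
        for p, (size, name) in enumerate(zip(spec.pc_pops, spec.pc_names)):
            prog = programs[p]
            if prog is not None and size > 0:
                if isinstance(prog, SpikeRaster):
                    if prog.n_sources != size:
                        raise ValueError("input raster must have one train "
                                         "per target cell")
                    raster = prog
                else:
                    if (abs(prog.duration - duration) > 1e-9
                            or abs(prog.dt - dt) > 1e-12):
                        raise ValueError(
                            "rate program grid must match the trial grid")
                    from .rates import draw_poisson_spikes

                    raster = draw_poisson_spikes(prog, size, seeds[2 * p])
                counts = engine.bin_spike_counts(raster, dt, n_steps)
                s = engine.double_exp_traces(counts, spec.ampa.tau_r,
                                             spec.ampa.tau_d, dt)
                gexc[col:col + size, 1:] += spec.g_inp * s.astype(np.float32)
                input_rasters[name] = raster
            if spec.background and size > 0:
                noise_prog = make_rate_program(
                    "asynchronous", r_inp=BACKGROUND_RATE, duration=duration,
                    dt=dt)
                from .rates import draw_poisson_spikes

                noise = draw_poisson_spikes(noise_prog, size, seeds[2 * p + 1])
                counts = engine.bin_spike_counts(noise, dt, n_steps)
                s = engine.double_exp_traces(counts, spec.ampa.tau_r,
                                             spec.ampa.tau_d, dt)
                gexc[col:col + size, 1:] += (spec.g_noise_value
                                             * s.astype(np.float32))
            col += size
        return gexc, input_rasters

    # -- integration ---------------------------------------------------------

    def run(self, programs, seed: int, duration: float = 2500.0,
            dt: float = 0.01, onset: float = 400.0,
            rec_stride: int = 10) -> SimResult:
        """Integrate one trial.

        ``programs`` is one RateProgram (or None) per PC population; each
        program must be sampled on the trial grid with the trial onset.
        """
        spec = self.spec
        if np.isscalar(programs) or isinstance(programs, RateProgram):
            programs = [programs]
        if len(programs) != len(spec.pc_pops):
            raise ValueError("need one rate program (or None) per PC population")
        n_pc, n_in = spec.n_pc, spec.n_in
        n_steps = round(duration / dt)
        gexc_pc, _ = self._input_conductance(programs, duration, dt, onset, seed)
        gexc_in = np.zeros((max(n_in, 1), n_steps + 1), dtype=np.float32)
        seeds = _spawn_seeds(seed + 1_013_904_223 if seed is not None else 0, 1)
        rng = np.random.default_rng(seeds[0])
        spike_cap = int(duration * 0.5) + 16

        if spec.model == "hh":
            result = self._run_hh(gexc_pc, gexc_in, rng, dt, n_steps,
                                  rec_stride, spike_cap)
        else:
            result = self._run_lif(gexc_pc, gexc_in, rng, dt, n_steps,
                                   rec_stride, spike_cap)
        spikes, counts, v_rec, status = result
        if status == 1:
            raise FloatingPointError(
                f"numerical divergence (|V| > 200 mV); seed={seed}, "
                f"dt={dt}, model={spec.model}")

        rasters, v = {}, {}
        col = 0
        for size, name in zip(spec.pc_pops, spec.pc_names):
            trains = tuple(np.asarray(spikes[col + i, :counts[col + i]])
                           for i in range(size))
            rasters[name] = SpikeRaster(trains=trains, window=(0.0, duration))
            v[name] = v_rec[col:col + size]
            col += size
        trains = tuple(np.asarray(spikes[n_pc + j, :counts[n_pc + j]])
                       for j in range(n_in))
        rasters["IN"] = SpikeRaster(trains=trains, window=(0.0, duration))
        v["IN"] = v_rec[n_pc:n_pc + n_in]
        return SimResult(rasters=rasters, v=v, v_dt=dt * rec_stride, dt=dt,
                         duration=duration, onset=onset, seed=seed,
                         status=status, spec_fingerprint=spec.fingerprint())

    def _run_hh(self, gexc_pc, gexc_in, rng, dt, n_steps, rec_stride,
                spike_cap):
        spec = self.spec
        n_pc, n_in = spec.n_pc, spec.n_in
        p, q = spec.pc_params, spec.in_params
        pcp = engine.pack_pc_params(p)
        inp = engine.pack_in_params(q)
        gvec = p.conductances()
        pc_g = np.tile(gvec, (max(n_pc, 1), 1))
        in_g = np.tile(q.conductances(), (max(n_in, 1), 1))
        y0 = np.zeros(n_pc * engine.PC_NSTATE + n_in * engine.IN_NSTATE)
        for i in range(n_pc):
            v0 = p.E_l + spec.init_jitter * (2.0 * rng.random() - 1.0)
            st = pc_rest_state(p, v0)
            y0[i * engine.PC_NSTATE:i * engine.PC_NSTATE + 6] = st
        off = n_pc * engine.PC_NSTATE
        for j in range(n_in):
            v0 = q.E_l + spec.init_jitter * (2.0 * rng.random() - 1.0)
            st = in_rest_state(q, v0)
            y0[off + j * engine.IN_NSTATE:off + j * engine.IN_NSTATE + 3] = st
        iapp_s = np.full(max(n_pc, 1), spec.I_app_soma)
        iapp_d = np.full(max(n_pc, 1), spec.I_app_dend)
        iapp_in = np.full(max(n_in, 1), spec.I_app_in)
        W_in_pc = self.W_in_pc if n_in and n_pc else np.zeros((max(n_in, 1),
                                                               max(n_pc, 1)))
        W_pc_in = self.W_pc_in if n_in and n_pc else np.zeros((max(n_pc, 1),
                                                               max(n_in, 1)))
        return engine.run_hh(
            y0, dt, n_steps, n_pc, n_in, pc_g, pcp, in_g, inp,
            W_in_pc, W_pc_in, gexc_pc, gexc_in,
            iapp_s, iapp_d, iapp_in,
            spec.ampa.tau_r, spec.ampa.tau_d,
            spec.gaba.tau_r, spec.gaba.tau_d,
            spec.ampa.E_syn, spec.gaba.E_syn,
            rec_stride, spike_cap)

    def _run_lif(self, gexc_pc, gexc_in, rng, dt, n_steps, rec_stride,
                 spike_cap):
        spec = self.spec
        lp = spec.lif_params
        n_pc, n_in = spec.n_pc, spec.n_in
        V0 = np.empty(n_pc + n_in)
        V0[:] = lp.E_l + spec.init_jitter * (2.0 * rng.random(n_pc + n_in)
                                             - 1.0)
        W_in_pc = self.W_in_pc if n_in and n_pc else np.zeros((max(n_in, 1),
                                                               max(n_pc, 1)))
        W_pc_in = self.W_pc_in if n_in and n_pc else np.zeros((max(n_pc, 1),
                                                               max(n_in, 1)))
        return engine.run_lif(
            dt, n_steps, n_pc, n_in,
            lp.g_l, lp.E_l, lp.V_thresh, lp.V_reset, lp.t_ref,
            W_in_pc, W_pc_in,
            lp.tau_r_in, lp.tau_d_in, lp.tau_r_pc, lp.tau_d_pc,
            lp.E_syn_in, lp.E_syn_pc,
            gexc_pc, gexc_in, V0, rec_stride, spike_cap)


def build_network(spec: NetworkSpec) -> NetworkSimulator:
    """Assemble a simulator instance from a network spec."""
    return NetworkSimulator(spec)


def integrate(simulator: NetworkSimulator, programs, seed: int,
              duration: float = 2500.0, dt: float = 0.01,
              onset: float = 400.0, **kw) -> SimResult:
    """Integrate an assembled simulator (alias for ``simulator.run``)."""
    return simulator.run(programs, seed, duration=duration, dt=dt,
                         onset=onset, **kw)


def run_trial(spec: NetworkSpec, programs, seed: int,
              duration: float = 2500.0, dt: float = 0.01,
              onset: float = 400.0, rec_stride: int = 10) -> SimResult:
    """Build + integrate in one call; fully reproducible from (spec, seed)."""
    return build_network(spec).run(programs, seed, duration=duration, dt=dt,
                                   onset=onset, rec_stride=rec_stride)


# -- presets -----------------------------------------------------------------

def control_network(**overrides) -> NetworkSpec:
    """20 PCs / 5 INs, g_GABA = 0.1, g_AMPA = 1, g_inp = 0.0015."""
    return NetworkSpec(**overrides)


def competition_network(n_pc: int = 20, n_in: int = 5,
                        **overrides) -> NetworkSpec:
    """Two PC pathways (target, distractor) sharing one IN pool."""
    return NetworkSpec(pc_pops=(n_pc, n_pc), pc_names=("PC_T", "PC_D"),
                       n_in=n_in, **overrides)


def minimal_network(pc_to_in_gain: float = 20.0, **overrides) -> NetworkSpec:
    """1 PC + 1 IN with the PC->IN synapse strengthened so one PC spike
    fires the IN (the per-source normalization would otherwise leave the
    single PC at the same total drive as the whole control population)."""
    ampa = replace(AMPA_PC_TO_IN, g_syn=AMPA_PC_TO_IN.g_syn)
    spec = NetworkSpec(pc_pops=(1,), n_in=1, ampa=ampa, background=False,
                       **overrides)
    return spec


def single_pc(**overrides) -> NetworkSpec:
    """One isolated PC, no INs, background off (subthreshold protocols)."""
    overrides.setdefault("background", False)
    return NetworkSpec(pc_pops=(1,), n_in=0, **overrides)


def big_network(**overrides) -> NetworkSpec:
    """Size-scaled variant: 100 PCs / 37 INs, all strengths unchanged."""
    return NetworkSpec(pc_pops=(100,), n_in=37, **overrides)


def lif_network(**overrides) -> NetworkSpec:
    """Integrate-and-fire control: 25 PCs / 5 INs."""
    return NetworkSpec(model="lif", pc_pops=(25,), n_in=5,
                       g_inp=LIFParams().g_inp, **overrides)
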