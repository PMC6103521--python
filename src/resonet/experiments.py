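"""Scripted studies: response profiles, resonance, competition, modulation.

The central object is a frequency sweep: the same network is driven by a
rate-modulated Poisson signal whose modulation frequency steps across a
grid, with a fixed number of realizations per grid point (paired seeds
across points), plus an equal-strength asynchronous reference condition.
The resulting :class:`ResponseProfile` aggregates mean firing rates and
population frequencies; :func:`extract_resonances` reduces it to the
resonance statistics (natural frequency f_N, firing-rate resonances
f_R^PC and f_R^IN, population-frequency resonance f_R^pop).

Competition runs use the two-pathway network with a shared IN pool and
quantify distractor suppression against a paired no-competition
reference.  Modulation runs repeat a sweep under channel knockouts or
applied currents.  The single-cell ladder reproduces the subthreshold /
suprathreshold / minimal-network progression that connects single-PC
delta-band resonance to the network's beta-band resonance.

Sine-modulated signals here use the mean-matched convention (time
average equal to r_inp) so that waveforms of equal nominal strength are
comparable, except for the single-cell ladder which uses the half-wave
convention (peak rate equal to r_inp) appropriate for its weak-drive
protocols.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .measures import (compute_ifr, mean_rate, natural_frequency,
                       nested_oscillation, population_frequency,
                       ResonanceSummary)
from .network import (NetworkSpec, competition_network, control_network,
                      lif_network, minimal_network, run_trial, single_pc)
from .rates import SpikeRaster, draw_poisson_spikes, make_rate_program

__all__ = [
    "SweepSpec",
    "ResponseProfile",
    "CompetitionResult",
    "frequency_sweep",
    "extract_resonances",
    "modulation_experiment",
    "competition_experiment",
    "single_cell_ladder",
    "filter_regime_classification",
    "scaled_sweep",
    "full_sweep",
]

IFR_SIGMA_SPECTRUM = 2.0   # ms kernel for spectral measures
IFR_SIGMA_DISPLAY = 6.0    # ms kernel for visualization


@dataclass(frozen=True)
class SweepSpec:
    """One frequency sweep: waveform, grid, realizations, network."""

    network: NetworkSpec = field(default_factory=control_network)
    kind: str = "square_fixed_mean"
    grid: Tuple[float, ...] = tuple(range(16, 33, 2))
    r_inp: float = 1000.0
    delta_inp: Optional[float] = 1.0
    r_p: Optional[float] = None
    normalization: str = "mean_matched"
    n_realizations: int = 2
    base_seed: int = 1
    duration: float = 1500.0
    onset: float = 400.0
    dt: float = 0.01
    target: Optional[str] = None    # PC population receiving the signal

    def __post_init__(self):
        if self.n_realizations < 1:
            raise ValueError("need at least one realization")
        if len(self.grid) == 0:
            raise ValueError("empty frequency grid")

    @property
    def target_pop(self) -> str:
        return self.target or self.network.pc_names[0]

    def seeds(self) -> List[int]:
        return [self.base_seed + r for r in range(self.n_realizations)]


def full_sweep(**overrides) -> SweepSpec:
    """The full study protocol: 1-50 Hz in 1 Hz steps, 10 realizations,
    2500 ms trials."""
    kw = dict(grid=tuple(range(1, 51)), n_realizations=10, duration=2500.0)
    kw.update(overrides)
    return SweepSpec(**kw)


def scaled_sweep(**overrides) -> SweepSpec:
    """Desk-scale protocol: 16-32 Hz in 2 Hz steps, 2 realizations,
    1500 ms trials."""
    return SweepSpec(**overrides)


@dataclass
class ResponseProfile:
    """Input-frequency-dependent response statistics (mean +- sd)."""

    grid: np.ndarray
    r_pc: np.ndarray
    r_pc_sd: np.ndarray
    r_in: np.ndarray
    r_in_sd: np.ndarray
    f_pop: np.ndarray            # nan where undefined/excluded
    f_pop_sd: np.ndarray
    nested_frac: np.ndarray
    r_pc_per_real: np.ndarray    # (n_points, n_realizations)
    r_in_per_real: np.ndarray
    f_pop_per_real: np.ndarray
    f_N: Optional[float]
    r_pc_ref: float              # asynchronous-reference PC rate
    r_in_ref: float
    sweep: SweepSpec = None

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "f_inp": self.grid, "r_pc": self.r_pc, "r_pc_sd": self.r_pc_sd,
            "r_in": self.r_in, "r_in_sd": self.r_in_sd, "f_pop": self.f_pop,
            "f_pop_sd": self.f_pop_sd, "nested_frac": self.nested_frac,
        })


def _signal_program(sweep: SweepSpec, f_inp: Optional[float]):
    if f_inp is None:
        return make_rate_program("asynchronous", r_inp=sweep.r_inp,
                                 onset=sweep.onset, duration=sweep.duration,
                                 dt=sweep.dt)
    return make_rate_program(sweep.kind, r_inp=sweep.r_inp, f_inp=f_inp,
                             delta_inp=sweep.delta_inp, r_p=sweep.r_p,
                             onset=sweep.onset, duration=sweep.duration,
                             dt=sweep.dt, normalization=sweep.normalization)


def _trial_measures(sweep: SweepSpec, res, f_inp):
    win = res.analysis_window
    target = sweep.target_pop
    tr_pc = compute_ifr(res.rasters[target], res.rasters[target].n_sources,
                        IFR_SIGMA_SPECTRUM, win)
    n_in = max(res.rasters["IN"].n_sources, 1)
    tr_in = compute_ifr(res.rasters["IN"], n_in, IFR_SIGMA_SPECTRUM, win) \
        if res.rasters["IN"].n_sources else None
    f_pop, spectrum = population_frequency(tr_pc)
    nested = (nested_oscillation(spectrum, f_inp)
              if (f_inp is not None and f_pop is not None) else False)
    return (mean_rate(tr_pc), mean_rate(tr_in) if tr_in is not None else 0.0,
            f_pop, nested)


def frequency_sweep(sweep: SweepSpec, progress: bool = False
                    ) -> ResponseProfile:
    """Run the sweep plus an asynchronous reference; aggregate per point.

    Realization seeds are paired across grid points so conditions are
    compared under identical input noise.  Aborted trials are excluded
    with a warning.
    """
    import warnings

    n_pts, n_real = len(sweep.grid), sweep.n_realizations
    r_pc = np.full((n_pts, n_real), np.nan)
    r_in = np.full((n_pts, n_real), np.nan)
    f_pop = np.full((n_pts, n_real), np.nan)
    nested = np.zeros((n_pts, n_real), dtype=bool)
    programs_for = lambda prog: [
        prog if name == sweep.target_pop else None
        for name in sweep.network.pc_names]

    for i, f in enumerate(sweep.grid):
        for r, seed in enumerate(sweep.seeds()):
            prog = _signal_program(sweep, f)
            try:
                res = run_trial(sweep.network, programs_for(prog), seed=seed,
                                duration=sweep.duration, dt=sweep.dt,
                                onset=sweep.onset)
            except FloatingPointError as err:  # diverged trial: log + skip
                warnings.warn(f"trial f_inp={f}, seed={seed} aborted: {err}")
                continue
            rp, ri, fp, ns = _trial_measures(sweep, res, f)
            r_pc[i, r], r_in[i, r] = rp, ri
            f_pop[i, r] = np.nan if fp is None else fp
            nested[i, r] = ns
        if progress:
            print(f"  f_inp={f}: r_pc={np.nanmean(r_pc[i]):.2f}", flush=True)

    # asynchronous equal-strength reference
    ref_pc, ref_in, ref_fpop = [], [], []
    for seed in sweep.seeds():
        prog = _signal_program(sweep, None)
        res = run_trial(sweep.network, programs_for(prog), seed=seed,
                        duration=sweep.duration, dt=sweep.dt,
                        onset=sweep.onset)
        rp, ri, fp, _ = _trial_measures(sweep, res, None)
        ref_pc.append(rp)
        ref_in.append(ri)
        if fp is not None:
            ref_fpop.append(fp)
    f_N = float(np.median(ref_fpop)) if ref_fpop else None

    return ResponseProfile(
        grid=np.asarray(sweep.grid, dtype=float),
        r_pc=np.nanmean(r_pc, axis=1), r_pc_sd=np.nanstd(r_pc, axis=1),
        r_in=np.nanmean(r_in, axis=1), r_in_sd=np.nanstd(r_in, axis=1),
        f_pop=np.nanmean(f_pop, axis=1), f_pop_sd=np.nanstd(f_pop, axis=1),
        nested_frac=nested.mean(axis=1),
        r_pc_per_real=r_pc, r_in_per_real=r_in, f_pop_per_real=f_pop,
        f_N=f_N, r_pc_ref=float(np.mean(ref_pc)),
        r_in_ref=float(np.mean(ref_in)), sweep=sweep)


def _argmax_with_sd(grid, per_real, mean_profile):
    """Argmax of the mean profile; dispersion = sd of per-realization argmax."""
    if np.all(np.isnan(mean_profile)):
        return None, 0.0
    best = float(grid[int(np.nanargmax(mean_profile))])
    per = []
    for r in range(per_real.shape[1]):
        col = per_real[:, r]
        if not np.all(np.isnan(col)):
            per.append(grid[int(np.nanargmax(col))])
    sd = float(np.std(per)) if per else 0.0
    return best, sd


def extract_resonances(profile: ResponseProfile,
                       nested_exclude_frac: float = 0.5) -> ResonanceSummary:
    """Resonant frequencies from a response profile.

    ``f_R^pop`` is the argmax of the f_pop profile after excluding grid
    points where at least ``nested_exclude_frac`` of realizations were
    flagged as nested-oscillation trials.
    """
    f_R_pc, pc_sd = _argmax_with_sd(profile.grid, profile.r_pc_per_real,
                                    profile.r_pc)
    f_R_in, in_sd = _argmax_with_sd(profile.grid, profile.r_in_per_real,
                                    profile.r_in)
    fpop_mean = profile.f_pop.copy()
    fpop_mean[profile.nested_frac >= nested_exclude_frac] = np.nan
    f_R_pop, pop_sd = _argmax_with_sd(profile.grid, profile.f_pop_per_real,
                                      fpop_mean)
    silent = bool(np.nanmax(profile.r_pc) <= 0.5) if len(profile.r_pc) else True
    return ResonanceSummary(f_N=profile.f_N, f_R_pc=f_R_pc, f_R_in=f_R_in,
                            f_R_pop=f_R_pop, f_R_pc_sd=pc_sd,
                            f_R_in_sd=in_sd, f_R_pop_sd=pop_sd,
                            pc_silent=silent)


# -- neuromodulation ---------------------------------------------------------

def modulation_experiment(knockouts: Sequence[Tuple[str, ...]] = (),
                          i_app: Sequence[float] = (),
                          sweep: Optional[SweepSpec] = None,
                          ) -> Dict[str, ResonanceSummary]:
    """Per-condition firing-rate resonance under channel knockouts or
    applied currents.

    ``knockouts`` is a sequence of channel-name tuples (from the PC
    channel key: NaF, KDR, NaP, Ks, Ca, KCa); ``i_app`` a sequence of
    somatic applied currents in uA/cm^2.  A silenced PC population is
    reported via ``pc_silent`` with ``f_R_pc=None``.
    """
    if sweep is None:
        sweep = scaled_sweep(kind="sine", delta_inp=None)
    out: Dict[str, ResonanceSummary] = {}
    conditions = [("control", sweep.network)]
    for names in knockouts:
        names = (names,) if isinstance(names, str) else tuple(names)
        conditions.append(("-" + "-".join(names),
                           sweep.network.knockout(*names)))
    for ia in i_app:
        conditions.append((f"I_app={ia:+g}",
                           replace(sweep.network, I_app_soma=ia)))
    for label, net in conditions:
        prof = frequency_sweep(replace(sweep, network=net))
        summary = extract_resonances(prof)
        if summary.pc_silent:
            summary = replace_summary_silent(summary)
        out[label] = summary
    return out


def replace_summary_silent(summary: ResonanceSummary) -> ResonanceSummary:
    return ResonanceSummary(f_N=summary.f_N, f_R_pc=None, f_R_in=None,
                            f_R_pop=None, pc_silent=True)


# -- competition / gating ----------------------------------------------------

@dataclass
class CompetitionResult:
    """Target/distractor measures and the distractor suppression index."""

    r_pc_t: float
    r_pc_d: float
    r_pc_d_natural: float       # distractor rate without the target pathway
    f_pop_t: Optional[float]
    f_pop_d: Optional[float]
    f_N_d: Optional[float]      # natural frequency of the distractor pathway
    suppression_index: float    # 1 - r_d(competition)/r_d(natural)
    n_realizations: int = 1

    def to_dict(self):
        return {k: getattr(self, k) for k in
                ("r_pc_t", "r_pc_d", "r_pc_d_natural", "f_pop_t", "f_pop_d",
                 "f_N_d", "suppression_index", "n_realizations")}


def _schedule_raster(segments, n_sources: int, duration: float, dt: float,
                     seed: int) -> SpikeRaster:
    """Draw a piecewise input: ``segments`` is a list of (t0, t1, program);
    each program is sampled on the full grid and truncated to its segment
    (exact for Poisson processes)."""
    trains = [np.empty(0)] * n_sources
    for k, (t0, t1, prog) in enumerate(segments):
        raster = draw_poisson_spikes(prog, n_sources, seed + 7919 * k)
        for i, tr in enumerate(raster.trains):
            part = tr[(tr >= t0) & (tr < t1)]
            trains[i] = np.concatenate([trains[i], part])
    return SpikeRaster(trains=tuple(np.sort(t) for t in trains),
                       window=(0.0, duration))


def competition_experiment(target_input: dict, distractor_input: dict,
                           network: Optional[NetworkSpec] = None,
                           n_realizations: int = 2, base_seed: int = 1,
                           duration: float = 1500.0, onset: float = 400.0,
                           dt: float = 0.01) -> CompetitionResult:
    """Drive PC_T and PC_D through a shared IN pool; measure suppression.

    ``target_input`` / ``distractor_input`` are keyword dicts for
    :func:`make_rate_program` (without onset/duration/dt).  The
    "natural" reference re-runs the distractor pathway alone with
    identical seeds, so the suppression index isolates the effect of
    competition.
    """
    net = network or competition_network()
    name_t, name_d = net.pc_names[0], net.pc_names[1]
    rt, rd, rdn = [], [], []
    fpt, fpd, fnd = [], [], []
    for r in range(n_realizations):
        seed = base_seed + r
        prog_t = make_rate_program(onset=onset, duration=duration, dt=dt,
                                   **target_input)
        prog_d = make_rate_program(onset=onset, duration=duration, dt=dt,
                                   **distractor_input)
        res = run_trial(net, [prog_t, prog_d], seed=seed, duration=duration,
                        dt=dt, onset=onset)
        win = res.analysis_window
        tr_t = compute_ifr(res.rasters[name_t], res.rasters[name_t].n_sources,
                           IFR_SIGMA_SPECTRUM, win)
        tr_d = compute_ifr(res.rasters[name_d], res.rasters[name_d].n_sources,
                           IFR_SIGMA_SPECTRUM, win)
        rt.append(mean_rate(tr_t))
        rd.append(mean_rate(tr_d))
        ft, _ = population_frequency(tr_t)
        fd, _ = population_frequency(tr_d)
        if ft is not None:
            fpt.append(ft)
        if fd is not None:
            fpd.append(fd)
        # natural reference: distractor alone, same seed
        res0 = run_trial(net, [None, prog_d], seed=seed, duration=duration,
                         dt=dt, onset=onset)
        tr_d0 = compute_ifr(res0.rasters[name_d],
                            res0.rasters[name_d].n_sources,
                            IFR_SIGMA_SPECTRUM, win)
        rdn.append(mean_rate(tr_d0))
        f0, _ = population_frequency(tr_d0)
        if f0 is not None:
            fnd.append(f0)
    r_d_nat = float(np.mean(rdn))
    r_d = float(np.mean(rd))
    supp = 1.0 - r_d / r_d_nat if r_d_nat > 0 else 0.0
    return CompetitionResult(
        r_pc_t=float(np.mean(rt)), r_pc_d=r_d, r_pc_d_natural=r_d_nat,
        f_pop_t=float(np.median(fpt)) if fpt else None,
        f_pop_d=float(np.median(fpd)) if fpd else None,
        f_N_d=float(np.median(fnd)) if fnd else None,
        suppression_index=float(supp), n_realizations=n_realizations)


def two_period_competition(target_t2: dict, distractor: dict,
                           network: Optional[NetworkSpec] = None,
                           t_switch: float = 950.0, seed: int = 1,
                           duration: float = 1500.0, onset: float = 400.0,
                           dt: float = 0.01):
    """Asynchronous-then-oscillatory target schedule (two periods).

    During T1 (onset..t_switch) the target receives an asynchronous
    signal of the same mean strength as ``target_t2``; at ``t_switch``
    it switches to the oscillatory program.  Returns the trial result
    and per-period (T1, T2) rates for both pathways.
    """
    net = network or competition_network()
    name_t, name_d = net.pc_names[0], net.pc_names[1]
    r_inp = target_t2["r_inp"]
    async_prog = make_rate_program("asynchronous", r_inp=r_inp, onset=onset,
                                   duration=duration, dt=dt)
    osc_prog = make_rate_program(onset=0.0, duration=duration, dt=dt,
                                 **target_t2)
    raster_t = _schedule_raster(
        [(onset, t_switch, async_prog), (t_switch, duration, osc_prog)],
        net.pc_pops[0], duration, dt, seed)
    prog_d = make_rate_program(onset=onset, duration=duration, dt=dt,
                               **distractor)
    res = run_trial(net, [raster_t, prog_d], seed=seed, duration=duration,
                    dt=dt, onset=onset)
    out = {}
    for label, (w0, w1) in (("T1", (onset + 100.0, t_switch)),
                            ("T2", (t_switch + 100.0, duration))):
        for name in (name_t, name_d):
            tr = compute_ifr(res.rasters[name], res.rasters[name].n_sources,
                             IFR_SIGMA_SPECTRUM, (w0, w1))
            out[f"{label}_{name}"] = mean_rate(tr)
    return res, out


# -- single-cell ladder ------------------------------------------------------

@dataclass
class LadderResult:
    grid: np.ndarray
    sub_amplitude: np.ndarray           # V_max - V_min, single PC, r=0.1 kHz
    supra_rate: Dict[float, np.ndarray]  # r_inp (kHz) -> rate profile
    minimal_rate: Dict[float, np.ndarray]  # 1PC/1IN network profiles

    def sub_peak(self) -> float:
        return float(self.grid[int(np.nanargmax(self.sub_amplitude))])

    def supra_peak(self, r_inp: float) -> float:
        return float(self.grid[int(np.argmax(self.supra_rate[r_inp]))])

    def minimal_peak(self, r_inp: float) -> float:
        return float(self.grid[int(np.argmax(self.minimal_rate[r_inp]))])


def single_cell_ladder(grid: Sequence[float] = tuple(range(1, 11)),
                       seeds: Sequence[int] = (1, 2, 3),
                       supra_strengths: Sequence[float] = (300.0,),
                       minimal_strengths: Sequence[float] = (),
                       duration: float = 4000.0, onset: float = 400.0,
                       dt: float = 0.01, pc_params=None,
                       gaba_tau_d: Optional[float] = None) -> LadderResult:
    """Single-PC subthreshold and suprathreshold sine resonance, plus the
    minimal 1-PC/1-IN network (background noise removed throughout).

    The subthreshold protocol uses r_inp = 0.1 kHz; suprathreshold
    profiles use the strengths given (spikes/s).  Sine programs use the
    half-wave convention (peak rate = r_inp), matching the weak-drive
    regime of the protocol.
    """
    kw = {} if pc_params is None else {"pc_params": pc_params}
    cell = single_pc(**kw)
    mini = minimal_network(**kw)
    if gaba_tau_d is not None:
        mini = replace(mini, gaba=replace(mini.gaba, tau_d=gaba_tau_d))
    grid = np.asarray(grid, dtype=float)
    sub = np.full(len(grid), np.nan)
    supra = {r: np.zeros(len(grid)) for r in supra_strengths}
    minimal = {r: np.zeros(len(grid)) for r in minimal_strengths}

    def one(net, r_inp, f, seed):
        prog = make_rate_program("sine", r_inp=r_inp, f_inp=f, onset=onset,
                                 duration=duration, dt=dt,
                                 normalization="half")
        res = run_trial(net, [prog], seed=seed, duration=duration, dt=dt,
                        onset=onset)
        win = res.analysis_window
        tr = res.rasters[net.pc_names[0]].trains[0]
        n = int(np.sum((tr >= win[0]) & (tr < win[1])))
        v = res.v[net.pc_names[0]][0]
        tv = res.v_times()
        vwin = v[tv >= win[0]]
        rate = n / ((win[1] - win[0]) * 1e-3)
        return rate, float(vwin.max() - vwin.min())

    for i, f in enumerate(grid):
        amps = []
        for seed in seeds:
            rate, amp = one(cell, 100.0, f, seed)
            if rate == 0:
                amps.append(amp)   # subthreshold amplitude needs no spikes
            for r in supra_strengths:
                supra[r][i] += one(cell, r, f, seed)[0] / len(seeds)
            for r in minimal_strengths:
                minimal[r][i] += one(mini, r, f, seed)[0] / len(seeds)
        sub[i] = np.mean(amps) if amps else np.nan
    return LadderResult(grid=grid, sub_amplitude=sub, supra_rate=supra,
                        minimal_rate=minimal)


# -- filter-regime taxonomy --------------------------------------------------

def filter_regime_classification(profile: ResponseProfile,
                                 floor_frac: float = 0.25,
                                 peak_frac: float = 1.3) -> str:
    """Classify a firing-rate profile as band-pass, low-pass, high-pass,
    or all-pass (with or without a resonant peak).

    A grid point "responds" when its mean PC rate exceeds ``floor_frac``
    times the profile maximum.  Band-pass: only an interior band
    responds; low-pass: the low end responds, the high end does not;
    high-pass: the reverse; all-pass: everything responds, tagged
    "+peak" when the maximum exceeds ``peak_frac`` times the edge-level
    response.  Thresholds are documented choices, not fitted values.
    """
    r = np.asarray(profile.r_pc, dtype=float)
    if np.nanmax(r) <= 0:
        return "silent"
    resp = r > floor_frac * np.nanmax(r)
    lo, hi = bool(resp[0]), bool(resp[-1])
    if lo and hi:
        edge = max(r[0], r[-1])
        has_peak = np.nanmax(r[1:-1]) > peak_frac * edge if len(r) > 2 else False
        return "all-pass+peak" if has_peak else "all-pass"
    if lo and not hi:
        return "low-pass"
    if hi and not lo:
        return "high-pass"
    if resp.any():
        return "band-pass"
    return "silent"


# -- presets for the command line -------------------------------------------

def preset_network(name: str) -> NetworkSpec:
    presets = {
        "control": control_network,
        "competition": competition_network,
        "minimal": minimal_network,
        "single": single_pc,
        "lif": lif_network,
    }
    try:
        return presets[name]()
    except KeyError:
        raise ValueError(f"unknown network preset {name!r}; "
                         f"choose from {sorted(presets)}")
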