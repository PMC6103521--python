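# Methods

## Scope and model overview

`resonet` simulates and analyses small cortical output circuits built
from excitatory principal cells (PCs) and fast-spiking interneurons
(INs) coupled by strong feedback inhibition — inhibition-based network
oscillators of the PING family. The circuits are driven by collections
of independent Poisson spike trains whose instantaneous rate λ(t) is
constant (an asynchronous upstream source), sinusoidal, or square-wave
modulated (periodic pulse packets). The package measures the network's
output as the instantaneous population firing rate (iFR) and the
population oscillation frequency `f_pop`, and characterizes responses by
four statistics: the natural frequency `f_N` (the `f_pop` elicited by an
asynchronous drive), the firing-rate resonances `f_R^PC` and `f_R^IN`
(input modulation frequencies maximizing the time-averaged PC and IN
rates), and the population-frequency resonance `f_R^pop` (the input
frequency maximizing `f_pop`, i.e. the fastest rhythm the network
relays).

## Input signals

All drive is inhomogeneous Poisson. Rate programs:

* `asynchronous`: λ(t) = r_inp after signal onset.
* `sine`: two conventions are provided because the conventional
  half-wave formula λ = r_inp (1 + sin 2πf t)/2 has time average
  r_inp/2, while r_inp is defined as the time-averaged rate. The
  `mean_matched` convention rescales so ⟨λ⟩ = r_inp; network
  experiments use it so that waveforms of equal nominal strength are
  comparable. The weak-drive single-cell protocols use the half-wave
  convention (`half`), whose peak rate equals r_inp.
* `square_fixed_mean`: rectangular pulses of width δ_inp at frequency
  f_inp with amplitude r_inp/(f_inp·δ_inp), so the mean rate is
  independent of f_inp (fixed total spike count; pulses grow as f_inp
  falls). δ_inp sets input synchrony: 1 ms (high), 10 ms (medium),
  19 ms (low).
* `square_fixed_amplitude`: pulse amplitude fixed at r_p; the mean rate
  then grows ∝ r_p·f_inp·δ_inp.

Pulse phase convention: the first pulse begins at signal onset.
Sampling is by thinning on the integration grid (dt = 0.01 ms; bin
occupancy λ·dt ≤ ~0.3 even for the largest pulse amplitudes), with
independent per-source streams derived from (master seed, source index)
via `numpy.random.SeedSequence`. Each PC receives its own realization of
the signal (one aggregate train of rate λ(t)) plus an independent
background train representing 100 uncorrelated cells at 1 sp/s
(aggregated to a single 100 sp/s source per cell; exact by Poisson
superposition).

Input spikes are pre-integrated into synaptic-gate conductance traces
before the integration loop: each spike adds a unit-peak
double-exponential (rise 0.4 ms, decay 2 ms) to the cell's input gate,
and the exogenous conductance is g_inp·s_signal(t) + g_noise·s_noise(t)
on the dendrite.

## Cell models

**Principal cell.** Two compartments (soma, dendrite), C_m = 1 μF/cm²,
channels named by the standard key NaF, KDR, NaP, Ks, Ca, KCa. The
kinetic constants are this package's own calibration (the `KINETICS`
registry, set `pfc_deep_default`), chosen to satisfy the behavioural
gates that define the cell class rather than copied from any published
table:

* regular spiking under strong asynchronous drive (~15–20 sp/s at
  r_inp = 1 kHz through g_inp = 0.0015 mS/cm²);
* subthreshold voltage resonance near 2 Hz under weak sinusoidal drive,
  carried by the slow M-type K current (τ_Ks = 300 ms, half-activation
  near rest) against the persistent-sodium amplifier;
* a silent resting state at zero input, reached when the
  near-saturated high-threshold Ca window current (activation midpoint
  well below rest, so it acts as a necessary depolarizing bias without
  a regenerative slope at the operating point) is balanced by leak and
  the slow K currents — removing Ca silences the cell, matching the
  knockout phenotype;
* a ~25–30 ms post-spike recovery clock set by NaF inactivation
  (a rate factor `h_phi` = 2 on the h gate), which paces the network's
  beta rhythm.

Fast activation gates (NaF m, NaP, Ca) are taken at voltage steady
state. The calcium pool integrates the Ca current (gain 0.1 μM·cm²/μA
per ms, clearance τ_Ca = 60 ms) and gates KCa; a per-spike calcium
increment is available (`ca_spike`) but the calibrated default is 0 —
spike-history heterogeneity in the pool otherwise desynchronizes volley
recruitment. The dendrite carries the input synapses and NaP; soma and
dendrite are coupled at g_c = 0.2 mS/cm² with area ratio 1 (values
chosen so dendritic input at the printed g_inp drives somatic spiking).

**Interneuron.** Single compartment with Wang–Buzsáki-style NaF/KDR
kinetics (hyperpolarized, fast; temperature factor 5), giving sustained
non-adapting firing above 100 sp/s — the fast-spiking phenotype. Its
passive load (C_m = 1.6 μF/cm², g_l = 0.25 mS/cm²) is calibrated so that IN
recruitment needs a fraction of near-coincident PC spikes: this is what
separates the IN rate resonance from the PC rate resonance
(f_R^IN > f_R^PC) and makes IN recruitment fail above ~30 Hz.

**Synapses.** First-order kinetics ds/dt = H(V_pre)(1−s)/τ_r − s/τ_d
with H(V) = 1 + tanh(V/4); currents g·s·(V−E). PC→IN: AMPA, g = 1
mS/cm², E = 0 mV, τ_r = 0.4 ms, τ_d = 2 ms. IN→PC: GABA_A, g = 0.1
mS/cm², E = −75 mV, τ_d = 5 ms, terminating on the PC soma
(perisomatic targeting). HH conductances are normalized by presynaptic
population size, which is what makes the 5×-scaled network (100 PC /
37 IN) reproduce the control resonances without retuning.

**LIF variant.** Leaky integrate-and-fire control with the standard
double-exponential conductance synapses (onto PCs: g = 0.1, E = −80 mV,
0.4/2 ms; onto INs: g = 0.03, E = 0 mV, 0.2/10 ms; g_inp = 0.00375,
g_noise = 0.0056 mS/cm²), reset to −65 mV and clamped for 3 ms.
Because every excitatory reversal is 0 mV, a conductance-driven cell
asymptotes strictly below 0 mV; the spike-initiation threshold is
therefore a parameter, default −57 mV. LIF synapses are summed without
population normalization (the printed per-synapse values are otherwise
too weak to recruit the INs).

## Numerics

Fixed-step 4th-order Runge–Kutta at dt = 0.01 ms (numba-compiled);
exogenous conductances are sampled on the grid with midpoint values at
half steps. Spikes are detected as upward 0 mV crossings at the soma
with a 2 ms minimum inter-detection interval. Trials run 1500–2500 ms
with signals delivered at 400 ms; the first 500 ms of response are
excluded from analysis. Initial state: rest-state gates and the calcium
pool at its fixed point for a per-cell jittered voltage (±2 mV); the
pool initialization matters — starting it empty transiently removes the
KCa current and fires spurious spikes. Voltage traces are stored
decimated (0.1 ms); rasters at full resolution. Trials abort with a
diagnostic if |V| exceeds 200 mV.

Step-halving convergence holds at the trajectory level on horizons
within the network's predictability time (single-cell spike times shift
< 0.1 ms over 1.5 s; network spike times < 1 ms over 300 ms). Over
longer horizons the network mixes chaotically — trajectories at
different steps decorrelate while the stationary statistics agree
within realization-to-realization variability, so long-horizon
statistics are always reported as averages or medians across seeds.

## Measures

iFR is Gaussian kernel regression on pooled population spike times
(unit-mass kernels, divided by population size; 1 ms grid), with a 6 ms
kernel for display and 2 ms for spectra. "Width" means the Gaussian
standard deviation (FWHM available as an option). Mean rates are time
averages of the iFR, equal to count/(N·T) up to edge effects.

`f_pop` is the peak of Welch's spectrum of the 2 ms-kernel iFR (Hann
window, ≤1024 ms segments, 50% overlap, zero-padded to ≤0.25 Hz grid,
search band 5–100 Hz, ties toward the lower frequency). Two
disambiguation rules, both documented choices: (1) a
fundamental-frequency rule — if the half-frequency of the raw peak
carries ≥ 50% of its power, the half-frequency is reported (pulsatile
rhythms put substantial power into the second harmonic, and the
period-doubled regime above the locking break would otherwise be read
at the drive frequency); (2) a nested-oscillation flag — a trial whose
spectrum has a secondary peak ≥ 50% of the primary while the primary
exceeds 1.5× f_inp is flagged and excluded from f_R^pop extraction
(strong, slow, low-synchrony drives generate internal rhythms nested in
the drive cycle whose peak would otherwise masquerade as a resonance).
`f_N` is the median `f_pop` across asynchronous-drive realizations; a
non-oscillating network (e.g. zero feedback inhibition) yields no
defined value.

## Experiments

A frequency sweep runs one trial per (grid point × realization) with
realization seeds paired across grid points, plus an equal-strength
asynchronous reference with the same seeds; profiles report mean ± sd
across realizations, and resonances are the argmax of the mean profiles
(dispersion = sd of per-realization argmax). The full protocol is
1–50 Hz in 1 Hz steps with 10 realizations of 2500 ms; the desk-scale
protocol used by the test suite and the acceptance script is 16–32 Hz
(20–36 Hz for the medium-synchrony population-resonance sweep) in 2 Hz
steps with 2 realizations of 1500 ms. These problem sizes were chosen
so that a full acceptance run completes in minutes on one core while
every extracted argmax is stable across seed draws at the profile
margins reported below.

Competition uses two 20-PC populations sharing one 5-IN pool; the
suppression index is 1 − r̄_D(competition)/r̄_D(reference), with the
reference re-running the distractor pathway alone under identical
seeds. The two-period schedule splices an asynchronous and an
oscillatory segment exactly (independent Poisson segments truncated at
the switch time). Knockout and applied-current experiments repeat a
sinusoidal sweep per condition; a silenced PC population is reported as
a distinct outcome rather than an argmax.

## Calibration outcomes and known limitations

At the calibrated defaults the control network produces `f_N` ≈ 19–20
Hz (median across seeds; single-seed estimates scatter by a few Hz),
`f_R^PC` = 24 Hz for the high-synchrony square drive, `f_R^IN` = 28–30
Hz, 1:1 locking of `f_pop` to the drive below the IN resonance, and the
knockout phenotype (−Ks, −KCa up; −NaP down; −Ca silent). Known
deviations, kept deliberately rather than masked:

* The sinusoidal firing-rate profile is much flatter than the square
  profile; its argmax sits at 20–22 Hz rather than sharing the square
  drive's 24 Hz peak.
* The 1:1 locking band extends further than the IN resonance: the
  collective period-doubling that should cap `f_pop` near 28 Hz for the
  medium-synchrony drive occurs only around 34–36 Hz. `f_R^pop`
  therefore reads high on the medium-synchrony sweep (it matches
  `f_R^IN` within one grid step on the high-synchrony sweep), and for
  the high-synchrony drive the return of `f_pop` toward `f_N` is not
  yet visible at 50 Hz.
* The coincidence-detector IN saturates near 180 sp/s and enters
  depolarization block under strong direct current, so the PC — whose
  fast sodium-inactivation recovery lets it follow very strong drive —
  reaches higher maximal rates; the fast-spiking phenotype holds as
  sustained, non-adapting firing rather than as a higher absolute
  ceiling.
* Driving both competition pathways asynchronously suppresses both by
  ~35% relative to the single-pathway reference (the two pathways'
  volleys interleave through the shared INs instead of merging), so the
  matched-frequency no-suppression controls are not reproduced; the
  suppression of an asynchronous distractor by a resonant rhythmic
  target is robust.

The synthetic inputs emulate Poisson spiking with the stated rate
modulations only: no spike-count correlations between source cells, no
conduction delays, no short-term plasticity. Passing tests therefore
speak to the model's behaviour under idealized upstream statistics, not
to recordings with correlated or bursty afferents.
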