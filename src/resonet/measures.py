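"""Output statistics: instantaneous firing rate, population frequency.

The instantaneous population firing rate (iFR) is a Gaussian
kernel-regression estimate on pooled population spike times: every spike
contributes a unit-mass Gaussian, the sum is divided by the population
size, so the time integral of ``iFR * N`` recovers the spike count and
the units are spikes/s per cell.  A 6 ms kernel is used for
visualization and a 2 ms kernel for spectral analysis.

The population frequency ``f_pop`` is the frequency with peak power in
Welch's spectrum of the iFR inside a search band (default 5-100 Hz); the
natural frequency ``f_N`` is the ``f_pop`` elicited by an asynchronous
input.  When a strong low-frequency drive with low spike synchrony
generates nested oscillations the spectrum is multi-peaked; such trials
can be flagged and excluded from population-frequency resonance
extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks, welch

from .rates import SpikeRaster

__all__ = [
    "iFRTrace",
    "PowerSpectrum",
    "ResonanceSummary",
    "compute_ifr",
    "mean_rate",
    "population_frequency",
    "nested_oscillation",
    "natural_frequency",
]

#: iFR sampling rate (kernel regression grid), kHz -> 1 ms bins
IFR_DT_MS = 1.0
#: Welch defaults: <= 1024 ms Hann segments, 50% overlap, zero-padded
WELCH_NPERSEG = 1024
WELCH_NFFT = 8192
SEARCH_BAND = (5.0, 100.0)


@dataclass
class iFRTrace:
    t: np.ndarray              # ms
    rate: np.ndarray           # spikes/s per cell
    sigma: float               # kernel width (standard deviation), ms
    population: str = ""

    def __post_init__(self):
        if len(self.t) != len(self.rate):
            raise ValueError("time grid and rate must have equal length")


@dataclass
class PowerSpectrum:
    freqs: np.ndarray
    power: np.ndarray
    nperseg: int
    noverlap: int
    window: str = "hann"

    def peak(self, band: Tuple[float, float] = SEARCH_BAND,
             subharmonic_ratio: float = 0.5) -> Optional[float]:
        """Frequency of peak power inside the band (ties -> lower
        frequency).

        Pulsatile population rhythms put substantial power into
        harmonics; when the half-frequency of the raw peak carries at
        least ``subharmonic_ratio`` of its power, the half-frequency is
        taken as the fundamental.
        """
        m = (self.freqs >= band[0]) & (self.freqs <= band[1])
        if not m.any() or not np.any(self.power[m] > 0):
            return None
        f, p = self.freqs[m], self.power[m]
        fstar = float(f[np.argmax(p)])
        pstar = p.max()
        half = (f >= fstar / 2.0 - 1.0) & (f <= fstar / 2.0 + 1.0)
        if half.any() and fstar / 2.0 >= band[0] \
                and p[half].max() >= subharmonic_ratio * pstar:
            return float(f[half][np.argmax(p[half])])
        return fstar


@dataclass
class ResonanceSummary:
    """Extracted resonance statistics of a response profile."""

    f_N: Optional[float] = None          # natural frequency, Hz
    f_R_pc: Optional[float] = None       # f_inp maximizing mean PC rate
    f_R_in: Optional[float] = None       # f_inp maximizing mean IN rate
    f_R_pop: Optional[float] = None      # f_inp maximizing f_pop
    f_N_sd: float = 0.0
    f_R_pc_sd: float = 0.0
    f_R_in_sd: float = 0.0
    f_R_pop_sd: float = 0.0
    pc_silent: bool = False

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("f_N", "f_R_pc", "f_R_in", "f_R_pop", "f_N_sd", "f_R_pc_sd",
                 "f_R_in_sd", "f_R_pop_sd", "pc_silent")}


def compute_ifr(raster: SpikeRaster, n_cells: int, sigma: float,
                window: Tuple[float, float], dt: float = IFR_DT_MS,
                population: str = "", width_convention: str = "sd"
                ) -> iFRTrace:
    """Gaussian kernel regression of the population rate on a time grid.

    ``sigma`` is the kernel width in ms -- by default the Gaussian
    standard deviation (``width_convention="sd"``); pass ``"fwhm"`` to
    interpret it as full width at half maximum instead.
    """
    if n_cells <= 0:
        raise ValueError("population must contain at least one cell")
    if sigma <= 0:
        raise ValueError("kernel width must be positive")
    if width_convention == "fwhm":
        sigma = sigma / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    elif width_convention != "sd":
        raise ValueError("width_convention must be 'sd' or 'fwhm'")
    t0, t1 = window
    edges = np.arange(t0, t1 + dt, dt)
    t = edges[:-1] + dt / 2.0
    times = raster.all_times()
    times = times[(times >= t0) & (times < edges[-1])]
    counts, _ = np.histogram(times, bins=edges)
    smoothed = gaussian_filter1d(counts.astype(float), sigma / dt,
                                 mode="constant")
    rate = smoothed / (n_cells * dt * 1e-3)   # spikes per second per cell
    return iFRTrace(t=t, rate=rate, sigma=sigma, population=population)


def mean_rate(trace: iFRTrace, window: Optional[Tuple[float, float]] = None
              ) -> float:
    """Time-averaged iFR (spikes/s per cell) over the analysis window."""
    if window is None:
        return float(trace.rate.mean())
    m = (trace.t >= window[0]) & (trace.t < window[1])
    if not m.any():
        raise ValueError("window does not overlap the trace")
    return float(trace.rate[m].mean())


def power_spectrum(trace: iFRTrace, nperseg: int = WELCH_NPERSEG,
                   overlap: float = 0.5, nfft: int = WELCH_NFFT
                   ) -> PowerSpectrum:
    fs = 1000.0 / IFR_DT_MS
    nper = int(min(nperseg, len(trace.rate)))
    nov = int(nper * overlap)
    f, p = welch(trace.rate, fs=fs, window="hann", nperseg=nper,
                 noverlap=nov, nfft=max(nfft, nper), detrend="constant")
    return PowerSpectrum(freqs=f, power=p, nperseg=nper, noverlap=nov)


def population_frequency(trace: iFRTrace,
                         band: Tuple[float, float] = SEARCH_BAND,
                         nperseg: int = WELCH_NPERSEG
                         ) -> Tuple[Optional[float], PowerSpectrum]:
    """Peak frequency of the Welch spectrum of the iFR.

    Returns ``(f_pop, spectrum)``; ``f_pop`` is None when the spectrum is
    flat (no spiking), so callers can distinguish "no oscillation" from a
    measured frequency.
    """
    spec = power_spectrum(trace, nperseg=nperseg)
    if trace.rate.max() <= 0:
        return None, spec
    return spec.peak(band), spec


def nested_oscillation(spectrum: PowerSpectrum, f_inp: float,
                       band: Tuple[float, float] = SEARCH_BAND,
                       secondary_ratio: float = 0.5,
                       primary_factor: float = 1.5) -> bool:
    """Flag spectra shaped by nested oscillations.

    A trial is "nested" when the spectrum has a secondary local peak with
    at least ``secondary_ratio`` of the primary peak's power and the
    primary lies above ``primary_factor * f_inp`` -- the signature of an
    internally generated rhythm riding on the depolarizing phase of a
    slower external drive.  Thresholds are documented choices.
    """
    m = (spectrum.freqs >= band[0]) & (spectrum.freqs <= band[1])
    f, p = spectrum.freqs[m], spectrum.power[m]
    if len(p) == 0 or p.max() <= 0:
        return False
    f_primary = f[np.argmax(p)]
    idx, _ = find_peaks(p)
    if len(idx) >= 2:
        peak_powers = np.sort(p[idx])[::-1]
        has_secondary = peak_powers[1] >= secondary_ratio * peak_powers[0]
    else:
        has_secondary = False
    return bool(has_secondary and f_primary > primary_factor * f_inp)


def spectral_sharpness(spectrum: PowerSpectrum,
                       band: Tuple[float, float] = SEARCH_BAND) -> float:
    """Peak power over median power in the search band -- an index of
    how strongly a single rhythm dominates the iFR."""
    m = (spectrum.freqs >= band[0]) & (spectrum.freqs <= band[1])
    p = spectrum.power[m]
    med = np.median(p)
    return float(p.max() / med) if med > 0 else 0.0


def natural_frequency(network_spec, r_inp: float, seeds,
                      duration: float = 1500.0, onset: float = 400.0,
                      dt: float = 0.01, sigma: float = 2.0,
                      population: Optional[str] = None,
                      min_sharpness: Optional[float] = None):
    """Median f_pop across seeds under equal-strength asynchronous drive.

    Returns ``(f_N, per-seed list)``; ``f_N`` is None when no oscillation
    is produced (e.g. feedback inhibition too weak for a natural
    rhythm).  When ``min_sharpness`` is given, seeds whose iFR spectrum
    has peak/median band power below it are treated as non-oscillatory
    and contribute None.
    """
    from .network import run_trial
    from .rates import make_rate_program

    pops = [n for n in network_spec.pc_names]
    target = population or pops[0]
    values = []
    for s in seeds:
        progs = [make_rate_program("asynchronous", r_inp=r_inp,
                                   onset=onset, duration=duration, dt=dt)
                 if name == target else None for name in network_spec.pc_names]
        res = run_trial(network_spec, progs, seed=s, duration=duration,
                        dt=dt, onset=onset)
        trace = compute_ifr(res.rasters[target],
                            n_cells=res.rasters[target].n_sources,
                            sigma=sigma, window=res.analysis_window)
        f_pop, spectrum = population_frequency(trace)
        if (f_pop is not None and min_sharpness is not None
                and spectral_sharpness(spectrum) < min_sharpness):
            f_pop = None
        values.append(f_pop)
    good = [v for v in values if v is not None]
    if not good:
        return None, values
    return float(np.median(good)), values
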