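"""Rate-modulated Poisson input signals.

Upstream source populations are modelled as collections of independent
inhomogeneous Poisson spike trains sharing a deterministic instantaneous
rate trajectory ``lambda(t)``.  Three dynamical states of the source are
supported:

* ``asynchronous`` -- constant rate ``r_inp``,
* ``sine`` -- sinusoidal rate modulation at frequency ``f_inp``,
* ``square_fixed_mean`` -- periodic rectangular pulses of width
  ``delta_inp`` whose amplitude is chosen so the time-averaged rate stays
  ``r_inp`` for every modulation frequency (pulse packets with fixed
  total spike count), and
* ``square_fixed_amplitude`` -- rectangular pulses with a fixed amplitude
  ``r_p`` so the time-averaged rate grows with ``f_inp * delta_inp``.

Rates are in spikes/s, times in ms throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "RateProgram",
    "SpikeRaster",
    "make_rate_program",
    "draw_poisson_spikes",
    "background_drive",
]

_KINDS = ("asynchronous", "sine", "square_fixed_mean", "square_fixed_amplitude")


@dataclass(frozen=True)
class RateProgram:
    """Deterministic instantaneous-rate trajectory of an input signal.

    Attributes
    ----------
    kind:
        One of ``asynchronous``, ``sine``, ``square_fixed_mean``,
        ``square_fixed_amplitude``.
    r_inp:
        Time-averaged rate in spikes/s (for the fixed-amplitude square
        wave this is the *nominal* rate; the realized mean varies with
        ``f_inp``).
    f_inp:
        Modulation frequency in Hz (periodic kinds only).
    delta_inp:
        Pulse width in ms (square kinds only).
    r_p:
        Pulse amplitude in spikes/s (fixed-amplitude kind only).
    onset:
        Signal start time in ms; ``lambda(t) = 0`` for ``t < onset``.
    duration:
        Total program duration in ms.
    dt:
        Sampling step of the simulation grid in ms.
    normalization:
        Sine convention: ``"half"`` uses
        ``lambda(t) = r_inp (1 + sin(2 pi f t)) / 2`` (time average
        ``r_inp / 2``); ``"mean_matched"`` rescales so the time average
        equals ``r_inp``, matching the strength of the other waveforms.
    phase:
        Phase convention for periodic kinds; the modulation cycle starts
        at ``onset`` (first square pulse begins at onset).
    """

    kind: str
    r_inp: float
    f_inp: Optional[float] = None
    delta_inp: Optional[float] = None
    r_p: Optional[float] = None
    onset: float = 0.0
    duration: float = 1000.0
    dt: float = 0.01
    normalization: str = "half"
    _lam: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown rate-program kind: {self.kind!r}")
        if self.r_inp < 0:
            raise ValueError("r_inp must be >= 0")
        if self.kind != "asynchronous":
            if self.f_inp is None or self.f_inp <= 0:
                raise ValueError("periodic kinds require f_inp > 0")
        if self.kind.startswith("square"):
            if self.delta_inp is None or self.delta_inp <= 0:
                raise ValueError("square kinds require delta_inp > 0")
            if self.duty_cycle > 1.0 + 1e-12:
                raise ValueError(
                    f"duty cycle {self.duty_cycle:.3f} > 1 "
                    f"(delta_inp={self.delta_inp} ms, f_inp={self.f_inp} Hz)"
                )
        if self.kind == "square_fixed_amplitude":
            if self.r_p is None or self.r_p < 0:
                raise ValueError("square_fixed_amplitude requires r_p >= 0")
        if self.normalization not in ("half", "mean_matched"):
            raise ValueError("normalization must be 'half' or 'mean_matched'")
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")
        n = round(self.duration / self.dt)
        if abs(n * self.dt - self.duration) > 1e-9 * max(1.0, self.duration):
            raise ValueError("dt must divide duration")
        object.__setattr__(self, "_lam", self._sample())

    # -- derived quantities -------------------------------------------------

    @property
    def duty_cycle(self) -> float:
        if not self.kind.startswith("square"):
            return 1.0
        return self.delta_inp * self.f_inp / 1000.0

    @property
    def pulse_amplitude(self) -> float:
        """Amplitude of the rectangular pulse in spikes/s.

        For the fixed-mean square wave the amplitude follows from the
        constraint that pulses of width ``delta_inp`` repeated at
        ``f_inp`` average to ``r_inp``:
        ``amplitude = r_inp / (f_inp * delta_inp)`` with the pulse width
        expressed in seconds.
        """
        if self.kind == "square_fixed_mean":
            return self.r_inp / self.duty_cycle
        if self.kind == "square_fixed_amplitude":
            return float(self.r_p)
        raise AttributeError("pulse_amplitude is defined for square kinds only")

    @property
    def times(self) -> np.ndarray:
        n = round(self.duration / self.dt)
        return np.arange(n + 1) * self.dt

    @property
    def values(self) -> np.ndarray:
        """lambda(t) in spikes/s on the simulation grid (including endpoint)."""
        return self._lam

    def mean_rate(self) -> float:
        """Time-averaged rate after onset, in spikes/s."""
        mask = self.times >= self.onset
        return float(np.trapezoid(self._lam[mask], dx=self.dt)
                     / (self.times[mask][-1] - self.onset + self.dt))

    # -- sampling -----------------------------------------------------------

    def _sample(self) -> np.ndarray:
        t = self.times
        lam = np.zeros_like(t)
        on = t >= self.onset
        ts = t[on] - self.onset  # time since signal onset, ms
        if self.kind == "asynchronous":
            lam[on] = self.r_inp
        elif self.kind == "sine":
            base = self.r_inp * (1.0 + np.sin(2e-3 * np.pi * self.f_inp * ts)) / 2.0
            if self.normalization == "mean_matched":
                base = 2.0 * base
            lam[on] = base
        else:
            amp = self.pulse_amplitude
            phase = np.mod(ts, 1000.0 / self.f_inp)
            lam[on] = np.where(phase < self.delta_inp, amp, 0.0)
        return lam

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in
             ("kind", "r_inp", "f_inp", "delta_inp", "r_p", "onset",
              "duration", "dt", "normalization")}
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "RateProgram":
        return cls(**json.loads(s))


@dataclass(frozen=True)
class SpikeRaster:
    """Spike times per source/cell over a simulation window.

    ``trains`` holds one strictly increasing array of spike times (ms)
    per source.  Used both for generated inputs and recorded outputs.
    """

    trains: tuple
    window: tuple

    def __post_init__(self):
        t0, t1 = self.window
        for tr in self.trains:
            if len(tr) and (tr[0] < t0 or tr[-1] > t1):
                raise ValueError("spike time outside raster window")
            if len(tr) > 1 and np.any(np.diff(tr) <= 0):
                raise ValueError("spike times must be strictly increasing")

    @property
    def n_sources(self) -> int:
        return len(self.trains)

    @property
    def n_spikes(self) -> int:
        return int(sum(len(tr) for tr in self.trains))

    def all_times(self) -> np.ndarray:
        if not self.trains:
            return np.empty(0)
        return np.sort(np.concatenate([np.asarray(tr) for tr in self.trains]))

    def to_dataframe(self):
        import pandas as pd

        sid = np.concatenate(
            [np.full(len(tr), i, dtype=int) for i, tr in enumerate(self.trains)]
        ) if self.trains else np.empty(0, dtype=int)
        tms = (np.concatenate([np.asarray(tr) for tr in self.trains])
               if self.trains else np.empty(0))
        return pd.DataFrame({"source_id": sid, "time_ms": tms})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, window) -> "SpikeRaster":
        import pandas as pd

        df = pd.read_csv(path)
        n = int(df["source_id"].max()) + 1 if len(df) else 0
        trains = tuple(
            np.sort(df.loc[df["source_id"] == i, "time_ms"].to_numpy())
            for i in range(n)
        )
        return cls(trains=trains, window=tuple(window))


def make_rate_program(kind, r_inp, f_inp=None, delta_inp=None, r_p=None,
                      onset=0.0, duration=1000.0, dt=0.01,
                      normalization="half") -> RateProgram:
    """Construct a :class:`RateProgram` sampled on the simulation grid."""
    return RateProgram(kind=kind, r_inp=r_inp, f_inp=f_inp,
                       delta_inp=delta_inp, r_p=r_p, onset=onset,
                       duration=duration, dt=dt, normalization=normalization)


def _source_rngs(seed: int, n_sources: int):
    """Independent per-source streams derived from (master seed, source index)."""
    ss = np.random.SeedSequence(seed)
    return [np.random.Generator(np.random.PCG64(c)) for c in ss.spawn(n_sources)]


def draw_poisson_spikes(rate_program: RateProgram, n_sources: int,
                        seed: int) -> SpikeRaster:
    """Sample independent inhomogeneous Poisson trains from a rate program.

    Sampling is by thinning on the ``dt`` grid: each bin emits at most one
    spike per source with probability ``lambda(t) dt`` (occupancy is far
    below one at the default dt = 0.01 ms).  Bit-reproducible for a fixed
    seed; per-source streams are derived from ``(seed, source index)`` so
    a raster for ``n_sources`` is a prefix-stable extension of a smaller
    one.
    """
    if n_sources < 0:
        raise ValueError("n_sources must be >= 0")
    lam = rate_program.values[:-1]  # rate at the left edge of each bin
    p = lam * rate_program.dt * 1e-3  # sp/s * ms -> probability per bin
    if np.any(p > 1.0):
        raise ValueError("lambda * dt exceeds 1; decrease dt")
    t_left = rate_program.times[:-1]
    trains = []
    nonzero = p.max() > 0
    for rng in _source_rngs(seed, n_sources):
        if not nonzero:
            trains.append(np.empty(0))
            continue
        hits = rng.random(p.shape) < p
        # spike at bin close; guard against float round-up at the window end
        trains.append(np.minimum(t_left[hits] + rate_program.dt,
                                 rate_program.duration))
    return SpikeRaster(trains=tuple(trains),
                       window=(0.0, rate_program.duration))


def background_drive(duration, seed, n_cells=100, rate=1.0,
                     dt=0.01) -> SpikeRaster:
    """Uncorrelated background spiking: ``n_cells`` Poisson sources at ``rate`` sp/s."""
    prog = make_rate_program("asynchronous", r_inp=rate, duration=duration,
                             dt=dt)
    return draw_poisson_spikes(prog, n_sources=n_cells, seed=seed)
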