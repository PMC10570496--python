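"""Evaluation indices for simulated LFPs.

Three quantities summarise a run:

* **Power spectrum** — one-sided FFT power of a mean-subtracted LFP
  segment (rectangular window, no taper); the dominant frequency is the
  argmax bin above 0 Hz.
* **Oscillation index (OI)** — mean squared deviation of an LFP over the
  final simulated second; low OI means the rhythm is suppressed.
* **Energy index (EI)** — mean squared stimulation signal over the
  post-onset window (the final two seconds of the default protocol); a
  proxy for stimulation energy expenditure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .model import NUCLEI

__all__ = [
    "Spectrum",
    "MetricsReport",
    "power_spectrum",
    "oscillation_index",
    "energy_index",
    "trace_extrema",
    "compute_metrics",
]

#: Below this total power (mV²) a spectrum is considered flat and its
#: dominant frequency undefined.
_FLAT_POWER = 1e-20


@dataclass
class Spectrum:
    """One-sided power spectrum of an LFP segment.

    ``power`` sums to the segment variance (Parseval, rectangular window);
    ``dominant_freq`` is NaN for a flat (constant) segment.
    """

    freqs: np.ndarray  # Hz, ascending from 0
    power: np.ndarray  # mV² per bin
    dominant_freq: float  # Hz
    dominant_power: float  # mV²

    @property
    def resolution(self) -> float:
        """Frequency-bin width in Hz (reciprocal of the window length)."""
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class MetricsReport:
    """Per-run summary: OI per nucleus, EI, and spectra per nucleus."""

    oi_stn: float
    oi_gpe: float
    oi_ppn: float
    ei: float
    spectra: Dict[str, Spectrum] = field(default_factory=dict)

    def oi(self, nucleus: str) -> float:
        return {"stn": self.oi_stn, "gpe": self.oi_gpe, "ppn": self.oi_ppn}[
            nucleus.lower()
        ]

    @property
    def oi_sum(self) -> float:
        return self.oi_stn + self.oi_gpe + self.oi_ppn

    def dominant_freqs(self) -> Dict[str, float]:
        return {name: spec.dominant_freq for name, spec in self.spectra.items()}


def _steps(seconds: float, dt: float) -> int:
    return int(round(seconds / dt))


def power_spectrum(
    lfp: np.ndarray, dt: float, window: Optional[Tuple[float, float]] = None
) -> Spectrum:
    """Power spectrum of ``lfp`` over ``window = (t_start, t_end)`` seconds.

    The window mean is subtracted (removing the DC component), a plain DFT
    with rectangular window is applied, and one-sided power is returned
    normalised so that the bins sum to the windowed signal variance.  The
    window defaults to the whole trace and must span at least 1 s, which
    bounds the frequency resolution by 1 Hz.
    """
    lfp = np.asarray(lfp, dtype=np.float64)
    n_total = lfp.size
    if window is None:
        i0, i1 = 0, n_total
    else:
        t_start, t_end = window
        i0, i1 = _steps(t_start, dt), _steps(t_end, dt)
        if i0 < 0 or i1 > n_total or i1 <= i0:
            raise ValueError(
                f"window {window} s outside trace of {n_total * dt:.4f} s"
            )
    n = i1 - i0
    if n * dt < 1.0 - 1e-9:
        raise ValueError(
            f"spectrum window of {n * dt:.4f} s is shorter than 1 s; "
            "frequency resolution would be too coarse"
        )
    seg = lfp[i0:i1]
    seg = seg - seg.mean()
    amp = np.fft.rfft(seg)
    power = (np.abs(amp) ** 2) / n**2
    # fold negative frequencies into the positive bins (one-sided spectrum)
    power[1:] *= 2.0
    if n % 2 == 0:
        power[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, dt)
    if power[1:].sum() < _FLAT_POWER:
        dom_f, dom_p = math.nan, 0.0
    else:
        k = 1 + int(np.argmax(power[1:]))
        dom_f, dom_p = float(freqs[k]), float(power[k])
    return Spectrum(freqs=freqs, power=power, dominant_freq=dom_f, dominant_power=dom_p)


def _last_second(trace: np.ndarray, dt: float) -> np.ndarray:
    m = _steps(1.0, dt)
    if trace.size < 3 * m:
        raise ValueError(
            f"trace of {trace.size * dt:.4f} s too short; need at least 3 s at dt={dt}"
        )
    return trace[trace.size - m :]


def oscillation_index(lfp: np.ndarray, dt: float, sqrt: bool = False) -> float:
    """Oscillation index: mean squared deviation over the final second.

    ``OI = Σ (v_i − mean(v))² / (1/dt)`` with the sum and mean taken over
    the last second of the trace, excluding the onset transient.  This is
    the biased variance of the final-second window; ``sqrt=True`` returns
    its square root (an RMS amplitude) instead.  Adding a constant to the
    trace leaves OI unchanged.
    """
    lfp = np.asarray(lfp, dtype=np.float64)
    seg = _last_second(lfp, dt)
    oi = float(np.sum((seg - seg.mean()) ** 2) / seg.size)
    return math.sqrt(oi) if sqrt else oi


def energy_index(w_trace: np.ndarray, dt: float) -> float:
    """Energy index: mean squared stimulation signal after the first second.

    ``EI = Σ w_i² / (2/dt)`` with the sum over samples from 1 s to the end
    of the 3 s protocol — the two seconds during which stimulation may be
    active.  Zero without stimulation; scales quadratically with the
    signal amplitude.
    """
    w_trace = np.asarray(w_trace, dtype=np.float64)
    m = _steps(1.0, dt)
    if w_trace.size < 3 * m:
        raise ValueError(
            f"trace of {w_trace.size * dt:.4f} s too short; need at least 3 s at dt={dt}"
        )
    seg = w_trace[m:]
    return float(np.sum(seg**2) / (2 * m))


def trace_extrema(lfp: np.ndarray, dt: float) -> Tuple[float, float]:
    """(max, min) of the LFP over the final second, for bifurcation plots."""
    seg = _last_second(np.asarray(lfp, dtype=np.float64), dt)
    return float(seg.max()), float(seg.min())


def compute_metrics(result, window: Optional[Tuple[float, float]] = None) -> MetricsReport:
    """Full `MetricsReport` for a `SimulationResult`.

    The spectrum window defaults to the whole trace for unstimulated runs
    and to the post-onset segment (onset → T) for stimulated ones, so the
    onset transient never leaks into stimulated-run spectra.
    """
    cfg = result.config
    if window is None and cfg.scheme is not None:
        window = (cfg.scheme.onset, cfg.T)
    spectra = {
        name: power_spectrum(result.lfp(name), cfg.dt, window) for name in NUCLEI
    }
    return MetricsReport(
        oi_stn=oscillation_index(result.v_stn, cfg.dt),
        oi_gpe=oscillation_index(result.v_gpe, cfg.dt),
        oi_ppn=oscillation_index(result.v_ppn, cfg.dt),
        ei=energy_index(result.w_trace, cfg.dt),
        spectra=spectra,
    )
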