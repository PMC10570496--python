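"""Delayed feedback stimulation.

The control signal is the linear delayed-feedback law

    w(t) = K · (v_src(t − τ) − v_src(t)),

where ``v_src`` is the LFP of a source nucleus, ``K`` the stimulation
intensity and ``τ`` the delay.  The signal is injected as a potential
offset into the sigmoid of a single target nucleus, starting at an onset
time.  Four preset strategies are provided:

=========  ======  ======  =====  =======
strategy   target  source  K      τ (ms)
=========  ======  ======  =====  =======
A          STN     STN      0.4   25
B          GPe     GPe     −2      2
C          GPe     PPN     −2      4
D          STN     PPN      3      8
=========  ======  ======  =====  =======

Strategy A is the traditional self-stimulation of STN; B–D involve the
GPe/PPN pathways.  The sign of an effective intensity follows the target's
synapse character: the excitatory STN responds to positive K (A, D), the
inhibitory GPe to negative K (B, C).  Note that C pairs the inhibitory GPe
target with the PPN-derived control signal; pairing the excitatory PPN
with a negative-K GPe-derived signal does not suppress the rhythm at any
intensity (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Optional, Tuple

import numpy as np

from .model import NUCLEI, ConfigurationError

__all__ = [
    "StimulationScheme",
    "DelayBuffer",
    "SCHEME_PRESETS",
    "get_scheme",
    "feedback_signal",
    "route_stimulation",
]


@dataclass(frozen=True)
class StimulationScheme:
    """One delayed-feedback stimulation configuration.

    Parameters
    ----------
    target : str
        Nucleus receiving the signal ("stn", "gpe" or "ppn").
    source : str
        Nucleus whose LFP drives the signal.
    K : float
        Stimulation intensity (dimensionless).
    tau : float
        Time delay in seconds.
    onset : float
        Stimulation start time in seconds (default 1 s).
    """

    target: str
    source: str
    K: float
    tau: float
    onset: float = 1.0

    def __post_init__(self) -> None:
        for role, name in (("target", self.target), ("source", self.source)):
            if name.lower() not in NUCLEI:
                raise ConfigurationError(
                    f"unknown {role} nucleus {name!r}; expected one of {NUCLEI}"
                )
        object.__setattr__(self, "target", self.target.lower())
        object.__setattr__(self, "source", self.source.lower())
        if not (self.tau >= 0):
            raise ConfigurationError(f"delay tau must be >= 0 s, got {self.tau}")
        if not (self.onset >= 0):
            raise ConfigurationError(f"onset must be >= 0 s, got {self.onset}")

    @classmethod
    def from_ms(
        cls, target: str, source: str, K: float, tau_ms: float, onset: float = 1.0
    ) -> "StimulationScheme":
        """Build a scheme with the delay given in milliseconds."""
        return cls(target=target, source=source, K=K, tau=tau_ms * 1e-3, onset=onset)

    @property
    def tau_ms(self) -> float:
        return self.tau * 1e3

    def with_params(
        self, K: Optional[float] = None, tau_ms: Optional[float] = None
    ) -> "StimulationScheme":
        """Copy of this scheme with intensity and/or delay replaced."""
        out = self
        if K is not None:
            out = replace(out, K=K)
        if tau_ms is not None:
            out = replace(out, tau=tau_ms * 1e-3)
        return out

    def delay_steps(self, dt: float) -> int:
        """Delay rounded to the nearest integer number of steps.

        At dt = 0.1 ms all preset delays (25, 2, 4, 8 ms) are exact
        multiples, so rounding introduces no error for them.
        """
        return int(round(self.tau / dt))


SCHEME_PRESETS: Dict[str, StimulationScheme] = {
    "A": StimulationScheme.from_ms("stn", "stn", K=0.4, tau_ms=25.0),
    "B": StimulationScheme.from_ms("gpe", "gpe", K=-2.0, tau_ms=2.0),
    "C": StimulationScheme.from_ms("gpe", "ppn", K=-2.0, tau_ms=4.0),
    "D": StimulationScheme.from_ms("stn", "ppn", K=3.0, tau_ms=8.0),
}


def get_scheme(name: str) -> StimulationScheme:
    """Look up a preset strategy by name ("A".."D", case-insensitive)."""
    try:
        return SCHEME_PRESETS[name.upper()]
    except KeyError:
        raise ConfigurationError(
            f"unknown scheme {name!r}; presets are {sorted(SCHEME_PRESETS)}"
        ) from None


class DelayBuffer:
    """Ring buffer of recent source-LFP samples for the delayed term.

    Holds the last ``capacity`` samples at spacing ``dt``; ``lagged(n)``
    returns the sample written ``n`` pushes ago.  The simulator keeps the
    full trace in memory and indexes it directly, but this class realises
    the same lookup with O(τ/dt) memory for streaming use and is the
    reference for the controller unit tests.
    """

    def __init__(self, max_lag_steps: int, dt: float):
        if max_lag_steps < 0:
            raise ConfigurationError("max_lag_steps must be >= 0")
        if not (dt > 0):
            raise ConfigurationError("dt must be > 0")
        self.dt = dt
        self._buf = np.zeros(max_lag_steps + 1, dtype=np.float64)
        self._cursor = 0  # next write position
        self._count = 0  # samples written so far

    def __len__(self) -> int:
        return min(self._count, self._buf.size)

    def push(self, value: float) -> None:
        self._buf[self._cursor] = value
        self._cursor = (self._cursor + 1) % self._buf.size
        self._count += 1

    def lagged(self, lag_steps: int) -> float:
        """Sample recorded ``lag_steps`` pushes before the most recent one."""
        if lag_steps < 0 or lag_steps >= self._buf.size:
            raise ConfigurationError(
                f"lag of {lag_steps} steps outside buffer capacity {self._buf.size - 1}"
            )
        if lag_steps >= self._count:
            raise RuntimeError(
                f"lag of {lag_steps} steps exceeds recorded history ({self._count})"
            )
        return float(self._buf[(self._cursor - 1 - lag_steps) % self._buf.size])


def feedback_signal(
    buffer: DelayBuffer, current_v: float, scheme: StimulationScheme, t: float
) -> float:
    """Stimulation signal at time ``t``; ``current_v`` must already be pushed.

    Returns 0 before the onset, otherwise ``K·(v(t−τ) − v(t))`` with the
    delayed sample read from the buffer.  Identically zero for τ = 0 and for
    a source LFP constant over the delay window.
    """
    if t < scheme.onset:
        return 0.0
    lag = scheme.delay_steps(buffer.dt)
    return scheme.K * (buffer.lagged(lag) - current_v)


def route_stimulation(
    scheme: Optional[StimulationScheme], w: float
) -> Tuple[float, float, float]:
    """Distribute the signal to per-nucleus sigmoid offsets (STN, GPe, PPN).

    Exactly one entry is nonzero (the scheme's target) whenever ``w`` is
    nonzero; with ``scheme=None`` all offsets are zero.
    """
    if scheme is None:
        return 0.0, 0.0, 0.0
    offsets = [0.0, 0.0, 0.0]
    offsets[NUCLEI.index(scheme.target)] = w
    return tuple(offsets)  # type: ignore[return-value]
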