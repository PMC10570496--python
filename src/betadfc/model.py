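"""Neural mass model of the STN–GPe–PPN loop.

Each nucleus (subthalamic nucleus, external globus pallidus,
pedunculopontine nucleus) is a lumped population characterised by an
average membrane potential ``v`` (mV, the local field potential) and an
average pulse density ``u`` (s⁻¹).  A synapse type is a critically damped
second-order low-pass filter ("linear block") with gain ``H`` and time
constant ``x``; a population's potential-to-rate conversion is a sigmoid
("nonlinear block") with ceiling ``r`` and slope ``y``.

The network wiring is fixed: GPe inhibits STN and itself, STN excites GPe
and PPN, PPN excites STN.  Cortex, striatum and GPi provide noisy external
drive.  The five internal pathway gains ``λ1..λ5`` switch the circuit
between a quiescent "normal" regime and a beta-oscillatory "pathological"
regime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

__all__ = [
    "NUCLEI",
    "PopulationParams",
    "CouplingConfig",
    "ChannelState",
    "ModelState",
    "STN_PARAMS",
    "GPE_PARAMS",
    "PPN_PARAMS",
    "NORMAL_COUPLING",
    "PATHOLOGICAL_COUPLING",
    "sigmoid_rate",
    "channel_derivative",
    "compose_lfp",
]

#: Canonical nucleus order used throughout the package (traces, offsets, CLI).
NUCLEI: Tuple[str, str, str] = ("stn", "gpe", "ppn")


class ConfigurationError(ValueError):
    """Raised for invalid model or simulation configuration."""


@dataclass(frozen=True)
class PopulationParams:
    """Constants of one population.

    Parameters
    ----------
    H : float
        Synaptic gain of the population's afferent channels (mV).
    x : float
        Lumped synaptic/dendritic time constant (s).
    r : float
        Maximum pulse density — the sigmoid ceiling (s⁻¹).
    y : float
        Sigmoid slope (mV⁻¹).
    """

    H: float
    x: float
    r: float
    y: float

    def __post_init__(self) -> None:
        if not (self.H >= 0):
            raise ConfigurationError(f"synaptic gain H must be >= 0, got {self.H}")
        if not (self.x > 0):
            raise ConfigurationError(f"time constant x must be > 0, got {self.x}")
        if not (self.r > 0):
            raise ConfigurationError(f"max pulse density r must be > 0, got {self.r}")
        if not (self.y > 0):
            raise ConfigurationError(f"sigmoid slope y must be > 0, got {self.y}")


# Default population constants (s = STN, g = GPe, p = PPN).
STN_PARAMS = PopulationParams(H=20.0, x=0.006, r=300.0, y=0.1)
GPE_PARAMS = PopulationParams(H=20.0, x=0.014, r=400.0, y=0.1)
PPN_PARAMS = PopulationParams(H=20.0, x=0.005, r=200.0, y=0.1)


@dataclass(frozen=True)
class CouplingConfig:
    """Pathway gains and external-input statistics.

    ``lambda1``: GPe→STN inhibition, ``lambda2``: STN→GPe excitation,
    ``lambda3``: GPe→GPe self-inhibition, ``lambda4``: STN→PPN excitation,
    ``lambda5``: PPN→STN excitation.  External pulse-density inputs from
    cortex, striatum and GPi are Gaussian, ``mean + sd·randn`` redrawn every
    integration step.
    """

    lambda1: float
    lambda2: float
    lambda3: float
    lambda4: float
    lambda5: float
    cor_mean: float = 27.0
    cor_sd: float = 0.1
    str_mean: float = 2.0
    str_sd: float = 0.1
    gpi_mean: float = 20.0
    gpi_sd: float = 0.1

    def __post_init__(self) -> None:
        for name in ("lambda1", "lambda2", "lambda3", "lambda4", "lambda5"):
            if not (getattr(self, name) >= 0):
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("cor_sd", "str_sd", "gpi_sd"):
            if not (getattr(self, name) >= 0):
                raise ConfigurationError(f"{name} must be >= 0")

    @property
    def lambdas(self) -> Tuple[float, float, float, float, float]:
        return (self.lambda1, self.lambda2, self.lambda3, self.lambda4, self.lambda5)


#: Healthy-circuit pathway gains.
NORMAL_COUPLING = CouplingConfig(1.12, 19.0, 6.6, 10.0, 3.0)
#: Dopamine-depleted gains producing the ~22 Hz beta rhythm.
PATHOLOGICAL_COUPLING = CouplingConfig(5.0, 20.0, 2.0, 13.0, 1.0)

COUPLING_PRESETS = {
    "normal": NORMAL_COUPLING,
    "pathological": PATHOLOGICAL_COUPLING,
}


@dataclass
class ChannelState:
    """State of one second-order synaptic channel: potential and its rate."""

    v: float = 0.0  # postsynaptic contribution, mV
    z: float = 0.0  # dv/dt, mV/s


@dataclass
class ModelState:
    """Full model state: 8 synaptic channels, 16 scalar variables.

    STN receives three channels (GPe→STN inhibitory, Cor→STN excitatory,
    PPN→STN excitatory), GPe three (STN→GPe excitatory, GPe→GPe inhibitory,
    Str→GPe inhibitory), PPN two (GPi→PPN inhibitory, STN→PPN excitatory).
    """

    stn1: ChannelState = field(default_factory=ChannelState)
    stn2: ChannelState = field(default_factory=ChannelState)
    stn3: ChannelState = field(default_factory=ChannelState)
    gpe1: ChannelState = field(default_factory=ChannelState)
    gpe2: ChannelState = field(default_factory=ChannelState)
    gpe3: ChannelState = field(default_factory=ChannelState)
    ppn1: ChannelState = field(default_factory=ChannelState)
    ppn2: ChannelState = field(default_factory=ChannelState)

    _ORDER = ("stn1", "stn2", "stn3", "gpe1", "gpe2", "gpe3", "ppn1", "ppn2")

    def channels(self) -> Tuple[ChannelState, ...]:
        return tuple(getattr(self, name) for name in self._ORDER)

    def to_array(self) -> np.ndarray:
        """Flatten to the 16-vector (v, z per channel, canonical order)."""
        out = np.empty(16, dtype=np.float64)
        for k, ch in enumerate(self.channels()):
            out[2 * k] = ch.v
            out[2 * k + 1] = ch.z
        return out

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "ModelState":
        arr = np.asarray(arr, dtype=np.float64)
        if arr.shape != (16,):
            raise ValueError(f"state vector must have shape (16,), got {arr.shape}")
        state = cls()
        for k, name in enumerate(cls._ORDER):
            setattr(state, name, ChannelState(float(arr[2 * k]), float(arr[2 * k + 1])))
        return state


def sigmoid_rate(v: float, w_stim: float, pop: PopulationParams) -> float:
    """Convert a membrane potential to a pulse density.

    ``u = r / (1 + exp(−y·(v + w_stim)))`` where ``w_stim`` is the
    stimulation signal injected into this population (0 when unstimulated).
    Output is strictly within ``(0, r)`` and monotone in both arguments.
    """
    if not (math.isfinite(v) and math.isfinite(w_stim)):
        raise ValueError(f"non-finite sigmoid input: v={v}, w_stim={w_stim}")
    # clamp the exponent so extreme potentials saturate instead of overflowing
    a = min(-pop.y * (v + w_stim), 700.0)
    return pop.r / (1.0 + math.exp(a))


def channel_derivative(
    state: ChannelState, u_in: float, gain: float, x: float
) -> Tuple[float, float]:
    """Time derivative of one synaptic channel.

    The channel is the critically damped filter ``x²·v'' + 2x·v' + v =
    gain·x·u`` written as a first-order system: ``dv/dt = z`` and
    ``dz/dt = (gain/x)·u − (2/x)·z − (1/x²)·v``.  ``gain`` is the effective
    synaptic gain (``λ·H`` for internal pathways, plain ``H`` for external
    drive).  At constant input the equilibrium potential is ``gain·x·u``.
    """
    if not (x > 0):
        raise ConfigurationError(f"time constant x must be > 0, got {x}")
    dv = state.z
    dz = (gain / x) * u_in - (2.0 / x) * state.z - state.v / (x * x)
    return dv, dz


def compose_lfp(state: ModelState) -> Tuple[float, float, float]:
    """Local field potentials of the three nuclei.

    Signs encode the synapse type: excitatory channels add, inhibitory
    channels subtract.

    ``v_STN = stn3 + stn2 − stn1``;
    ``v_GPe = gpe1 − gpe2 − gpe3``;
    ``v_PPN = ppn2 − ppn1``.
    """
    v_stn = state.stn3.v + state.stn2.v - state.stn1.v
    v_gpe = state.gpe1.v - state.gpe2.v - state.gpe3.v
    v_ppn = state.ppn2.v - state.ppn1.v
    return v_stn, v_gpe, v_ppn
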