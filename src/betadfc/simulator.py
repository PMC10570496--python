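"""Closed-loop forward-Euler simulation of the STN–GPe–PPN model.

A run integrates the 16 channel variables for ``T`` seconds at step ``dt``
(defaults 3 s, 0.1 ms) with Gaussian external drive redrawn every step,
records the three LFPs and the applied stimulation signal, and is
bit-for-bit reproducible from its seed.  The hot loop is JIT-compiled with
numba; a plain-Python single step (`step`) is exposed as the reference
update and for unit testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
from numba import njit

from .controller import StimulationScheme
from .model import (
    GPE_PARAMS,
    NUCLEI,
    PPN_PARAMS,
    STN_PARAMS,
    ChannelState,
    ConfigurationError,
    CouplingConfig,
    ModelState,
    PopulationParams,
    channel_derivative,
    compose_lfp,
    sigmoid_rate,
)

__all__ = [
    "DEFAULT_PARAMS",
    "SimulationConfig",
    "SimulationResult",
    "DivergenceError",
    "draw_external_inputs",
    "step",
    "simulate",
]

#: Default per-nucleus population constants.
DEFAULT_PARAMS: Dict[str, PopulationParams] = {
    "stn": STN_PARAMS,
    "gpe": GPE_PARAMS,
    "ppn": PPN_PARAMS,
}

#: RNG family used for the external drive; recorded in run metadata.
GENERATOR_FAMILY = "numpy.random.Generator(PCG64)"


class DivergenceError(RuntimeError):
    """Raised when the state becomes non-finite during integration."""

    def __init__(self, step_index: int, t: float):
        self.step_index = step_index
        self.t = t
        super().__init__(
            f"simulation diverged (non-finite state) at step {step_index} (t={t:.4f} s)"
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Integration settings for one run.

    ``T`` total duration (s), ``dt`` Euler step (s), ``seed`` for the
    external noise, ``scheme`` the stimulation strategy (None = no
    stimulation).  The default grid is 30000 steps of 0.1 ms.
    """

    T: float = 3.0
    dt: float = 1e-4
    seed: int = 0
    scheme: Optional[StimulationScheme] = None
    initial_state: Optional[ModelState] = None

    def __post_init__(self) -> None:
        if not (self.T > 0):
            raise ConfigurationError(f"duration T must be > 0, got {self.T}")
        if not (0 < self.dt < self.T):
            raise ConfigurationError(f"require 0 < dt < T, got dt={self.dt}")
        if self.scheme is not None:
            if not (self.scheme.onset < self.T):
                raise ConfigurationError(
                    f"stimulation onset {self.scheme.onset} s not before T={self.T} s"
                )
            if self.scheme.tau > self.scheme.onset:
                raise ConfigurationError(
                    f"delay tau={self.scheme.tau} s exceeds onset "
                    f"{self.scheme.onset} s: no history available at stimulation start"
                )

    @property
    def n_steps(self) -> int:
        n = self.T / self.dt
        n_int = int(round(n))
        if abs(n - n_int) > 1e-9 * max(1.0, n):
            raise ConfigurationError(f"T/dt = {n} is not an integer step count")
        return n_int


@dataclass
class SimulationResult:
    """Time grid, LFP traces, stimulation-signal trace and config echo.

    ``t[i] = i·dt`` is the time of the state the i-th samples were read
    from; ``w_trace`` is identically zero before the onset and for
    unstimulated runs.
    """

    t: np.ndarray
    v_stn: np.ndarray
    v_gpe: np.ndarray
    v_ppn: np.ndarray
    w_trace: np.ndarray
    config: SimulationConfig
    generator_family: str = GENERATOR_FAMILY

    def lfp(self, nucleus: str) -> np.ndarray:
        """LFP trace of one nucleus by name ("stn"/"gpe"/"ppn")."""
        try:
            return {"stn": self.v_stn, "gpe": self.v_gpe, "ppn": self.v_ppn}[
                nucleus.lower()
            ]
        except KeyError:
            raise ConfigurationError(f"unknown nucleus {nucleus!r}") from None

    def lfps(self) -> Dict[str, np.ndarray]:
        return {name: self.lfp(name) for name in NUCLEI}


def draw_external_inputs(
    rng: np.random.Generator, coupling: CouplingConfig
) -> Tuple[float, float, float]:
    """One step of external drive: (u_Cor, u_Str, u_GPi) in s⁻¹.

    Each input is ``mean + sd·ξ`` with independent standard-normal ξ, drawn
    in the fixed order (Cor, Str, GPi) from the run's single stream.  With
    all sd = 0 the means are returned exactly.
    """
    xi = rng.standard_normal(3)
    return (
        coupling.cor_mean + coupling.cor_sd * xi[0],
        coupling.str_mean + coupling.str_sd * xi[1],
        coupling.gpi_mean + coupling.gpi_sd * xi[2],
    )


def _input_array(
    rng: np.random.Generator, coupling: CouplingConfig, n: int
) -> np.ndarray:
    """All n steps of external drive at once; stream-identical to n calls
    of :func:`draw_external_inputs` on the same generator."""
    xi = rng.standard_normal((n, 3))
    means = np.array([coupling.cor_mean, coupling.str_mean, coupling.gpi_mean])
    sds = np.array([coupling.cor_sd, coupling.str_sd, coupling.gpi_sd])
    return means + sds * xi


def step(
    state: ModelState,
    inputs: Tuple[float, float, float],
    offsets: Tuple[float, float, float],
    params: Mapping[str, PopulationParams],
    coupling: CouplingConfig,
    dt: float,
) -> ModelState:
    """One explicit Euler update of the full model (reference implementation).

    ``inputs`` are the external pulse densities (u_Cor, u_Str, u_GPi);
    ``offsets`` the per-nucleus stimulation potentials (w_STN, w_GPe,
    w_PPN).  The current LFPs are converted to pulse densities through the
    sigmoids (with offsets applied), all eight channel derivatives are
    evaluated at the current state, and every (v, z) pair is advanced by
    ``dt``.
    """
    stn, gpe, ppn = params["stn"], params["gpe"], params["ppn"]
    u_cor, u_str, u_gpi = inputs
    w_stn, w_gpe, w_ppn = offsets

    v_stn, v_gpe, v_ppn = compose_lfp(state)
    u_stn = sigmoid_rate(v_stn, w_stn, stn)
    u_gpe = sigmoid_rate(v_gpe, w_gpe, gpe)
    u_ppn = sigmoid_rate(v_ppn, w_ppn, ppn)

    # (channel, drive, effective gain, time constant) for all 8 pathways
    wiring = (
        (state.stn1, u_gpe, coupling.lambda1 * stn.H, stn.x),
        (state.stn2, u_cor, stn.H, stn.x),
        (state.stn3, u_ppn, coupling.lambda5 * stn.H, stn.x),
        (state.gpe1, u_stn, coupling.lambda2 * gpe.H, gpe.x),
        (state.gpe2, u_gpe, coupling.lambda3 * gpe.H, gpe.x),
        (state.gpe3, u_str, gpe.H, gpe.x),
        (state.ppn1, u_gpi, ppn.H, ppn.x),
        (state.ppn2, u_stn, coupling.lambda4 * ppn.H, ppn.x),
    )
    new = ModelState()
    for ch_new, (ch, u_in, gain, x) in zip(new.channels(), wiring):
        dv, dz = channel_derivative(ch, u_in, gain, x)
        ch_new.v = ch.v + dt * dv
        ch_new.z = ch.z + dt * dz
    return new


@njit(cache=False)
def _euler_loop(
    state,
    inputs,
    dt,
    onset_idx,
    target,
    source,
    K,
    lag,
    Hs, xs, rs, ys,
    Hg, xg, rg, yg,
    Hp, xp, rp, yp,
    l1, l2, l3, l4, l5,
):  # pragma: no cover - exercised through simulate()
    n = inputs.shape[0]
    traces = np.zeros((n, 3))
    w_tr = np.zeros(n)
    for i in range(n):
        v_stn = state[4] + state[2] - state[0]
        v_gpe = state[6] - state[8] - state[10]
        v_ppn = state[14] - state[12]
        if not (
            math.isfinite(v_stn) and math.isfinite(v_gpe) and math.isfinite(v_ppn)
        ):
            return traces, w_tr, state, i
        traces[i, 0] = v_stn
        traces[i, 1] = v_gpe
        traces[i, 2] = v_ppn

        w_s = 0.0
        w_g = 0.0
        w_p = 0.0
        if target >= 0 and i >= onset_idx:
            w = K * (traces[i - lag, source] - traces[i, source])
            w_tr[i] = w
            if target == 0:
                w_s = w
            elif target == 1:
                w_g = w
            else:
                w_p = w

        u_stn = rs / (1.0 + math.exp(-ys * (v_stn + w_s)))
        u_gpe = rg / (1.0 + math.exp(-yg * (v_gpe + w_g)))
        u_ppn = rp / (1.0 + math.exp(-yp * (v_ppn + w_p)))
        u_cor = inputs[i, 0]
        u_str = inputs[i, 1]
        u_gpi = inputs[i, 2]

        # dz/dt = (gain/x)·u − (2/x)·z − v/x²  per channel, explicit Euler
        d0 = (l1 * Hs / xs) * u_gpe - (2.0 / xs) * state[1] - state[0] / (xs * xs)
        d1 = (Hs / xs) * u_cor - (2.0 / xs) * state[3] - state[2] / (xs * xs)
        d2 = (l5 * Hs / xs) * u_ppn - (2.0 / xs) * state[5] - state[4] / (xs * xs)
        d3 = (l2 * Hg / xg) * u_stn - (2.0 / xg) * state[7] - state[6] / (xg * xg)
        d4 = (l3 * Hg / xg) * u_gpe - (2.0 / xg) * state[9] - state[8] / (xg * xg)
        d5 = (Hg / xg) * u_str - (2.0 / xg) * state[11] - state[10] / (xg * xg)
        d6 = (Hp / xp) * u_gpi - (2.0 / xp) * state[13] - state[12] / (xp * xp)
        d7 = (l4 * Hp / xp) * u_stn - (2.0 / xp) * state[15] - state[14] / (xp * xp)

        state[0] += dt * state[1]
        state[1] += dt * d0
        state[2] += dt * state[3]
        state[3] += dt * d1
        state[4] += dt * state[5]
        state[5] += dt * d2
        state[6] += dt * state[7]
        state[7] += dt * d3
        state[8] += dt * state[9]
        state[9] += dt * d4
        state[10] += dt * state[11]
        state[11] += dt * d5
        state[12] += dt * state[13]
        state[13] += dt * d6
        state[14] += dt * state[15]
        state[15] += dt * d7
    return traces, w_tr, state, -1


def simulate(
    config: SimulationConfig,
    params: Optional[Mapping[str, PopulationParams]] = None,
    coupling: CouplingConfig = None,
    inputs: Optional[np.ndarray] = None,
) -> SimulationResult:
    """Run one full closed-loop simulation.

    Parameters
    ----------
    config : SimulationConfig
        Duration, step, seed, stimulation scheme.
    params : mapping, optional
        Per-nucleus `PopulationParams` keyed "stn"/"gpe"/"ppn"
        (default: the standard constants).
    coupling : CouplingConfig
        Pathway gains and input statistics (required).
    inputs : ndarray (n_steps, 3), optional
        Externally supplied drive (u_Cor, u_Str, u_GPi) per step; overrides
        the seeded noise.  Used e.g. for common-random-number step-size
        studies.

    Raises
    ------
    DivergenceError
        If any LFP becomes non-finite, with the offending step index.
    """
    if coupling is None:
        raise ConfigurationError("a CouplingConfig is required")
    if params is None:
        params = DEFAULT_PARAMS
    n = config.n_steps

    if inputs is None:
        rng = np.random.default_rng(config.seed)
        inputs = _input_array(rng, coupling, n)
    else:
        inputs = np.ascontiguousarray(inputs, dtype=np.float64)
        if inputs.shape != (n, 3):
            raise ConfigurationError(
                f"external inputs must have shape ({n}, 3), got {inputs.shape}"
            )

    scheme = config.scheme
    if scheme is None:
        target = source = -1
        K = 0.0
        lag = 0
        onset_idx = n
    else:
        target = NUCLEI.index(scheme.target)
        source = NUCLEI.index(scheme.source)
        K = scheme.K
        lag = scheme.delay_steps(config.dt)
        onset_idx = int(round(scheme.onset / config.dt))
        if lag > onset_idx:
            raise ConfigurationError(
                "delay exceeds available history at stimulation onset"
            )

    state0 = config.initial_state or ModelState()
    stn, gpe, ppn = params["stn"], params["gpe"], params["ppn"]
    traces, w_tr, _, bad = _euler_loop(
        state0.to_array(),
        inputs,
        config.dt,
        onset_idx,
        target,
        source,
        K,
        lag,
        stn.H, stn.x, stn.r, stn.y,
        gpe.H, gpe.x, gpe.r, gpe.y,
        ppn.H, ppn.x, ppn.r, ppn.y,
        coupling.lambda1,
        coupling.lambda2,
        coupling.lambda3,
        coupling.lambda4,
        coupling.lambda5,
    )
    if bad >= 0:
        raise DivergenceError(bad, bad * config.dt)
    t = np.arange(n) * config.dt
    return SimulationResult(
        t=t,
        v_stn=traces[:, 0],
        v_gpe=traces[:, 1],
        v_ppn=traces[:, 2],
        w_trace=w_tr,
        config=config,
    )
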