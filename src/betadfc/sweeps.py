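"""Parameter-space analyses: intensity and delay sweeps.

A sweep evaluates a stimulation strategy on a grid of intensities K and
delays τ, running R seeded replicates per cell and averaging OI (per
nucleus), EI, and last-second LFP extrema.  On top of the grid sit two
readouts: the suppressed-cell mask ("suppression" = replicate-averaged
summed OI below a fraction of the unstimulated baseline) and the centre of
the primary suppression island.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .controller import StimulationScheme
from .metrics import oscillation_index, energy_index, trace_extrema
from .model import (
    ConfigurationError,
    CouplingConfig,
    PopulationParams,
)
from .simulator import (
    DEFAULT_PARAMS,
    DivergenceError,
    SimulationConfig,
    simulate,
)

__all__ = [
    "SweepSpec",
    "SweepGrid",
    "IslandCenter",
    "cell_seed",
    "run_sweep",
    "baseline_oi",
    "island_center",
    "oi_minimizing_delay",
]

#: Fraction of the summed baseline OI below which a cell counts as suppressed.
DEFAULT_SUPPRESSION_FRACTION = 0.1


@dataclass(frozen=True)
class SweepSpec:
    """Grid definition for one strategy.

    ``k_grid`` and ``tau_ms_grid`` span the cells (either may be a
    singleton for a 1-D sweep); each cell runs ``replicates`` seeded
    simulations derived from ``base_seed``.
    """

    target: str
    source: str
    k_grid: Sequence[float]
    tau_ms_grid: Sequence[float]
    replicates: int = 20
    base_seed: int = 0
    onset: float = 1.0
    T: float = 3.0
    dt: float = 1e-4

    def __post_init__(self) -> None:
        if len(self.k_grid) == 0 or len(self.tau_ms_grid) == 0:
            raise ConfigurationError("sweep grids must be non-empty")
        if not (
            np.all(np.isfinite(self.k_grid)) and np.all(np.isfinite(self.tau_ms_grid))
        ):
            raise ConfigurationError("sweep grids must be finite")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")

    def scheme(self, K: float, tau_ms: float) -> StimulationScheme:
        return StimulationScheme.from_ms(
            self.target, self.source, K=K, tau_ms=tau_ms, onset=self.onset
        )


@dataclass
class SweepGrid:
    """Replicate-averaged sweep results on the (K, τ) grid.

    All per-cell arrays have shape ``(len(k_grid), len(tau_ms_grid))``;
    ``n_ok`` counts completed (non-diverged) replicates per cell, and cells
    where every replicate diverged hold NaN.
    """

    k_grid: np.ndarray
    tau_ms_grid: np.ndarray
    oi: Dict[str, np.ndarray]  # per nucleus
    ei: np.ndarray
    vmax: Dict[str, np.ndarray]
    vmin: Dict[str, np.ndarray]
    n_ok: np.ndarray
    spec: SweepSpec

    @property
    def oi_sum(self) -> np.ndarray:
        """Summed OI of the three nuclei per cell."""
        return self.oi["stn"] + self.oi["gpe"] + self.oi["ppn"]

    def suppressed_mask(
        self,
        baseline: Mapping[str, float],
        fraction: float = DEFAULT_SUPPRESSION_FRACTION,
    ) -> np.ndarray:
        """Cells whose summed OI is below ``fraction`` of the summed baseline."""
        base_sum = sum(baseline[n] for n in ("stn", "gpe", "ppn"))
        with np.errstate(invalid="ignore"):
            return self.oi_sum < fraction * base_sum


@dataclass
class IslandCenter:
    """Centre of the primary suppression island (or an explicit miss)."""

    found: bool
    tau_ms: Optional[float] = None
    K: Optional[float] = None
    n_cells: int = 0
    mask: Optional[np.ndarray] = None

    def __bool__(self) -> bool:
        return self.found


def cell_seed(base_seed: int, K: float, tau_ms: float, rep: int) -> np.random.SeedSequence:
    """Deterministic per-replicate seed, stable under grid refinement.

    The seed depends only on (base_seed, K, τ, replicate index) — not on
    grid positions — so refining a grid never changes existing cells.
    K and τ are quantised at 1e−6 to make the keys integral.
    """
    k_key = int(round(K * 1e6)) + (1 << 40)  # offset keeps entropy non-negative
    t_key = int(round(tau_ms * 1e6)) + (1 << 40)
    return np.random.SeedSequence(entropy=(int(base_seed), k_key, t_key, int(rep)))


def _replicate_seed_int(base_seed: int, K: float, tau_ms: float, rep: int) -> int:
    # SimulationConfig carries a plain integer seed so manifests stay flat.
    return int(cell_seed(base_seed, K, tau_ms, rep).generate_state(1, np.uint32)[0])


def run_sweep(
    spec: SweepSpec,
    params: Optional[Mapping[str, PopulationParams]] = None,
    coupling: CouplingConfig = None,
    progress: bool = False,
) -> SweepGrid:
    """Evaluate every (K, τ) cell of ``spec`` with replicate averaging.

    Cells are independent (results do not depend on evaluation order).
    Diverged replicates are skipped and counted out of ``n_ok``; a cell
    where all replicates diverge holds NaN.
    """
    if coupling is None:
        raise ConfigurationError("a CouplingConfig is required")
    if params is None:
        params = DEFAULT_PARAMS
    ks = np.asarray(spec.k_grid, dtype=np.float64)
    taus = np.asarray(spec.tau_ms_grid, dtype=np.float64)
    shape = (ks.size, taus.size)
    oi = {n: np.zeros(shape) for n in ("stn", "gpe", "ppn")}
    ei = np.zeros(shape)
    vmax = {n: np.zeros(shape) for n in ("stn", "gpe", "ppn")}
    vmin = {n: np.zeros(shape) for n in ("stn", "gpe", "ppn")}
    n_ok = np.zeros(shape, dtype=np.int64)

    cells = [(a, b) for a in range(ks.size) for b in range(taus.size)]
    iterator = cells
    if progress:  # pragma: no cover - cosmetic
        from tqdm import tqdm

        iterator = tqdm(cells, desc="sweep", unit="cell")

    for a, b in iterator:
        K, tau_ms = float(ks[a]), float(taus[b])
        scheme = spec.scheme(K, tau_ms)
        for rep in range(spec.replicates):
            cfg = SimulationConfig(
                T=spec.T,
                dt=spec.dt,
                seed=_replicate_seed_int(spec.base_seed, K, tau_ms, rep),
                scheme=scheme,
            )
            try:
                res = simulate(cfg, params=params, coupling=coupling)
            except DivergenceError:
                continue
            for n in ("stn", "gpe", "ppn"):
                trace = res.lfp(n)
                oi[n][a, b] += oscillation_index(trace, spec.dt)
                hi, lo = trace_extrema(trace, spec.dt)
                vmax[n][a, b] += hi
                vmin[n][a, b] += lo
            ei[a, b] += energy_index(res.w_trace, spec.dt)
            n_ok[a, b] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.where(n_ok > 0, n_ok, 1)
        for n in ("stn", "gpe", "ppn"):
            oi[n] = np.where(n_ok > 0, oi[n] / denom, np.nan)
            vmax[n] = np.where(n_ok > 0, vmax[n] / denom, np.nan)
            vmin[n] = np.where(n_ok > 0, vmin[n] / denom, np.nan)
        ei = np.where(n_ok > 0, ei / denom, np.nan)

    return SweepGrid(
        k_grid=ks,
        tau_ms_grid=taus,
        oi=oi,
        ei=ei,
        vmax=vmax,
        vmin=vmin,
        n_ok=n_ok,
        spec=spec,
    )


def baseline_oi(
    params: Optional[Mapping[str, PopulationParams]] = None,
    coupling: CouplingConfig = None,
    base_seed: int = 0,
    replicates: int = 20,
    T: float = 3.0,
    dt: float = 1e-4,
) -> Dict[str, float]:
    """Replicate-averaged unstimulated OI per nucleus (the sweep reference).

    Uses seeds ``base_seed .. base_seed+replicates−1``.
    """
    if coupling is None:
        raise ConfigurationError("a CouplingConfig is required")
    acc = {n: 0.0 for n in ("stn", "gpe", "ppn")}
    for rep in range(replicates):
        res = simulate(
            SimulationConfig(T=T, dt=dt, seed=base_seed + rep, scheme=None),
            params=params,
            coupling=coupling,
        )
        for n in acc:
            acc[n] += oscillation_index(res.lfp(n), dt)
    return {n: v / replicates for n, v in acc.items()}


def island_center(
    grid: SweepGrid,
    baseline: Mapping[str, float],
    fraction: float = DEFAULT_SUPPRESSION_FRACTION,
) -> IslandCenter:
    """Centre of the primary suppression island of a sweep.

    Suppressed cells (summed OI below ``fraction`` of the summed baseline)
    are grouped into 4-connected components; the primary island is the
    largest component and its centre the cell minimising summed OI, with
    ties broken by smaller EI, then smaller τ.  Returns an explicit
    not-found result when no cell is suppressed.
    """
    mask = grid.suppressed_mask(baseline, fraction)
    if not mask.any():
        return IslandCenter(found=False, mask=mask)
    labels, n_comp = ndimage.label(mask)  # default structure = 4-connectivity
    sizes = ndimage.sum_labels(mask, labels, index=range(1, n_comp + 1))
    primary = 1 + int(np.argmax(sizes))
    in_island = labels == primary
    oi_sum = np.where(in_island, grid.oi_sum, np.inf)
    # lexicographic argmin: summed OI, then EI, then tau
    order = np.lexsort(
        (
            np.broadcast_to(grid.tau_ms_grid, oi_sum.shape).ravel(),
            np.where(in_island, grid.ei, np.inf).ravel(),
            oi_sum.ravel(),
        )
    )
    a, b = np.unravel_index(order[0], oi_sum.shape)
    return IslandCenter(
        found=True,
        tau_ms=float(grid.tau_ms_grid[b]),
        K=float(grid.k_grid[a]),
        n_cells=int(sizes[primary - 1]),
        mask=mask,
    )


def oi_minimizing_delay(grid: SweepGrid) -> float:
    """Delay (ms) minimising the replicate-averaged summed OI of a τ sweep.

    Intended for single-K delay sweeps; with a 2-D grid the minimum is
    taken over all cells and the corresponding τ returned.
    """
    oi_sum = np.where(np.isnan(grid.oi_sum), np.inf, grid.oi_sum)
    a, b = np.unravel_index(int(np.argmin(oi_sum)), oi_sum.shape)
    return float(grid.tau_ms_grid[b])
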