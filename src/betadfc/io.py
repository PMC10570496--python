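"""Configuration loading, result serialization, manifests and test signals.

Configs are flat YAML documents with sections ``stn``/``gpe``/``ppn``
(population constants), ``coupling`` (pathway gains), ``inputs``
(external-drive statistics), ``simulation`` and optional ``scheme``.  Two
presets ship with the package: ``normal`` and ``pathological``.  Unknown
keys are rejected outright — a misspelled parameter never silently keeps
its default.

Every artifact written by :func:`write_result` gets a JSON manifest
sidecar sufficient to regenerate it bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, Mapping, Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .controller import SCHEME_PRESETS, StimulationScheme, get_scheme
from .model import (
    ConfigurationError,
    CouplingConfig,
    NUCLEI,
    PopulationParams,
)
from .simulator import (
    GENERATOR_FAMILY,
    SimulationConfig,
    SimulationResult,
)
from .sweeps import SweepGrid

__all__ = [
    "ModelConfig",
    "RunManifest",
    "load_config",
    "write_result",
    "read_result",
    "write_grid",
    "read_grid",
    "make_fixture",
]

PRESET_NAMES = ("normal", "pathological")


@dataclass
class ModelConfig:
    """A fully resolved configuration bundle."""

    params: Dict[str, PopulationParams]
    coupling: CouplingConfig
    simulation: SimulationConfig
    scheme: Optional[StimulationScheme] = None

    def sim_config(self) -> SimulationConfig:
        """The SimulationConfig with the scheme attached."""
        return dataclasses.replace(self.simulation, scheme=self.scheme)


def _require_keys(section: str, doc: Mapping, allowed: set, required: set) -> None:
    unknown = set(doc) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) in [{section}]: {sorted(unknown)}; allowed: {sorted(allowed)}"
        )
    missing = required - set(doc)
    if missing:
        raise ConfigurationError(f"missing key(s) in [{section}]: {sorted(missing)}")


def _parse_document(doc: Mapping) -> ModelConfig:
    if not isinstance(doc, Mapping):
        raise ConfigurationError("config document must be a mapping")
    top_allowed = {"stn", "gpe", "ppn", "coupling", "inputs", "simulation", "scheme"}
    _require_keys("top level", doc, top_allowed, {"stn", "gpe", "ppn", "coupling", "inputs"})

    params = {}
    for nucleus in NUCLEI:
        sec = doc[nucleus]
        _require_keys(nucleus, sec, {"H", "x", "r", "y"}, {"H", "x", "r", "y"})
        params[nucleus] = PopulationParams(**{k: float(v) for k, v in sec.items()})

    lam = doc["coupling"]
    lam_keys = {f"lambda{i}" for i in range(1, 6)}
    _require_keys("coupling", lam, lam_keys, lam_keys)
    inp = doc["inputs"]
    inp_keys = {"cor_mean", "cor_sd", "str_mean", "str_sd", "gpi_mean", "gpi_sd"}
    _require_keys("inputs", inp, inp_keys, inp_keys)
    coupling = CouplingConfig(
        **{k: float(v) for k, v in lam.items()},
        **{k: float(v) for k, v in inp.items()},
    )

    sim_doc = dict(doc.get("simulation") or {})
    _require_keys("simulation", sim_doc, {"T", "dt", "seed"}, set())
    simulation = SimulationConfig(
        T=float(sim_doc.get("T", 3.0)),
        dt=float(sim_doc.get("dt", 1e-4)),
        seed=int(sim_doc.get("seed", 0)),
    )

    scheme_doc = doc.get("scheme")
    scheme = None
    if scheme_doc is not None:
        if isinstance(scheme_doc, str):
            scheme = get_scheme(scheme_doc)
        else:
            _require_keys(
                "scheme",
                scheme_doc,
                {"name", "target", "source", "K", "tau_ms", "onset"},
                set(),
            )
            if "name" in scheme_doc:
                scheme = get_scheme(scheme_doc["name"])
                extra = set(scheme_doc) - {"name"}
                if extra - {"K", "tau_ms", "onset"}:
                    raise ConfigurationError(
                        f"scheme preset accepts only K/tau_ms/onset overrides, got {sorted(extra)}"
                    )
                scheme = scheme.with_params(
                    K=scheme_doc.get("K"), tau_ms=scheme_doc.get("tau_ms")
                )
                if "onset" in scheme_doc:
                    scheme = dataclasses.replace(scheme, onset=float(scheme_doc["onset"]))
            else:
                _require_keys(
                    "scheme",
                    scheme_doc,
                    {"target", "source", "K", "tau_ms", "onset"},
                    {"target", "source", "K", "tau_ms"},
                )
                scheme = StimulationScheme.from_ms(
                    target=scheme_doc["target"],
                    source=scheme_doc["source"],
                    K=float(scheme_doc["K"]),
                    tau_ms=float(scheme_doc["tau_ms"]),
                    onset=float(scheme_doc.get("onset", 1.0)),
                )
    return ModelConfig(params=params, coupling=coupling, simulation=simulation, scheme=scheme)


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), Mapping):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def _preset_document(name: str) -> dict:
    ref = resources.files("betadfc").joinpath(f"presets/{name}.yaml")
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def load_config(
    source: Union[str, Path], overrides: Optional[Mapping] = None
) -> ModelConfig:
    """Load a configuration from a preset name or a YAML file path.

    ``source`` may be ``"normal"``, ``"pathological"`` or a path to a YAML
    document.  ``overrides`` (a possibly partial nested mapping) merges over
    the loaded document — e.g. ``{"simulation": {"seed": 7}, "scheme": "A"}``.
    Unknown keys anywhere raise a `ConfigurationError` naming the key.
    """
    if isinstance(source, str) and source in PRESET_NAMES:
        doc = _preset_document(source)
    else:
        path = Path(source)
        if not path.exists():
            raise ConfigurationError(
                f"config {source!r} is neither a preset {PRESET_NAMES} nor an existing file"
            )
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    if overrides:
        doc = _deep_merge(doc, overrides)
    return _parse_document(doc)


# ---------------------------------------------------------------------------
# Manifests and result I/O
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    """Everything needed to regenerate an output artifact bit-for-bit."""

    kind: str  # "simulation" | "sweep"
    config: dict
    seed: int
    version: str
    generator_family: str
    outputs: list
    summary: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))


def _scheme_dict(scheme: Optional[StimulationScheme]) -> Optional[dict]:
    if scheme is None:
        return None
    return {
        "target": scheme.target,
        "source": scheme.source,
        "K": scheme.K,
        "tau_s": scheme.tau,
        "tau_ms": scheme.tau_ms,  # seconds are canonical; ms echoed for readability
        "onset": scheme.onset,
    }


def _config_dict(
    config: SimulationConfig,
    params: Mapping[str, PopulationParams],
    coupling: CouplingConfig,
) -> dict:
    return {
        "T": config.T,
        "dt": config.dt,
        "seed": config.seed,
        "scheme": _scheme_dict(config.scheme),
        "params": {n: dataclasses.asdict(p) for n, p in params.items()},
        "coupling": dataclasses.asdict(coupling),
    }


def _manifest_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".manifest.json")


def write_result(
    result: SimulationResult,
    path: Union[str, Path],
    params: Optional[Mapping[str, PopulationParams]] = None,
    coupling: Optional[CouplingConfig] = None,
    summary: Optional[dict] = None,
) -> Path:
    """Write a run as CSV (t, v_stn, v_gpe, v_ppn, w) plus a JSON manifest.

    Traces round-trip losslessly through :func:`read_result`.  Returns the
    manifest path.
    """
    path = Path(path)
    frame = pd.DataFrame(
        {
            "t": result.t,
            "v_stn": result.v_stn,
            "v_gpe": result.v_gpe,
            "v_ppn": result.v_ppn,
            "w": result.w_trace,
        }
    )
    try:
        # %.17g round-trips float64 exactly through text
        frame.to_csv(path, index=False, float_format="%.17g")
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"cannot write result to {path}: {exc}") from exc
    from .simulator import DEFAULT_PARAMS

    manifest = RunManifest(
        kind="simulation",
        config=_config_dict(
            result.config, params or DEFAULT_PARAMS, coupling or _nan_coupling()
        ),
        seed=result.config.seed,
        version=__version__,
        generator_family=result.generator_family,
        outputs=[path.name],
        summary=summary or {},
    )
    mpath = _manifest_path(path)
    mpath.write_text(manifest.to_json())
    return mpath


def _nan_coupling() -> CouplingConfig:
    # placeholder when the caller did not pass the coupling used
    return CouplingConfig(0, 0, 0, 0, 0)


def read_result(path: Union[str, Path]) -> SimulationResult:
    """Read back a run written by :func:`write_result`."""
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    mpath = _manifest_path(path)
    config = SimulationConfig()
    if mpath.exists():
        manifest = RunManifest.from_json(mpath.read_text())
        cdoc = manifest.config
        scheme_doc = cdoc.get("scheme")
        scheme = None
        if scheme_doc is not None:
            scheme = StimulationScheme(
                target=scheme_doc["target"],
                source=scheme_doc["source"],
                K=scheme_doc["K"],
                tau=scheme_doc["tau_s"],
                onset=scheme_doc["onset"],
            )
        config = SimulationConfig(
            T=cdoc["T"], dt=cdoc["dt"], seed=cdoc["seed"], scheme=scheme
        )
    return SimulationResult(
        t=frame["t"].to_numpy(),
        v_stn=frame["v_stn"].to_numpy(),
        v_gpe=frame["v_gpe"].to_numpy(),
        v_ppn=frame["v_ppn"].to_numpy(),
        w_trace=frame["w"].to_numpy(),
        config=config,
    )


def write_grid(
    grid: SweepGrid,
    path: Union[str, Path],
    summary: Optional[dict] = None,
) -> Path:
    """Write a sweep as long-format CSV plus a JSON manifest.

    Columns: target, source, K, tau_ms, oi_stn, oi_gpe, oi_ppn, ei,
    vmax_*/vmin_* per nucleus, n_ok.  An empty grid cannot be constructed,
    but cells with no completed replicate appear with n_ok=0 and NaNs.
    """
    path = Path(path)
    rows = []
    spec = grid.spec
    for a, K in enumerate(grid.k_grid):
        for b, tau in enumerate(grid.tau_ms_grid):
            row = {
                "target": spec.target,
                "source": spec.source,
                "K": K,
                "tau_ms": tau,
                "oi_stn": grid.oi["stn"][a, b],
                "oi_gpe": grid.oi["gpe"][a, b],
                "oi_ppn": grid.oi["ppn"][a, b],
                "ei": grid.ei[a, b],
                "n_ok": grid.n_ok[a, b],
            }
            for n in NUCLEI:
                row[f"vmax_{n}"] = grid.vmax[n][a, b]
                row[f"vmin_{n}"] = grid.vmin[n][a, b]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    manifest = RunManifest(
        kind="sweep",
        config={
            "target": spec.target,
            "source": spec.source,
            "k_grid": list(map(float, grid.k_grid)),
            "tau_ms_grid": list(map(float, grid.tau_ms_grid)),
            "replicates": spec.replicates,
            "base_seed": spec.base_seed,
            "onset": spec.onset,
            "T": spec.T,
            "dt": spec.dt,
        },
        seed=spec.base_seed,
        version=__version__,
        generator_family=GENERATOR_FAMILY,
        outputs=[path.name],
        summary=summary or {},
    )
    mpath = _manifest_path(path)
    mpath.write_text(manifest.to_json())
    return mpath


def read_grid(path: Union[str, Path]) -> pd.DataFrame:
    """Read back a sweep CSV written by :func:`write_grid` as a DataFrame."""
    return pd.read_csv(path, float_precision="round_trip")


# ---------------------------------------------------------------------------
# Deterministic test signals
# ---------------------------------------------------------------------------


def make_fixture(kind: str, dt: float = 1e-4, T: float = 3.0, **kwargs) -> np.ndarray:
    """Analytically sampled test signal on the grid ``t = i·dt, i < T/dt``.

    Kinds: ``const`` (c), ``sin`` (f, A, phase), ``ramp`` (slope,
    intercept), ``two_tone`` (f1, A1, f2, A2).  Used as exact oracles for
    the metric and controller tests.
    """
    n = int(round(T / dt))
    t = np.arange(n) * dt
    if kind == "const":
        return np.full(n, float(kwargs.get("c", 0.0)))
    if kind == "sin":
        f = float(kwargs.get("f", 22.0))
        A = float(kwargs.get("A", 1.0))
        phase = float(kwargs.get("phase", 0.0))
        return A * np.sin(2 * np.pi * f * t + phase)
    if kind == "ramp":
        slope = float(kwargs.get("slope", 1.0))
        intercept = float(kwargs.get("intercept", 0.0))
        return intercept + slope * t
    if kind == "two_tone":
        f1 = float(kwargs.get("f1", 10.0))
        a1 = float(kwargs.get("A1", 1.0))
        f2 = float(kwargs.get("f2", 30.0))
        a2 = float(kwargs.get("A2", 2.0))
        return a1 * np.sin(2 * np.pi * f1 * t) + a2 * np.sin(2 * np.pi * f2 * t)
    raise ConfigurationError(f"unknown fixture kind {kind!r}")
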