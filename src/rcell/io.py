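"""Configuration loading, result serialization and scenario reproduction.

YAML in, CSV/JSON out.  Every run writes a manifest (config hash, package
version, seed) alongside its outputs so any result can be reproduced from
the manifest alone.  Plots are a convenience layer; all quantitative checks
operate on the emitted tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .circuits import (
    EMPTY_CIRCUIT,
    CircuitSpec,
    GeneSpec,
    RegulationSpec,
    RNASpec,
    build_aif_controller,
    build_constitutive_gene,
    build_disturbance_gene,
    build_inducible_module,
    build_t7_self_activator,
    build_winner_takes_all,
)
from .params import ChloramphenicolParams, HostParams, default_host_params, load_host_params
from .simulate import SteadyState, Trajectory

log = logging.getLogger("rcell")

__all__ = [
    "RunConfig",
    "load_config",
    "circuit_from_config",
    "write_trajectory",
    "read_trajectory",
    "write_steady_state",
    "write_report",
    "write_manifest",
    "reproduce_figure",
    "FIGURE_TAGS",
]

CIRCUIT_PRESETS = {
    "constitutive": build_constitutive_gene,
    "wta": build_winner_takes_all,
    "t7": build_t7_self_activator,
    "aif": build_aif_controller,
    "inducible": build_inducible_module,
    "disturbance": build_disturbance_gene,
}

_MODES = ("deterministic", "hybrid", "steady-state", "sweep", "fit", "design")
FLOAT_FMT = "%.12g"


@dataclass
class RunConfig:
    """Validated top-level run description."""

    sigma: float = 0.5
    host_params: str | None = None        # path to a YAML parameter file
    circuit: str | dict | None = None     # preset name, inline dict, or None
    circuit_options: dict = field(default_factory=dict)
    chloramphenicol: float = 0.0          # internal concentration (uM)
    k_cm: float | None = None
    mode: str = "steady-state"
    out_dir: str = "results"
    seed: int = 0
    rtol: float = 1e-8
    atol: float = 1e-6
    horizon: float = 72.0
    t_span: float = 24.0

    _KNOWN = None  # filled after definition

    def resolve_params(self) -> HostParams:
        p = load_host_params(self.host_params) if self.host_params else default_host_params()
        return p.replace(sigma=self.sigma)

    def resolve_cm(self) -> ChloramphenicolParams | None:
        if self.chloramphenicol <= 0:
            return None
        kw = {"h_cm": self.chloramphenicol}
        if self.k_cm is not None:
            kw["k_cm"] = self.k_cm
        return ChloramphenicolParams(**kw)

    def resolve_circuit(self) -> CircuitSpec:
        return circuit_from_config(self.circuit, self.circuit_options)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


RunConfig._KNOWN = {f for f in RunConfig.__dataclass_fields__ if not f.startswith("_")}


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a run configuration; unknown keys are rejected."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError("run config must be a YAML mapping")
    unknown = set(doc) - RunConfig._KNOWN
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    cfg = RunConfig(**doc)
    if not 0.0 < cfg.sigma <= 1.0:
        raise ValueError(f"config key 'sigma' must lie in (0, 1], got {cfg.sigma}")
    if cfg.chloramphenicol < 0:
        raise ValueError("config key 'chloramphenicol' must be >= 0")
    if cfg.mode not in _MODES:
        raise ValueError(f"config key 'mode' must be one of {_MODES}")
    cfg.resolve_circuit()  # validates inline circuit blocks
    return cfg


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)


def circuit_from_config(circuit, options: dict | None = None) -> CircuitSpec:
    """Build a CircuitSpec from a preset name or an inline YAML block."""
    options = options or {}
    if circuit is None:
        return EMPTY_CIRCUIT
    if isinstance(circuit, str):
        try:
            builder = CIRCUIT_PRESETS[circuit]
        except KeyError:
            raise ValueError(
                f"unknown circuit preset {circuit!r}; valid presets: "
                f"{', '.join(sorted(CIRCUIT_PRESETS))}"
            ) from None
        return builder(**options)
    if isinstance(circuit, dict):
        genes = [_gene_from_dict(g) for g in circuit.get("genes", [])]
        rnas = [_rna_from_dict(r) for r in circuit.get("rnas", [])]
        ann = [tuple(a) for a in circuit.get("annihilations", [])]
        return CircuitSpec(genes=genes, rnas=rnas, annihilations=ann,
                           name=circuit.get("name", "inline"))
    raise ValueError("circuit must be a preset name or a mapping")


def _reg_from_dict(d: dict | None) -> RegulationSpec:
    return RegulationSpec(**(d or {}))


def _gene_from_dict(d: dict) -> GeneSpec:
    d = dict(d)
    reg = _reg_from_dict(d.pop("regulation", None))
    return GeneSpec(regulation=reg, **d)


def _rna_from_dict(d: dict) -> RNASpec:
    d = dict(d)
    reg = _reg_from_dict(d.pop("regulation", None))
    return RNASpec(regulation=reg, **d)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _derived_frame(traj: Trajectory) -> pd.DataFrame:
    rows = [traj.derived_at(i).to_dict() for i in range(len(traj.times))]
    return pd.DataFrame(rows)


def write_trajectory(traj: Trajectory, path: str | Path) -> Path:
    """CSV with one row per time: t_h, state columns, then derived columns."""
    path = Path(path)
    df = pd.DataFrame(traj.states, columns=traj.names)
    df.insert(0, "t_h", traj.times)
    df = pd.concat([df, _derived_frame(traj)], axis=1)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    return path


def read_trajectory(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_steady_state(ss: SteadyState, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "state": {n: float(v) for n, v in zip(ss.names, ss.x)},
        "derived": {k: float(v) for k, v in ss.derived.to_dict().items()},
        "converged": bool(ss.converged),
        "residual": float(ss.residual),
        "horizon_used_h": float(ss.horizon_used),
        "sigma": float(ss.params.sigma),
        "circuit": ss.spec.name,
    }
    path.write_text(json.dumps(doc, indent=2, sort_keys=True))
    return path


def write_report(report: dict, path: str | Path) -> Path:
    path = Path(path)

    def _coerce(x):
        if isinstance(x, (np.floating, np.integer)):
            return x.item()
        if isinstance(x, np.ndarray):
            return x.tolist()
        raise TypeError(f"not JSON-serializable: {type(x)}")

    path.write_text(json.dumps(report, indent=2, sort_keys=True, default=_coerce))
    return path


def write_manifest(out_dir: str | Path, cfg: RunConfig | None = None,
                   seed: int | None = None, extra: dict | None = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    doc = {"package_version": _version}
    if cfg is not None:
        doc["config"] = asdict(cfg)
        doc["config_hash"] = cfg.digest()
        doc["seed"] = cfg.seed
    if seed is not None:
        doc["seed"] = seed
    if extra:
        doc.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(doc, indent=2, sort_keys=True, default=str))
    return path


# ---------------------------------------------------------------------------
# scenario reproduction
# ---------------------------------------------------------------------------

FIGURE_TAGS = ("growth_laws", "optimality", "burden_sweep", "wta", "t7",
               "aif_step", "aif_range", "induction")


def reproduce_figure(tag: str, out_dir: str | Path = "results", seed: int = 0,
                     plot: bool = True, fast: bool = True) -> dict[str, pd.DataFrame]:
    """Run one of the headline scenarios end to end; emits CSV tables (+PNG).

    Desk-scale problem sizes are used throughout (see docs/methods.md).
    """
    if tag not in FIGURE_TAGS:
        raise ValueError(
            f"unknown figure tag {tag!r}; valid tags: {', '.join(FIGURE_TAGS)}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    from . import scenarios
    tables = getattr(scenarios, f"run_{tag}")(seed=seed, fast=fast)
    for name, df in tables.items():
        df.to_csv(out_dir / f"{tag}_{name}.csv", index=False, float_format=FLOAT_FMT)
    if plot:
        try:
            scenarios.plot_tables(tag, tables, out_dir)
        except Exception as exc:  # plotting must never fail a run
            log.warning("plotting failed for %s: %s", tag, exc)
    write_manifest(out_dir, seed=seed, extra={"scenario": tag})
    return tables
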