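"""Structured configuration: one YAML file resolves to the full model.

Sections (all optional; defaults are the baseline control model):

    geometry:  fields of GeometryParams
    materials: MY / CJ / MEMBRANE, each with A (Pa), B, D (1/Pa)
    schedule:  process endpoint overrides by name (value 1 disables),
               plus step_durations
    solver:    fields of SimulationConfig
    scenario:  name from the perturbation catalogue
    outputs:   outdir, save_vtu

Unknown keys anywhere are rejected with their full key path.  Units are
fixed package-wide: micrometres, Pascals; forces in Pa*um^2.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .constitutive import CARDIAC_JELLY, MEMBRANE, MYOCARDIUM, MaterialParams
from .geometry import GeometryParams
from .morphogenesis import MorphSchedule, baseline_schedule
from .solver import SimulationConfig

__all__ = ["FullConfig", "load_config", "RunManifest", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class FullConfig:
    geometry: GeometryParams
    materials: dict
    schedule: MorphSchedule
    solver: SimulationConfig
    scenario: str = "baseline"
    outputs: dict = field(default_factory=lambda: {"outdir": "cloop_out",
                                                   "save_vtu": True})

    def resolved_dict(self) -> dict:
        return {
            "geometry": dataclasses.asdict(self.geometry),
            "materials": {k: dataclasses.asdict(v) for k, v in self.materials.items()},
            "schedule": {
                "step_durations": list(self.schedule.step_durations),
                "processes": [dataclasses.asdict(p) for p in self.schedule.processes],
            },
            "solver": dataclasses.asdict(self.solver),
            "scenario": self.scenario,
            "outputs": dict(self.outputs),
        }

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.resolved_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _build_dataclass(cls, overrides: dict, path: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(overrides) - valid
    if unknown:
        raise ConfigError(f"unknown key {path}.{sorted(unknown)[0]}")
    clean = {}
    for k, v in overrides.items():
        if isinstance(v, list):
            v = tuple(v)
        clean[k] = v
    try:
        return cls(**clean)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"invalid value under {path}: {e}") from e


def load_config(path=None, overrides: dict | None = None) -> FullConfig:
    """Load and resolve a YAML config; an empty/missing file is the baseline."""
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    if overrides:
        raw = {**raw, **overrides}

    known_sections = {"geometry", "materials", "schedule", "solver", "scenario", "outputs"}
    unknown = set(raw) - known_sections
    if unknown:
        raise ConfigError(f"unknown key {sorted(unknown)[0]}")

    geometry = _build_dataclass(GeometryParams, raw.get("geometry") or {}, "geometry")
    solver = _build_dataclass(SimulationConfig, raw.get("solver") or {}, "solver")

    mats = {"MY": MYOCARDIUM, "CJ": CARDIAC_JELLY, "MEMBRANE": MEMBRANE}
    mraw = raw.get("materials") or {}
    unknown = set(mraw) - set(mats)
    if unknown:
        raise ConfigError(f"unknown key materials.{sorted(unknown)[0]}")
    for name, mo in mraw.items():
        base = dataclasses.asdict(mats[name])
        bad = set(mo or {}) - set(base)
        if bad:
            raise ConfigError(f"unknown key materials.{name}.{sorted(bad)[0]}")
        base.update(mo or {})
        mats[name] = MaterialParams(**base)

    schedule = baseline_schedule()
    sraw = dict(raw.get("schedule") or {})
    durations = sraw.pop("step_durations", None)
    if durations is not None:
        schedule = dataclasses.replace(schedule, step_durations=tuple(durations))
    names = {p.name for p in schedule.processes}
    bad = set(sraw) - names
    if bad:
        raise ConfigError(f"unknown key schedule.{sorted(bad)[0]}")
    if sraw:
        schedule = schedule.with_overrides(**{k: float(v) for k, v in sraw.items()})

    scenario = raw.get("scenario") or "baseline"
    if isinstance(scenario, dict):
        bad = set(scenario) - {"name"}
        if bad:
            raise ConfigError(f"unknown key scenario.{sorted(bad)[0]}")
        scenario = scenario.get("name", "baseline")

    outputs = {"outdir": "cloop_out", "save_vtu": True}
    oraw = raw.get("outputs") or {}
    bad = set(oraw) - set(outputs)
    if bad:
        raise ConfigError(f"unknown key outputs.{sorted(bad)[0]}")
    outputs.update(oraw)

    return FullConfig(geometry=geometry, materials=mats, schedule=schedule,
                      solver=solver, scenario=scenario, outputs=outputs)


@dataclass
class RunManifest:
    """Provenance record written next to every run's outputs."""

    config_hash: str
    code_version: str
    seed: int
    mesh_checksum: str
    increments: list
    outputs: list

    @classmethod
    def create(cls, cfg: FullConfig, mesh, traj, outputs) -> "RunManifest":
        mh = hashlib.sha256()
        mh.update(np.ascontiguousarray(mesh.nodes).tobytes())
        mh.update(np.ascontiguousarray(mesh.tets).tobytes())
        return cls(
            config_hash=cfg.config_hash(),
            code_version=__version__,
            seed=cfg.solver.seed,
            mesh_checksum=mh.hexdigest()[:16],
            increments=traj.log_rows,
            outputs=[str(p) for p in outputs],
        )

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         default=float))
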