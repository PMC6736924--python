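"""TOML run configuration.

One file drives a whole run: a ``[settings]`` block mirroring the
solver/discretization settings, a ``[grid]`` block with the calibration
value lists, and a ``[run]`` block for seeds, paths and correspondence
mode.  Unknown keys are rejected rather than ignored, so typos fail
loudly; omitted keys keep the calibration defaults.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .calibrate import CalibrationGrid
from .engine import SimulationSettings

_SETTINGS_KEYS = {
    "time_step", "substeps", "iterations_per_substep", "gravity",
    "damping_factor", "shape_friction", "particle_friction",
    "relaxation_factor", "tissue_density",
    # discretization settings that live alongside the solver settings
    "cluster_spacing_factor", "volume_sampling_factor",
}
_GRID_KEYS = {"cluster_stiffness", "spring_stiffness", "particle_radius",
              "pressure"}
_RUN_KEYS = {"seed", "correspondence_mode", "out_dir", "labels", "meshes",
             "landmarks"}


@dataclass
class RunConfig:
    """Validated configuration for the command-line pipeline."""

    settings: SimulationSettings = field(default_factory=SimulationSettings)
    grid: CalibrationGrid = field(default_factory=CalibrationGrid)
    cluster_spacing_factor: float = 3.33
    volume_sampling_factor: float = 4.0
    seed: int = 0
    correspondence_mode: str = "indexed"
    out_dir: str = "."
    paths: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.correspondence_mode not in ("indexed", "closest"):
            raise ValueError(
                f"correspondence_mode must be 'indexed' or 'closest', "
                f"got {self.correspondence_mode!r}")
        if self.cluster_spacing_factor <= 1.0:
            raise ValueError("cluster_spacing_factor must exceed 1")
        if self.volume_sampling_factor <= 0:
            raise ValueError("volume_sampling_factor must be positive")

    def digest(self) -> str:
        """Stable hash of the full configuration (for run manifests)."""
        doc = {
            "settings": asdict(self.settings),
            "grid": asdict(self.grid),
            "cluster_spacing_factor": self.cluster_spacing_factor,
            "volume_sampling_factor": self.volume_sampling_factor,
            "seed": self.seed,
            "correspondence_mode": self.correspondence_mode,
            "paths": self.paths,
        }
        blob = json.dumps(doc, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _reject_unknown(block: dict, allowed: set[str], name: str) -> None:
    unknown = sorted(set(block) - allowed)
    if unknown:
        raise ValueError(f"unknown keys in [{name}]: {unknown}")


def load_config(path) -> RunConfig:
    """Parse and validate a TOML run configuration."""
    with open(Path(path), "rb") as fh:
        doc = tomllib.load(fh)
    _reject_unknown(doc, {"settings", "grid", "run"}, "top level")

    sblock = dict(doc.get("settings", {}))
    _reject_unknown(sblock, _SETTINGS_KEYS, "settings")
    cluster_spacing = float(sblock.pop("cluster_spacing_factor", 3.33))
    volume_sampling = float(sblock.pop("volume_sampling_factor", 4.0))
    settings = SimulationSettings(**sblock)

    gblock = dict(doc.get("grid", {}))
    _reject_unknown(gblock, _GRID_KEYS, "grid")
    grid = CalibrationGrid(**{k: tuple(v) for k, v in gblock.items()})

    rblock = dict(doc.get("run", {}))
    _reject_unknown(rblock, _RUN_KEYS, "run")
    paths = {k: rblock.pop(k) for k in ("labels", "meshes", "landmarks")
             if k in rblock}
    return RunConfig(settings=settings, grid=grid,
                     cluster_spacing_factor=cluster_spacing,
                     volume_sampling_factor=volume_sampling,
                     paths=paths, **rblock)


def write_manifest(path, config: RunConfig, command: str,
                   extra: dict | None = None) -> None:
    """Record what produced the artifacts beside them."""
    import numpy
    import scipy
    import trimesh

    from . import __version__

    doc = {
        "command": command,
        "config_digest": config.digest(),
        "seed": config.seed,
        "versions": {
            "pneumosim": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "trimesh": trimesh.__version__,
        },
    }
    doc.update(extra or {})
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))
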