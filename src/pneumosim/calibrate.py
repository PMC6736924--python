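"""Parameter calibration: exhaustive grid search and pressure sweeps.

Four parameters govern the simulated insufflation: cluster stiffness
(soft-tissue deformability), spring stiffness (inflatable membrane),
particle radius (discretization density) and the simulation pressure
factor (target inflatable volume as a multiple of its rest volume).
Calibration evaluates every combination of a value grid, scoring each
by the mean per-vertex distance between the simulated pneumoperitoneum
surface and ground truth, averaged over datasets with equal weights,
and returns the arg-min (ties broken lexicographically ascending on
cluster stiffness, spring stiffness, radius, pressure).

The pressure sweep holds the other parameters fixed and traces mean
error against pressure; on well-posed data the curve falls to a minimum
and rises again once the inflatable over-expands.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import asdict, dataclass, field
from itertools import product
from pathlib import Path

import numpy as np

from .discretize import (add_connectivity_springs, bind_skin, build_clusters,
                         build_inflatable, build_surface_springs,
                         concat_systems, fix_back_particles, sample_particles)
from .engine import (EquilibriumCriteria, SimulationSettings, SimulationState,
                     deform_skin, simulate_to_equilibrium)
from .imaging import SurfaceMesh
from .metrics import summarize_errors, vertex_errors


def _float_range(start: float, stop: float, step: float) -> tuple[float, ...]:
    n = int(round((stop - start) / step)) + 1
    return tuple(round(start + k * step, 10) for k in range(n))


@dataclass
class CalibrationGrid:
    """Value grids for the exhaustive search (defaults: the full
    calibration grid — 5 × 10 × 3 × 29 = 4350 combinations)."""

    cluster_stiffness: tuple[float, ...] = _float_range(0.4, 0.8, 0.1)
    spring_stiffness: tuple[float, ...] = _float_range(0.1, 1.0, 0.1)
    particle_radius: tuple[float, ...] = (2.2, 2.7, 3.3)
    pressure: tuple[float, ...] = _float_range(1.0, 15.0, 0.5)

    def __post_init__(self):
        for name in ("cluster_stiffness", "spring_stiffness",
                     "particle_radius", "pressure"):
            vals = tuple(float(v) for v in getattr(self, name))
            if not vals:
                raise ValueError(f"{name} grid is empty")
            setattr(self, name, vals)

    @property
    def n_combos(self) -> int:
        return (len(self.cluster_stiffness) * len(self.spring_stiffness)
                * len(self.particle_radius) * len(self.pressure))

    def combos(self):
        """Cartesian product in canonical (lexicographic) order."""
        for ck, sk, r, p in product(sorted(self.cluster_stiffness),
                                    sorted(self.spring_stiffness),
                                    sorted(self.particle_radius),
                                    sorted(self.pressure)):
            yield SimParams(ck, sk, r, p)

    @classmethod
    def preset(cls, name: str) -> "CalibrationGrid":
        """``paper`` = the full grid; ``ci`` = a small 3×3×1×5 grid around
        the published optimum, for fast self-consistency checks."""
        if name == "paper":
            return cls()
        if name == "ci":
            return cls(cluster_stiffness=(0.5, 0.6, 0.7),
                       spring_stiffness=(0.4, 0.5, 0.6),
                       particle_radius=(2.7,),
                       pressure=(4.0, 5.0, 6.0, 7.0, 8.0))
        raise ValueError(f"unknown grid preset {name!r}")


@dataclass(frozen=True)
class SimParams:
    """One point of the calibration grid."""

    cluster_stiffness: float
    spring_stiffness: float
    particle_radius: float
    pressure: float

    def key(self) -> tuple[float, float, float, float]:
        return (self.cluster_stiffness, self.spring_stiffness,
                self.particle_radius, self.pressure)


@dataclass
class OptimalParams:
    """Search result: the arg-min combination and its achieved error."""

    cluster_stiffness: float
    spring_stiffness: float
    particle_radius: float
    pressure: float
    mean_error_mm: float

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


@dataclass
class PressureSweep:
    """Mean error (mm) as a function of simulation pressure."""

    pressures: tuple[float, ...]
    errors: tuple[float, ...]

    def __post_init__(self):
        p = np.asarray(self.pressures)
        if len(p) and not (np.diff(p) > 0).all():
            raise ValueError("pressures must be strictly increasing")

    @property
    def minimum(self) -> tuple[float, float]:
        k = int(np.argmin(self.errors))
        return self.pressures[k], self.errors[k]

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["pressure", "mean_error_mm"])
            for p, e in zip(self.pressures, self.errors):
                w.writerow([p, e])


@dataclass
class CalibrationDataset:
    """One deflated subject plus its insufflated ground truth.

    ``deflated`` must contain the wall, viscera, inflatable and skin
    region meshes; ``truth_inflatable`` is the insufflated
    pneumoperitoneum surface the simulation is scored against.  When it
    shares vertex topology with the deflated inflatable (same subject,
    registered reconstruction, or engine-generated truth) indexed
    correspondence is used, otherwise closest-point.
    """

    name: str
    deflated: dict[str, SurfaceMesh]
    truth_inflatable: SurfaceMesh
    truth_skin: SurfaceMesh | None = None

    def correspondence_mode(self) -> str:
        same = (len(self.truth_inflatable.vertices)
                == len(self.deflated["inflatable"].vertices))
        return "indexed" if same else "closest"


@dataclass
class EvaluationResult:
    params: SimParams
    mean_error_mm: float
    converged: bool
    frames: int
    dataset: str = ""


@dataclass
class PipelineResult:
    state: SimulationState
    inflatable_mesh: SurfaceMesh
    skin_mesh: SurfaceMesh
    report: object


def build_state(deflated: dict[str, SurfaceMesh], params: SimParams,
                settings: SimulationSettings | None = None,
                fix_band: float = 3.0, cluster_spacing_factor: float = 3.33,
                volume_sampling_factor: float = 4.0):
    """Discretize the deflated regions into a ready-to-run state.

    Wall and viscera are volume-sampled at the particle radius, clustered
    per region; the inflatable boundary gets per-vertex particles, edge
    springs and connectivity springs to the wall (reach 2 radii); dorsal
    wall particles are pinned; the skin mesh is bound to wall particles.
    Returns (state, skin binding).
    """
    settings = settings or SimulationSettings()
    soft = {r: deflated[r] for r in ("wall", "viscera")}
    ps = sample_particles(soft, params.particle_radius,
                          volume_sampling_factor=volume_sampling_factor,
                          density=settings.tissue_density)
    # soft bodies only are clustered; the inflatable is governed by springs
    # and its volume target (cluster indices stay valid after concatenation
    # because soft particles come first)
    clusters = build_clusters(ps, spacing_factor=cluster_spacing_factor,
                              stiffness=params.cluster_stiffness)
    infl_ps, surface = build_inflatable(
        deflated["inflatable"], params.pressure,
        density=settings.tissue_density, radius=params.particle_radius,
        first_particle=len(ps))
    ps = concat_systems(ps, infl_ps)
    springs = [build_surface_springs(surface, params.spring_stiffness)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        conn = add_connectivity_springs(
            surface, ps, max_dist=2.0 * params.particle_radius,
            stiffness=params.spring_stiffness)
    if len(conn):
        springs.append(conn)
    fix_back_particles(ps, band=fix_band)
    binding = bind_skin(deflated["skin"], ps)
    from .engine import rest_contact_table
    state = SimulationState(ps=ps, clusters=clusters, springs=springs,
                            inflatable=surface,
                            contact_rest=rest_contact_table(ps))
    return state, binding


def run_pipeline(deflated: dict[str, SurfaceMesh], params: SimParams,
                 settings: SimulationSettings | None = None,
                 criteria: EquilibriumCriteria | None = None
                 ) -> PipelineResult:
    """Discretize, simulate to equilibrium, and extract deformed surfaces."""
    settings = settings or SimulationSettings()
    state, binding = build_state(deflated, params, settings)
    skin0 = deflated["skin"]
    state, report = simulate_to_equilibrium(state, settings, criteria)
    infl_mesh = state.inflatable.as_mesh(state.ps.positions)
    skin_mesh = deform_skin(binding, state, skin0)
    return PipelineResult(state, infl_mesh, skin_mesh, report)


def evaluate_combo(dataset: CalibrationDataset, params: SimParams,
                   settings: SimulationSettings | None = None,
                   criteria: EquilibriumCriteria | None = None
                   ) -> EvaluationResult:
    """Score one parameter combination on one dataset.

    Non-convergence yields +inf error with the flag down, never an
    exception, so a search can simply skip past bad corners of the grid.
    """
    result = run_pipeline(dataset.deflated, params, settings, criteria)
    if not result.report.converged:
        return EvaluationResult(params, float("inf"), False,
                                result.report.frames, dataset.name)
    mode = dataset.correspondence_mode()
    err = vertex_errors(result.inflatable_mesh, dataset.truth_inflatable,
                        mode)
    return EvaluationResult(params, float(err.mean()), True,
                            result.report.frames, dataset.name)


def exhaustive_search(grid: CalibrationGrid,
                      datasets: list[CalibrationDataset],
                      settings: SimulationSettings | None = None,
                      criteria: EquilibriumCriteria | None = None,
                      n_jobs: int = 1,
                      table_path=None
                      ) -> tuple[OptimalParams, list[EvaluationResult]]:
    """Evaluate every grid combination on every dataset; return the
    combination minimizing the dataset-averaged mean error plus the full
    evaluation table (optionally persisted to CSV).

    Results are independent of evaluation order and of ``n_jobs``.
    """
    if not datasets:
        raise ValueError("at least one dataset is required")
    combos = list(grid.combos())
    jobs = [(params, ds) for params in combos for ds in datasets]
    if n_jobs != 1:
        from joblib import Parallel, delayed
        rows = Parallel(n_jobs=n_jobs)(
            delayed(evaluate_combo)(ds, params, settings, criteria)
            for params, ds in jobs)
    else:
        rows = [evaluate_combo(ds, params, settings, criteria)
                for params, ds in jobs]

    by_combo: dict[tuple, list[float]] = {}
    for row in rows:
        by_combo.setdefault(row.params.key(), []).append(row.mean_error_mm)
    averaged = {k: float(np.mean(v)) for k, v in by_combo.items()}
    if all(np.isinf(e) for e in averaged.values()):
        raise RuntimeError("no parameter combination converged")
    # combos() yields lexicographic order; strict < keeps the first minimum
    best_key, best_err = None, float("inf")
    for params in combos:
        e = averaged[params.key()]
        if e < best_err:
            best_key, best_err = params, e
    optimal = OptimalParams(*best_key.key(), mean_error_mm=best_err)
    if table_path is not None:
        with open(table_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["dataset", "cluster_stiffness", "spring_stiffness",
                        "particle_radius", "pressure", "mean_error_mm",
                        "converged", "frames"])
            for row in rows:
                w.writerow([row.dataset, *row.params.key(),
                            row.mean_error_mm, row.converged, row.frames])
    return optimal, rows


def pressure_sweep(params: SimParams, dataset: CalibrationDataset,
                   pressures, settings: SimulationSettings | None = None,
                   criteria: EquilibriumCriteria | None = None
                   ) -> PressureSweep:
    """Mean error against pressure with the other parameters fixed."""
    pressures = tuple(float(p) for p in pressures)
    if not all(b > a for a, b in zip(pressures, pressures[1:])):
        raise ValueError("pressures must be strictly increasing")
    errors = []
    for p in pressures:
        combo = SimParams(params.cluster_stiffness, params.spring_stiffness,
                          params.particle_radius, p)
        errors.append(evaluate_combo(dataset, combo, settings,
                                     criteria).mean_error_mm)
    return PressureSweep(pressures=pressures, errors=tuple(errors))


def make_engine_truth(deflated: dict[str, SurfaceMesh], params: SimParams,
                      settings: SimulationSettings | None = None,
                      criteria: EquilibriumCriteria | None = None,
                      name: str = "engine-truth") -> CalibrationDataset:
    """Run the pipeline once at known parameters and wrap the deformed
    surfaces as a ground-truth dataset (self-consistency harness)."""
    result = run_pipeline(deflated, params, settings, criteria)
    if not result.report.converged:
        raise RuntimeError("truth generation did not converge")
    return CalibrationDataset(name=name, deflated=deflated,
                              truth_inflatable=result.inflatable_mesh,
                              truth_skin=result.skin_mesh)


def error_report_for(dataset: CalibrationDataset, params: SimParams,
                     settings: SimulationSettings | None = None,
                     criteria: EquilibriumCriteria | None = None):
    """Full error summary (mean/std/min/max) at one parameter set."""
    result = run_pipeline(dataset.deflated, params, settings, criteria)
    mode = dataset.correspondence_mode()
    err = vertex_errors(result.inflatable_mesh, dataset.truth_inflatable,
                        mode)
    return summarize_errors(err, mode), result
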