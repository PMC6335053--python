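"""Reproducible file-writing entry points over the modeling modules.

Each runner takes a :class:`RunConfig` (or keyword arguments), executes
one analysis and writes CSV tables plus a JSON provenance sidecar
(parameters, geometry, seed, package version) sufficient to reproduce
the outputs byte-for-byte. These functions are the scripting surface of
the package; there is no shell command — call them from Python.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .kinetics import StimulusProtocol, conserved_sums, simulate, sweep_k12
from .spatial import (
    center_concentration_vs_radius,
    disk_source_profile_numeric,
    global_balance_error,
    point_source_profile,
)
from .synth import fit_k12, generate_trace, recovery_experiment
from .units import (
    GeometryParams,
    ParameterSet,
    default_parameters,
    load_parameters,
    save_parameters,
)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Common settings for the runners.

    ``params_file`` (JSON, see :func:`girkflow.units.load_parameters`)
    overrides the built-in defaults; ``geometry`` fields override the
    default membrane geometry. ``seed`` is required by the stochastic
    runners (:func:`run_recover`, :func:`make_fixtures`).
    """

    out_dir: str | Path = "."
    params_file: str | Path | None = None
    receptor_class: str = "Gi-coupled"
    geometry_overrides: dict = field(default_factory=dict)
    seed: int | None = None

    def load(self) -> tuple[ParameterSet, GeometryParams]:
        if self.params_file is not None:
            path = Path(self.params_file)
            if not path.exists():
                raise ConfigError(f"params_file not found: {path}")
            params = load_parameters(path)
        else:
            params = default_parameters(self.receptor_class)
        try:
            geometry = GeometryParams(**self.geometry_overrides)
        except (TypeError, ValueError) as err:
            raise ConfigError(f"bad geometry override: {err}") from err
        return params, geometry

    def outdir(self) -> Path:
        out = Path(self.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        return out


def _write_sidecar(path: Path, payload: dict) -> None:
    payload = dict(payload)
    payload["girkflow_version"] = __version__
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_jsonify) + "\n")


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (ParameterSet, GeometryParams)):
        return asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_simulate(
    config: RunConfig,
    k12: float | None = None,
    t_end: float = 10.0,
    initial: str = "naive",
) -> dict[str, Path]:
    """Simulate a k12 step stimulus and write the time course.

    Writes ``timecourse.csv`` (t plus all species densities) and
    ``timecourse.json`` with parameters, protocol, conservation drift
    and solver settings. Returns the paths.
    """
    params, geometry = config.load()
    if k12 is not None:
        params = params.replace(k12=k12)
    protocol = StimulusProtocol.step(params.k12, t_end)
    tc = simulate(params, geometry, protocol, t_end, initial=initial)
    out = config.outdir()
    csv_path = out / "timecourse.csv"
    df = tc.to_dataframe()
    df.to_csv(csv_path, index=False, float_format="%.10g")
    drift = tc.conservation_drift()
    _write_sidecar(out / "timecourse.json", {
        "command": "simulate",
        "params": params,
        "geometry": geometry,
        "protocol": list(protocol.segments),
        "initial": initial,
        "conservation_drift": drift,
    })
    return {"csv": csv_path, "sidecar": out / "timecourse.json"}


def run_sweep(
    config: RunConfig,
    k12_grid: np.ndarray | None = None,
) -> dict[str, Path]:
    """Steady-state GIRK·βγ₄ across a k12 grid; writes ``sweep.csv``."""
    params, geometry = config.load()
    if k12_grid is None:
        k12_grid = np.geomspace(params.k12 * 1e-3, params.k12 * 10.0, 30)
    table = sweep_k12(params, geometry, k12_grid)
    out = config.outdir()
    csv_path = out / "sweep.csv"
    table.to_csv(csv_path, index=False, float_format="%.10g")
    _write_sidecar(out / "sweep.json", {
        "command": "sweep", "params": params, "geometry": geometry,
        "k12_grid": np.asarray(k12_grid),
    })
    return {"csv": csv_path, "sidecar": out / "sweep.json"}


def run_spatial(
    config: RunConfig,
    radii: np.ndarray | None = None,
    mesh_size: int = 1200,
) -> dict[str, Path]:
    """Write the point-source and hotspot-disk profiles and the
    center-concentration-vs-radius table.

    Outputs: ``point_profile.csv``, ``disk_profile.csv`` (columns
    r_um, C_per_um2, C_uM), ``center_vs_radius.csv`` and a JSON sidecar
    including the global balance error and boundary-insensitivity margin.
    """
    _, geometry = config.load()
    out = config.outdir()

    point = point_source_profile(geometry)
    disk = disk_source_profile_numeric(geometry, mesh_size=mesh_size)
    if radii is None:
        radii = np.linspace(0.05, 1.0, 20)
    cvr = center_concentration_vs_radius(geometry, radii, mesh_size=mesh_size)

    thickness = geometry.layer_thickness
    point.to_dataframe(thickness).to_csv(out / "point_profile.csv", index=False,
                                         float_format="%.10g")
    disk.to_dataframe(thickness).to_csv(out / "disk_profile.csv", index=False,
                                        float_format="%.10g")
    cvr.to_csv(out / "center_vs_radius.csv", index=False, float_format="%.10g")

    # boundary-insensitivity margin: C(0) change when the far boundary doubles
    wide = disk_source_profile_numeric(
        geometry.replace(outer_radius=2.0 * geometry.far_boundary),
        mesh_size=mesh_size,
    )
    margin = abs(wide.C[0] - disk.C[0]) / disk.C[0]
    _write_sidecar(out / "spatial.json", {
        "command": "spatial",
        "geometry": geometry,
        "mesh_size": mesh_size,
        "center_concentration_per_um2": float(disk.C[0]),
        "global_balance_error": global_balance_error(disk),
        "boundary_insensitivity_margin": float(margin),
    })
    return {
        "point_csv": out / "point_profile.csv",
        "disk_csv": out / "disk_profile.csv",
        "center_vs_radius_csv": out / "center_vs_radius.csv",
        "sidecar": out / "spatial.json",
    }


def run_recover(
    config: RunConfig,
    k12_true_grid: np.ndarray | None = None,
    n_reps: int = 50,
    noise_frac: float = 0.05,
    n_boot: int = 200,
) -> dict[str, Path]:
    """Run the seeded k12 recovery study and write ``recovery.csv``."""
    if config.seed is None:
        raise ConfigError("run_recover requires a seed")
    params, geometry = config.load()
    if k12_true_grid is None:
        k12_true_grid = np.array([params.k12 / 10.0, params.k12, params.k12 * 3.0])
    table = recovery_experiment(
        k12_true_grid, n_reps=n_reps, noise_frac=noise_frac,
        seed=config.seed, params=params, geometry=geometry, n_boot=n_boot,
    )
    out = config.outdir()
    csv_path = out / "recovery.csv"
    table.to_csv(csv_path, index=False, float_format="%.10g")
    _write_sidecar(out / "recovery.json", {
        "command": "recover", "params": params, "geometry": geometry,
        "seed": config.seed, "n_reps": n_reps, "noise_frac": noise_frac,
        "n_boot": n_boot, "k12_true_grid": np.asarray(k12_true_grid),
    })
    return {"csv": csv_path, "sidecar": out / "recovery.json"}


def make_fixtures(seed: int, outdir: str | Path) -> dict[str, Path]:
    """Emit a small seeded fixture bundle for tests and examples.

    Contents: the default parameter JSON, a noiseless and a noisy trace
    (CSV + truth JSON), and a coarse hotspot radial profile. Idempotent:
    the same seed reproduces identical bytes.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    params = default_parameters()
    geometry = GeometryParams()
    paths: dict[str, Path] = {}

    paths["params"] = out / "params.json"
    save_parameters(params, paths["params"])

    protocol = StimulusProtocol.step(params.k12, 10.0)
    clean = generate_trace(params, geometry, protocol, scale=1.0, noise_sd=0.0,
                           seed=seed)
    noise_sd = 0.05 * float(clean.y.max())
    noisy = generate_trace(params, geometry, protocol, scale=1.0,
                           noise_sd=noise_sd, seed=seed)
    for name, trace in (("trace_clean", clean), ("trace_noisy", noisy)):
        paths[name] = out / f"{name}.csv"
        trace.to_dataframe().to_csv(paths[name], index=False, float_format="%.10g")
    _write_sidecar(out / "trace_truth.json", {
        "k12": params.k12, "scale": 1.0, "noise_sd": noise_sd, "seed": seed,
    })
    paths["truth"] = out / "trace_truth.json"

    profile = disk_source_profile_numeric(geometry, mesh_size=400)
    paths["profile"] = out / "disk_profile.csv"
    profile.to_dataframe(geometry.layer_thickness).to_csv(
        paths["profile"], index=False, float_format="%.10g")
    return paths
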