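"""Config-driven, reproducible runs wiring the modules together.

Each run function takes a flat configuration mapping (typically loaded from
a YAML document), executes one pipeline stage, writes its outputs as
plain-text files into an output directory, and drops a manifest (config
copy, seed, package version) beside them so the full
synth -> fit -> bootstrap -> derive chain is reproducible from the manifests
alone.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .bootstrap import run_bootstrap as _run_bootstrap
from .data import load_counts, save_counts
from .estimation import (
    FitProblem,
    default_values,
    fit as _fit,
    values_to_irradiation,
    values_to_params,
)
from .experiments import knockout_experiment, compare_topologies
from .metrics import derive_from_fit
from .params import Topology, params_from_yaml, params_to_yaml
from .simulate import SimulationSpec, simulate
from .synth import NoiseModel, StudyDesign, generate

__all__ = [
    "load_config",
    "run_synth",
    "run_simulate",
    "run_fit",
    "run_bootstrap",
    "run_derive",
    "run_knockout",
    "run_compare_models",
]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path} does not contain a configuration mapping")
    return cfg


def _write_manifest(out_dir: Path, command: str, cfg: Mapping, seed) -> None:
    from . import __version__

    manifest = {
        "command": command,
        "config": {k: v for k, v in cfg.items()},
        "seed": seed,
        "package_version": __version__,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def _resolve_values(cfg: Mapping, topology: Topology) -> dict:
    values = default_values(topology)
    if cfg.get("values_file"):
        values.update(params_from_yaml(cfg["values_file"]))
    values.update({k: float(v) for k, v in (cfg.get("values") or {}).items()})
    return values


def _out_dir(cfg: Mapping) -> Path:
    out = Path(cfg.get("out_dir", "."))
    out.mkdir(parents=True, exist_ok=True)
    return out


def run_synth(cfg: Mapping) -> Path:
    """Generate a synthetic dataset; writes dataset.csv and truth.yaml."""
    topology = Topology[cfg.get("topology", "COARSE")]
    values = _resolve_values(cfg, topology)
    seed = cfg.get("seed", 0)
    design = StudyDesign(**(cfg.get("design") or {}))
    noise = NoiseModel(sigma=cfg.get("sigma", 0.2))
    df = generate(values_to_params(topology, values),
                  values_to_irradiation(topology, values),
                  design=design, noise=noise, seed=seed)
    out = _out_dir(cfg)
    save_counts(df, out / "dataset.csv")
    params_to_yaml(values, out / "truth.yaml")
    _write_manifest(out, "synth", cfg, seed)
    return out / "dataset.csv"


def run_simulate(cfg: Mapping) -> Path:
    """Simulate a trajectory; writes trajectory.csv (tidy day/cell_type table)."""
    topology = Topology[cfg.get("topology", "COARSE")]
    values = _resolve_values(cfg, topology)
    t_end = float(cfg.get("t_end", 49.0))
    n_points = int(cfg.get("n_points", 491))
    spec = SimulationSpec(
        params=values_to_params(topology, values),
        irr=values_to_irradiation(topology, values),
        grid=np.linspace(0.0, t_end, n_points),
        rtol=float(cfg.get("rtol", 1e-8)), atol=float(cfg.get("atol", 1e-2)))
    traj = simulate(spec)
    out = _out_dir(cfg)
    traj.to_frame().to_csv(out / "trajectory.csv", index=False)
    _write_manifest(out, "simulate", cfg, cfg.get("seed"))
    return out / "trajectory.csv"


def _problem_from_cfg(cfg: Mapping) -> FitProblem:
    topology = Topology[cfg.get("topology", "COARSE")]
    values = _resolve_values(cfg, topology)
    data = load_counts(cfg["dataset"])
    return FitProblem(
        topology=topology, data=data, values=values,
        free=list(cfg.get("free", [])),
        guess={k: float(v) for k, v in (cfg.get("guess") or {}).items()},
        replicate_mode=cfg.get("replicate_mode", "replicates"),
        rtol=float(cfg.get("fit_rtol", 1e-6)))


def run_fit(cfg: Mapping) -> Path:
    """Fit a topology to a dataset; writes fit.yaml and fit_summary.csv."""
    problem = _problem_from_cfg(cfg)
    result = _fit(problem, max_nfev=cfg.get("max_nfev"))
    out = _out_dir(cfg)
    params_to_yaml(result.values, out / "fit.yaml")
    result.summary().assign(objective=result.objective,
                            converged=result.success).to_csv(
        out / "fit_summary.csv", index=False)
    _write_manifest(out, "fit", cfg, cfg.get("seed"))
    return out / "fit.yaml"


def run_bootstrap(cfg: Mapping) -> Path:
    """Fit then bootstrap; writes bootstrap_samples.csv and intervals.csv."""
    problem = _problem_from_cfg(cfg)
    result = _fit(problem, max_nfev=cfg.get("max_nfev"))
    seed = cfg.get("seed", 0)
    bres = _run_bootstrap(result, B=int(cfg.get("B", 1000)),
                          alpha=float(cfg.get("alpha", 0.95)), seed=seed)
    out = _out_dir(cfg)
    bres.samples_frame().to_csv(out / "bootstrap_samples.csv", index=False)
    bres.interval_frame().to_csv(out / "bootstrap_intervals.csv", index=False)
    _write_manifest(out, "bootstrap", cfg, seed)
    return out / "bootstrap_intervals.csv"


def run_derive(cfg: Mapping) -> Path:
    """Fit then compute composite kinetic quantities; writes derived.csv."""
    problem = _problem_from_cfg(cfg)
    result = _fit(problem, max_nfev=cfg.get("max_nfev"))
    dq = derive_from_fit(result)
    out = _out_dir(cfg)
    dq.to_frame().to_csv(out / "derived.csv", index=False)
    _write_manifest(out, "derive", cfg, cfg.get("seed"))
    return out / "derived.csv"


def run_knockout(cfg: Mapping) -> Path:
    """In-silico crosstalk knockout; writes knockout.csv."""
    topology = Topology[cfg.get("topology", "COARSE")]
    values = _resolve_values(cfg, topology)
    overrides = cfg.get("overrides")
    report = knockout_experiment(
        values_to_params(topology, values),
        values_to_irradiation(topology, values),
        overrides={k: float(v) for k, v in overrides.items()} if overrides else None)
    out = _out_dir(cfg)
    report.outcomes_frame().to_csv(out / "knockout.csv", index=False)
    _write_manifest(out, "knockout", cfg, cfg.get("seed"))
    return out / "knockout.csv"


def run_compare_models(cfg: Mapping) -> Path:
    """Fit alternative topologies and report rejection diagnostics (JSON)."""
    data = load_counts(cfg["dataset"])
    problems = []
    for sub in cfg["topologies"]:
        topology = Topology[sub["topology"]]
        values = _resolve_values(sub, topology)
        problems.append(FitProblem(
            topology=topology, data=data, values=values,
            free=list(sub.get("free", [])),
            guess={k: float(v) for k, v in (sub.get("guess") or {}).items()},
            rtol=float(sub.get("fit_rtol", 1e-6))))
    report = compare_topologies(problems, **(cfg.get("options") or {}))
    out = _out_dir(cfg)
    with open(out / "topology_comparison.json", "w") as fh:
        json.dump(report.outcomes, fh, indent=2, sort_keys=True, default=float)
    _write_manifest(out, "compare-models", cfg, cfg.get("seed"))
    return out / "topology_comparison.json"
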