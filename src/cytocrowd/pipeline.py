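"""Configuration-driven orchestration: generate -> simulate -> analyze.

A run configuration (YAML/JSON or dict) names a master seed, an output
directory and an ordered list of stages with parameter blocks.  The
workflow validates the whole configuration against a schema before any
stage runs, executes stages in order passing artifacts (system,
trajectory) forward, and emits a machine-readable JSON report with
per-stage metrics, seeds, package version, the configuration hash and
per-stage content hashes (identical configuration and seed give identical
hashes for deterministic stages).  Presets encode the production parameter
choices (tau_max = 10 ns, dt_origin, 50 A coordination cutoff, Rcut in
[2, 3], tau_short) so defaults match the methods conventions.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .bd_engine import BDParams, PotentialParams, run_simulation
from .diffusion import fit_size_scaling, species_diffusion
from .interactions import group_interaction_matrix
from .io_core import SimulationBox, SpeciesTable, Trajectory, write_trajectory
from .synthetic_data import (gen_lj_mixture, gen_packed_configuration,
                             mg_like_species_table)

__all__ = ["RunConfig", "ConfigError", "run_workflow", "preset_config",
           "lj_depletion_excess"]

log = logging.getLogger("cytocrowd.pipeline")

_STAGES = ("generate_packed", "simulate", "analyze_diffusion",
           "analyze_quinary", "lj_depletion")


class ConfigError(ValueError):
    """Configuration violates the workflow schema."""


class RunConfig(dict):
    """Validated workflow configuration (a thin dict wrapper)."""

    @classmethod
    def load(cls, source) -> "RunConfig":
        if isinstance(source, (str, Path)):
            text = Path(source).read_text()
            data = yaml.safe_load(text)
        elif isinstance(source, dict):
            data = dict(source)
        else:
            raise ConfigError(f"cannot load configuration from {type(source)}")
        if "preset" in data:
            base = preset_config(data.pop("preset"))
            base.update(data)
            data = base
        cfg = cls(data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not isinstance(self.get("seed"), int):
            raise ConfigError("'seed' must be an integer")
        stages = self.get("stages")
        if not isinstance(stages, list) or not stages:
            raise ConfigError("'stages' must be a non-empty list")
        for i, st in enumerate(stages):
            if not isinstance(st, dict) or "name" not in st:
                raise ConfigError(f"stage {i} must be a mapping with a 'name'")
            if st["name"] not in _STAGES:
                raise ConfigError(
                    f"unknown stage '{st['name']}'; allowed: {_STAGES}")
            params = st.get("params", {})
            if not isinstance(params, dict):
                raise ConfigError(f"stage {st['name']}: 'params' must be a mapping")
            if st["name"] == "generate_packed":
                table = params.get("species_table")
                if table is not None and not Path(table).exists():
                    raise ConfigError(
                        f"species table not found: {table}")
        needs_traj = {"analyze_diffusion", "analyze_quinary"}
        have_traj = False
        for st in stages:
            if st["name"] == "simulate":
                have_traj = True
            if st["name"] in needs_traj and not have_traj:
                raise ConfigError(
                    f"stage '{st['name']}' needs a prior 'simulate' stage")

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def preset_config(name: str) -> dict:
    """Built-in configurations.

    * ``demo``: small packed system, 1e5 BD steps, diffusion + quinary
      analysis -- a desk-scale smoke run.
    * ``mgcg_scaled``: the cytoplasm-like composition at scale factor 3
      (648 spheres), 1 us of production BD.
    * ``ljmix``: the depletion mixture comparison (AB vs AD).
    """
    if name == "demo":
        return {
            "seed": 0,
            "stages": [
                {"name": "generate_packed",
                 "params": {"demo_table": True, "scale_factor": 1}},
                {"name": "simulate",
                 "params": {"steps": 100_000, "timestep": 8.0,
                            "output_stride": 100}},
                {"name": "analyze_diffusion",
                 "params": {"tau_max": 10_000.0, "fit_fraction": 0.8}},
                {"name": "analyze_quinary", "params": {"tau_short": 5000.0}},
            ],
        }
    if name == "mgcg_scaled":
        return {
            "seed": 0,
            "stages": [
                {"name": "generate_packed", "params": {"scale_factor": 3}},
                {"name": "simulate",
                 "params": {"steps": 131_250, "timestep": 8.0,
                            "output_stride": 50, "discard_ps": 50_000.0}},
                {"name": "analyze_diffusion",
                 "params": {"tau_max": 10_000.0, "fit_fraction": 0.8}},
            ],
        }
    if name == "ljmix":
        return {
            "seed": 0,
            "stages": [
                {"name": "lj_depletion",
                 "params": {"cases": ["AB", "AD"], "r_eval": 6.0}},
            ],
        }
    raise ConfigError(f"unknown preset '{name}'")


def _demo_species_table() -> SpeciesTable:
    return SpeciesTable.from_records([
        dict(name="big", stokes_radius=50.0, copies=2, group="huge"),
        dict(name="medium", stokes_radius=25.0, copies=20, group="protein"),
        dict(name="glyco", stokes_radius=22.0, copies=10, group="glycolytic"),
        dict(name="small", stokes_radius=16.0, copies=30, group="protein"),
    ])


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _stage_hash(metrics: dict) -> str:
    return hashlib.sha256(
        json.dumps(metrics, sort_keys=True, default=_json_default).encode()
    ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def lj_depletion_excess(cases=("AB", "AD"), seed: int = 0, r_eval: float = 6.0,
                        equil_steps: int = 100_000, steps: int = 200_000,
                        timestep: float = 0.02, output_stride: int = 500,
                        r_contact: float = 4.0) -> dict:
    """Cumulative A-around-A coordination for two mixtures and their excess.

    Runs both mixture cases with identical protocols and returns the
    frame-averaged cumulative number of A neighbours within ``r_eval`` of
    each A particle, plus the excess of the second case over the first
    beyond the A-A contact distance (~4 A).
    """
    from ._kernels import count_within

    results = {}
    for case in cases:
        system = gen_lj_mixture(case, seed=seed)
        case_tag = sum(ord(c) for c in case)
        bd = BDParams(timestep=timestep, scheme="iniesta_delatorre",
                      seed=(seed * 1009 + case_tag) % (2 ** 31),
                      steps=steps, output_stride=output_stride)
        pot = PotentialParams(form="lj_coulomb" if case == "AD_rep"
                              else "lennard_jones")
        traj = run_simulation(system, bd, pot, soft_start=True,
                              equilibration_steps=equil_steps, force_cap=50.0)
        a_idx = traj.indices_of("A")
        L = traj.box.edge_length
        acc = 0.0
        n_frames = 0
        for f in range(traj.n_frames // 2, traj.n_frames):
            pos = np.mod(traj.positions[f, a_idx], L)
            counts = count_within(pos, pos, L, r_eval)
            acc += float(counts.mean()) - 1.0   # self-count removed
            n_frames += 1
        results[case] = acc / n_frames
    keys = list(results)
    return {
        "cumulative_A_around_A": results,
        "r_eval": r_eval,
        "r_contact": r_contact,
        "excess": results[keys[1]] - results[keys[0]],
        "cases": keys,
    }


def _stage_generate(ctx: dict, params: dict, seed: int) -> dict:
    if params.get("demo_table"):
        table = _demo_species_table()
        phi = 0.30
        edge = (table.sphere_volume() * params.get("scale_factor", 1) / phi) ** (1 / 3)
        box = SimulationBox(edge)
    elif params.get("species_table"):
        table = SpeciesTable.from_tsv(params["species_table"])
        box = SimulationBox(params["box_edge"]) if "box_edge" in params else None
    else:
        table = mg_like_species_table()
        box = None
    system = gen_packed_configuration(table, box=box, seed=seed,
                                      scale_factor=params.get("scale_factor", 1))
    ctx["system"] = system
    ctx["table"] = system.table
    return {
        "n_particles": system.n_particles,
        "volume_fraction": round(system.volume_fraction(), 6),
        "box_edge": system.box.edge_length,
        "min_surface_gap": round(system.min_surface_gap(), 6),
    }


def _stage_simulate(ctx: dict, params: dict, seed: int) -> dict:
    if "system" not in ctx:
        raise ConfigError("simulate stage requires a generated system")
    bd = BDParams(timestep=params.get("timestep", 8.0),
                  scheme=params.get("scheme", "iniesta_delatorre"),
                  seed=seed, steps=int(params.get("steps", 100_000)),
                  output_stride=int(params.get("output_stride", 100)))
    traj, report = run_simulation(ctx["system"], bd, return_report=True)
    discard = float(params.get("discard_ps", 0.0))
    if discard > 0:
        keep = traj.times >= discard
        traj = Trajectory(times=traj.times[keep] - traj.times[keep][0],
                          positions=traj.positions[keep], labels=traj.labels,
                          box=traj.box, wrapped=False)
    ctx["trajectory"] = traj
    if "outdir" in ctx and params.get("write_trajectory", False):
        out = Path(ctx["outdir"]) / "trajectory.xyz"
        write_trajectory(traj, out)
    return {
        "steps": bd.steps, "timestep_ps": bd.timestep,
        "n_frames": traj.n_frames, "span_ps": float(traj.times[-1]),
        "scheme": bd.scheme,
        "final_energy_kBT": report["energy_trace_kBT"][-1],
    }


def _stage_diffusion(ctx: dict, params: dict, seed: int) -> dict:
    traj, table = ctx["trajectory"], ctx["table"]
    results = species_diffusion(traj, table,
                                tau_max=params.get("tau_max", 10_000.0),
                                fit_fraction=params.get("fit_fraction", 0.8))
    rs = np.array([table.radius_of(n) for n in results])
    ratio = np.array([results[n].ratio for n in results])
    fit = fit_size_scaling(rs, ratio, "B_over_Rs")
    per_species = {
        n: {"Rs": table.radius_of(n), "D_tr": results[n].d_tr,
            "D0": results[n].d0, "ratio": results[n].ratio,
            "r_squared": results[n].r_squared}
        for n in results
    }
    return {"per_species": per_species,
            "B_over_Rs": fit.coefficients["B"],
            "fit_r_squared": fit.r_squared}


def _stage_quinary(ctx: dict, params: dict, seed: int) -> dict:
    traj, table = ctx["trajectory"], ctx["table"]
    mat = group_interaction_matrix(traj, table,
                                   tau_short=params.get("tau_short", 5000.0),
                                   seed=seed)
    out = {}
    for key, val in mat.delta_d.items():
        out["-".join(key)] = {"delta_d": val, "se": mat.stderr[key],
                              "n_pairs": mat.n_pairs[key]}
    for key in mat.absent:
        out["-".join(key)] = {"absent": True}
    return {"delta_d_matrix": out}


def _stage_lj(ctx: dict, params: dict, seed: int) -> dict:
    return lj_depletion_excess(cases=tuple(params.get("cases", ("AB", "AD"))),
                               seed=seed, r_eval=params.get("r_eval", 6.0),
                               equil_steps=int(params.get("equil_steps", 200_000)),
                               steps=int(params.get("steps", 400_000)))


_STAGE_FNS = {
    "generate_packed": _stage_generate,
    "simulate": _stage_simulate,
    "analyze_diffusion": _stage_diffusion,
    "analyze_quinary": _stage_quinary,
    "lj_depletion": _stage_lj,
}


def run_workflow(config, outdir: str | Path | None = None) -> dict:
    """Validate and execute a workflow; returns (and writes) the report."""
    cfg = RunConfig.load(config)
    outdir = Path(outdir or cfg.get("outdir", "."))
    outdir.mkdir(parents=True, exist_ok=True)
    master_seed = int(cfg["seed"])
    report: dict = {
        "version": __version__,
        "config_hash": cfg.hash(),
        "seed": master_seed,
        "stages": {},
        "stage_hashes": {},
        "timing_s": {},
    }
    ctx: dict = {"outdir": str(outdir)}
    for i, st in enumerate(cfg["stages"]):
        name = st["name"]
        stage_seed = (master_seed * 100_003 + i * 7919 + 1) % (2 ** 31)
        t0 = time.time()
        log.info("stage %s (seed %d) ...", name, stage_seed)
        try:
            metrics = _STAGE_FNS[name](ctx, st.get("params", {}), stage_seed)
        except Exception as exc:
            report["stages"][name] = {"failed": True, "error": str(exc)}
            report["failed_stage"] = name
            log.error("stage %s failed: %s", name, exc)
            break
        report["stages"][name] = metrics
        report["stage_hashes"][name] = _stage_hash(metrics)
        report["timing_s"][name] = round(time.time() - t0, 3)
    path = outdir / "report.json"
    path.write_text(json.dumps(report, indent=2, default=_json_default))
    return report
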