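"""End-to-end orchestration: build -> simulate (two arms) -> analyze.

Mirrors the restrained/unrestrained two-arm design: a shared force field is
run once with a harmonic ligand-target restraint and once without it; the
restrained arm is filtered to close-approach frames (< 7 A by default) and
decomposed into rotation/tilt angles, while the unrestrained arm provides the
per-residue average spatial deviation and the free energy versus tilt.

All artifacts of a run live under one output directory together with an
append-only JSON manifest recording the configuration snapshot, seeds, force
field hash and per-stage outputs.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import os
import time

import numpy as np
import yaml

from . import __version__
from .builder import (
    ForceField,
    add_distance_restraint,
    build_force_field,
    spring_constant_per_A2,
)
from .rotation import (
    asd_per_residue,
    decompositions_to_frame,
    er_axis_angle,
    free_energy_vs_tilt,
    kabsch_fit,
    rotation_tilt_timeseries,
)
from .simulator import SimConfig, State, Trajectory, distance_mask, distance_timeseries, run_langevin
from .structure import Selection, select_atoms, write_structure
from .synthetic import (
    ToySpec,
    make_disordered_tail,
    make_rotated_conformation,
    make_toy_two_domain_system,
    write_ground_truth,
)
from .topology import export_topology

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "out_dir": "sbmkit_run",
    "seed": 1,
    "toy": {},                       # ToySpec fields
    "disorder_tail": True,
    "restraint": {"r_min": 5.0, "k_per_nm2": 150.0},
    "simulation": {
        "temperature": 0.5,
        "timestep": 0.002,
        "friction": 1.0,
        "n_steps": 20000,
        "save_interval": 100,
    },
    "analysis": {
        "distance_threshold": 7.0,
        "bin_width": 1.0,
        "jacobian": False,
        "pre_rotation_deg": 45.0,
    },
}

_KNOWN_KEYS = set(DEFAULT_CONFIG)


@dataclasses.dataclass
class RunManifest:
    """Append-only record of one pipeline run."""

    out_dir: str
    config: dict
    seeds: dict
    version: str = __version__
    ff_hash: str = ""
    stages: list = dataclasses.field(default_factory=list)

    def record(self, stage: str, status: str, outputs: list[str] | None = None):
        self.stages.append(
            {"stage": stage, "status": status, "outputs": outputs or [],
             "time": time.strftime("%Y-%m-%dT%H:%M:%S")}
        )
        self.write()

    def write(self):
        path = os.path.join(self.out_dir, "manifest.json")
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @property
    def failed(self) -> bool:
        return any(s["status"] == "failed" for s in self.stages)


def load_config(config: dict | str | os.PathLike) -> dict:
    """Load and validate a pipeline configuration (dict or YAML path)."""
    if not isinstance(config, dict):
        with open(os.fspath(config)) as fh:
            config = yaml.safe_load(fh) or {}
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    merged = {}
    for key, default in DEFAULT_CONFIG.items():
        val = config.get(key, default)
        if isinstance(default, dict):
            sub_unknown = set(val) - set(default) if isinstance(val, dict) else set()
            if key == "toy":
                sub_unknown -= {f.name for f in dataclasses.fields(ToySpec)}
            if sub_unknown:
                raise ValueError(f"unknown config keys in {key!r}: {sorted(sub_unknown)}")
            merged[key] = {**default, **(val or {})}
        else:
            merged[key] = val
    if merged["restraint"]["k_per_nm2"] < 0:
        raise ValueError("restraint spring constant must be >= 0")
    return merged


def run_pipeline(config: dict | str | os.PathLike) -> RunManifest:
    """Execute build -> two simulation arms -> rotation/a.s.d./FES analysis.

    On a stage failure the manifest marks that stage failed and downstream
    stages are skipped; the manifest is returned either way.
    """
    cfg = load_config(config)
    out_dir = cfg["out_dir"]
    os.makedirs(out_dir, exist_ok=True)
    seed = int(cfg["seed"])
    seeds = {"restrained": seed, "unrestrained": seed + 1}
    manifest = RunManifest(out_dir=out_dir, config=cfg, seeds=seeds)

    state: dict = {}
    stages = [
        ("build", _stage_build),
        ("simulate", _stage_simulate),
        ("analyze", _stage_analyze),
    ]
    for name, fn in stages:
        try:
            outputs = fn(cfg, state, manifest)
            manifest.record(name, "ok", outputs)
        except Exception:
            logger.exception("pipeline stage %r failed", name)
            manifest.record(name, "failed")
            break
    return manifest


def _stage_build(cfg, state, manifest):
    out_dir = cfg["out_dir"]
    spec = ToySpec(seed=int(cfg["seed"]), **cfg["toy"])
    native, meta = make_toy_two_domain_system(spec)
    disorder = None
    if cfg["disorder_tail"] and spec.disorder_tail_length > 0:
        native, disorder = make_disordered_tail(native, spec)
        meta["disorder_ranges"] = list(disorder.ranges)
        meta["n_atoms"] = native.n_atoms
    # indices must be taken on the final (possibly tail-extended) structure
    meta["ligand_atom"]["index"] = native.atom_index("L", 1, "S1")
    meta["target_atom"]["index"] = native.atom_index("T", 1, "C1")

    native_pdb = os.path.join(out_dir, "native.pdb")
    write_structure(native, native_pdb)
    gt_path = os.path.join(out_dir, "ground_truth.json")
    write_ground_truth(meta, gt_path)

    ff = build_force_field(native, disorder=disorder)
    top_path = os.path.join(out_dir, "topology.top")
    export_topology(ff, top_path)

    lig = meta["ligand_atom"]["index"]
    trg = meta["target_atom"]["index"]
    k = spring_constant_per_A2(cfg["restraint"]["k_per_nm2"])
    ff_res = add_distance_restraint(ff, lig, trg, cfg["restraint"]["r_min"], k)

    # constructed pre-catalytic end state defines the E-R axis
    domain_idx = select_atoms(native, Selection(meta["domain_selection"]))
    body_idx = select_atoms(native, Selection(meta["body_selection"]))
    pre = make_rotated_conformation(
        native, np.asarray(meta["er_axis_hint"], float),
        cfg["analysis"]["pre_rotation_deg"],
        (meta["hinge"]["chain"], meta["hinge"]["resid"]), domain_idx,
    )
    pre_pdb = os.path.join(out_dir, "pre_catalytic.pdb")
    write_structure(pre, pre_pdb)
    t_body = kabsch_fit(native.coord, pre.coord, body_idx)
    pre_aligned = t_body.apply(pre.coord)
    t_dom = kabsch_fit(pre_aligned, native.coord, domain_idx)
    er_axis, er_angle = er_axis_angle(np.eye(3), t_dom.rotation)
    meta["er_axis"] = [float(v) for v in er_axis]
    meta["er_angle_deg"] = er_angle
    write_ground_truth(meta, gt_path)

    manifest.ff_hash = ff.provenance.get("hash", "")
    state.update(
        native=native, meta=meta, ff=ff, ff_restrained=ff_res,
        domain_idx=domain_idx, body_idx=body_idx, er_axis=np.asarray(er_axis),
    )
    return [native_pdb, gt_path, top_path, pre_pdb]


def _stage_simulate(cfg, state, manifest):
    out_dir = cfg["out_dir"]
    sim = cfg["simulation"]
    outputs = []
    for arm, ff in (("restrained", state["ff_restrained"]), ("unrestrained", state["ff"])):
        config = SimConfig(
            temperature=sim["temperature"], timestep=sim["timestep"],
            friction=sim["friction"], n_steps=int(sim["n_steps"]),
            save_interval=int(sim["save_interval"]),
            seed=manifest.seeds[arm], restraints_active=(arm == "restrained"),
        )
        traj = run_langevin(ff, State(state["native"].coord.copy()), config)
        state[f"traj_{arm}"] = traj
        elog = os.path.join(out_dir, f"energies_{arm}.tsv")
        traj.energies.to_csv(elog, sep="\t", index=False)
        outputs.append(elog)
    return outputs


def _stage_analyze(cfg, state, manifest):
    out_dir = cfg["out_dir"]
    ana = cfg["analysis"]
    meta = state["meta"]
    native = state["native"]
    lig = meta["ligand_atom"]["index"]
    trg = meta["target_atom"]["index"]
    outputs = []

    # restrained arm: close-approach filter then rotation/tilt
    traj_r = state["traj_restrained"]
    dist = distance_timeseries(traj_r, lig, trg)
    mask = distance_mask(traj_r, lig, trg, ana["distance_threshold"])
    decomps_r = rotation_tilt_timeseries(
        traj_r, native, state["body_idx"], state["domain_idx"],
        state["er_axis"], frame_mask=mask,
    )
    df_r = decompositions_to_frame(decomps_r)
    df_all = decompositions_to_frame(
        rotation_tilt_timeseries(
            traj_r, native, state["body_idx"], state["domain_idx"], state["er_axis"]
        )
    )
    df_all["distance"] = dist
    df_all["close"] = mask
    p = os.path.join(out_dir, "rotation_restrained.tsv")
    df_all.to_csv(p, sep="\t", index=False)
    outputs.append(p)
    state["rotation_restrained_close"] = df_r

    # unrestrained arm: rotation/tilt, a.s.d., free energy vs tilt
    traj_u = state["traj_unrestrained"]
    decomps_u = rotation_tilt_timeseries(
        traj_u, native, state["body_idx"], state["domain_idx"], state["er_axis"]
    )
    df_u = decompositions_to_frame(decomps_u)
    p = os.path.join(out_dir, "rotation_unrestrained.tsv")
    df_u.to_csv(p, sep="\t", index=False)
    outputs.append(p)

    d0, d1 = meta["domain_residues"]
    dom_ca = select_atoms(native, Selection(f"chain A and resid {d0}:{d1} and name CA"))
    for arm, traj in (("restrained", traj_r), ("unrestrained", traj_u)):
        prof = asd_per_residue(traj, native, dom_ca)
        p = os.path.join(out_dir, f"asd_{arm}.tsv")
        prof.table.to_csv(p, sep="\t", index=False)
        outputs.append(p)
        state[f"asd_{arm}"] = prof

    fes = free_energy_vs_tilt(
        decomps_u, cfg["simulation"]["temperature"],
        bin_width=ana["bin_width"], jacobian=ana["jacobian"],
    )
    p = os.path.join(out_dir, "fes_tilt.tsv")
    fes.table.to_csv(p, sep="\t", index=False)
    outputs.append(p)
    state["fes"] = fes
    return outputs
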