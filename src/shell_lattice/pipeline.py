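"""End-to-end runs driven by one YAML config, with seeds and JSON reports.

Two entry points mirror the two halves of the analysis:

* :func:`run_insitu_geometry` — surface → (synthetic) particles → cleaning →
  lattice estimate → curvature / bend angles, with STAR/CSV/JSON outputs.
* :func:`run_models_suite` — ideal assemblies (sheet/cube/prism), hinge and
  mass reports, elastic-network modes on the synthetic sheet, pore profiles
  on analytic channel fixtures, collected into one results table.

Reports embed the resolved config and package version and contain no
timestamps, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .builder import (
    TetramerUnit,
    assembly_to_particle_table,
    build_cube,
    build_prism,
    build_sheet,
    point_group_check,
    unfold_cube_to_sheet,
)
from .curation import CurationParams, estimate_lattice, neighbor_count_filter, remove_duplicates
from .curvature import neighbor_bend_angles, principal_curvatures
from .enm import build_anm, build_gnm, generate_ensemble, variance_fractions
from .io_formats import BeadModel, read_mesh, read_particle_table, write_particle_table
from .synthetic import CorruptionSpec, SurfaceSpec, corrupt_particles, decorate_lattice, make_channel, make_sheet_beads, make_surface

__all__ = ["load_config", "run_insitu_geometry", "run_models_suite"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        return dict(path_or_dict)
    with open(path_or_dict) as fh:
        return yaml.safe_load(fh) or {}


def run_insitu_geometry(config) -> dict:
    """Seed/clean/measure pipeline on real or synthetic shell data.

    Config keys: ``seed`` (global), ``output_dir``, and either ``mesh`` (+
    optional ``particles``) paths or a ``synthetic`` block with ``surface``,
    ``lattice`` and ``corruption`` sub-blocks.  Optional ``curation``,
    ``bend`` and ``curvature`` blocks override defaults.
    """
    cfg = load_config(config)
    seed = int(cfg.get("seed", 0))
    outdir = Path(cfg.get("output_dir", "."))

    has_synth = "synthetic" in cfg
    has_mesh = "mesh" in cfg
    if not has_synth and not has_mesh:
        raise PipelineError("stage 'validate' failed: config needs either a mesh path or a synthetic block")
    outdir.mkdir(parents=True, exist_ok=True)

    report: dict = {"config": cfg, "version": __version__, "stages": {}}

    if has_synth:
        synth = cfg["synthetic"]
        surf_cfg = dict(synth.get("surface", {"kind": "sphere", "size": [800.0]}))
        surf_cfg.setdefault("seed", seed)
        mesh = make_surface(SurfaceSpec(**surf_cfg))
        lat_cfg = dict(synth.get("lattice", {}))
        decorated = decorate_lattice(mesh, **lat_cfg)
        table = decorated.table
        report["stages"]["simulate"] = {
            "n_true_particles": len(table),
            "surface_area_A2": round(float(mesh.area), 3),
        }
        corr_cfg = dict(synth.get("corruption", {}))
        if corr_cfg:
            corr_cfg.setdefault("seed", seed)
            table = corrupt_particles(table, CorruptionSpec(**corr_cfg), mesh=mesh)
            report["stages"]["corrupt"] = {"n_particles": len(table)}
    else:
        mesh = read_mesh(cfg["mesh"])
        if "particles" not in cfg:
            raise PipelineError("stage 'validate' failed: mesh without particles or synthetic block")
        table = read_particle_table(cfg["particles"])
        report["stages"]["load"] = {"n_particles": len(table)}

    cur_cfg = CurationParams(**cfg.get("curation", {}))
    n0 = len(table)
    table = remove_duplicates(table, cur_cfg)
    n1 = len(table)
    table = neighbor_count_filter(table, cur_cfg)
    n2 = len(table)
    report["stages"]["clean"] = {
        "input": n0,
        "removed_duplicates": n0 - n1,
        "removed_few_neighbors": n1 - n2,
        "output": n2,
    }
    write_particle_table(table, outdir / "cleaned.star")

    est = estimate_lattice(table, **cfg.get("lattice_estimate", {}))
    report["stages"]["estimate_lattice"] = {
        "a_A": round(est.a, 3),
        "b_A": round(est.b, 3),
        "gamma_deg": round(est.gamma, 3),
        "group_call": est.group_call,
    }

    bend_cfg = cfg.get("bend", {})
    pairs, angles = neighbor_bend_angles(table, bend_cfg.get("rmin", 100.0), bend_cfg.get("rmax", 130.0))
    if len(angles):
        report["stages"]["bend"] = {
            "n_pairs": int(len(angles)),
            "mean_deg": round(float(angles.mean()), 3),
            "min_deg": round(float(angles.min()), 3),
            "max_deg": round(float(angles.max()), 3),
        }
    curv_cfg = cfg.get("curvature", {})
    field = principal_curvatures(mesh, curv_cfg.get("radius_hint"), curv_cfg.get("polygon_side", 57.5))
    ok = field.valid
    report["stages"]["curvature"] = {
        "n_vertices": int(len(ok)),
        "n_valid": int(ok.sum()),
        "kappa1_mean_invA": float(np.round(np.nanmean(field.kappa1[ok]), 8)),
        "kappa2_mean_invA": float(np.round(np.nanmean(field.kappa2[ok]), 8)),
        "theta1_mean_deg": round(float(np.nanmean(field.theta1[ok])), 3),
    }
    import pandas as pd

    pd.DataFrame({
        "kappa1_invA": field.kappa1,
        "kappa2_invA": field.kappa2,
        "theta1_deg": field.theta1,
        "theta2_deg": field.theta2,
        "valid": field.valid,
    }).to_csv(outdir / "curvature.csv", index=False)

    _write_report(report, outdir / "report.json")
    return report


def run_models_suite(config=None) -> dict:
    """Ideal-assembly, elastic-network and pore-fixture suite.

    Produces a results table of the desk-scale observables (protomer counts,
    masses, bend angles, expansion factors, mode spectra, fixture pore
    sizes) with each row's computed value, reference value and pass flag.
    """
    cfg = load_config(config or {})
    outdir = Path(cfg.get("output_dir", ".")) if "output_dir" in cfg else None
    unit = TetramerUnit(**cfg.get("unit", {}))
    stages = cfg.get("stages", ["assemblies", "enm", "pore"])
    report: dict = {"config": cfg, "version": __version__, "results": []}
    rows = report["results"]

    def add(name, value, reference, tol):
        rows.append({
            "name": name,
            "value": value,
            "reference": reference,
            "pass": bool(abs(value - reference) <= tol),
        })

    if "assemblies" in stages:
        cube = build_cube(unit)
        prism = build_prism(unit)
        sheet = build_sheet(unit, 3, 3)
        add("cube_protomers", cube.n_protomers, 24, 0)
        add("cube_mass_MDa", round(cube.mass_mda, 2), 1.67, 0.005)
        add("prism_protomers", prism.n_protomers, 40, 0)
        add("prism_mass_MDa", round(prism.mass_mda, 2), 2.78, 0.005)
        add("sheet3x3_mass_kDa", sheet.mass_kda, 2502.0, 1e-9)
        from .curvature import neighbor_bend_angles as nba

        ctab = assembly_to_particle_table(cube)
        edge_len = unit.side / np.sqrt(2.0)
        _, angles = nba(ctab, rmin=edge_len * 0.9, rmax=edge_len * 1.1)
        add("cube_edge_bend_deg", round(float(np.mean(np.abs(angles))), 6), 90.0, 1e-6)
        add("cube_O_symmetry", float(point_group_check(cube, "O")), 1.0, 0)
        add("prism_D4_symmetry", float(point_group_check(prism, "D4")), 1.0, 0)
        net, unfold_report = unfold_cube_to_sheet(cube)
        add("cube_net_tiles", unfold_report["n_tiles"], 6, 0)
        add("cts1_rotation_deg", round(unfold_report["cts1_rotation_deg"], 1), 54.7, 0.1)
        env = prism.envelope()
        add("prism_aspect", round(float(env[2] / env[0]), 3), round(335.0 / 220.0, 3), 1e-9)

    if "enm" in stages:
        # closed-form three-bead chain: eigenvalues {0, 1, 3}
        chain = BeadModel(coords=[[0, 0, 0], [8, 0, 0], [16, 0, 0]], masses=[100, 100, 100])
        gnm = build_gnm(chain, cutoff=10.0)
        add("gnm_chain_lambda2", round(float(gnm.eigenvalues[1]), 9), 1.0, 1e-9)
        add("gnm_chain_lambda3", round(float(gnm.eigenvalues[2]), 9), 3.0, 1e-9)
        add("gnm_chain_varfrac_k1", round(variance_fractions(gnm, 1), 9), 0.75, 1e-9)
        # bead density and cutoff chosen so every bead has several
        # non-collinear contacts: the only zero modes are the 6 rigid-body ones
        sheet_beads = make_sheet_beads(3, 3, a=115.0, beads_per_unit=60, seed=cfg.get("seed", 0))
        anm = build_anm(sheet_beads, cutoff=50.0)
        add("anm_sheet_zero_modes", anm.n_zero, 6, 0)
        plus, _ = generate_ensemble(sheet_beads, anm, 0, target_rmsd=25.0)
        rmsd = float(np.sqrt(((plus.coords - sheet_beads.coords) ** 2).sum(axis=1).mean()))
        add("anm_ensemble_rmsd_A", round(rmsd, 6), 25.0, 1e-6)

    if "pore" in stages:
        from .pore import pore_profile, pore_volume, restrictive_diameter

        cyl = make_channel("cylinder", ring_radius=8.0, atom_radius=1.0, length=100.0)
        prof = pore_profile(cyl.model, zrange=(-50.0, 50.0), dz=2.0)
        add("cylinder_restrictive_diameter_nm", round(restrictive_diameter(prof), 9), 1.4, 1e-9)
        hour = make_channel("hourglass", ring_radius=8.0, atom_radius=1.0, length=100.0, waist=4.0)
        prof_h = pore_profile(hour.model, zrange=(-50.0, 50.0), dz=2.0)
        add("hourglass_restrictive_diameter_nm", round(restrictive_diameter(prof_h), 9), 0.6, 1e-9)
        cyl5 = make_channel("cylinder", ring_radius=6.7, atom_radius=1.7, length=100.0)
        prof5 = pore_profile(cyl5.model, zrange=(-50.0, 50.0), dz=2.0)
        add("cylinder_R5_volume_nm3", round(pore_volume(prof5), 6), round(float(np.pi * 0.25 * 10.0), 6), 1e-6)

    report["n_pass"] = int(sum(r["pass"] for r in rows))
    report["n_rows"] = len(rows)
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        _write_report(report, outdir / "models_report.json")
    return report


def _write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
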