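"""End-to-end orchestration: generate → label → upscale → assign-bc →
simulate → analyze.

Every stage reads/writes plain artifacts inside a run directory and
records a provenance header (stage name, parameters, seed, package
version).  A single global seed fans out to per-stage seeds through
``numpy.random.SeedSequence([global_seed, stage_index])`` so stages stay
reproducible independently of each other.  Re-running with an unchanged
configuration skips stages whose artifacts already exist.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

import mvnflow
from mvnflow import analysis as ana
from mvnflow.boundary import assign_boundary_conditions
from mvnflow.generate import BedConfig, TreeConfig, build_artificial_mvn
from mvnflow.network import VascularNetwork, label_vessels, read_network, trim_network, write_network
from mvnflow.solver import BoundaryCondition
from mvnflow.transport import SimulationConfig, run_simulation, save_trajectories_ndjson
from mvnflow.upscaling import UpscaleConfig, upscale_network

logger = logging.getLogger(__name__)

STAGES = ("generate", "label", "upscale", "assign_bc", "simulate", "analyze")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([global_seed, idx]).generate_state(1)[0] % (2**31))


def default_config(seed: int = 0, outdir: str = "mvn_run") -> dict:
    """Demonstration configuration: a small artificial implant (a
    hexagonal bed fed by 2 DAs and drained by 2 AVs) inside a larger
    artificial host."""
    return {
        "seed": seed,
        "outdir": outdir,
        "stages": list(STAGES),
        "implant": {
            "bed": {"lateral_extent": 900.0, "depth": 660.0, "hex_edge": 60.0},
            "n_da": 2,
            "n_av": 2,
            "tree": {
                "template_depth": 1000.0,
                "n_levels": 6,
                "branches_per_level": 3,
                "root_diameter": 18.0,
                "taper": 0.85,
            },
            "lattice_spacing": 380.0,
            "trim_depth": 580.0,
            "trim_side_fraction": 0.06,
        },
        "host": {
            "bed_margin": 450.0,
            "n_da": 4,
            "n_av": 4,
            "tree": {
                "template_depth": 1000.0,
                "n_levels": 6,
                "root_diameter": 20.0,
                "taper": 0.85,
            },
            "lattice_spacing": 450.0,
        },
        "labeling": {"min_av_diam": 6.0, "max_cap_diam": 9.0, "consec_thresh": 7.0},
        "upscale": {},
        "boundary": {"constant_ht": 0.3},
        "simulation": {
            "warmup_turnovers": 15.0,
            "recording_turnovers": 1.0,
            "drain_turnovers": 10.0,
        },
    }


def _provenance(stage: str, params: dict, seed: int) -> dict:
    return {
        "stage": stage,
        "params": params,
        "seed": seed,
        "version": mvnflow.__version__,
        "written": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, default=str))


def _make_trees(kind: str, n: int, tree_params: dict, seed: int) -> list[TreeConfig]:
    return [TreeConfig(kind=kind, seed=seed + i, **tree_params) for i in range(n)]


def run_pipeline(config: dict) -> Path:
    """Execute all enabled stages in order; returns the run directory."""
    out = Path(config["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    gseed = int(config.get("seed", 0))
    enabled = config.get("stages", list(STAGES))

    # ---------------- generate ---------------------------------------
    implant_nodes = out / "implant_nodes.csv"
    implant_edges = out / "implant_edges.csv"
    host_nodes = out / "host_nodes.csv"
    host_edges = out / "host_edges.csv"
    if "generate" in enabled and not implant_nodes.exists():
        seed = stage_seed(gseed, "generate")
        icfg = config["implant"]
        bed = BedConfig(seed=seed, **icfg["bed"])
        das = _make_trees("DA", icfg["n_da"], icfg["tree"], seed + 100)
        avs = _make_trees("AV", icfg["n_av"], icfg["tree"], seed + 200)
        implant_full = build_artificial_mvn(bed, das, avs, icfg["lattice_spacing"], seed)
        implant = trim_network(
            implant_full,
            side_fraction=icfg["trim_side_fraction"],
            depth_cut=icfg["trim_depth"],
        )
        write_network(implant, implant_nodes, implant_edges)

        hcfg = config["host"]
        hb = BedConfig(
            lateral_extent=icfg["bed"]["lateral_extent"] + 2 * hcfg["bed_margin"],
            depth=icfg["bed"]["depth"] + 120.0,
            hex_edge=icfg["bed"].get("hex_edge", 60.0),
            seed=seed + 7,
        )
        hdas = _make_trees("DA", hcfg["n_da"], hcfg["tree"], seed + 300)
        havs = _make_trees("AV", hcfg["n_av"], hcfg["tree"], seed + 400)
        host = build_artificial_mvn(hb, hdas, havs, hcfg["lattice_spacing"], seed + 7)
        write_network(host, host_nodes, host_edges)
        _write_json(out / "generate_provenance.json", _provenance("generate", config["implant"], seed))
        logger.info("generate: implant %s, host %s", implant, host)

    # ---------------- label ------------------------------------------
    labeled_nodes = out / "labeled_nodes.csv"
    labeled_edges = out / "labeled_edges.csv"
    if "label" in enabled and not labeled_nodes.exists():
        net = read_network(implant_nodes, implant_edges)
        net = label_vessels(net, **config.get("labeling", {}))
        write_network(net, labeled_nodes, labeled_edges)
        _write_json(
            out / "label_provenance.json",
            _provenance("label", config.get("labeling", {}), stage_seed(gseed, "label")),
        )

    # ---------------- upscale ----------------------------------------
    upscaled_nodes = out / "upscaled_nodes.csv"
    upscaled_edges = out / "upscaled_edges.csv"
    if "upscale" in enabled and not upscaled_nodes.exists():
        net = read_network(labeled_nodes, labeled_edges)
        net = upscale_network(net, UpscaleConfig(**config.get("upscale", {})))
        write_network(net, upscaled_nodes, upscaled_edges)
        _write_json(
            out / "upscale_provenance.json",
            _provenance("upscale", config.get("upscale", {}), stage_seed(gseed, "upscale")),
        )

    # ---------------- assign-bc --------------------------------------
    bc_path = out / "boundary_conditions.csv"
    if "assign_bc" in enabled and not bc_path.exists():
        implant = read_network(upscaled_nodes, upscaled_edges)
        host = read_network(host_nodes, host_edges)
        ht = config.get("boundary", {}).get("constant_ht", 0.3)
        bcs, compound, _ = assign_boundary_conditions(implant, host, constant_ht=ht)
        pd.DataFrame(
            [(b.node_id, b.value, b.inflow_ht) for b in bcs],
            columns=["node_id", "pressure_mmhg", "inflow_ht"],
        ).to_csv(bc_path, index=False)
        _write_json(
            out / "assign_bc_provenance.json",
            _provenance("assign_bc", config.get("boundary", {}), stage_seed(gseed, "assign_bc")),
        )
        logger.info("assign-bc: %d boundary conditions (%d stitched)", len(bcs), len(compound.stitch_map))

    # ---------------- simulate ---------------------------------------
    traj_path = out / "trajectories.ndjson"
    sim_summary_path = out / "simulation_summary.json"
    if "simulate" in enabled and not traj_path.exists():
        implant = read_network(upscaled_nodes, upscaled_edges)
        bc_df = pd.read_csv(bc_path)
        bcs = [
            BoundaryCondition(int(r.node_id), float(r.pressure_mmhg), float(r.inflow_ht))
            for r in bc_df.itertuples()
        ]
        seed = stage_seed(gseed, "simulate")
        sim_cfg = SimulationConfig(seed=seed, **config.get("simulation", {}))
        result = run_simulation(implant, bcs, sim_cfg)
        save_trajectories_ndjson(result.trajectories, traj_path)
        _write_json(
            sim_summary_path,
            {
                "dt_s": result.dt,
                "turnover_time_s": result.turnover_time,
                "n_steps": result.n_steps,
                "n_injected": result.n_injected,
                "n_exited": result.n_exited,
                "n_resident": result.n_resident,
                "rbc_conservation_exact": result.conserved,
                "n_trajectories": len(result.trajectories),
                "capillary_rule_agreement": result.capillary_rule_agreement,
                "provenance": _provenance("simulate", config.get("simulation", {}), seed),
            },
        )
        logger.info(
            "simulate: dt=%.4g s, T=%.3g s, %d steps, %d trajectories",
            result.dt,
            result.turnover_time,
            result.n_steps,
            len(result.trajectories),
        )

    # ---------------- analyze ----------------------------------------
    layer_path = out / "layer_summary.csv"
    if "analyze" in enabled and not layer_path.exists():
        from mvnflow.transport import load_trajectories_ndjson

        implant = read_network(upscaled_nodes, upscaled_edges)
        trajectories = load_trajectories_ndjson(traj_path)
        layers = ana.AnalysisLayerConfig()
        # steady solve at the inflow hematocrit supplies per-edge flows
        # for the feeding statistics
        from mvnflow.rheology import effective_resistance
        from mvnflow.solver import solve_pressure_flow
        import warnings as _w

        bc_df = pd.read_csv(bc_path)
        bcs = [
            BoundaryCondition(int(r.node_id), float(r.pressure_mmhg), float(r.inflow_ht))
            for r in bc_df.itertuples()
        ]
        ht = config.get("boundary", {}).get("constant_ht", 0.3)
        with _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)
            r = effective_resistance(
                implant.vessels["diameter"].to_numpy(float),
                implant.vessels["length"].to_numpy(float),
                ht,
            )
        sol = solve_pressure_flow(implant, r, bcs)
        flows = dict(zip((int(i) for i in sol.vessel_ids), sol.flows_m3s))
        sim_meta = json.loads(sim_summary_path.read_text())
        rec_time = sim_meta["turnover_time_s"]
        summary = ana.transit_and_feeding_stats(
            trajectories, implant, layers, flows=flows, recording_time=rec_time
        )
        summary.table.to_csv(layer_path, index=False)
        drop = ana.pressure_drop_by_type(trajectories, implant, layers)
        drop.to_csv(out / "pressure_drop_by_type.csv", index=False)
        _write_json(out / "inplane_fit.json", summary.inplane_fit)
        summary.feeding_matrix.to_csv(out / "feeding_matrix.csv")
        _write_json(
            out / "analyze_provenance.json",
            _provenance("analyze", {}, stage_seed(gseed, "analyze")),
        )
    return out
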