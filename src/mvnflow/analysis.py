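"""Analyses of recorded RBC trajectories.

A *correct* RBC path traverses the vessel types in the order
PA → DA+A → C → V+AV → PV.  Because diameter/topology-based labeling is
error prone, a path may deviate from that order for up to two subsequent
branches as long as it then resumes at a stage at least as far along as
before the excursion.  Paths that only satisfy
(PA or DA+A) → C → (V+AV or PV) are accepted for capillary-bed analyses.

The layer-specific analyses slice the cortex into 200 μm thick analysis
layers (AL1..AL5 over the upper 1000 μm) keyed by the cortical depth of
the *capillary start point* — the node where the RBC moves from an
arteriole into the capillary bed.  Provided are: preferred end point /
preferred path statistics with their correlation against five path
characteristics, averaged pressure/diameter curves over normalized path
length, the pressure-drop decomposition by vessel type (with two
alternative labelings for sensitivity), capillary transit-time and
feeding statistics, and the in-plane regression of capillary end depth
on start depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from mvnflow.network import TYPE_STAGE, VascularNetwork

logger = logging.getLogger(__name__)

STAGE_GROUPS = ("PA", "DA+A", "C", "V+AV", "PV")  # stage index 0..4


# --------------------------------------------------------------------- #
# path validity
# --------------------------------------------------------------------- #
@dataclass(frozen=True)
class TrajectoryClass:
    full_valid: bool
    capillary_valid: bool
    exit_class: str  # arteriole_outlet | capillary_outlet | other | valid


def classify_trajectory(types, max_deviation: int = 2) -> TrajectoryClass:
    """Classify a sequence of per-edge vessel-type labels.

    An edge whose stage is below the current stage counts as a deviation;
    after at most ``max_deviation`` consecutive deviating edges the path
    must resume at a stage >= the stage before the excursion (the
    deviation budget resets after every valid stretch).
    """
    types = list(types)
    if not types:
        return TrajectoryClass(False, False, "other")
    current = -1
    visited = set()
    run = 0
    broken = False
    for t in types:
        s = TYPE_STAGE[t]
        if s >= current:
            current = s
            visited.add(s)
            run = 0
        else:
            run += 1
            if run > max_deviation:
                broken = True
                break
    full = (not broken) and visited >= {0, 1, 2, 3, 4}
    cap = (
        (not broken)
        and (visited & {0, 1})
        and (2 in visited)
        and (visited & {3, 4})
        and TYPE_STAGE[types[0]] <= 1
    )
    if full or cap:
        return TrajectoryClass(full, bool(cap), "valid")
    last = types[-1]
    if TYPE_STAGE[last] <= 1:
        exit_class = "arteriole_outlet"
    elif last == "C":
        exit_class = "capillary_outlet"
    else:
        exit_class = "other"
    return TrajectoryClass(False, False, exit_class)


# --------------------------------------------------------------------- #
# analysis layers and capillary endpoints
# --------------------------------------------------------------------- #
@dataclass(frozen=True)
class AnalysisLayerConfig:
    """200 μm thick analysis layers over the upper 1000 μm by default
    (AL1..AL5, half-open depth bins [lower, upper))."""

    thickness: float = 200.0
    max_depth: float = 1000.0

    def __post_init__(self):
        n = self.max_depth / self.thickness
        if abs(n - round(n)) > 1e-9:
            raise ValueError("layer thickness must divide max depth")

    @property
    def n_layers(self) -> int:
        return int(round(self.max_depth / self.thickness))

    def layer_of(self, depth: float):
        """1-based AL index of a cortical depth, or None beyond max depth."""
        if depth < 0 or depth >= self.max_depth:
            return None
        return int(depth // self.thickness) + 1


@dataclass
class CapillaryPassage:
    """Where a trajectory enters and leaves the capillary bed."""

    start_index: int  # index of the first capillary edge in the path
    end_index: int  # index of the first venular edge after the capillaries
    start_node: int
    end_node: int
    start_depth: float
    end_depth: float
    layer: int | None


def capillary_passage(traj, network: VascularNetwork, layers: AnalysisLayerConfig | None = None):
    """Locate the capillary start/end points of a trajectory.

    The start point is the entry node of the first edge where the type
    goes (PA|DA|A) -> C; the end point is the entry node of the first
    (V|AV|PV) edge thereafter.  Returns None if the path has no such
    passage.
    """
    layers = layers or AnalysisLayerConfig()
    labels = traj.vessel_types
    start = None
    for i in range(1, len(labels)):
        if labels[i] == "C" and TYPE_STAGE[labels[i - 1]] <= 1:
            start = i
            break
    if start is None:
        if labels and labels[0] == "C":
            return None  # injected straight into the bed: history unknown
        return None
    end = None
    for i in range(start + 1, len(labels)):
        if TYPE_STAGE[labels[i]] >= 3:
            end = i
            break
    if end is None:
        return None
    z = network.nodes["z"]
    sd = float(z.loc[int(traj.entry_nodes[start])])
    ed = float(z.loc[int(traj.entry_nodes[end])])
    return CapillaryPassage(
        start_index=start,
        end_index=end,
        start_node=int(traj.entry_nodes[start]),
        end_node=int(traj.entry_nodes[end]),
        start_depth=sd,
        end_depth=ed,
        layer=layers.layer_of(sd),
    )


# --------------------------------------------------------------------- #
# preferred end points / paths and their correlates
# --------------------------------------------------------------------- #
def normalize_by_max(values: np.ndarray) -> np.ndarray:
    """Per-start-point normalization of a path characteristic by its
    maximum over the available end points."""
    values = np.asarray(values, dtype=float)
    if not np.any(np.isfinite(values)):
        return values
    m = np.nanmax(values)
    return values / m if m > 0 else values


@dataclass
class EndpointStats:
    pairs: pd.DataFrame  # one row per (start, end) pair
    starts: pd.DataFrame  # one row per capillary start point
    correlations: dict
    n_excluded_single: int


def endpoint_preference_and_correlation(
    trajectories,
    network: VascularNetwork,
    resistances=None,
    flows=None,
    layers: AnalysisLayerConfig | None = None,
) -> EndpointStats:
    """Relative end-point frequencies, preference flags and Pearson
    correlations with five path characteristics.

    For every capillary start point the relative frequency ``f_ep`` of
    each end point is the fraction of its RBCs reaching that end point; a
    start point has a *preferred end point* if the largest frequency
    exceeds 0.5 while the runner-up stays below 0.3 (preferred paths are
    defined analogously on per-path frequencies).  Five characteristics
    of the capillary passage — euclidean start-end distance, mean path
    length, mean summed vessel resistance, mean flow rate and mean RBC
    velocity (averaged over the unique paths start -> end) — are
    normalized per start point by their maximum over its end points and
    correlated (Pearson) with ``f_ep`` over all (start, end) pairs.

    ``resistances``/``flows`` map vessel id -> R (Pa·s·m^-3) / q (m^3/s);
    without them the corresponding characteristics are skipped.
    """
    layers = layers or AnalysisLayerConfig()
    pos = network.nodes[["x", "y", "z"]]

    rows = []
    for traj in trajectories:
        cls = classify_trajectory(traj.vessel_types)
        if not cls.capillary_valid:
            continue
        pas = capillary_passage(traj, network, layers)
        if pas is None:
            continue
        seg = slice(pas.start_index, pas.end_index)
        edges = tuple(int(e) for e in traj.edges[seg])
        lengths = traj.edge_lengths[seg]
        v_seg = traj.v_rbc[seg]
        r_sum = (
            float(np.sum([resistances[e] for e in edges])) if resistances is not None else np.nan
        )
        q_mean = (
            float(np.mean([abs(flows[e]) for e in edges])) if flows is not None else np.nan
        )
        rows.append(
            {
                "start": pas.start_node,
                "end": pas.end_node,
                "path": edges,
                "layer": pas.layer,
                "path_length": float(lengths.sum()),
                "resistance": r_sum,
                "flow": q_mean,
                "v_rbc": float(np.mean(v_seg[np.isfinite(v_seg)])) if len(v_seg) else np.nan,
            }
        )
    if not rows:
        raise ValueError("no capillary-valid trajectories with a capillary passage")
    df = pd.DataFrame(rows)

    # per unique path first (unweighted mean over paths per (start,end))
    per_path = df.groupby(["start", "end", "path"], sort=True).agg(
        n_rbc=("path_length", "size"),
        path_length=("path_length", "first"),
        resistance=("resistance", "first"),
        flow=("flow", "mean"),
        v_rbc=("v_rbc", "mean"),
        layer=("layer", "first"),
    )
    per_pair = per_path.groupby(["start", "end"]).agg(
        n_rbc=("n_rbc", "sum"),
        n_paths=("n_rbc", "size"),
        path_length=("path_length", "mean"),
        resistance=("resistance", "mean"),
        flow=("flow", "mean"),
        v_rbc=("v_rbc", "mean"),
        layer=("layer", "first"),
    )
    per_pair = per_pair.reset_index()
    per_pair["euclidean"] = [
        float(
            np.linalg.norm(
                pos.loc[s].to_numpy(float) - pos.loc[e].to_numpy(float)
            )
        )
        for s, e in zip(per_pair["start"], per_pair["end"])
    ]
    totals = per_pair.groupby("start")["n_rbc"].transform("sum")
    per_pair["f_ep"] = per_pair["n_rbc"] / totals

    characteristics = ("euclidean", "path_length", "resistance", "flow", "v_rbc")
    for ch in characteristics:
        per_pair[f"{ch}_norm"] = per_pair.groupby("start")[ch].transform(
            lambda v: normalize_by_max(v.to_numpy(float))
        )

    # start-point summaries and preference flags
    start_rows = []
    for start, grp in per_pair.groupby("start"):
        f = np.sort(grp["f_ep"].to_numpy(float))[::-1]
        pref_ep = f[0] > 0.5 and (f[1] if f.size > 1 else 0.0) < 0.3
        sub = df[df["start"] == start]
        pf = sub.groupby("path").size().to_numpy(float)
        pf = np.sort(pf / pf.sum())[::-1]
        pref_path = pf[0] > 0.5 and (pf[1] if pf.size > 1 else 0.0) < 0.3
        start_rows.append(
            {
                "start": start,
                "n_rbc": int(grp["n_rbc"].sum()),
                "n_end_points": len(grp),
                "n_paths": int(grp["n_paths"].sum()),
                "preferred_end_point": bool(pref_ep),
                "preferred_path": bool(pref_path),
                "layer": grp["layer"].iloc[0],
            }
        )
    starts = pd.DataFrame(start_rows).set_index("start")

    # correlations over pairs of start points with >= 2 end points
    multi = per_pair[per_pair.groupby("start")["end"].transform("size") >= 2]
    n_excluded = int(starts["n_end_points"].eq(1).sum())
    correlations = {}
    for ch in characteristics:
        x = multi[f"{ch}_norm"].to_numpy(float)
        y = multi["f_ep"].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() >= 3 and np.std(x[ok]) > 0 and np.std(y[ok]) > 0:
            correlations[ch] = float(sstats.pearsonr(x[ok], y[ok])[0])
        else:
            correlations[ch] = float("nan")
    return EndpointStats(per_pair, starts, correlations, n_excluded)


# --------------------------------------------------------------------- #
# averaged curves over normalized path length
# --------------------------------------------------------------------- #
def averaged_curves(
    trajectories,
    network: VascularNetwork,
    quantity: str = "pressure",
    layers: AnalysisLayerConfig | None = None,
    grid: int = 100,
):
    """Layer-averaged pressure or diameter along the normalized path.

    Every full-valid trajectory is resampled by linear interpolation onto
    a uniform normalized-path-length grid (``s_norm = s/s_tot``), curves
    are averaged pointwise per analysis layer, and the abscissa is
    rescaled by the layer's mean total path length.  The mean capillary
    start/end positions are reported per layer.
    """
    if quantity not in ("pressure", "diameter"):
        raise ValueError("quantity must be 'pressure' or 'diameter'")
    layers = layers or AnalysisLayerConfig()
    s_grid = np.linspace(0.0, 1.0, grid)
    diam = network.vessels["diameter"]

    per_layer: dict[int, list] = {}
    for traj in trajectories:
        if not classify_trajectory(traj.vessel_types).full_valid:
            continue
        pas = capillary_passage(traj, network, layers)
        if pas is None or pas.layer is None:
            continue
        s_tot = traj.s_tot
        if s_tot <= 0:
            continue
        s = traj.s / s_tot
        if quantity == "pressure":
            vals = traj.entry_pressures
            curve = np.interp(s_grid, s, vals)
        else:
            vals = diam.loc[traj.edges].to_numpy(float)
            idx = np.clip(np.searchsorted(s, s_grid, side="right") - 1, 0, len(vals) - 1)
            curve = vals[idx]
        per_layer.setdefault(pas.layer, []).append(
            (curve, s_tot, s[pas.start_index], s[pas.end_index])
        )

    out = {}
    for al, items in sorted(per_layer.items()):
        curves = np.array([c for c, *_ in items])
        s_tots = np.array([t for _, t, *_ in items])
        out[al] = {
            "s_norm": s_grid,
            "mean_curve": curves.mean(axis=0),
            "std_curve": curves.std(axis=0),
            "mean_s_tot": float(s_tots.mean()),
            "s_scaled": s_grid * float(s_tots.mean()),
            "mean_capillary_start_s_norm": float(np.mean([a for *_, a, _ in items])),
            "mean_capillary_end_s_norm": float(np.mean([b for *_, b in items])),
            "n": len(items),
        }
    return out


# --------------------------------------------------------------------- #
# pressure drop by vessel type
# --------------------------------------------------------------------- #
LABELING_VARIANTS = ("standard", "first_C_as_DA+A", "last_DA+A_as_C")


def _stage_sequence(labels, variant: str):
    """Per-edge stage indices with the sensitivity-variant relabelings of
    the DA+A / C transition applied along the path."""
    stages = [TYPE_STAGE[t] for t in labels]
    if variant == "standard":
        return stages
    # locate the first arteriole->capillary transition along the path
    for i in range(1, len(stages)):
        if stages[i] == 2 and stages[i - 1] <= 1:
            if variant == "first_C_as_DA+A":
                stages[i] = 1
            elif variant == "last_DA+A_as_C":
                stages[i - 1] = 2
            return stages
    return stages


def pressure_drop_by_type(
    trajectories,
    network: VascularNetwork,
    layers: AnalysisLayerConfig | None = None,
    labeling_variant: str = "standard",
) -> pd.DataFrame:
    """Mean inlet pressure / path length per vessel type and layer.

    For every full-valid trajectory the pressure and cumulative path
    length at the first edge of each vessel-type group (PA, DA+A, C,
    V+AV, PV in path order) are extracted; layer means and standard
    deviations follow.  The per-type drop fraction is the difference of
    consecutive mean inlet pressures over the total drop (PA inlet to PV
    inlet), attributed to the group in which the drop occurs.  The two
    modified labelings shift the DA+A/C boundary by one branch for the
    sensitivity analysis.
    """
    if labeling_variant not in LABELING_VARIANTS:
        raise ValueError(f"unknown labeling variant {labeling_variant!r}")
    layers = layers or AnalysisLayerConfig()

    rows = []
    for traj in trajectories:
        if not classify_trajectory(traj.vessel_types).full_valid:
            continue
        pas = capillary_passage(traj, network, layers)
        if pas is None or pas.layer is None:
            continue
        stages = _stage_sequence(traj.vessel_types, labeling_variant)
        s = traj.s
        p = traj.entry_pressures
        inlet = {}
        current = -1
        for i, st in enumerate(stages):
            if st > current:
                if st not in inlet:
                    inlet[st] = (p[i], s[i])
                current = st
        if set(inlet) != {0, 1, 2, 3, 4}:
            continue
        for st in range(5):
            rows.append(
                {
                    "layer": pas.layer,
                    "group": STAGE_GROUPS[st],
                    "stage": st,
                    "inlet_pressure": float(inlet[st][0]),
                    "path_length": float(inlet[st][1]),
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=["layer", "group", "inlet_pressure_mean", "inlet_pressure_std",
                     "path_length_mean", "drop_fraction"]
        )
    df = pd.DataFrame(rows)
    agg = (
        df.groupby(["layer", "stage", "group"])
        .agg(
            inlet_pressure_mean=("inlet_pressure", "mean"),
            inlet_pressure_std=("inlet_pressure", "std"),
            path_length_mean=("path_length", "mean"),
            n=("inlet_pressure", "size"),
        )
        .reset_index()
    )
    out = []
    for al, grp in agg.groupby("layer"):
        grp = grp.sort_values("stage").reset_index(drop=True)
        p_in = grp["inlet_pressure_mean"].to_numpy(float)
        total = p_in[0] - p_in[-1]
        frac = np.full(len(grp), np.nan)
        if total > 0:
            frac[:-1] = -np.diff(p_in) / total
        grp["drop_fraction"] = frac
        out.append(grp)
    return pd.concat(out, ignore_index=True)


# --------------------------------------------------------------------- #
# transit, feeding, unique paths, in-plane fit
# --------------------------------------------------------------------- #
@dataclass
class LayerSummary:
    table: pd.DataFrame  # one row per analysis layer
    feeding_matrix: pd.DataFrame  # origin (DA inflow node) x exit (AV outflow node) counts
    primary_feeding: pd.DataFrame  # per exit: primary origin and its fraction
    inplane_fit: dict  # slope, intercept (mm), pearson_r, n


def transit_and_feeding_stats(
    trajectories,
    network: VascularNetwork,
    layers: AnalysisLayerConfig | None = None,
    flows=None,
    recording_time: float | None = None,
) -> LayerSummary:
    """Layer-specific transit statistics, feeding properties and the
    in-plane depth regression.

    Per analysis layer: capillary transit time ``tt_C`` (capillary start
    to end), transit path length ``ts_C``, capillary RBC velocity
    ``ts_C/tt_C`` (mean ± std; the std of ``tt_C`` is the capillary
    transit time heterogeneity), the number of unique capillary paths,
    the number of distinct feeding branches (arteriole→capillary
    transition edges) and the blood/RBC flow they carry.  The feeding
    matrix counts RBCs per (inflow origin, outflow exit) pair, from which
    every drainage vessel's primary feeder fraction follows.  The
    in-plane fit regresses capillary end depth on start depth (mm).
    """
    layers = layers or AnalysisLayerConfig()
    rows = []
    for traj in trajectories:
        cls = classify_trajectory(traj.vessel_types)
        if not cls.capillary_valid:
            continue
        pas = capillary_passage(traj, network, layers)
        if pas is None:
            continue
        t_start = float(traj.entry_times[pas.start_index])
        t_end = float(traj.entry_times[pas.end_index])
        s_seg = float(np.sum(traj.edge_lengths[pas.start_index : pas.end_index]))
        rows.append(
            {
                "layer": pas.layer,
                "tt": t_end - t_start,
                "ts": s_seg * 1e-3,  # mm
                "start_depth": pas.start_depth * 1e-3,
                "end_depth": pas.end_depth * 1e-3,
                "origin": int(traj.entry_nodes[0]),
                "exit": int(traj.exit_node),
                "feeding_edge": int(traj.edges[pas.start_index]),
                "path": tuple(int(e) for e in traj.edges[pas.start_index : pas.end_index + 1]),
                "full": cls.full_valid,
            }
        )
    if not rows:
        raise ValueError("no capillary-valid trajectories")
    df = pd.DataFrame(rows)
    df["v"] = np.where(df["tt"] > 0, df["ts"] / df["tt"], np.nan)

    layer_rows = []
    for al in range(1, layers.n_layers + 1):
        sub = df[df["layer"] == al]
        if sub.empty:
            logger.info("analysis layer %d holds no trajectories; omitted", al)
            continue
        feeding_edges = sub["feeding_edge"].unique()
        blood = (
            float(np.sum([abs(flows[e]) for e in feeding_edges])) * 1e12
            if flows is not None
            else np.nan
        )  # nl/s
        rbc_flow = len(sub) / recording_time if recording_time else float(len(sub))
        layer_rows.append(
            {
                "layer": al,
                "n_rbc": len(sub),
                "tt_mean_s": float(sub["tt"].mean()),
                "tt_std_s": float(sub["tt"].std(ddof=0)),
                "ts_mean_mm": float(sub["ts"].mean()),
                "ts_std_mm": float(sub["ts"].std(ddof=0)),
                "v_rbc_mean_mms": float(sub["v"].mean()),
                "v_rbc_std_mms": float(sub["v"].std(ddof=0)),
                "unique_paths": int(sub["path"].nunique()),
                "feeding_branches": int(len(feeding_edges)),
                "feeding_blood_flow_nls": blood,
                "feeding_rbc_flow": rbc_flow,
            }
        )
    table = pd.DataFrame(layer_rows)

    feeding = df.groupby(["origin", "exit"]).size().unstack(fill_value=0)
    primary_rows = []
    for exit_node in feeding.columns:
        col = feeding[exit_node]
        total = col.sum()
        primary_rows.append(
            {
                "exit": exit_node,
                "primary_origin": int(col.idxmax()),
                "primary_fraction": float(col.max() / total) if total else np.nan,
                "n_feeders": int((col > 0).sum()),
            }
        )
    primary = pd.DataFrame(primary_rows).set_index("exit")

    x = df["start_depth"].to_numpy(float)
    y = df["end_depth"].to_numpy(float)
    if len(df) >= 3 and np.ptp(x) > 0:
        fit = sstats.linregress(x, y)
        inplane = {
            "slope": float(fit.slope),
            "intercept_mm": float(fit.intercept),
            "pearson_r": float(fit.rvalue),
            "n": len(df),
        }
    else:
        inplane = {"slope": np.nan, "intercept_mm": np.nan, "pearson_r": np.nan, "n": len(df)}

    return LayerSummary(table, feeding, primary, inplane)


def count_unique_graph_paths(network: VascularNetwork, sources, targets, cutoff=None) -> int:
    """Number of simple paths between node sets (brute-force enumeration;
    intended for small graphs as an independent cross-check of the
    trajectory-based unique path counts)."""
    import networkx as nx

    g = nx.Graph(network.to_networkx())
    n = 0
    for s in sources:
        for t in targets:
            if s in g and t in g:
                n += sum(1 for _ in nx.all_simple_paths(g, s, t, cutoff=cutoff))
    return n
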