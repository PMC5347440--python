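"""Synthetic cortical vasculature: hexagonal capillary beds, penetrating
arteriole/venule trees and their assembly into an artificial MVN.

The capillary bed is a stack of planar hexagonal (honeycomb) lattices.
A honeycomb is 3-regular in the plane; to interconnect the layers without
raising the bifurcation degree, a third of the "rung" edges (the perfect
matching joining neighbouring zigzag chains) is rewired into vertical
connections: rungs in row group 0 link layer pairs (0,1), (2,3), ...;
rungs in row group 1 link pairs (1,2), (3,4), ...; row group 2 stays
in-plane.  Every interior bifurcation then has exactly three adjacent
edges and the slab is a single connected component.

Penetrating trees are parametric: a descending trunk with tapering
diameter and lateral side branches per level, depth-scaled by the
mouse-to-rat cortical-thickness ratio (0.66 by default).  Tree roots are
arranged on a rhombic lattice (alternating arteriole/venule kinds) above
the bed and every tree leaf is stitched to its nearest capillary node.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mvnflow.network import VascularNetwork
from mvnflow.upscaling import UpscaleConfig

logger = logging.getLogger(__name__)


class GenerationError(ValueError):
    pass


# --------------------------------------------------------------------- #
# capillary bed
# --------------------------------------------------------------------- #
@dataclass(frozen=True)
class BedConfig:
    """Stacked hexagonal capillary bed.

    ``lateral_extent`` (μm) sets the approximate x/y footprint, ``depth``
    the slab thickness covered by ``depth/layer_spacing + 1`` hexagonal
    layers.  Capillary diameters are drawn from the goal beta
    distribution (mean 4 μm, std 1 μm on [2.5, 9] μm) unless another
    sampler configuration is given.
    """

    lateral_extent: float = 400.0
    depth: float = 400.0
    hex_edge: float = 60.0
    layer_spacing: float = 60.0
    z_offset: float = 0.0
    diameters: UpscaleConfig = field(default_factory=UpscaleConfig)
    seed: int = 0

    def __post_init__(self):
        if self.lateral_extent <= 0 or self.depth < 0:
            raise GenerationError("extents must be positive")
        if self.hex_edge <= 0 or self.hex_edge >= self.lateral_extent:
            raise GenerationError("hexagon edge must be positive and smaller than the extent")


def generate_capillary_bed(config: BedConfig) -> VascularNetwork:
    """Generate the stacked hexagonal capillary bed.

    All vessels are labeled C; interior bifurcations have exactly three
    adjacent edges; the result is deterministic under a fixed seed.
    """
    import networkx as nx

    s = config.hex_edge
    n_cols = max(2, round(config.lateral_extent / (1.5 * s)))
    n_rows = max(2, round(config.lateral_extent / (math.sqrt(3.0) * s)))
    n_layers = max(1, round(config.depth / config.layer_spacing) + 1)

    hexg = nx.hexagonal_lattice_graph(n_rows, n_cols)
    pos2d = nx.get_node_attributes(hexg, "pos")
    nodes2d = sorted(hexg.nodes())
    n2i = {n: i for i, n in enumerate(nodes2d)}

    # classify edges: "rungs" join neighbouring columns ((i,j)-(i+1,j));
    # group them cyclically by row to rewire a third into vertical links
    in_plane, s_groups = [], ([], [])
    for u, v in sorted(hexg.edges()):
        if u[0] == v[0]:
            in_plane.append((u, v))
        else:
            g = u[1] % 3
            if g == 2:
                in_plane.append((u, v))
            else:
                s_groups[g].append((u, v))

    node_rows = []
    vessel_rows = []
    nid = 0
    vid = 0
    layer_of = {}
    for layer in range(n_layers):
        z = config.z_offset + layer * config.layer_spacing
        for n in nodes2d:
            x, y = pos2d[n]
            node_rows.append((nid, x * s, y * s, z, "interior"))
            layer_of[(layer, n)] = nid
            nid += 1

    def add_vessel(a, b, length):
        nonlocal vid
        vessel_rows.append((vid, a, b, length))
        vid += 1

    for layer in range(n_layers):
        for u, v in in_plane:
            add_vessel(layer_of[(layer, u)], layer_of[(layer, v)], s)
    for g, pairs_start in ((0, 0), (1, 1)):
        for lo in range(pairs_start, n_layers - 1, 2):
            for u, v in s_groups[g]:
                add_vessel(layer_of[(lo, u)], layer_of[(lo + 1, u)], config.layer_spacing)
                add_vessel(layer_of[(lo, v)], layer_of[(lo + 1, v)], config.layer_spacing)

    rng = np.random.default_rng(config.seed)
    dist = config.diameters.goal_distribution()
    diam = dist.rvs(size=len(vessel_rows), random_state=rng)

    nodes = pd.DataFrame(
        node_rows, columns=["id", "x", "y", "z", "boundary"]
    ).set_index("id")
    vessels = pd.DataFrame(vessel_rows, columns=["id", "n1", "n2", "length"]).set_index("id")
    vessels["diameter"] = diam
    vessels["type"] = "C"
    return VascularNetwork(nodes, vessels[["n1", "n2", "diameter", "length", "type"]])


def interior_degree_check(network: VascularNetwork, lateral_margin: float = 0.0, z_margin: float = 0.0):
    """Degrees of the bed nodes away from its boundary.

    Nodes within ``lateral_margin`` of the x/y bounding box (the
    honeycomb boundary is jagged, so a margin of one row spacing,
    ``sqrt(3)/2 * hex_edge``, captures the notch nodes) or within
    ``z_margin`` of the top/bottom face are treated as boundary.
    """
    pos = network.positions
    lo, hi = pos.min(axis=0), pos.max(axis=0)
    margin = np.array([lateral_margin, lateral_margin, z_margin]) + 1e-6
    on_face = np.any((pos <= lo + margin) | (pos >= hi - margin), axis=1)
    deg = np.zeros(network.n_nodes, dtype=int)
    for i, j in network.edge_node_rows():
        deg[i] += 1
        deg[j] += 1
    return deg[~on_face]


# --------------------------------------------------------------------- #
# penetrating trees
# --------------------------------------------------------------------- #
@dataclass(frozen=True)
class TreeConfig:
    """Parametric penetrating arteriole (DA) or ascending venule (AV) tree.

    The trunk descends from the pial surface to
    ``template_depth * depth_scale`` (the 0.66 default is the
    mouse-to-rat cortical-thickness ratio) in ``n_levels`` segments; at
    each intermediate trunk node ``branches_per_level`` lateral side
    branches are attached.  Diameters taper by ``taper`` per level
    (1/sqrt(2) halves the lumen area); side branches below 2.5 μm are
    truncated with a warning.  A short pial stub (PA or PV) at the root
    carries the pial boundary node.
    """

    kind: str = "DA"
    template_depth: float = 1500.0
    depth_scale: float = 0.66
    n_levels: int = 4
    branches_per_level: int = 2
    root_diameter: float = 15.0
    taper: float = 1.0 / math.sqrt(2.0)
    branch_length: float = 80.0
    branch_tilt_deg: float = 60.0
    stub_length: float = 40.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("DA", "AV"):
            raise GenerationError("tree kind must be 'DA' or 'AV'")
        if not (0 < self.taper < 1):
            raise GenerationError("taper must lie in (0, 1)")
        if self.root_diameter <= 2.5:
            raise GenerationError("root diameter must exceed the capillary floor")


def generate_penetrating_tree(config: TreeConfig) -> VascularNetwork:
    """Build one penetrating tree rooted at the origin of the pial plane."""
    rng = np.random.default_rng(config.seed)
    depth = config.template_depth * config.depth_scale
    n = config.n_levels
    trunk_label, side_label, pial_label, bkind = (
        ("DA", "A", "PA", "pial_inflow") if config.kind == "DA" else ("AV", "V", "PV", "pial_outflow")
    )

    node_rows = [(0, config.stub_length, 0.0, 0.0, bkind), (1, 0.0, 0.0, 0.0, "interior")]
    vessel_rows = [(0, 0, 1, config.root_diameter, config.stub_length, pial_label)]
    nid, vid = 2, 1
    golden = math.degrees(math.pi * (3.0 - math.sqrt(5.0)))
    tilt = math.radians(config.branch_tilt_deg)

    prev = 1
    phi0 = rng.uniform(0.0, 2.0 * math.pi)  # per-tree azimuthal rotation
    for level in range(1, n + 1):
        z = depth * level / n
        d_trunk = config.root_diameter * config.taper ** level
        if d_trunk < 2.5:
            logger.warning("trunk taper hit the 2.5 μm floor at level %d; clamped", level)
            d_trunk = 2.5
        node_rows.append((nid, 0.0, 0.0, z, "interior"))
        seg_len = depth / n
        vessel_rows.append((vid, prev, nid, d_trunk, seg_len, trunk_label))
        prev = nid
        nid += 1
        vid += 1
        if level == n:
            break  # trunk tip is a leaf
        d_side = d_trunk * config.taper
        if d_side < 2.5:
            logger.warning("side-branch taper below 2.5 μm at level %d; branch truncated", level)
            continue
        for b in range(config.branches_per_level):
            phi = phi0 + math.radians((level * config.branches_per_level + b) * golden)
            bx = math.sin(tilt) * math.cos(phi) * config.branch_length
            by = math.sin(tilt) * math.sin(phi) * config.branch_length
            bz = math.cos(tilt) * config.branch_length
            node_rows.append((nid, bx, by, z + bz, "interior"))
            vessel_rows.append((vid, prev, nid, d_side, config.branch_length, side_label))
            nid += 1
            vid += 1

    nodes = pd.DataFrame(node_rows, columns=["id", "x", "y", "z", "boundary"]).set_index("id")
    vessels = pd.DataFrame(
        vessel_rows, columns=["id", "n1", "n2", "diameter", "length", "type"]
    ).set_index("id")
    return VascularNetwork(nodes, vessels)


# --------------------------------------------------------------------- #
# assembly
# --------------------------------------------------------------------- #
def rhombic_lattice(n1: int, n2: int, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Root positions of a rhombic (centered rectangular) lattice.

    Returns ``(primary, centered)`` position arrays; by convention the
    primary sites host DA trees and the centered sites AV trees (or vice
    versa), giving the alternating arrangement of penetrating vessels.
    """
    primary = np.array([(i * spacing, j * spacing) for i in range(n1) for j in range(n2)])
    centered = np.array(
        [
            ((i + 0.5) * spacing, (j + 0.5) * spacing)
            for i in range(max(n1 - 1, 1))
            for j in range(max(n2 - 1, 1))
        ]
    )
    return primary, centered


def assemble_artificial_mvn(
    bed: VascularNetwork,
    trees: list[tuple[VascularNetwork, tuple[float, float]]],
    max_stitch_radius: float = 250.0,
    require_pial: bool = True,
) -> VascularNetwork:
    """Implant penetrating trees into a capillary bed.

    ``trees`` is a list of ``(tree_network, (x, y))`` root placements.
    Every tree leaf (degree-1 node at depth) is joined to its nearest
    capillary node by a new connecting capillary; equidistant candidates
    resolve to the lowest node id.  The result must be a single connected
    component with the tree roots as pial in-/outflow nodes.
    """
    nodes = bed.nodes.copy()
    vessels = bed.vessels.copy()
    next_nid = int(nodes.index.max()) + 1
    next_vid = int(vessels.index.max()) + 1

    cap_pos = bed.positions
    cap_ids = bed.nodes.index.to_numpy(np.int64)

    stitch_rows = []
    for tree, (ox, oy) in trees:
        tn = tree.nodes.copy()
        tn["x"] = tn["x"] + ox
        tn["y"] = tn["y"] + oy
        id_map = {int(old): next_nid + i for i, old in enumerate(tn.index)}
        tn.index = pd.Index([id_map[int(i)] for i in tn.index], name="id")
        next_nid += len(tn)
        tv = tree.vessels.copy()
        tv["n1"] = [id_map[int(i)] for i in tv["n1"]]
        tv["n2"] = [id_map[int(i)] for i in tv["n2"]]
        tv.index = pd.Index(range(next_vid, next_vid + len(tv)), name="id")
        next_vid += len(tv)
        nodes = pd.concat([nodes, tn])
        vessels = pd.concat([vessels, tv])

        # leaves: degree-1 non-pial nodes
        deg = pd.Series(0, index=tn.index)
        for col in ("n1", "n2"):
            deg = deg.add(tv[col].value_counts(), fill_value=0)
        leaves = [
            int(i)
            for i in tn.index
            if deg.get(i, 0) == 1 and tn.loc[i, "boundary"] == "interior" and tn.loc[i, "z"] > 0
        ]
        leaf_diam = {}
        for i in leaves:
            inc = tv[(tv["n1"] == i) | (tv["n2"] == i)]
            leaf_diam[i] = float(inc["diameter"].iloc[0])
        for i in leaves:
            p = tn.loc[i, ["x", "y", "z"]].to_numpy(float)
            dist = np.linalg.norm(cap_pos - p, axis=1)
            best = dist.min()
            if best > max_stitch_radius:
                raise GenerationError(
                    f"tree leaf at {p} has no capillary node within {max_stitch_radius} μm"
                )
            target = int(cap_ids[dist <= best + 1e-9].min())
            d_conn = float(np.clip(leaf_diam[i] / math.sqrt(2.0), 2.5, 9.0))
            stitch_rows.append((next_vid, i, target, d_conn, max(best, 1.0), "C"))
            next_vid += 1

    stitches = pd.DataFrame(
        stitch_rows, columns=["id", "n1", "n2", "diameter", "length", "type"]
    ).set_index("id")
    vessels = pd.concat([vessels, stitches])
    net = VascularNetwork(nodes, vessels)

    import networkx as nx

    g = net.to_networkx()
    if nx.number_connected_components(g) != 1:
        raise GenerationError("assembled artificial MVN is not a single connected component")
    net.validate(require_pial=require_pial)
    return net


def build_artificial_mvn(
    bed_config: BedConfig,
    da_configs: list[TreeConfig],
    av_configs: list[TreeConfig],
    lattice_spacing: float = 350.0,
    seed: int = 0,
) -> VascularNetwork:
    """Convenience builder: bed + trees on a rhombic lattice footprint."""
    bed = generate_capillary_bed(bed_config)
    pos = bed.positions
    cx, cy = pos[:, 0].mean(), pos[:, 1].mean()
    n_da, n_av = len(da_configs), len(av_configs)
    n1 = max(1, math.ceil(math.sqrt(n_da)))
    n2 = max(1, math.ceil(n_da / n1))
    primary, centered = rhombic_lattice(max(n1, 2), max(n2, 2), lattice_spacing)
    primary = primary - primary.mean(axis=0) + (cx, cy)
    centered = centered - centered.mean(axis=0) + (cx, cy)
    trees = []
    for i, cfg in enumerate(da_configs):
        trees.append((generate_penetrating_tree(cfg), tuple(primary[i % len(primary)])))
    for i, cfg in enumerate(av_configs):
        trees.append((generate_penetrating_tree(cfg), tuple(centered[i % len(centered)])))
    return assemble_artificial_mvn(bed, trees)
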