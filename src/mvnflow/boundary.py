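"""Hierarchical boundary conditions for realistic network implants.

Realistic MVN acquisitions are trimmed cuboids: besides the pial in- and
outflows they expose many cut vessels deep in the cortex whose pressures
are unknown.  Instead of imposing no-flow there (which underestimates
perfusion), the implant is embedded into a large artificial MVN
("compound network"): a hole the size of the implant's bounding box is
cut from the artificial network, the implant is positioned inside, every
deep in-/outflow is stitched to the nearest remaining artificial
capillary vertex, and a steady solve at constant tube hematocrit (no RBC
tracking) yields realistic pressures at the stitched nodes.  Those
pressures are then used as Dirichlet boundary conditions for the
discrete RBC simulation on the implant alone.

Pial pressures come from a cubic polynomial in vessel diameter on the
arteriolar side (fitted to a bundled synthetic digitization of classic
pial micropipette measurements; replaceable by user data) and a uniform
10 mmHg on the venular side.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mvnflow.network import VascularNetwork
from mvnflow.rheology import RheologyParams, effective_resistance
from mvnflow.solver import BoundaryCondition, PressureSolution, solve_pressure_flow

logger = logging.getLogger(__name__)


# Synthetic stand-in for the digitized literature scatter of pial
# arteriolar pressure vs. diameter (micropipette measurements in rodents
# and cats; pressures rise from ~35 mmHg in the smallest pial arterioles
# toward systemic levels in the largest).  Columns: diameter μm,
# pressure mmHg.  These points are *synthetic* — hand-placed to emulate
# the published trend, not digitized from any figure.
SYNTHETIC_PIAL_PRESSURE_POINTS = np.array(
    [
        (10.0, 34.0),
        (12.0, 36.0),
        (15.0, 38.5),
        (20.0, 42.0),
        (25.0, 44.0),
        (30.0, 47.5),
        (40.0, 52.0),
        (50.0, 56.0),
        (60.0, 59.0),
        (80.0, 64.0),
        (100.0, 68.0),
        (125.0, 72.0),
        (150.0, 75.5),
        (200.0, 81.0),
        (250.0, 85.0),
        (300.0, 88.0),
        (350.0, 90.0),
    ]
)


@dataclass(frozen=True)
class PialPressureModel:
    """Diameter-dependent pial boundary pressures.

    Arteriolar pressures follow a degree-3 polynomial in diameter
    (coefficients in ascending order, mmHg); venular pressures are
    uniform (10 mmHg default, the diameter dependence being weak).
    Queries outside the supported diameter range are clamped with a
    warning.
    """

    coefficients: tuple
    d_range: tuple = (10.0, 350.0)
    venular_pressure: float = 10.0

    @classmethod
    def default(cls) -> "PialPressureModel":
        return cls.from_points(SYNTHETIC_PIAL_PRESSURE_POINTS)

    @classmethod
    def from_points(cls, points, venular_pressure: float = 10.0) -> "PialPressureModel":
        """Least-squares cubic fit to (diameter, pressure) points."""
        pts = np.asarray(points, dtype=float)
        coeffs = np.polynomial.polynomial.polyfit(pts[:, 0], pts[:, 1], deg=3)
        return cls(
            coefficients=tuple(coeffs),
            d_range=(float(pts[:, 0].min()), float(pts[:, 0].max())),
            venular_pressure=venular_pressure,
        )

    def arteriole_pressure(self, d: float) -> float:
        """Pial arteriolar pressure (mmHg) at diameter ``d`` (μm)."""
        lo, hi = self.d_range
        if d < lo or d > hi:
            warnings.warn(
                f"pial arteriole diameter {d:.1f} μm outside fitted range "
                f"[{lo}, {hi}]; clamped",
                RuntimeWarning,
                stacklevel=2,
            )
            d = float(np.clip(d, lo, hi))
        return float(np.polynomial.polynomial.polyval(d, np.asarray(self.coefficients)))

    def pressure(self, d: float, venular: bool) -> float:
        return self.venular_pressure if venular else self.arteriole_pressure(d)


def pial_arteriole_pressure(d: float, model: PialPressureModel | None = None) -> float:
    return (model or PialPressureModel.default()).arteriole_pressure(d)


# --------------------------------------------------------------------- #
@dataclass
class CompoundNetwork:
    """Realistic implant embedded in an artificial host.

    ``stitch_map`` maps every deep-boundary node of the implant (in the
    merged id space) to the artificial node it was connected to;
    ``implant_node_map`` maps original implant node ids to merged ids;
    provenance is tracked per node and per vessel
    ({realistic, artificial, stitch}).
    """

    network: VascularNetwork
    stitch_map: dict
    implant_node_map: dict
    node_provenance: pd.Series
    vessel_provenance: pd.Series


class CompoundAssemblyError(ValueError):
    pass


def build_compound(
    realistic: VascularNetwork,
    artificial: VascularNetwork,
    margin: float = 1.0,
    max_stitch_radius: float = 250.0,
) -> CompoundNetwork:
    """Implant ``realistic`` into ``artificial``.

    A hole of the implant's bounding box (inflated by ``margin`` μm) is
    cut from the artificial network (vessels with *both* endpoints inside
    the box are removed, then isolated nodes dropped); each deep
    boundary node of the implant is joined by a stitch vessel to the
    nearest remaining artificial capillary vertex.
    """
    deep = realistic.nodes.index[realistic.nodes["boundary"] == "deep_boundary"]
    if len(deep) == 0:
        raise CompoundAssemblyError(
            "implant exposes no deep boundary node; nothing to stitch"
        )

    pos_r = realistic.positions
    lo = pos_r.min(axis=0) - margin
    hi = pos_r.max(axis=0) + margin

    a_nodes = artificial.nodes.copy()
    a_vessels = artificial.vessels.copy()
    apos = artificial.positions
    inside = np.all((apos >= lo) & (apos <= hi), axis=1)
    inside_ids = set(a_nodes.index[inside])
    drop = a_vessels["n1"].isin(inside_ids) & a_vessels["n2"].isin(inside_ids)
    a_vessels = a_vessels.loc[~drop]
    used = set(a_vessels["n1"]) | set(a_vessels["n2"])
    a_nodes = a_nodes.loc[sorted(used)]

    # merge with offset implant ids
    nid_off = int(a_nodes.index.max()) + 1
    vid_off = int(a_vessels.index.max()) + 1
    r_nodes = realistic.nodes.copy()
    implant_node_map = {int(i): int(i) + nid_off for i in r_nodes.index}
    r_nodes.index = pd.Index([implant_node_map[int(i)] for i in r_nodes.index], name="id")
    r_vessels = realistic.vessels.copy()
    r_vessels["n1"] = [implant_node_map[int(i)] for i in r_vessels["n1"]]
    r_vessels["n2"] = [implant_node_map[int(i)] for i in r_vessels["n2"]]
    r_vessels.index = pd.Index(
        [int(i) + vid_off for i in r_vessels.index], name="id"
    )

    nodes = pd.concat([a_nodes, r_nodes])
    vessels = pd.concat([a_vessels, r_vessels])

    # stitch candidates: artificial nodes touching a capillary vessel
    cap_nodes = sorted(
        set(a_vessels.loc[a_vessels["type"] == "C", "n1"])
        | set(a_vessels.loc[a_vessels["type"] == "C", "n2"])
    )
    if not cap_nodes:
        raise CompoundAssemblyError("artificial host has no capillary vertices left")
    cap_ids = np.array(cap_nodes, dtype=np.int64)
    cap_pos = a_nodes.loc[cap_ids, ["x", "y", "z"]].to_numpy(float)

    next_vid = int(vessels.index.max()) + 1
    stitch_map = {}
    stitch_rows = []
    for old_id in deep:
        new_id = implant_node_map[int(old_id)]
        p = r_nodes.loc[new_id, ["x", "y", "z"]].to_numpy(float)
        dist = np.linalg.norm(cap_pos - p, axis=1)
        best = dist.min()
        if best > max_stitch_radius:
            raise CompoundAssemblyError(
                f"deep boundary node {int(old_id)} has no artificial capillary vertex "
                f"within {max_stitch_radius} μm (nearest {best:.0f} μm)"
            )
        target = int(cap_ids[dist <= best + 1e-9].min())
        # diameter of the severed implant vessel carries over to the stitch
        inc = r_vessels[(r_vessels["n1"] == new_id) | (r_vessels["n2"] == new_id)]
        d_conn = float(np.clip(inc["diameter"].iloc[0], 2.5, 9.0)) if len(inc) else 4.0
        stitch_rows.append((next_vid, new_id, target, d_conn, max(best, 1.0), "C"))
        stitch_map[new_id] = target
        # the stitched node is now interior to the compound
        nodes.loc[new_id, "boundary"] = "interior"
        next_vid += 1

    stitches = pd.DataFrame(
        stitch_rows, columns=["id", "n1", "n2", "diameter", "length", "type"]
    ).set_index("id")
    vessels = pd.concat([vessels, stitches])

    node_prov = pd.Series("artificial", index=nodes.index)
    node_prov.loc[list(implant_node_map.values())] = "realistic"
    vessel_prov = pd.Series("artificial", index=vessels.index)
    vessel_prov.loc[r_vessels.index] = "realistic"
    vessel_prov.loc[stitches.index] = "stitch"

    net = VascularNetwork(nodes, vessels)
    import networkx as nx

    if nx.number_connected_components(net.to_networkx()) != 1:
        raise CompoundAssemblyError("compound network is not connected")
    return CompoundNetwork(
        network=net,
        stitch_map=stitch_map,
        implant_node_map=implant_node_map,
        node_provenance=node_prov,
        vessel_provenance=vessel_prov,
    )


# --------------------------------------------------------------------- #
def pial_boundary_conditions(
    network: VascularNetwork,
    model: PialPressureModel | None = None,
    inflow_ht: float = 0.3,
) -> list[BoundaryCondition]:
    """Pressure BCs at every pial node of a network.

    Arteriolar pial nodes get the cubic pressure evaluated at the
    diameter of their (largest) incident vessel; venular pial nodes get
    the uniform venular pressure.
    """
    model = model or PialPressureModel.default()
    inc = network.incident()
    bcs = []
    for nid, row in network.nodes.iterrows():
        if row["boundary"] == "pial_inflow":
            d = max(network.vessels.loc[v, "diameter"] for v in inc[int(nid)])
            bcs.append(BoundaryCondition(int(nid), model.arteriole_pressure(float(d)), inflow_ht))
        elif row["boundary"] == "pial_outflow":
            bcs.append(BoundaryCondition(int(nid), model.venular_pressure, inflow_ht))
    return bcs


def hierarchical_pressures(
    compound: CompoundNetwork,
    constant_ht: float = 0.3,
    model: PialPressureModel | None = None,
    rheology: RheologyParams | None = None,
) -> tuple[dict, PressureSolution]:
    """Steady compound solve at constant tube hematocrit.

    All pial nodes of the compound (artificial and implant alike) carry
    pressure BCs from the pial model; every edge's resistance is
    evaluated at the constant tube hematocrit (no RBC tracking).  Returns
    the solved pressures (mmHg) at the implant's stitched deep boundary
    nodes — keyed by *original* implant node id — along with the full
    compound solution.
    """
    net = compound.network
    rheology = rheology or RheologyParams()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = effective_resistance(
            net.vessels["diameter"].to_numpy(float),
            net.vessels["length"].to_numpy(float),
            constant_ht,
            rheology,
        )
    bcs = pial_boundary_conditions(net, model, constant_ht)
    sol = solve_pressure_flow(net, r, bcs)

    inv = {v: k for k, v in compound.implant_node_map.items()}
    deep_pressures = {
        inv[new_id]: sol.pressure_of(new_id) for new_id in compound.stitch_map
    }
    return deep_pressures, sol


def assign_boundary_conditions(
    implant: VascularNetwork,
    artificial: VascularNetwork,
    constant_ht: float = 0.3,
    model: PialPressureModel | None = None,
    **compound_kwargs,
) -> tuple[list[BoundaryCondition], CompoundNetwork, PressureSolution]:
    """End-to-end hierarchical BC assignment for an implant.

    Returns the full BC list for the discrete simulation on the implant
    alone: pial nodes from the pial pressure model, deep boundary nodes
    from the steady compound solve (pressure BCs even where the compound
    marks them as outflows).
    """
    compound = build_compound(implant, artificial, **compound_kwargs)
    deep_p, sol = hierarchical_pressures(compound, constant_ht, model)
    bcs = pial_boundary_conditions(implant, model, constant_ht)
    for nid, p in sorted(deep_p.items()):
        bcs.append(BoundaryCondition(int(nid), float(p), constant_ht))
    return bcs, compound, sol
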