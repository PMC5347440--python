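"""Discrete red-blood-cell tracking coupled to the network pressure solve.

Blood is treated as a biphasic fluid: every time step the pressure and
flow field is recomputed from the *current* distribution of RBCs (whose
per-edge tube hematocrit raises the effective resistances), then all RBCs
are propagated.  RBCs move faster than the bulk flow by the Fåhraeus
factor ``hd/ht`` (floored at 1), cannot overlap the cell ahead (minimum
center spacing = effective cell length = cell volume / lumen
cross-section, capped at the vessel length) and are held at convergent
nodes while the downstream vessel lacks space, proceeding as soon as they
fit (first blocked, first admitted).

At divergent capillary bifurcations an RBC follows the path of the
largest pressure force, i.e. the outgoing branch with the largest bulk
flow velocity; the alternative largest-flow-rate rule is evaluated
alongside and an agreement indicator is accumulated.  At arteriolar
divergent bifurcations the RBC flux is partitioned by the empirical
phase-separation law (logit parameterization with coefficients from the
Pries lineage, configurable), sampled per cell with a seeded RNG.

The time step is constant over the whole run and chosen so that
``dt <= L/v`` holds for at least a coverage fraction (99.8 % by default)
of all vessels; several bifurcation events per cell and step are allowed.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from mvnflow.network import TYPE_STAGE, VascularNetwork
from mvnflow.rheology import RheologyParams, discharge_hematocrit, relative_viscosity
from mvnflow.solver import BoundaryCondition, PressureSolution, solve_pressure_flow
from mvnflow.units import MMHG_TO_PA

logger = logging.getLogger(__name__)

try:  # numba accelerates the per-edge spacing enforcement
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    njit = None


# --------------------------------------------------------------------- #
# time step
# --------------------------------------------------------------------- #
def select_timestep(network: VascularNetwork, velocities_mms, coverage: float = 0.998) -> float:
    """Constant time step from the vessel transit-time distribution.

    Returns the largest ``dt`` such that ``dt <= L_ij/|v_ij|`` holds for
    at least ``coverage`` of all vessels (velocities from a converged
    initial pure-plasma solve, mm/s).  ``coverage=1`` gives the minimum
    transit time.
    """
    if not (0.9 < coverage <= 1.0):
        raise ValueError("coverage must lie in (0.9, 1]")
    L = network.vessels["length"].to_numpy(float)
    if np.any(L <= 0):
        raise ValueError("zero-length vessel in network")
    v = np.abs(np.asarray(velocities_mms, dtype=float))
    with np.errstate(divide="ignore"):
        transit = (L * 1e-3) / v  # s
    transit = np.sort(transit)
    m = transit.size
    k = max(0, math.ceil((1.0 - coverage) * m - 1e-9) - 1)
    return float(transit[k])


# --------------------------------------------------------------------- #
# bifurcation rules
# --------------------------------------------------------------------- #
@dataclass(frozen=True)
class BranchChoice:
    velocity_rule: int  # edge id chosen by the largest-bulk-velocity rule
    flow_rule: int  # edge id chosen by the largest-flow-rate rule
    agree: bool


def branch_choice_divergent(edge_ids, velocities, flows) -> BranchChoice:
    """Deterministic branch choice at a divergent capillary bifurcation.

    The production rule follows the branch with the largest bulk flow
    velocity (the stated equivalent of the largest pressure force); the
    largest-flow-rate alternative is evaluated alongside.  Ties are broken
    toward the lowest edge id.
    """
    ids = np.asarray(edge_ids, dtype=np.int64)
    if ids.size < 1:
        raise ValueError("divergent bifurcation needs at least one outgoing edge")
    v = np.abs(np.asarray(velocities, dtype=float))
    q = np.abs(np.asarray(flows, dtype=float))

    def argbest(x):
        best = x.max()
        return int(ids[x == best].min())

    cv, cq = argbest(v), argbest(q)
    return BranchChoice(velocity_rule=cv, flow_rule=cq, agree=cv == cq)


@dataclass(frozen=True)
class PhaseSeparationParams:
    """Coefficients of the empirical phase-separation (plasma skimming)
    law; the defaults follow the Pries et al. lineage, stored here so
    alternative calibrations can be swapped in."""

    coef_a: float = -13.29
    coef_b: float = 6.98
    coef_x0: float = 0.964


def phase_separation_split(
    parent_flow: float,
    daughter_flows,
    parent_d: float,
    daughter_ds,
    parent_hd: float,
    params: PhaseSeparationParams | None = None,
) -> np.ndarray:
    """RBC flux fractions at an arteriolar divergent bifurcation.

    For two daughters the logit law is used: with ``FQB`` the fractional
    blood flow of a daughter,

    ``logit(FQE) = A + B logit((FQB - X0)/(1 - 2 X0))``

    where ``X0 = x0 (1-hd)/df`` is the low-flow threshold (no cells below
    ``X0``, all cells above ``1 - X0``), ``B = 1 + b (1-hd)/df`` and ``A``
    is the diameter-asymmetry term ``a ((da^2-db^2)/(da^2+db^2))(1-hd)/df``
    (diameters in μm).  Fractions are in [0, 1], sum to 1, are monotone in
    the daughter flow fraction and symmetric for identical daughters.
    For more than two daughters the flux is partitioned proportionally to
    the thresholded flow fractions.
    """
    if params is None:
        params = PhaseSeparationParams()
    if parent_flow <= 0:
        raise ValueError("parent flow must be positive at a divergent bifurcation")
    qd = np.asarray(daughter_flows, dtype=float)
    dd = np.asarray(daughter_ds, dtype=float)
    if qd.size < 2:
        return np.ones(qd.size)
    frac_q = qd / qd.sum()
    hd = parent_hd
    x0 = params.coef_x0 * (1.0 - hd) / parent_d

    if qd.size == 2:
        fqb = frac_q[0]
        if fqb <= x0:
            f0 = 0.0
        elif fqb >= 1.0 - x0:
            f0 = 1.0
        else:
            a = (
                params.coef_a
                * ((dd[0] ** 2 - dd[1] ** 2) / (dd[0] ** 2 + dd[1] ** 2))
                * (1.0 - hd)
                / parent_d
            )
            b = 1.0 + params.coef_b * (1.0 - hd) / parent_d
            arg = (fqb - x0) / (1.0 - 2.0 * x0)
            logit = a + b * math.log(arg / (1.0 - arg))
            f0 = 1.0 / (1.0 + math.exp(-logit))
        return np.array([f0, 1.0 - f0])

    # >2 daughters: thresholded proportional split
    eff = np.clip(frac_q - x0, 0.0, None)
    if eff.sum() == 0:
        eff = frac_q
    return eff / eff.sum()


# --------------------------------------------------------------------- #
# configuration and results
# --------------------------------------------------------------------- #
@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a discrete RBC tracking run.

    ``dt_coverage`` is the fraction of vessels whose transit time must not
    be undercut by the constant time step; the run consists of a warm-up
    (15 turn-over times by default, not recorded), a recording window
    (1 turn-over time) and a drain phase in which already-recorded cells
    are followed to their exit (capped at ``drain_turnovers``).
    """

    dt_coverage: float = 0.998
    warmup_turnovers: float = 15.0
    recording_turnovers: float = 1.0
    drain_turnovers: float = 10.0
    rbc_volume_fl: float = 49.0
    seed: int = 0
    max_steps: int | None = None
    rheology: RheologyParams = field(default_factory=RheologyParams)
    phase_separation: PhaseSeparationParams = field(default_factory=PhaseSeparationParams)


@dataclass
class Trajectory:
    """One recorded RBC path: ordered edges with entry times/pressures.

    ``s`` is the cumulative tortuous path length (μm) at each edge entry,
    ``s_tot`` the total path length; ``v_rbc`` is the cell velocity per
    edge (mm/s, edge length over residence time).
    """

    rbc_id: int
    edges: np.ndarray
    entry_nodes: np.ndarray
    entry_times: np.ndarray
    entry_pressures: np.ndarray  # mmHg
    vessel_types: list
    edge_lengths: np.ndarray
    exit_time: float
    exit_node: int

    @property
    def s(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.edge_lengths)])[:-1]

    @property
    def s_tot(self) -> float:
        return float(np.sum(self.edge_lengths))

    @property
    def v_rbc(self) -> np.ndarray:
        times = np.concatenate([self.entry_times, [self.exit_time]])
        dt = np.diff(times)
        with np.errstate(divide="ignore"):
            return np.where(dt > 0, self.edge_lengths * 1e-3 / dt, np.inf)


@dataclass
class SimulationResult:
    trajectories: list
    dt: float
    turnover_time: float
    n_steps: int
    n_injected: int
    n_exited: int
    n_resident: int
    n_recorded: int
    n_incomplete_recorded: int
    capillary_rule_agreement: float  # fraction of capillary divergent events where both rules agree
    capillary_rule_events: int
    stalled_events: int
    time_series: dict
    final_state: "DiscreteRBCSimulation" = field(repr=False, default=None)

    @property
    def conserved(self) -> bool:
        return self.n_injected == self.n_exited + self.n_resident


# --------------------------------------------------------------------- #
# spacing enforcement kernel
# --------------------------------------------------------------------- #
def _clamp_segments_py(pos, seg_start, seg_end, sign, length, ell):
    for s in range(seg_start.size):
        a, b = seg_start[s], seg_end[s]
        if sign[s] > 0:
            bound = length[s]
            for k in range(b - 1, a - 1, -1):
                p = pos[k]
                if p > bound:
                    p = bound
                if p < 0.0:
                    p = 0.0
                pos[k] = p
                bound = p - ell[s]
        elif sign[s] < 0:
            bound = 0.0
            for k in range(a, b):
                p = pos[k]
                if p < bound:
                    p = bound
                if p > length[s]:
                    p = length[s]
                pos[k] = p
                bound = p + ell[s]


if njit is not None:
    _clamp_segments = njit(cache=False)(_clamp_segments_py)
else:  # pragma: no cover
    _clamp_segments = _clamp_segments_py


# --------------------------------------------------------------------- #
# the engine
# --------------------------------------------------------------------- #
class DiscreteRBCSimulation:
    """Coupled pressure-solve / RBC-propagation engine.

    Holds the per-edge geometry, the per-cell state (edge, linear
    coordinate from the edge's ``n1`` in μm) and the path records of the
    cells injected during the recording window.
    """

    def __init__(
        self,
        network: VascularNetwork,
        bcs,
        config: SimulationConfig | None = None,
        dt: float | None = None,
    ):
        self.network = network
        self.config = config or SimulationConfig()
        self.bcs = list(bcs)
        self.dt = dt
        self.rng = np.random.default_rng(self.config.seed)

        v = network.vessels
        self.edge_ids = v.index.to_numpy(np.int64)
        self.L = v["length"].to_numpy(float)  # μm
        self.d = v["diameter"].to_numpy(float)  # μm
        self.types = list(v["type"])
        self.stage = np.array([TYPE_STAGE[t] for t in self.types], dtype=np.int64)
        self.is_arteriolar_parent = np.array([t in ("PA", "DA", "A") for t in self.types])
        self.is_capillary = np.array([t == "C" for t in self.types])
        self.area_um2 = np.pi * self.d**2 / 4.0
        self.area_m2 = self.area_um2 * 1e-12
        vol = self.config.rbc_volume_fl  # 1 fL = 1 μm^3
        self.rbc_vol_um3 = vol
        self.ell = np.minimum(vol / self.area_um2, self.L)  # effective cell length, μm
        self.rows = network.edge_node_rows()
        self.node_ids = network.nodes.index.to_numpy(np.int64)
        self.node_boundary = network.nodes["boundary"].to_numpy()
        self._id_to_row = {int(nid): i for i, nid in enumerate(self.node_ids)}
        self._edge_pos = {int(e): i for i, e in enumerate(self.edge_ids)}

        # node -> incident edge row indices
        self.node_edges: list[list[int]] = [[] for _ in range(len(self.node_ids))]
        for k, (i, j) in enumerate(self.rows):
            self.node_edges[i].append(k)
            self.node_edges[j].append(k)

        # --- cell state (slot arrays with free-list reuse) -------------
        cap = 1024
        self.pos = np.zeros(cap)
        self.edge = np.full(cap, -1, dtype=np.int64)
        self.uid = np.full(cap, -1, dtype=np.int64)
        self.alive = np.zeros(cap, dtype=bool)
        self.blocked = np.zeros(cap, dtype=bool)
        self.free: list[int] = list(range(cap))[::-1]
        self.occupants: list[deque] = [deque() for _ in range(len(self.edge_ids))]
        self.next_uid = 0
        self.blocked_fifo: deque = deque()  # slots in blocking order

        self.paths: dict[int, list] = {}  # uid -> [(edge_id, node_id, t, p_mmHg), ...]
        self.exits: dict[int, tuple] = {}  # uid -> (t_exit, node_id)
        self.recording = False
        self.clock = 0.0
        self.n_injected = 0
        self.n_exited = 0
        self.rule_events = 0
        self.rule_agreements = 0
        self.stalled_events = 0
        self._cross_cap_warned = False

        # injection accumulators per boundary-incident edge (seeded phase)
        self._bc_by_node = {bc.node_id: bc for bc in self.bcs}
        self.inflow_acc: dict[int, float] = {}

        # per-step caches
        self.ht = np.zeros(len(self.edge_ids))
        self.solution: PressureSolution | None = None
        self.q = np.zeros(len(self.edge_ids))
        self.v_bulk = np.zeros(len(self.edge_ids))  # mm/s signed n1->n2
        self.v_rbc = np.zeros(len(self.edge_ids))  # mm/s signed, Fåhraeus-corrected

    # ---------------------------------------------------------------- #
    def _grow(self):
        old = self.pos.size
        new = old * 2
        for name in ("pos",):
            setattr(self, name, np.resize(getattr(self, name), new))
        self.edge = np.resize(self.edge, new)
        self.uid = np.resize(self.uid, new)
        self.alive = np.resize(self.alive, new)
        self.blocked = np.resize(self.blocked, new)
        self.alive[old:] = False
        self.blocked[old:] = False
        self.free.extend(range(new - 1, old - 1, -1))

    def _new_slot(self) -> int:
        if not self.free:
            self._grow()
        return self.free.pop()

    # ---------------------------------------------------------------- #
    def update_hematocrit(self):
        counts = np.zeros(len(self.edge_ids))
        act = np.flatnonzero(self.alive)
        if act.size:
            counts = np.bincount(self.edge[act], minlength=len(self.edge_ids)).astype(float)
        self.ht = np.clip(counts * self.rbc_vol_um3 / (self.area_um2 * self.L), 0.0, 0.99)

    def solve(self):
        """Pressure/flow solve at the instantaneous hematocrit."""
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)
            hd = discharge_hematocrit(self.ht, self.d)
            mu = relative_viscosity(self.d, None, hd=hd)
        r = mu * 128.0 * self.config.rheology.mu_plasma * (self.L * 1e-6) / (
            np.pi * (self.d * 1e-6) ** 4
        )
        self.solution = solve_pressure_flow(self.network, r, self.bcs)
        self.q = self.solution.flows_m3s
        self.v_bulk = self.solution.velocities_mms
        factor = np.ones_like(self.ht)
        nz = self.ht > 0
        factor[nz] = np.maximum(1.0, hd[nz] / self.ht[nz])
        self.v_rbc = self.v_bulk * factor
        self._p_mmhg = self.solution.pressures_mmhg

    # ---------------------------------------------------------------- #
    def _entrance(self, k: int) -> float:
        return 0.0 if self.v_rbc[k] > 0 else self.L[k]

    def _exit_row(self, k: int) -> int:
        return self.rows[k][1] if self.v_rbc[k] > 0 else self.rows[k][0]

    def _headroom_ok(self, k: int) -> bool:
        occ = self.occupants[k]
        if not occ:
            return True
        if self.v_rbc[k] > 0:
            return self.pos[occ[0]] >= self.ell[k]
        return self.L[k] - self.pos[occ[-1]] >= self.ell[k]

    def _insert(self, slot: int, k: int, p: float):
        occ = self.occupants[k]
        if self.v_rbc[k] > 0:
            if occ:
                p = min(p, self.pos[occ[0]] - self.ell[k])
            p = max(p, 0.0)
            occ.appendleft(slot)
        else:
            if occ:
                p = max(p, self.pos[occ[-1]] + self.ell[k])
            p = min(p, self.L[k])
            occ.append(slot)
        self.pos[slot] = p
        self.edge[slot] = k

    def _pop_front(self, k: int) -> int:
        return self.occupants[k].pop() if self.v_rbc[k] > 0 else self.occupants[k].popleft()

    def _front_slot(self, k: int):
        occ = self.occupants[k]
        if not occ:
            return None
        return occ[-1] if self.v_rbc[k] > 0 else occ[0]

    def _record_entry(self, slot: int, k: int, node_row: int, t: float):
        u = int(self.uid[slot])
        if u in self.paths:
            self.paths[u].append(
                (
                    int(self.edge_ids[k]),
                    int(self.node_ids[node_row]),
                    float(t),
                    float(self._p_mmhg[node_row]),
                )
            )

    def _outgoing(self, node_row: int, exclude: int):
        out = []
        for k in self.node_edges[node_row]:
            if k == exclude:
                continue
            qk = self.q[k]
            if (self.rows[k][0] == node_row and qk > 0) or (self.rows[k][1] == node_row and qk < 0):
                out.append(k)
        return out

    def _choose_branch(self, parent_k: int, node_row: int, out: list[int]) -> int:
        if len(out) == 1:
            return out[0]
        if self.is_arteriolar_parent[parent_k]:
            with np.errstate(all="ignore"):
                hd_p = float(
                    discharge_hematocrit(min(self.ht[parent_k], 0.9), self.d[parent_k])
                )
            frac = phase_separation_split(
                abs(self.q[parent_k]),
                [abs(self.q[k]) for k in out],
                float(self.d[parent_k]),
                [float(self.d[k]) for k in out],
                hd_p,
                self.config.phase_separation,
            )
            return out[int(self.rng.choice(len(out), p=frac))]
        choice = branch_choice_divergent(
            [self.edge_ids[k] for k in out],
            [self.v_bulk[k] for k in out],
            [self.q[k] for k in out],
        )
        if len(out) > 1 and all(self.is_capillary[k] for k in out):
            self.rule_events += 1
            self.rule_agreements += int(choice.agree)
        return self._edge_pos[choice.velocity_rule]

    # ---------------------------------------------------------------- #
    def _try_cross(self, slot: int, t_rem: float, depth: int = 0) -> None:
        """Move ``slot`` across the node at the exit of its edge, carrying
        ``t_rem`` seconds of remaining travel time."""
        k = int(self.edge[slot])
        node_row = self._exit_row(k)
        out = self._outgoing(node_row, exclude=k)
        if not out:
            kind = self.node_boundary[node_row]
            if kind != "interior":
                # leaves the network
                self._pop_front(k)
                self.alive[slot] = False
                u = int(self.uid[slot])
                if u in self.paths:
                    self.exits[u] = (self.clock + self.dt - t_rem, int(self.node_ids[node_row]))
                self.free.append(slot)
                self.n_exited += 1
                return
            # interior dead end / stagnation: stall at the node
            self.stalled_events += 1
            self._block(slot, k)
            return
        target = self._choose_branch(k, node_row, out)
        if not self._headroom_ok(target):
            self._block(slot, k)
            return
        # admitted: hop edges
        self._pop_front(k)
        u_t = self.v_rbc[target]
        speed = abs(u_t) * 1e3  # μm/s
        entrance = self._entrance(target)
        advance = speed * t_rem
        p_new = entrance + advance if u_t > 0 else entrance - advance
        self._insert(slot, target, float(np.clip(p_new, 0.0, self.L[target])))
        self._record_entry(slot, target, node_row, self.clock + self.dt - t_rem)
        # may cross again within the same step
        overshoot = (p_new - self.L[target]) if u_t > 0 else (0.0 - p_new)
        if overshoot > 0 and speed > 0 and self._front_slot(target) == slot:
            if depth >= 64:
                if not self._cross_cap_warned:
                    logger.warning("per-step crossing cap hit; possible tight cycle")
                    self._cross_cap_warned = True
                return
            self._try_cross(slot, overshoot / speed, depth + 1)

    def _block(self, slot: int, k: int):
        self.pos[slot] = self.L[k] if self.v_rbc[k] > 0 else 0.0
        if not self.blocked[slot]:
            self.blocked[slot] = True
            self.blocked_fifo.append(slot)

    # ---------------------------------------------------------------- #
    def advance(self):
        """Propagate all RBCs by one constant time step ``self.dt``."""
        dt = self.dt
        act = np.flatnonzero(self.alive & ~self.blocked)
        if act.size:
            self.pos[act] += self.v_rbc[self.edge[act]] * 1e3 * dt

        # previously blocked cells first, in blocking order
        retry = list(self.blocked_fifo)
        self.blocked_fifo.clear()
        for slot in retry:
            if not self.alive[slot]:
                continue
            self.blocked[slot] = False
            k = int(self.edge[slot])
            if self._front_slot(k) == slot and abs(self.v_rbc[k]) > 0:
                self._try_cross(slot, dt)
            # else: no longer front (direction flipped); rejoin normal flow

        # fresh overshooters, earliest exit (largest remaining time) first
        act = np.flatnonzero(self.alive & ~self.blocked)
        if act.size:
            k_arr = self.edge[act]
            u = self.v_rbc[k_arr] * 1e3  # μm/s
            over = np.where(
                u > 0, self.pos[act] - self.L[k_arr], np.where(u < 0, -self.pos[act], -1.0)
            )
            speed = np.abs(u)
            cand = (over > 0) & (speed > 0)
            if np.any(cand):
                t_rem = np.zeros(act.size)
                t_rem[cand] = over[cand] / speed[cand]
                order = np.argsort(-t_rem, kind="stable")
                for idx in order:
                    if t_rem[idx] <= 0:
                        break
                    slot = int(act[idx])
                    if not self.alive[slot] or self.blocked[slot]:
                        continue
                    k = int(self.edge[slot])
                    if self._front_slot(k) != slot:
                        continue  # stuck behind a blocked leader; clamp resolves
                    self._try_cross(slot, float(t_rem[idx]))

        self._enforce_spacing()

    def _enforce_spacing(self):
        act = np.flatnonzero(self.alive)
        if act.size == 0:
            return
        edges_a = self.edge[act]
        order = np.lexsort((self.pos[act], edges_a))
        slots = act[order]
        pos_s = self.pos[slots].copy()
        edge_s = edges_a[order]
        breaks = np.flatnonzero(np.diff(edge_s)) + 1
        seg_start = np.concatenate([[0], breaks]).astype(np.int64)
        seg_end = np.concatenate([breaks, [edge_s.size]]).astype(np.int64)
        seg_edges = edge_s[seg_start]
        sign = np.sign(self.v_rbc[seg_edges])
        _clamp_segments(
            pos_s, seg_start, seg_end, sign, self.L[seg_edges], self.ell[seg_edges]
        )
        self.pos[slots] = pos_s

    # ---------------------------------------------------------------- #
    def inject(self):
        """Inject RBCs at inflow boundary edges to hold the prescribed
        inflow tube hematocrit in expectation."""
        for node_id, bc in self._bc_by_node.items():
            node_row = self._id_to_row[node_id]
            for k in self._outgoing(node_row, exclude=-1):
                speed = abs(self.v_rbc[k]) * 1e3  # μm/s
                if speed <= 0:
                    continue
                n_dot = speed * bc.inflow_ht * self.area_um2[k] / self.rbc_vol_um3
                key = (node_id, k)
                if key not in self.inflow_acc:
                    self.inflow_acc[key] = float(self.rng.random())
                self.inflow_acc[key] += n_dot * self.dt
                while self.inflow_acc[key] >= 1.0:
                    if not self._headroom_ok(k):
                        break  # no space: defer, hematocrit feedback throttles
                    slot = self._new_slot()
                    self.alive[slot] = True
                    self.blocked[slot] = False
                    self.uid[slot] = self.next_uid
                    self._insert(slot, k, self._entrance(k))
                    if self.recording:
                        self.paths[self.next_uid] = []
                    self._record_entry(slot, k, node_row, self.clock + self.dt)
                    self.next_uid += 1
                    self.n_injected += 1
                    self.inflow_acc[key] -= 1.0

    # ---------------------------------------------------------------- #
    def step(self):
        self.update_hematocrit()
        self.solve()
        self.advance()
        self.inject()
        self.clock += self.dt

    @property
    def n_resident(self) -> int:
        return int(self.alive.sum())


# --------------------------------------------------------------------- #
def turnover_time(network: VascularNetwork, solution: PressureSolution, bcs) -> float:
    """Total vascular volume over total boundary inflow (seconds)."""
    d = network.vessels["diameter"].to_numpy(float) * 1e-6
    L = network.vessels["length"].to_numpy(float) * 1e-6
    volume = float(np.sum(np.pi * d**2 / 4.0 * L))  # m^3
    from mvnflow.solver import node_residuals

    res = node_residuals(network, solution)  # net outflow per node
    node_index = network.node_index()
    bc_rows = np.array([node_index.loc[bc.node_id] for bc in bcs], dtype=np.int64)
    # a boundary node feeding the network has positive net outflow
    inflow = float(np.sum(np.clip(res[bc_rows], 0.0, None)))
    if inflow <= 0:
        raise ValueError("no net boundary inflow; check boundary conditions")
    return volume / inflow


def run_simulation(
    network: VascularNetwork, bcs, config: SimulationConfig | None = None
) -> SimulationResult:
    """Full discrete RBC tracking run.

    An initial pure-plasma solve fixes the constant time step and the
    turn-over time (vascular volume / total inflow).  The coupled loop
    then alternates pressure solve and RBC propagation; cell paths are
    recorded only for cells injected after the warm-up (15 turn-over
    times by default) during a recording window of one turn-over time,
    and the run continues until the recorded cells have left the network
    (capped).  RBC count is conserved exactly: injected = exited +
    resident.
    """
    config = config or SimulationConfig()
    sim = DiscreteRBCSimulation(network, bcs, config)

    # initial pure-plasma solve (unit relative viscosity)
    r_plasma = (
        128.0
        * config.rheology.mu_plasma
        * (sim.L * 1e-6)
        / (np.pi * (sim.d * 1e-6) ** 4)
    )
    plasma = solve_pressure_flow(network, r_plasma, bcs)
    dt = select_timestep(network, plasma.velocities_mms, config.dt_coverage)
    sim.dt = dt
    t_turn = turnover_time(network, plasma, bcs)

    n_warm = math.ceil(config.warmup_turnovers * t_turn / dt)
    n_rec = math.ceil(config.recording_turnovers * t_turn / dt)
    n_drain = math.ceil(config.drain_turnovers * t_turn / dt)
    if config.max_steps is not None:
        n_warm = min(n_warm, config.max_steps)
        n_rec = min(n_rec, config.max_steps)
        n_drain = min(n_drain, config.max_steps)

    series = {"t": [], "n_resident": [], "n_injected": [], "n_exited": []}

    def log_series():
        series["t"].append(sim.clock)
        series["n_resident"].append(sim.n_resident)
        series["n_injected"].append(sim.n_injected)
        series["n_exited"].append(sim.n_exited)

    for _ in range(n_warm):
        sim.step()
        log_series()
    sim.recording = True
    for _ in range(n_rec):
        sim.step()
        log_series()
    sim.recording = False
    for _ in range(n_drain):
        live_recorded = set(sim.paths) - set(sim.exits)
        if not live_recorded:
            break
        sim.step()
        log_series()

    trajectories = []
    incomplete = 0
    for u, path in sorted(sim.paths.items()):
        if u not in sim.exits or not path:
            incomplete += int(u not in sim.exits)
            continue
        t_exit, node_exit = sim.exits[u]
        edges = np.array([p[0] for p in path], dtype=np.int64)
        rowpos = np.array([sim._edge_pos[int(e)] for e in edges])
        trajectories.append(
            Trajectory(
                rbc_id=u,
                edges=edges,
                entry_nodes=np.array([p[1] for p in path], dtype=np.int64),
                entry_times=np.array([p[2] for p in path]),
                entry_pressures=np.array([p[3] for p in path]),
                vessel_types=[sim.types[i] for i in rowpos],
                edge_lengths=sim.L[rowpos],
                exit_time=t_exit,
                exit_node=node_exit,
            )
        )

    agree = sim.rule_agreements / sim.rule_events if sim.rule_events else float("nan")
    return SimulationResult(
        trajectories=trajectories,
        dt=dt,
        turnover_time=t_turn,
        n_steps=len(series["t"]),
        n_injected=sim.n_injected,
        n_exited=sim.n_exited,
        n_resident=sim.n_resident,
        n_recorded=len(sim.paths),
        n_incomplete_recorded=incomplete,
        capillary_rule_agreement=agree,
        capillary_rule_events=sim.rule_events,
        stalled_events=sim.stalled_events,
        time_series={k: np.asarray(v) for k, v in series.items()},
        final_state=sim,
    )


# --------------------------------------------------------------------- #
# trajectory serialization
# --------------------------------------------------------------------- #
def save_trajectories_ndjson(trajectories, path):
    """One JSON record per RBC: edge ids, entry nodes/times/pressures,
    vessel types, edge lengths and the exit event."""
    import json

    with open(path, "w") as f:
        for t in trajectories:
            rec = {
                "rbc_id": int(t.rbc_id),
                "edges": [int(e) for e in t.edges],
                "entry_nodes": [int(n) for n in t.entry_nodes],
                "entry_times": [float(x) for x in t.entry_times],
                "entry_pressures": [float(x) for x in t.entry_pressures],
                "vessel_types": list(t.vessel_types),
                "edge_lengths": [float(x) for x in t.edge_lengths],
                "exit_time": float(t.exit_time),
                "exit_node": int(t.exit_node),
            }
            f.write(json.dumps(rec) + "\n")


def load_trajectories_ndjson(path):
    import json

    out = []
    with open(path) as f:
        for line in f:
            if not line.strip():
                continue
            r = json.loads(line)
            out.append(
                Trajectory(
                    rbc_id=r["rbc_id"],
                    edges=np.array(r["edges"], dtype=np.int64),
                    entry_nodes=np.array(r["entry_nodes"], dtype=np.int64),
                    entry_times=np.array(r["entry_times"]),
                    entry_pressures=np.array(r["entry_pressures"]),
                    vessel_types=list(r["vessel_types"]),
                    edge_lengths=np.array(r["edge_lengths"]),
                    exit_time=r["exit_time"],
                    exit_node=r["exit_node"],
                )
            )
    return out


def save_trajectories_hdf5(trajectories, path, group="trajectories"):
    """Ragged trajectory storage: concatenated arrays plus offsets."""
    import h5py

    offs = np.cumsum([0] + [len(t.edges) for t in trajectories])
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        g.create_dataset("offsets", data=offs)
        g.create_dataset("rbc_id", data=np.array([t.rbc_id for t in trajectories], np.int64))
        g.create_dataset("exit_time", data=np.array([t.exit_time for t in trajectories]))
        g.create_dataset("exit_node", data=np.array([t.exit_node for t in trajectories], np.int64))
        for name, dtype in (
            ("edges", np.int64),
            ("entry_nodes", np.int64),
            ("entry_times", float),
            ("entry_pressures", float),
            ("edge_lengths", float),
        ):
            g.create_dataset(
                name,
                data=np.concatenate([np.asarray(getattr(t, name), dtype) for t in trajectories])
                if trajectories
                else np.array([], dtype),
            )
        types = np.concatenate(
            [np.array(t.vessel_types, dtype="S4") for t in trajectories]
        ) if trajectories else np.array([], dtype="S4")
        g.create_dataset("vessel_types", data=types)
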