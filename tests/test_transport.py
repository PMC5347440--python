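"""Discrete RBC tracking: time step, bifurcation rules, propagation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mvnflow.solver import BoundaryCondition, solve_pressure_flow
from mvnflow.transport import (
    DiscreteRBCSimulation,
    SimulationConfig,
    branch_choice_divergent,
    load_trajectories_ndjson,
    phase_separation_split,
    run_simulation,
    save_trajectories_ndjson,
    select_timestep,
)
from tests.conftest import make_network


class TestSelectTimestep:
    def net_with_transits(self, transits):
        """Vessels engineered so that L/v equals the given transits: the
        time step quantile only depends on L and the supplied velocities."""
        n = len(transits)
        node_rows = [(0, 0, 0, 0, "pial_inflow")] + [
            (i + 1, 100.0 * (i + 1), 0, 0, "interior") for i in range(n)
        ]
        vessel_rows = [
            (i, i, i + 1, 5.0, 100.0, "C") for i in range(n)
        ]  # L = 100 μm = 0.1 mm
        return make_network(node_rows, vessel_rows)

    def test_full_coverage_gives_minimum(self):
        net = self.net_with_transits([1, 2, 3])
        v = [0.1 / t for t in (0.1, 0.2, 0.3)]  # mm/s so L/v = 0.1, 0.2, 0.3 s
        assert select_timestep(net, v, coverage=1.0) == pytest.approx(0.1)

    def test_quantile_is_second_smallest_of_1000(self):
        rng = np.random.default_rng(0)
        transits = rng.uniform(0.05, 1.0, 1000)
        net = self.net_with_transits(transits)
        v = 0.1 / transits
        dt = select_timestep(net, v, coverage=0.998)
        assert dt == pytest.approx(np.sort(transits)[1])

    def test_identical_vessels_degenerate(self):
        net = self.net_with_transits([1] * 7)
        v = [0.5] * 7  # L/v = 0.2 s each
        assert select_timestep(net, v, coverage=0.998) == pytest.approx(0.2)

    def test_zero_length_rejected(self):
        net = self.net_with_transits([1, 2])
        net.vessels.loc[0, "length"] = 0.0
        with pytest.raises(ValueError):
            select_timestep(net, [1.0, 1.0])


class TestBranchChoice:
    def test_largest_velocity_wins(self):
        c = branch_choice_divergent([5, 6], [2.0, 1.0], [1.0, 2.0])
        assert c.velocity_rule == 5

    def test_tie_breaks_to_lowest_id_and_rules_agree(self):
        c = branch_choice_divergent([9, 4], [1.0, 1.0], [1.0, 1.0])
        assert c.velocity_rule == 4 and c.flow_rule == 4 and c.agree

    def test_velocity_and_flow_rules_can_disagree(self):
        # q proportional to v d^2: A (v=2, d=3) vs B (v=1.5, d=4)
        v = np.array([2.0, 1.5])
        d = np.array([3.0, 4.0])
        q = v * np.pi * d**2 / 4
        c = branch_choice_divergent([1, 2], v, q)
        assert c.velocity_rule == 1 and c.flow_rule == 2 and not c.agree


class TestPhaseSeparation:
    def test_symmetric_split(self):
        f = phase_separation_split(1.0, [0.5, 0.5], 10.0, [6.0, 6.0], 0.4)
        assert f == pytest.approx([0.5, 0.5])

    def test_low_flow_threshold(self):
        # X0 = 0.964 (1 - hd)/df; below it the daughter receives no cells
        hd, df = 0.4, 10.0
        x0 = 0.964 * (1 - hd) / df
        f = phase_separation_split(1.0, [x0 * 0.9, 1 - x0 * 0.9], df, [6.0, 6.0], hd)
        assert f[0] == 0.0 and f[1] == 1.0

    def test_high_flow_complement(self):
        hd, df = 0.4, 10.0
        x0 = 0.964 * (1 - hd) / df
        f = phase_separation_split(1.0, [1 - x0 / 2, x0 / 2], df, [6.0, 6.0], hd)
        assert f[0] == 1.0

    def test_monotone_and_complementary_sweep(self):
        hd, df = 0.3, 12.0
        xs = np.linspace(0.01, 0.99, 97)
        fs = np.array(
            [phase_separation_split(1.0, [x, 1 - x], df, [5.0, 5.0], hd)[0] for x in xs]
        )
        assert np.all(np.diff(fs) >= -1e-12)
        sym = np.array(
            [phase_separation_split(1.0, [1 - x, x], df, [5.0, 5.0], hd)[0] for x in xs]
        )
        assert np.allclose(fs + sym, 1.0, atol=1e-12)

    def test_fractions_always_valid(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            q = rng.uniform(0.05, 1.0, 2)
            f = phase_separation_split(
                1.0, q, rng.uniform(8, 20), rng.uniform(4, 10, 2), rng.uniform(0.1, 0.5)
            )
            assert np.all(f >= 0) and np.all(f <= 1)
            assert f.sum() == pytest.approx(1.0)

    def test_nonpositive_parent_flow_rejected(self):
        with pytest.raises(ValueError):
            phase_separation_split(0.0, [0.5, 0.5], 10.0, [5.0, 5.0], 0.3)


def straight_pipe_sim(n_rbc=0):
    net = make_network(
        [(0, 0, 0, 0, "pial_inflow"), (1, 1000, 0, 0, "pial_outflow")],
        [(0, 0, 1, 8.0, 1000.0, "C")],
    )
    bcs = [BoundaryCondition(0, 30.0, inflow_ht=0.0), BoundaryCondition(1, 10.0)]
    sim = DiscreteRBCSimulation(net, bcs, SimulationConfig(seed=0), dt=0.01)
    for i in range(n_rbc):
        slot = sim._new_slot()
        sim.alive[slot] = True
        sim.uid[slot] = sim.next_uid
        sim.next_uid += 1
        sim.edge[slot] = 0
        sim.pos[slot] = 100.0 + 10.0 * i
        sim.occupants[0].appendleft(slot)
        sim.n_injected += 1
    return sim


class TestAdvance:
    def test_kinematics_single_cell(self):
        sim = straight_pipe_sim(n_rbc=1)
        sim.update_hematocrit()
        sim.solve()
        p0 = sim.pos[0]
        sim.advance()
        expected = sim.v_rbc[0] * 1e3 * sim.dt
        assert sim.pos[0] - p0 == pytest.approx(expected)

    def test_fahraeus_speedup_at_least_bulk(self):
        sim = straight_pipe_sim(n_rbc=3)
        sim.update_hematocrit()
        sim.solve()
        assert abs(sim.v_rbc[0]) >= abs(sim.v_bulk[0])

    def test_hematocrit_direct_arithmetic(self):
        net = make_network(
            [(0, 0, 0, 0, "pial_inflow"), (1, 50, 0, 0, "pial_outflow")],
            [(0, 0, 1, 4.0, 50.0, "C")],
        )
        bcs = [BoundaryCondition(0, 30.0, 0.0), BoundaryCondition(1, 10.0)]
        sim = DiscreteRBCSimulation(net, bcs, SimulationConfig(seed=0), dt=0.001)
        for i in range(3):
            slot = sim._new_slot()
            sim.alive[slot] = True
            sim.uid[slot] = i
            sim.edge[slot] = 0
            sim.pos[slot] = 10.0 * (i + 1)
            sim.occupants[0].appendleft(slot)
        sim.update_hematocrit()
        expected = 3 * 49.0 / (np.pi * 2.0**2 * 50.0)
        assert sim.ht[0] == pytest.approx(expected)

    def test_spacing_enforced_after_step(self):
        sim = straight_pipe_sim(n_rbc=2)
        # squeeze the two cells 1 μm apart; effective length is larger
        sim.pos[0] = 101.0
        sim.pos[1] = 100.0
        sim.update_hematocrit()
        sim.solve()
        sim.advance()
        ell = sim.ell[0]
        gap = abs(sim.pos[0] - sim.pos[1])
        assert gap >= ell - 1e-9

    def test_no_rbcs_matches_plasma_solve_exactly(self):
        sim = straight_pipe_sim(n_rbc=0)
        sim.update_hematocrit()
        sim.solve()
        r_plasma = 128 * 1.2e-3 * 1000e-6 / (np.pi * (8e-6) ** 4)
        plasma = solve_pressure_flow(sim.network, [r_plasma], sim.bcs)
        assert sim.q[0] == plasma.flows_m3s[0]


class TestRunSimulation:
    def test_conservation_and_trajectories(self, y_network, y_bcs):
        cfg = SimulationConfig(seed=3, warmup_turnovers=2, recording_turnovers=20, drain_turnovers=5)
        res = run_simulation(y_network, y_bcs, cfg)
        assert res.conserved
        assert res.n_injected == res.n_exited + res.n_resident
        assert len(res.trajectories) > 10
        # no branching before the bifurcation: paths visit edge 0 first
        for t in res.trajectories:
            assert t.edges[0] == 0
            assert len(t.edges) == 2

    def test_single_path_network_unique_route(self, series_pipes):
        bcs = [BoundaryCondition(0, 40.0), BoundaryCondition(2, 10.0)]
        cfg = SimulationConfig(seed=1, warmup_turnovers=1, recording_turnovers=10, drain_turnovers=5)
        res = run_simulation(series_pipes, bcs, cfg)
        assert res.conserved
        for t in res.trajectories:
            assert list(t.edges) == [0, 1]

    def test_turnover_time_definition(self, single_pipe):
        from mvnflow.transport import turnover_time

        bcs = [BoundaryCondition(0, 100.0), BoundaryCondition(1, 0.0)]
        r = np.array([1e15])
        sol = solve_pressure_flow(single_pipe, r, bcs)
        volume = np.pi * (10e-6) ** 2 / 4 * 1000e-6 * 0.1  # d=10 μm, L=100 μm
        assert turnover_time(single_pipe, sol, bcs) == pytest.approx(
            volume / sol.flows_m3s[0]
        )

    def test_pressure_nonincreasing_along_paths(self, y_network, y_bcs):
        cfg = SimulationConfig(seed=5, warmup_turnovers=2, recording_turnovers=10, drain_turnovers=5)
        res = run_simulation(y_network, y_bcs, cfg)
        for t in res.trajectories:
            assert np.all(np.diff(t.entry_pressures) <= 1e-9)

    def test_symmetric_arteriolar_split_binomial(self, y_network, y_bcs):
        """Phase separation at a symmetric bifurcation: the exit split over
        >= 2000 cells lies within the 99% binomial interval."""
        cfg = SimulationConfig(
            seed=11, warmup_turnovers=2, recording_turnovers=900, drain_turnovers=10
        )
        res = run_simulation(y_network, y_bcs, cfg)
        exits = np.array([t.exit_node for t in res.trajectories])
        n = exits.size
        assert n >= 2000
        k = int((exits == 2).sum())
        half_width = 2.576 * np.sqrt(n * 0.25)
        assert abs(k - n / 2) <= half_width

    def test_deterministic_under_seed(self, y_network, y_bcs):
        cfg = SimulationConfig(seed=7, warmup_turnovers=1, recording_turnovers=5, drain_turnovers=5)
        r1 = run_simulation(y_network, y_bcs, cfg)
        r2 = run_simulation(y_network, y_bcs, cfg)
        assert r1.n_injected == r2.n_injected
        assert len(r1.trajectories) == len(r2.trajectories)
        for a, b in zip(r1.trajectories, r2.trajectories):
            assert np.array_equal(a.edges, b.edges)
            assert np.allclose(a.entry_times, b.entry_times)

    def test_timestep_criterion_coverage(self, y_network, y_bcs):
        r = 128 * 1.2e-3 * (y_network.vessels["length"].to_numpy() * 1e-6) / (
            np.pi * (y_network.vessels["diameter"].to_numpy() * 1e-6) ** 4
        )
        plasma = solve_pressure_flow(y_network, r, y_bcs)
        dt = select_timestep(y_network, plasma.velocities_mms, 0.998)
        transit = y_network.vessels["length"].to_numpy() * 1e-3 / np.abs(plasma.velocities_mms)
        assert (dt <= transit + 1e-15).mean() >= 0.998


def test_trajectory_ndjson_round_trip(tmp_path, y_network, y_bcs):
    cfg = SimulationConfig(seed=2, warmup_turnovers=1, recording_turnovers=5, drain_turnovers=5)
    res = run_simulation(y_network, y_bcs, cfg)
    path = tmp_path / "t.ndjson"
    save_trajectories_ndjson(res.trajectories, path)
    back = load_trajectories_ndjson(path)
    assert len(back) == len(res.trajectories)
    for a, b in zip(res.trajectories, back):
        assert np.array_equal(a.edges, b.edges)
        assert np.allclose(a.entry_pressures, b.entry_pressures)
        assert a.vessel_types == b.vessel_types
        assert a.s_tot == pytest.approx(b.s_tot)
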