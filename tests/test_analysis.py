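"""Trajectory classification, layers, preferences, curves and statistics."""

import numpy as np
import pandas as pd
import pytest

from mvnflow import analysis as ana
from mvnflow.transport import Trajectory
from tests.conftest import make_network


class TestClassifier:
    @pytest.mark.parametrize(
        "seq,full,cap",
        [
            (["PA", "DA", "C", "C", "AV", "PV"], True, True),
            (["PA", "DA", "C", "DA", "DA", "C", "AV", "PV"], True, True),  # 2 deviations
            (["PA", "DA", "C", "DA", "DA", "DA", "C", "AV", "PV"], False, False),  # 3
            (["DA", "C", "AV"], False, True),  # capillary-valid only
            (["PA", "DA", "A", "C", "V", "AV", "PV"], True, True),
            (["PA", "DA", "DA"], False, False),
            (["C", "C", "AV"], False, False),  # unknown arteriolar history
            ([], False, False),
        ],
    )
    def test_examples(self, seq, full, cap):
        cls = ana.classify_trajectory(seq)
        assert cls.full_valid is full
        assert cls.capillary_valid is cap

    def test_exit_classes(self):
        assert ana.classify_trajectory(["PA", "DA", "DA"]).exit_class == "arteriole_outlet"
        assert ana.classify_trajectory(["PA", "DA", "C", "C"]).exit_class == "capillary_outlet"
        assert ana.classify_trajectory(["PA", "DA", "C", "AV", "C", "C", "C"]).exit_class == "capillary_outlet"

    def test_deviation_budget_resets_per_excursion(self):
        seq = ["PA", "DA", "C", "DA", "DA", "C", "DA", "DA", "C", "AV", "PV"]
        assert ana.classify_trajectory(seq).full_valid


class TestLayers:
    def test_layer_assignment(self):
        layers = ana.AnalysisLayerConfig()
        assert layers.layer_of(150.0) == 1
        assert layers.layer_of(200.0) == 2  # half-open bins
        assert layers.layer_of(999.9) == 5
        assert layers.layer_of(1050.0) is None

    def test_thickness_must_divide(self):
        with pytest.raises(ValueError):
            ana.AnalysisLayerConfig(thickness=300.0, max_depth=1000.0)


class PathFactory:
    """Builds a toy network and synthetic trajectories along fresh chains."""

    def __init__(self):
        self.node_rows = []
        self.vessel_rows = []
        self.trajs = []
        self.nid = 0
        self.vid = 0
        self.uid = 0

    def node(self, z, x=None, boundary="interior"):
        i = self.nid
        self.node_rows.append((i, float(x if x is not None else i * 10), 0.0, float(z), boundary))
        self.nid += 1
        return i

    def chain(self, types, depths, pressures=None, times=None, lengths=None, diameters=None, xs=None):
        """One trajectory along a fresh chain of nodes/edges."""
        n = len(types)
        nodes = [
            self.node(depths[k], x=None if xs is None else xs[k]) for k in range(n + 1)
        ]
        edges = []
        lengths = lengths or [100.0] * n
        diameters = diameters or [6.0] * n
        for k in range(n):
            self.vessel_rows.append(
                (self.vid, nodes[k], nodes[k + 1], diameters[k], lengths[k], types[k])
            )
            edges.append(self.vid)
            self.vid += 1
        times = times if times is not None else [0.1 * k for k in range(n)]
        pressures = pressures if pressures is not None else list(np.linspace(60, 10, n))
        t = Trajectory(
            rbc_id=self.uid,
            edges=np.array(edges, dtype=np.int64),
            entry_nodes=np.array(nodes[:-1], dtype=np.int64),
            entry_times=np.array(times, float),
            entry_pressures=np.array(pressures, float),
            vessel_types=list(types),
            edge_lengths=np.array(lengths, float),
            exit_time=float(times[-1] + 0.1),
            exit_node=nodes[-1],
        )
        self.uid += 1
        self.trajs.append(t)
        return t

    def network(self):
        return make_network(self.node_rows, self.vessel_rows)


def shared_start_trajectories(counts):
    """Trajectories from one capillary start point to len(counts) end
    points, with the given multiplicities; returns (trajs, network)."""
    f = PathFactory()
    # shared arteriolar prefix nodes/edges
    n0 = f.node(0.0, boundary="pial_inflow")
    n1 = f.node(50.0)
    start = f.node(150.0)
    f.vessel_rows.append((f.vid, n0, n1, 12.0, 100.0, "PA")); e_pa = f.vid; f.vid += 1
    f.vessel_rows.append((f.vid, n1, start, 10.0, 100.0, "DA")); e_da = f.vid; f.vid += 1
    trajs = []
    for j, c in enumerate(counts):
        end = f.node(150.0 + 5 * j, x=100.0 + 40 * j)
        ven = f.node(100.0)
        out = f.node(0.0, boundary="pial_outflow")
        f.vessel_rows.append((f.vid, start, end, 5.0, 120.0 + 10 * j, "C")); e_c = f.vid; f.vid += 1
        f.vessel_rows.append((f.vid, end, ven, 8.0, 100.0, "AV")); e_av = f.vid; f.vid += 1
        f.vessel_rows.append((f.vid, ven, out, 12.0, 100.0, "PV")); e_pv = f.vid; f.vid += 1
        for _ in range(c):
            t = Trajectory(
                rbc_id=f.uid,
                edges=np.array([e_pa, e_da, e_c, e_av, e_pv], np.int64),
                entry_nodes=np.array([n0, n1, start, end, ven], np.int64),
                entry_times=np.arange(5) * 0.1,
                entry_pressures=np.array([60.0, 55.0, 40.0, 15.0, 11.0]),
                vessel_types=["PA", "DA", "C", "AV", "PV"],
                edge_lengths=np.array([100.0, 100.0, 120.0 + 10 * j, 100.0, 100.0]),
                exit_time=0.5,
                exit_node=out,
            )
            f.uid += 1
            trajs.append(t)
    return trajs, f.network()


class TestEndpointPreference:
    def test_frequencies_and_preferred_flag(self):
        trajs, net = shared_start_trajectories([12, 5, 3])
        stats = ana.endpoint_preference_and_correlation(trajs, net)
        f = np.sort(stats.pairs["f_ep"].to_numpy())[::-1]
        assert f == pytest.approx([0.6, 0.25, 0.15])
        assert stats.pairs.groupby("start")["f_ep"].sum().iloc[0] == pytest.approx(1.0)
        assert bool(stats.starts["preferred_end_point"].iloc[0])
        assert bool(stats.starts["preferred_path"].iloc[0])

    def test_runner_up_blocks_preference(self):
        trajs, net = shared_start_trajectories([11, 7, 2])  # 0.55 / 0.35 / 0.10
        stats = ana.endpoint_preference_and_correlation(trajs, net)
        assert not bool(stats.starts["preferred_end_point"].iloc[0])

    def test_correlations_bounded(self):
        trajs, net = shared_start_trajectories([8, 6, 4, 2])
        stats = ana.endpoint_preference_and_correlation(trajs, net)
        assert set(stats.correlations) == {
            "euclidean",
            "path_length",
            "resistance",
            "flow",
            "v_rbc",
        }
        for v in stats.correlations.values():
            assert np.isnan(v) or -1.0 <= v <= 1.0


def test_normalize_by_max_example():
    assert ana.normalize_by_max(np.array([2.0, 4.0, 8.0])) == pytest.approx([0.25, 0.5, 1.0])


class TestAveragedCurves:
    def full_ramp(self, f, p_in, p_out, depth=100.0):
        return f.chain(
            ["PA", "DA", "C", "AV", "PV"],
            [0.0, 20.0, depth, depth, 50.0, 0.0],
            pressures=list(np.linspace(p_in, p_out, 5)),
        )

    def test_identical_trajectories_average_to_themselves(self):
        f = PathFactory()
        self.full_ramp(f, 80.0, 10.0)
        self.full_ramp(f, 80.0, 10.0)
        net = f.network()
        out = ana.averaged_curves(f.trajs, net, "pressure")
        al = list(out)[0]
        single = np.interp(out[al]["s_norm"], f.trajs[0].s / f.trajs[0].s_tot, f.trajs[0].entry_pressures)
        assert np.allclose(out[al]["mean_curve"], single)
        assert out[al]["n"] == 2

    def test_endpoint_values(self):
        f = PathFactory()
        self.full_ramp(f, 90.0, 12.0)
        net = f.network()
        out = ana.averaged_curves(f.trajs, net, "pressure")
        al = list(out)[0]
        assert out[al]["mean_curve"][0] == pytest.approx(90.0)
        assert out[al]["mean_curve"][-1] == pytest.approx(12.0)

    def test_linear_ramps_average_analytically(self):
        f = PathFactory()
        ramps = [(100.0, 20.0), (80.0, 10.0), (60.0, 30.0)]
        for p_in, p_out in ramps:
            self.full_ramp(f, p_in, p_out)
        net = f.network()
        out = ana.averaged_curves(f.trajs, net, "pressure")
        al = list(out)[0]
        s = out[al]["s_norm"]
        # equal edge lengths: entry pressures are linear in s, so each
        # curve is the analytic ramp between its endpoints over s in [0, 0.8]
        expected = np.mean(
            [np.interp(s, np.linspace(0, 0.8, 5), np.linspace(a, b, 5)) for a, b in ramps],
            axis=0,
        )
        assert np.allclose(out[al]["mean_curve"], expected)

    def test_diameter_curves_step_constant(self):
        f = PathFactory()
        f.chain(
            ["PA", "DA", "C", "AV", "PV"],
            [0.0, 20.0, 100.0, 100.0, 50.0, 0.0],
            diameters=[12.0, 10.0, 4.0, 8.0, 14.0],
        )
        net = f.network()
        out = ana.averaged_curves(f.trajs, net, "diameter")
        al = list(out)[0]
        curve = out[al]["mean_curve"]
        assert curve[0] == 12.0
        assert curve[-1] == 14.0
        assert set(np.unique(curve)) <= {12.0, 10.0, 4.0, 8.0, 14.0}


class TestPressureDrop:
    def make_single(self):
        f = PathFactory()
        f.chain(
            ["PA", "DA", "DA", "C", "C", "AV", "PV"],
            [0.0, 20.0, 60.0, 100.0, 110.0, 100.0, 50.0, 0.0],
            pressures=[80.0, 60.0, 45.0, 30.0, 20.0, 15.0, 10.0],
        )
        return f

    def test_drop_fractions_single_trajectory(self):
        # inlet pressures 80/60/30/15/10 at the PA/DA+A/C/V+AV/PV
        # transitions: drops 20/30/15/5 over a 70 mmHg total
        f = self.make_single()
        out = ana.pressure_drop_by_type(f.trajs, f.network())
        out = out.set_index("group")
        total = 70.0
        assert out.loc["PA", "drop_fraction"] == pytest.approx(20 / total)
        assert out.loc["DA+A", "drop_fraction"] == pytest.approx(30 / total)
        assert out.loc["C", "drop_fraction"] == pytest.approx(15 / total)
        assert out.loc["V+AV", "drop_fraction"] == pytest.approx(5 / total)
        assert np.isnan(out.loc["PV", "drop_fraction"])

    def test_variant_shifts_capillary_boundary(self):
        f = self.make_single()
        net = f.network()
        std = ana.pressure_drop_by_type(f.trajs, net, labeling_variant="standard").set_index("group")
        var = ana.pressure_drop_by_type(f.trajs, net, labeling_variant="first_C_as_DA+A").set_index("group")
        # the first capillary edge joins DA+A: C's inlet moves downstream
        assert var.loc["C", "inlet_pressure_mean"] < std.loc["C", "inlet_pressure_mean"]
        assert var.loc["C", "drop_fraction"] < std.loc["C", "drop_fraction"]
        var2 = ana.pressure_drop_by_type(f.trajs, net, labeling_variant="last_DA+A_as_C").set_index("group")
        assert var2.loc["C", "inlet_pressure_mean"] > std.loc["C", "inlet_pressure_mean"]

    def test_ensemble_matches_brute_force_average(self):
        rng = np.random.default_rng(0)
        f = PathFactory()
        inlet_lists = {g: [] for g in ana.STAGE_GROUPS}
        for _ in range(100):
            p = np.sort(rng.uniform(10, 90, 5))[::-1]
            f.chain(
                ["PA", "DA", "C", "AV", "PV"],
                [0.0, 20.0, 100.0, 100.0, 50.0, 0.0],
                pressures=list(p),
            )
            for g, val in zip(["PA", "DA+A", "C", "V+AV", "PV"], p):
                inlet_lists[g].append(val)
        out = ana.pressure_drop_by_type(f.trajs, f.network()).set_index("group")
        for g in ana.STAGE_GROUPS:
            assert out.loc[g, "inlet_pressure_mean"] == pytest.approx(np.mean(inlet_lists[g]))

    def test_pressure_monotone_at_type_inlets(self):
        f = self.make_single()
        out = ana.pressure_drop_by_type(f.trajs, f.network()).sort_values("stage")
        p = out["inlet_pressure_mean"].to_numpy()
        assert np.all(np.diff(p) <= 0)


class TestTransitFeeding:
    def test_transit_arithmetic(self):
        f = PathFactory()
        f.chain(
            ["DA", "C", "C", "AV"],
            [0.0, 100.0, 110.0, 120.0, 50.0],
            times=[0.5, 1.0, 1.2, 1.5],
            lengths=[100.0, 150.0, 150.0, 100.0],
        )
        net = f.network()
        summary = ana.transit_and_feeding_stats(f.trajs, net)
        row = summary.table.iloc[0]
        assert row["tt_mean_s"] == pytest.approx(0.5)
        assert row["ts_mean_mm"] == pytest.approx(0.3)
        assert row["v_rbc_mean_mms"] == pytest.approx(0.6)

    def test_primary_feeder_fraction(self):
        f = PathFactory()
        for origin_idx, c in zip(range(3), (7, 2, 1)):
            for _ in range(c):
                f.chain(["DA", "C", "AV"], [0.0, 100.0, 100.0, 50.0])
        net = f.network()
        # rewrite exit nodes so all trajectories drain to one venule and
        # origins group into three feeders
        for i, t in enumerate(f.trajs):
            t.exit_node = 99999
            t.entry_nodes[0] = [1, 2, 3][0 if i < 7 else (1 if i < 9 else 2)]
        summary = ana.transit_and_feeding_stats(f.trajs, net)
        row = summary.primary_feeding.loc[99999]
        assert row["primary_origin"] == 1
        assert row["primary_fraction"] == pytest.approx(0.7)
        assert row["n_feeders"] == 3

    def test_inplane_regression_recovery(self):
        rng = np.random.default_rng(1)
        f = PathFactory()
        for _ in range(200):
            start = rng.uniform(50, 950)
            end = start + rng.normal(0, 5)
            f.chain(["DA", "C", "AV"], [0.0, start, max(end, 1.0), 40.0])
        net = f.network()
        summary = ana.transit_and_feeding_stats(f.trajs, net)
        fit = summary.inplane_fit
        assert fit["slope"] == pytest.approx(1.0, abs=0.02)
        assert abs(fit["intercept_mm"]) < 0.02
        assert fit["pearson_r"] > 0.99

    def test_unique_paths_match_enumeration(self):
        """Diamond capillary bed: two simple routes; trajectories covering
        both give a unique-path count equal to brute-force enumeration."""
        f = PathFactory()
        n0 = f.node(0.0, boundary="pial_inflow")
        start = f.node(100.0)
        a = f.node(110.0)
        b = f.node(120.0)
        end = f.node(100.0)
        out = f.node(0.0, boundary="pial_outflow")
        rows = f.vessel_rows
        e = {}
        for name, (u, v, t) in {
            "da": (n0, start, "DA"),
            "ca": (start, a, "C"),
            "cb": (start, b, "C"),
            "ae": (a, end, "C"),
            "be": (b, end, "C"),
            "av": (end, out, "AV"),
        }.items():
            rows.append((f.vid, u, v, 5.0, 100.0, t))
            e[name] = f.vid
            f.vid += 1
        net = f.network()

        def traj(route, nodes):
            return Trajectory(
                rbc_id=len(f.trajs),
                edges=np.array(route, np.int64),
                entry_nodes=np.array(nodes, np.int64),
                entry_times=np.arange(len(route)) * 0.1,
                entry_pressures=np.linspace(50, 10, len(route)),
                vessel_types=["DA", "C", "C", "AV"],
                edge_lengths=np.full(len(route), 100.0),
                exit_time=0.1 * len(route),
                exit_node=out,
            )

        trajs = [
            traj([e["da"], e["ca"], e["ae"], e["av"]], [n0, start, a, end]),
            traj([e["da"], e["cb"], e["be"], e["av"]], [n0, start, b, end]),
            traj([e["da"], e["ca"], e["ae"], e["av"]], [n0, start, a, end]),
        ]
        summary = ana.transit_and_feeding_stats(trajs, net)
        assert int(summary.table["unique_paths"].iloc[0]) == 2
        n_brute = ana.count_unique_graph_paths(
            net.subgraph_capillaries() if hasattr(net, "subgraph_capillaries") else net,
            [start],
            [end],
        )
        # enumeration on the full graph counts start->end simple paths
        assert n_brute == 2


def test_plotting_helpers_render(tmp_path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from mvnflow import plotting

    f = PathFactory()
    for p_in in (90.0, 80.0):
        f.chain(
            ["PA", "DA", "C", "AV", "PV"],
            [0.0, 20.0, 100.0, 100.0, 50.0, 0.0],
            pressures=list(np.linspace(p_in, 10.0, 5)),
        )
    net = f.network()
    curves = ana.averaged_curves(f.trajs, net, "pressure")
    plotting.plot_averaged_curves(curves)
    summary = ana.transit_and_feeding_stats(f.trajs, net)
    plotting.plot_transit_statistics(summary.table)
    drop = ana.pressure_drop_by_type(f.trajs, net)
    al = int(drop["layer"].iloc[0])
    plotting.plot_pressure_drop_by_type(drop, al)
    plt.close("all")
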