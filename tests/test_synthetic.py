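"""Generator invariants: topology, conservation, phase separation, and
field rendering."""

import numpy as np
import pytest

from hemonet import synthetic as sv
from hemonet.errors import TopologyError

EXPECTED_DEGREES = {"inlet": (0, 1), "outlet": (1, 0),
                    "bifurcation": (1, 2), "merger": (2, 1)}


class TestGenerateNetwork:
    def test_smallest_topology(self, tiny_network):
        kinds = [n.kind for n in tiny_network.nodes]
        assert kinds.count("inlet") == 1
        assert kinds.count("bifurcation") == 1
        assert kinds.count("merger") == 1
        assert kinds.count("outlet") == 1
        assert len(tiny_network.vessels) == 4
        tiny_network.validate()

    def test_seed_determinism(self):
        a = sv.generate_network(3, seed=9)
        b = sv.generate_network(3, seed=9)
        assert a.to_dict() == b.to_dict()

    def test_degree_table_all_nodes(self, small_network):
        # brute-force degree audit over every node
        for node in small_network.nodes:
            got = (len(small_network.in_vessels(node.id)),
                   len(small_network.out_vessels(node.id)))
            assert got == EXPECTED_DEGREES[node.kind], node.id

    @pytest.mark.parametrize("g", [1, 2, 4])
    def test_component_counts_scale(self, g):
        net = sv.generate_network(g, seed=3)
        kinds = [n.kind for n in net.nodes]
        assert kinds.count("bifurcation") == 2 ** g - 1
        assert kinds.count("merger") == 2 ** g - 1
        assert len(net.vessels) == 3 * 2 ** g - 2

    def test_diameters_taper(self, small_network):
        for node in small_network.nodes:
            if node.kind != "bifurcation":
                continue
            dm = small_network.in_vessels(node.id)[0].d_um
            for d in small_network.out_vessels(node.id):
                assert 0.7 * dm <= d.d_um <= 0.9 * dm

    def test_invalid_generations(self):
        with pytest.raises(ValueError):
            sv.generate_network(0, seed=1)


class TestSolveFlow:
    def test_single_vessel_passthrough(self):
        nodes = [sv.Node("a", "inlet", 0, 0), sv.Node("b", "outlet", 100, 0)]
        vessels = [sv.Vessel("v", "a", "b", 10.0, 100.0, 0.0)]
        net = sv.NetworkSpec(nodes, vessels)
        flow = sv.solve_flow(net, inlet_flows=5000.0, inlet_hematocrit=0.3)
        assert flow.q["v"] == pytest.approx(5000.0, rel=1e-12)
        assert flow.h["v"] == 0.3

    def test_symmetric_bifurcation_splits_evenly(self):
        nodes = [sv.Node("i", "inlet", 0, 0),
                 sv.Node("b", "bifurcation", 100, 0),
                 sv.Node("o1", "outlet", 200, 50),
                 sv.Node("o2", "outlet", 200, -50)]
        vessels = [sv.Vessel("vm", "i", "b", 20.0, 150.0, 0.0),
                   sv.Vessel("v1", "b", "o1", 15.0, 120.0, 30.0),
                   sv.Vessel("v2", "b", "o2", 15.0, 120.0, -30.0)]
        net = sv.NetworkSpec(nodes, vessels)
        flow = sv.solve_flow(net, inlet_flows=8000.0)
        assert flow.q["v1"] == pytest.approx(flow.q["v2"], rel=1e-12)
        assert flow.h["v1"] == pytest.approx(flow.h["v2"], rel=1e-12)
        assert flow.h["v1"] == pytest.approx(flow.h["vm"], rel=1e-12)

    def test_conservation_audit(self, small_network, small_flow):
        # brute-force audit over all junctions
        net, flow = small_network, small_flow
        for node in net.nodes:
            if node.kind not in ("bifurcation", "merger"):
                continue
            q_in = sum(flow.q[v.id] for v in net.in_vessels(node.id))
            q_out = sum(flow.q[v.id] for v in net.out_vessels(node.id))
            assert abs(q_in - q_out) / q_in < 1e-10
            f_in = sum(flow.q[v.id] * flow.h[v.id]
                       for v in net.in_vessels(node.id))
            f_out = sum(flow.q[v.id] * flow.h[v.id]
                        for v in net.out_vessels(node.id))
            assert abs(f_in - f_out) / f_in < 1e-8

    def test_daughter_skew_signs(self, small_network, small_flow):
        # hematocrit skews toward the apex, velocity away from it
        for node in small_network.nodes:
            if node.kind != "bifurcation":
                continue
            (left, right), apex = sv.bifurcation_daughters(small_network,
                                                           node.id)
            for v in (left, right):
                sh = small_flow.shapes[v.id]
                sign = +1.0 if apex[v.id] == "left" else -1.0
                assert sh.lam_h0 * sign > 0
                assert sh.lam_u0 * sh.lam_h0 < 0

    def test_skew_relaxes_along_vessel(self, small_flow, small_network):
        vid = next(v.id for v in small_network.vessels
                   if small_flow.shapes[v.id].lam_h0 != 0.0)
        v = small_network.vessel(vid)
        sh = small_flow.shapes[vid]
        lam_u_start, lam_h_start = sh.lam_at(0.0, v.d_um, 10.0)
        lam_u_end, lam_h_end = sh.lam_at(v.l_um, v.d_um, 10.0)
        assert abs(lam_h_end) < abs(lam_h_start)
        assert lam_h_end == pytest.approx(
            lam_h_start * np.exp(-v.l_um / (10.0 * v.d_um)))
        assert abs(lam_u_end) < abs(lam_u_start)

    def test_unreachable_node_rejected(self):
        nodes = [sv.Node("a", "inlet", 0, 0), sv.Node("b", "outlet", 1, 0),
                 sv.Node("c", "inlet", 5, 5), sv.Node("d", "outlet", 6, 5)]
        vessels = [sv.Vessel("v1", "a", "b", 10, 100, 0),
                   sv.Vessel("v2", "c", "d", 10, 100, 0)]
        net = sv.NetworkSpec(nodes, vessels)
        with pytest.raises(TopologyError):
            sv.solve_flow(net, inlet_flows={"a": 1000.0})


class TestPhaseSeparation:
    def test_symmetric_split(self):
        h1, h2 = sv.phase_separation_split(0.3, 0.5, 10, 10, 14)
        assert h1 == pytest.approx(0.3, abs=1e-14)
        assert h2 == pytest.approx(0.3, abs=1e-14)

    def test_full_diversion_limit(self):
        h1, h2 = sv.phase_separation_split(0.3, 1.0, 10, 10, 14)
        assert h2 == 0.0
        assert h1 == pytest.approx(0.3)

    def test_flux_conservation_identity(self):
        h_m, q1 = 0.3, 0.7
        h1, h2 = sv.phase_separation_split(h_m, q1, 9.0, 11.0, 14.0)
        assert q1 * h1 + (1 - q1) * h2 == pytest.approx(h_m, abs=1e-12)

    @pytest.mark.parametrize("q1", [0.0, 0.03, 0.2, 0.5, 0.8, 0.97, 1.0])
    def test_conservation_across_split_range(self, q1):
        h1, h2 = sv.phase_separation_split(0.45, q1, 8.0, 12.0, 15.0)
        assert h1 >= 0 and h2 >= 0
        assert q1 * h1 + (1 - q1) * h2 == pytest.approx(0.45, abs=1e-12)

    def test_low_flow_daughter_starved(self):
        h1, h2 = sv.phase_separation_split(0.3, 0.03, 10, 10, 14)
        assert h1 == 0.0            # below the q_low cutoff: no RBC flux

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            sv.phase_separation_split(0.3, 1.5, 10, 10, 14)
        with pytest.raises(ValueError):
            sv.phase_separation_split(1.0, 0.5, 10, 10, 14)


class TestRenderFields:
    def test_no_skew_is_symmetric(self, small_flow, small_network):
        vid = small_network.out_vessels(small_network.inlets[0].id)[0].id
        gt = sv.render_fields(small_flow, vid, 0.0, ng=32, noise_sd=0.0)
        # inlet vessels have lam = 0: field symmetric under theta -> theta+pi
        g = gt.u.grid
        assert np.max(np.abs(g - g[::-1, ::-1])) < 1e-12 * gt.u_max

    def test_no_slip_outside_and_boundary(self, small_flow, small_network):
        vid = small_network.vessels[5].id
        v = small_network.vessel(vid)
        gt = sv.render_fields(small_flow, vid, v.l_um, ng=32, noise_sd=0.0)
        assert np.all(gt.u.grid[~gt.u.mask] == 0.0)
        # boundary cells (outermost in-mask ring) carry near-zero velocity
        c = (np.arange(32) + 0.5) / 32 * 2 - 1
        xx, yy = np.meshgrid(c, c)
        ring = gt.u.mask & (np.hypot(xx, yy) > 1 - 1.0 / 32)
        assert np.all(gt.u.grid[ring] < 0.2 * gt.u_max)

    def test_velocity_integrates_to_flow_rate(self, small_flow,
                                              small_network):
        # quadrature oracle on a fine grid
        vid = small_network.vessels[7].id
        gt = sv.render_fields(small_flow, vid, 0.0, ng=256, noise_sd=0.0)
        r = gt.d_um / 2.0
        cell_area = (2.0 * r / 256) ** 2            # um^2
        q_quad = gt.u.grid.sum() * 1e3 * cell_area  # um^3/s
        assert q_quad == pytest.approx(gt.q, rel=0.01)

    def test_hematocrit_in_range_and_flux_consistent(self, small_flow,
                                                     small_network):
        vid = small_network.out_vessels(small_network.inlets[0].id)[0].id
        gt = sv.render_fields(small_flow, vid, 0.0, ng=64, noise_sd=0.0)
        assert gt.h.grid.min() >= 0.0 and gt.h.grid.max() <= 1.0
        # flux-weighted (discharge) hematocrit matches the inflow value 30%
        m = gt.h.mask
        h_d = (gt.u.grid[m] * gt.h.grid[m]).sum() / gt.u.grid[m].sum()
        assert 0.25 <= h_d <= 0.35

    def test_mean_hematocrit_decreases_with_delta(self, small_flow,
                                                  small_network):
        vid = small_network.vessels[4].id
        shape = small_flow.shapes[vid]
        means = []
        for frac in (0.05, 0.15, 0.30):
            old = shape.delta_um
            shape.delta_um = frac * small_network.vessel(vid).d_um / 2
            gt = sv.render_fields(small_flow, vid, 0.0, ng=64, noise_sd=0.0)
            means.append(gt.h.grid[gt.h.mask].mean())
            shape.delta_um = old
        assert means[0] > means[1] > means[2]

    def test_seed_determinism(self, small_flow, small_network):
        vid = small_network.vessels[3].id
        a = sv.render_fields(small_flow, vid, 0.0, seed=9)
        b = sv.render_fields(small_flow, vid, 0.0, seed=9)
        assert np.array_equal(a.u.grid, b.u.grid)
        assert np.array_equal(a.h.grid, b.h.grid)

    def test_invalid_station_and_delta(self, small_flow, small_network):
        vid = small_network.vessels[3].id
        with pytest.raises(ValueError):
            sv.render_fields(small_flow, vid, -1.0)
        shape = small_flow.shapes[vid]
        old = shape.delta_um
        shape.delta_um = small_network.vessel(vid).d_um   # delta >= R
        try:
            with pytest.raises(ValueError):
                sv.render_fields(small_flow, vid, 0.0)
        finally:
            shape.delta_um = old

    def test_network_spec_json_roundtrip(self, small_network, tmp_path):
        from hemonet import io as hio
        path = tmp_path / "net.json"
        hio.save_network(small_network, path)
        again = hio.load_network(path)
        assert again.to_dict() == small_network.to_dict()
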