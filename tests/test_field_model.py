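"""Lumped chip model: segment resistances and network solutions."""

import itertools
import math

import numpy as np
import pytest

from etaxis.errors import InvalidSegmentError, SingularNetworkError
from etaxis.field_model import (
    MEDIUM_CONDUCTIVITY,
    ChannelNetwork,
    ChannelSegment,
    electrical_resistance,
    hydraulic_resistance,
    make_r2r_ladder,
    scale_to_max,
    section_efs,
    solve_network,
)


def mesh_currents_oracle(edges, source, ground, current):
    """Independent check: solve the same network by sparse-tableau
    least squares on KCL + KVL equations (no shared code with the
    nodal solver)."""
    nodes = sorted({n for a, b, _ in edges for n in (a, b)} | set(source))
    nidx = {n: i for i, n in enumerate(nodes)}
    ne = len(edges)
    # unknowns: edge currents then node potentials
    rows, rhs = [], []
    for n in nodes:  # KCL with source injection
        row = np.zeros(ne + len(nodes))
        for k, (a, b, _) in enumerate(edges):
            if a == n:
                row[k] -= 1
            if b == n:
                row[k] += 1
        r = 0.0
        if n == source[0]:
            r = -current
        if n == source[1]:
            r = current
        rows.append(row)
        rhs.append(r)
    for k, (a, b, res) in enumerate(edges):  # Ohm per edge
        row = np.zeros(ne + len(nodes))
        row[k] = res
        row[ne + nidx[a]] = -1
        row[ne + nidx[b]] = 1
        rows.append(row)
        rhs.append(0.0)
    row = np.zeros(ne + len(nodes))  # gauge: ground potential 0
    row[ne + nidx[ground]] = 1
    rows.append(row)
    rhs.append(0.0)
    sol, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
    return sol[:ne]


class TestSegments:
    def test_electrical_resistance_hand_value(self):
        seg = ChannelSegment(length=1e-3, width=1e-3, height=100e-6,
                             conductivity=1.536)
        assert electrical_resistance(seg) == pytest.approx(6510, rel=1e-3)

    def test_resistance_linear_in_length(self):
        a = ChannelSegment(1e-3, 1e-3, 1e-4)
        b = ChannelSegment(2e-3, 1e-3, 1e-4)
        assert electrical_resistance(b) == pytest.approx(
            2 * electrical_resistance(a))

    def test_default_conductivity_is_culture_medium(self):
        assert ChannelSegment(1, 1e-3, 1e-4).conductivity == 1.536

    def test_interconnect_vs_main_hydraulic_ratio(self):
        """Thin 10 μm × 0.84 mm interconnects resist flow >1000× more than
        100 μm × 2 mm mains (per unit length) — the chip's transport
        isolation argument."""
        inter = ChannelSegment(1e-3, width=0.84e-3, height=10e-6)
        main = ChannelSegment(1e-3, width=2e-3, height=100e-6)
        assert hydraulic_resistance(inter) / hydraulic_resistance(main) > 1000

    def test_square_duct_limit_finite(self):
        seg = ChannelSegment(1e-3, width=1e-4, height=1e-4)
        assert 0 < hydraulic_resistance(seg) < math.inf

    def test_hydraulic_linear_in_viscosity(self):
        a = ChannelSegment(1e-3, 1e-3, 1e-4, viscosity=1e-3)
        b = ChannelSegment(1e-3, 1e-3, 1e-4, viscosity=2e-3)
        assert hydraulic_resistance(b) == pytest.approx(
            2 * hydraulic_resistance(a))

    def test_height_above_width_rejected(self):
        with pytest.raises(InvalidSegmentError, match="swap"):
            hydraulic_resistance(ChannelSegment(1e-3, width=1e-5, height=1e-4))

    @pytest.mark.parametrize("bad", [
        dict(length=0, width=1, height=1),
        dict(length=1, width=-1, height=1),
        dict(length=1, width=1, height=1, conductivity=0),
    ])
    def test_invalid_segment_rejected(self, bad):
        with pytest.raises(InvalidSegmentError):
            ChannelSegment(**bad)


class TestSolveNetwork:
    def test_single_resistor_ohms_law(self):
        net = ChannelNetwork(edges=(("a", "b", 100.0),), source=("a", "b"),
                             ground="b", current=0.5)
        sol = solve_network(net)
        assert sol.potentials["a"] == pytest.approx(50.0)
        assert sol.edge_currents[0] == pytest.approx(0.5)

    def test_parallel_resistors_split_equally(self):
        net = ChannelNetwork(
            edges=(("a", "b", 100.0), ("a", "b", 100.0)),
            source=("a", "b"), ground="b", current=1.0)
        sol = solve_network(net)
        assert sol.edge_currents == pytest.approx((0.5, 0.5))

    def test_divider_matches_mesh_oracle(self):
        """R–2R divider with midpoint shunt, vs the sparse-tableau oracle."""
        edges = (("a", "m", 100.0), ("m", "b", 200.0), ("m", "b", 200.0))
        net = ChannelNetwork(edges=edges, source=("a", "b"), ground="b",
                             current=1.0)
        sol = solve_network(net)
        oracle = mesh_currents_oracle(edges, ("a", "b"), "b", 1.0)
        np.testing.assert_allclose(sol.edge_currents, oracle, atol=1e-9)

    def test_voltage_source(self):
        net = ChannelNetwork(edges=(("a", "b", 50.0),), source=("a", "b"),
                             ground="b", voltage=10.0)
        sol = solve_network(net)
        assert sol.potentials["a"] == pytest.approx(10.0)
        assert sol.source_current == pytest.approx(0.2)

    def test_disconnected_source_raises(self):
        net = ChannelNetwork(edges=(("a", "b", 1.0), ("c", "d", 1.0)),
                             source=("a", "d"), ground="d", current=1.0)
        with pytest.raises(SingularNetworkError):
            solve_network(net)

    def test_reciprocity(self):
        """Swapping source and ground negates every edge current."""
        edges = (("a", "m", 10.0), ("m", "b", 20.0), ("a", "b", 15.0),
                 ("m", "b", 30.0))
        fwd = solve_network(ChannelNetwork(edges=edges, source=("a", "b"),
                                           ground="b", current=1.0))
        rev = solve_network(ChannelNetwork(edges=edges, source=("b", "a"),
                                           ground="a", current=1.0))
        np.testing.assert_allclose(rev.edge_currents,
                                   [-i for i in fwd.edge_currents], atol=1e-12)

    def test_random_networks_satisfy_kcl(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            n = rng.integers(3, 9)
            nodes = [f"n{i}" for i in range(n)]
            edges = [(nodes[i], nodes[i + 1],
                      float(rng.uniform(1, 1e4))) for i in range(n - 1)]
            extra = rng.integers(0, 6)
            for _ in range(extra):
                i, j = rng.choice(n, 2, replace=False)
                edges.append((nodes[i], nodes[j], float(rng.uniform(1, 1e4))))
            net = ChannelNetwork(edges=tuple(edges),
                                 source=(nodes[0], nodes[-1]),
                                 ground=nodes[-1],
                                 current=float(rng.uniform(1e-6, 1.0)))
            assert solve_network(net).kcl_residual < 1e-9

    def test_ratio_invariant_over_source_decades(self):
        edges = (("a", "m", 100.0), ("m", "b", 200.0), ("m", "b", 300.0))
        ratios = []
        for cur in (1e-3, 1e-1, 1e1):
            sol = solve_network(ChannelNetwork(
                edges=edges, source=("a", "b"), ground="b", current=cur))
            cs = np.abs(sol.edge_currents)
            ratios.append(cs / cs.max())
        np.testing.assert_allclose(ratios[0], ratios[1], rtol=1e-9)
        np.testing.assert_allclose(ratios[0], ratios[2], rtol=1e-9)

    def test_r2r_ladder_rung_currents_halve(self):
        net = make_r2r_ladder(n_rungs=5, r_unit=1000.0)
        sol = solve_network(net)
        rung = [i for (a, b, r), i in zip(net.edges, sol.edge_currents)
                if b == "gnd" and r == 2000.0][:5]
        for i0, i1 in zip(rung, rung[1:]):
            assert i1 / i0 == pytest.approx(0.5, rel=1e-9)


class TestSectionFields:
    def test_efs_from_current_and_geometry(self):
        seg = ChannelSegment(1e-3, width=2e-3, height=100e-6)
        (sf,) = section_efs({"I": 1e-4}, {"I": seg})
        expected = 1e-4 / (MEDIUM_CONDUCTIVITY * 2e-3 * 100e-6)
        assert sf.efs == pytest.approx(expected)

    def test_uniform_series_channel_equal_efs(self):
        seg = ChannelSegment(1e-3, width=2e-3, height=100e-6)
        fields = section_efs({s: 2e-4 for s in "ABCD"}, {s: seg for s in "ABCD"})
        vals = [f.efs for f in fields]
        assert vals == pytest.approx([vals[0]] * 4)

    def test_design_ratio_scaled_to_300(self):
        efs = scale_to_max([5.25, 2.5, 1.0, 0.0], 300.0)
        assert efs[0] == pytest.approx(300.0)
        assert efs[1] == pytest.approx(142.857, abs=0.1)
        assert efs[2] == pytest.approx(57.143, abs=0.1)
        assert efs[3] == 0.0

    def test_scale_to_zero(self):
        assert scale_to_max([5.25, 2.5, 1, 0], 0.0) == pytest.approx([0, 0, 0, 0])

    def test_scaling_preserves_ratio_exactly(self):
        r = np.array([5.25, 2.5, 1.0, 0.0])
        efs = scale_to_max(r, 123.4)
        np.testing.assert_allclose(efs / efs.max(), r / r.max(), rtol=1e-12)
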