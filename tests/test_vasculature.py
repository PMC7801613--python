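"""Vessel network: fixtures, probability laws, sprouting, extension,
regression and length accounting."""

import numpy as np
import pytest

from angiosim.errors import ConfigError
from angiosim.fields import Grid
from angiosim.vasculature import (
    SproutParams,
    VesselNetwork,
    VesselNode,
    branching_probability,
    extension_cycle,
    generate_initial_vasculature,
    instability_condition,
    regression_probability,
    total_new_length,
)


@pytest.fixture
def params():
    return SproutParams()


@pytest.fixture
def grid():
    return Grid(16, 16.0, 1 / 33)


def build_sprout(shape=(16, 16, 16), chain=((5, 5, 5), (5, 5, 6), (5, 5, 7)),
                 anchor=(5, 5, 4), now=0.0):
    """Anchor (existing) -> chain of new nodes, last one the TEC."""
    net = VesselNetwork(shape)
    net.add_node(VesselNode(anchor, kind="existing"))
    sid = net._next_sprout_id
    net._next_sprout_id += 1
    net.sprout_birth[sid] = now
    net.sprout_anchor[sid] = anchor
    prev = anchor
    for i, pos in enumerate(chain):
        net.add_node(VesselNode(pos, kind="new", is_tec=(i == len(chain) - 1),
                                sprout_id=sid, parent=prev))
        prev = pos
    return net, sid


class TestInitialVasculature:
    def test_default_two_lines(self, grid, rng):
        net = generate_initial_vasculature(None, grid, rng)
        assert len(net.nodes) == 2 * grid.points_per_axis
        assert all(n.kind == "existing" for n in net.nodes.values())
        assert net.n_new() == 0

    def test_empty_spec(self, grid, rng):
        net = generate_initial_vasculature({"kind": "empty"}, grid, rng)
        assert len(net.nodes) == 0

    def test_deterministic_given_seed(self, grid):
        a = generate_initial_vasculature(None, grid, np.random.default_rng(3))
        b = generate_initial_vasculature(None, grid, np.random.default_rng(3))
        assert sorted(a.nodes) == sorted(b.nodes)

    def test_collision_with_tumour_seed_rejected(self, grid, rng):
        n = grid.points_per_axis
        seed = (max(2, n // 8), 4, n // 2)   # on the first vessel line
        with pytest.raises(ConfigError):
            generate_initial_vasculature(None, grid, rng, tumour_seeds=[seed])

    def test_explicit_nodes_outside_grid_rejected(self, grid, rng):
        with pytest.raises(ConfigError):
            generate_initial_vasculature(
                {"kind": "nodes", "positions": [(99, 0, 0)]}, grid, rng)


class TestProbabilityLaws:
    def test_branching_spot_values(self):
        p = SproutParams(k_BH_0=0.2, alpha_BH=10.0, f=1.0)
        # c = 1: exponent vanishes -> prefactor only
        assert branching_probability(1.0, 50.0, p, 100.0) == pytest.approx(0.1)
        # l = 0 kills the prefactor
        assert branching_probability(1.0, 0.0, p, 100.0) == 0.0
        # l = l_max, c = 1 -> bare scale
        assert branching_probability(1.0, 100.0, p, 100.0) == pytest.approx(0.2)

    def test_branching_zero_below_floor(self, params):
        assert branching_probability(0.0, 50.0, params, 100.0) == 0.0

    def test_probabilities_clamped_to_unit_interval(self, params, rng):
        c = 10.0 ** rng.uniform(-14, 4, 500)
        l = rng.uniform(0, 100.0, 500)
        for fn in (branching_probability, regression_probability):
            vals = fn(c, l, params, 100.0)
            assert np.all((vals >= 0.0) & (vals <= 1.0))

    def test_regression_spot_values(self):
        p = SproutParams(k_rg_0=0.4, alpha_rg=0.5, g=1.0)
        assert regression_probability(1.0, 100.0, p, 100.0) == 0.0
        assert regression_probability(1.0, 0.0, p, 100.0) == pytest.approx(0.4)

    def test_regression_decreasing_in_vegf(self):
        p = SproutParams(k_rg_0=1e-3, alpha_rg=0.5)
        cs = 10.0 ** np.linspace(-3, 3, 25)
        vals = regression_probability(cs, 0.0, p, 100.0)
        assert np.all(np.diff(vals) < 0)

    def test_instability_strict_inequality(self):
        assert not instability_condition(1.0, 0.0, 2.0)
        assert not instability_condition(1.0, 2.0, 2.0)   # equality excluded
        assert instability_condition(1.0, 2.0 + 1e-12, 2.0)

    @pytest.mark.parametrize("k_v,alpha_v,dp,expected", [
        (1.0, 2.0, 0.0, 1.0),
        (1.0, 2.0, 1.0, 2.0),
        (1.0, 2.0, -1.0, 0.5),
        (0.25, 1.0, 17.3, 0.25),
    ])
    def test_extension_cycle(self, k_v, alpha_v, dp, expected):
        p = SproutParams(k_v=k_v, alpha_v=alpha_v)
        assert extension_cycle(dp, p) == pytest.approx(expected)


class TestMarkAndSprout:
    def test_no_vegf_no_candidates(self, grid, rng, params):
        net = generate_initial_vasculature(None, grid, rng)
        c = np.zeros(grid.shape)
        l = np.ones(grid.shape)
        made = net.mark_candidates(c, l, 10.0, net.occupancy.copy(), rng, params)
        assert made == 0

    def test_certain_probability_marks_all_eligible(self, grid, rng):
        p = SproutParams(k_BH_0=1.0, alpha_BH=1.0, f=0.0)
        net = generate_initial_vasculature(None, grid, rng)
        c = np.ones(grid.shape)
        l = np.full(grid.shape, 5.0)
        made = net.mark_candidates(c, l, 10.0, net.occupancy.copy(), rng, p)
        assert made == len(net.nodes)

    def test_seeded_marking_reproducible(self, grid, params):
        counts = []
        for _ in range(2):
            rng = np.random.default_rng(11)
            net = generate_initial_vasculature(None, grid, rng)
            c = np.full(grid.shape, 5.0)
            l = np.full(grid.shape, 8.0)
            net.mark_candidates(c, l, 10.0, net.occupancy.copy(), rng, params)
            counts.append(tuple(net.positions(candidate=True)))
        assert counts[0] == counts[1]

    def test_sprout_targets_max_vegf_neighbour(self, rng):
        net = VesselNetwork((9, 9, 9))
        net.add_node(VesselNode((4, 4, 4), kind="existing"))
        net._set_candidate((4, 4, 4), True)
        c = np.zeros((9, 9, 9))
        c[4, 4, 5] = 3.0
        c[4, 4, 3] = 1.0
        target = net.sprout((4, 4, 4), c, net.occupancy.copy(), rng, now=2.0)
        assert target == (4, 4, 5)
        node = net.nodes[target]
        assert node.is_tec and node.kind == "new"
        assert net.sprout_birth[node.sprout_id] == 2.0
        assert net.sprout_anchor[node.sprout_id] == (4, 4, 4)
        assert not net.nodes[(4, 4, 4)].is_candidate
        assert net.nodes[(4, 4, 4)].is_ang2_source   # anchors keep Ang2

    def test_boxed_candidate_is_noop(self, rng):
        net = VesselNetwork((5, 5, 5))
        net.add_node(VesselNode((2, 2, 2), kind="existing"))
        net._set_candidate((2, 2, 2), True)
        blocked = np.ones((5, 5, 5), dtype=bool)
        assert net.sprout((2, 2, 2), np.zeros((5, 5, 5)), blocked, rng, 0.0) is None
        assert net.nodes[(2, 2, 2)].is_candidate


class TestExtension:
    def test_moves_up_gradient_and_transfers_flag(self, rng):
        net, sid = build_sprout()
        c = np.zeros((16, 16, 16))
        c[5, 5, 8] = 2.0
        tip = net.extend_tec((5, 5, 7), c, net.occupancy.copy(), rng)
        assert tip == (5, 5, 8)
        assert net.nodes[tip].is_tec
        assert not net.nodes[(5, 5, 7)].is_tec
        assert net.nodes[tip].sprout_id == sid

    def test_boxed_tip_is_noop(self, rng):
        net, _ = build_sprout()
        blocked = np.ones((16, 16, 16), dtype=bool)
        assert net.extend_tec((5, 5, 7), np.zeros((16, 16, 16)), blocked,
                              rng) is None

    def test_stalls_below_vegf_minimum(self, rng):
        net, _ = build_sprout()
        c = np.full((16, 16, 16), 1e-4)
        assert net.extend_tec((5, 5, 7), c, net.occupancy.copy(), rng,
                              c_min=0.05) is None

    def test_never_leaves_grid(self, rng):
        net = VesselNetwork((5, 5, 5))
        net.add_node(VesselNode((0, 0, 1), kind="existing"))
        sid = 0
        net.sprout_birth[sid] = 0.0
        net.add_node(VesselNode((0, 0, 0), kind="new", is_tec=True,
                                sprout_id=sid, parent=(0, 0, 1)))
        c = np.zeros((5, 5, 5))
        tip = net.extend_tec((0, 0, 0), c, net.occupancy.copy(), rng)
        assert tip is not None
        assert all(0 <= v < 5 for v in tip)


class TestRegression:
    def test_prunes_whole_sprout_to_anchor(self):
        net, _ = build_sprout()
        removed = net.regress_branch((5, 5, 7))
        assert removed == 3
        assert (5, 5, 4) in net.nodes          # existing anchor intact
        assert net.n_new() == 0

    def test_sibling_branch_untouched(self):
        net, sid = build_sprout()
        # sibling hanging off the first chain node
        net.add_node(VesselNode((5, 6, 5), kind="new", sprout_id=sid,
                                parent=(5, 5, 5)))
        net.add_node(VesselNode((5, 7, 5), kind="new", is_tec=True,
                                sprout_id=sid, parent=(5, 6, 5)))
        before = set(net.nodes)
        removed = net.regress_branch((5, 5, 7))
        # prune stops at (5,5,5), the upstream branch point
        assert removed == 2
        assert (5, 6, 5) in net.nodes and (5, 7, 5) in net.nodes
        assert (5, 5, 5) in net.nodes
        assert before - set(net.nodes) == {(5, 5, 6), (5, 5, 7)}

    def test_length_strictly_decreases(self, grid):
        net, _ = build_sprout(shape=grid.shape)
        before = total_new_length(net, grid)
        net.regress_branch((5, 5, 7))
        assert total_new_length(net, grid) < before


class TestLengthAccounting:
    def test_empty_network(self, grid):
        assert total_new_length(VesselNetwork(grid.shape), grid) == 0.0

    def test_reference_scale(self):
        """20 new nodes at the published resolution span 1 mm."""
        grid = Grid(200, 1.0, 1 / 33)
        net = VesselNetwork(grid.shape)
        net.sprout_birth[0] = 0.0
        prev = None
        for i in range(20):
            net.add_node(VesselNode((i, 0, 0), kind="new", sprout_id=0,
                                    parent=prev))
            prev = (i, 0, 0)
        assert total_new_length(net, grid) == pytest.approx(1.0)

    def test_existing_nodes_do_not_count(self, grid, rng):
        net = generate_initial_vasculature(None, grid, rng)
        assert total_new_length(net, grid) == 0.0


class TestNetworkInvariants:
    def test_forest_anchoring_after_operations(self, rng):
        """Every new node keeps a parent path ending at an existing node."""
        net, _ = build_sprout()
        c = np.random.default_rng(5).random((16, 16, 16))
        for _ in range(6):
            tips = net.positions(tec=True)
            if not tips:
                break
            net.extend_tec(tips[0], c, net.occupancy.copy(), rng)
        for pos, node in net.nodes.items():
            if node.kind == "existing":
                continue
            seen = set()
            cur = node
            while cur.kind != "existing":
                assert cur.parent is not None and cur.parent not in seen
                seen.add(cur.parent)
                cur = net.nodes[cur.parent]

    def test_radius_map_consistency(self):
        net, sid = build_sprout(now=0.0)
        R = net.radius_map(now=2.0, k_AR1=1.0, k_AR2=2.0)
        assert R[5, 5, 4] == 1.0            # existing: mature
        assert R[5, 5, 7] == pytest.approx(0.5)   # age 2, half-saturation
        assert R[np.where(~net.occupancy)].max() == 0.0

    def test_duplicate_position_rejected(self):
        net = VesselNetwork((4, 4, 4))
        net.add_node(VesselNode((1, 1, 1)))
        with pytest.raises(ValueError):
            net.add_node(VesselNode((1, 1, 1)))
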