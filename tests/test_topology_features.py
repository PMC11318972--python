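import itertools

import networkx as nx
import numpy as np
import pytest

from arbornet.arbor_graph import build_graph
from arbornet.errors import GeometryError, ValidationError
from arbornet.topology_features import (
    classify_region,
    extract_bare_terminals,
    feature_length_occurrence,
    minimum_cycle_basis,
    minimum_cycle_basis_edges,
    normalized_feature_counts,
    partition_lengths,
    relative_height,
    terminal_loop_correlation,
)
from arbornet.trace_io import ArborTrace, SkeletonPath

from conftest import line_path


def brute_force_mcb_weight(edges, weights):
    """Greedy minimum cycle basis over exhaustively enumerated simple cycles.

    The cycle space is a matroid, so sorting all simple cycles by weight and
    greedily selecting GF(2)-independent ones yields a minimum-weight basis.
    """
    g = nx.MultiGraph()
    for i, (u, v) in enumerate(edges):
        g.add_edge(u, v, key=i)
    nu = len(edges) - g.number_of_nodes() + nx.number_connected_components(g)
    if nu <= 0:
        return 0.0, 0
    cycles = []
    for cyc in nx.simple_cycles(g):
        # map node cycle back to edge sets (all key choices for each hop)
        hops = list(zip(cyc, cyc[1:] + cyc[:1]))
        if len(cyc) == 1:
            key_opts = [[k for k in g[cyc[0]].get(cyc[0], {})]]
        else:
            key_opts = [[k for k in g[u][v]] for u, v in hops]
        for keys in itertools.product(*key_opts):
            eset = frozenset(keys) if len(cyc) > 1 else frozenset(keys)
            if len(eset) == len(keys):
                cycles.append(eset)
    cycles = sorted(set(cycles), key=lambda c: sum(weights[e] for e in c))
    pivots = {}
    total = 0.0
    count = 0
    for cyc in cycles:
        vec = 0
        for e in cyc:
            vec |= 1 << e
        cur = vec
        while cur:
            p = cur.bit_length() - 1
            if p in pivots:
                cur ^= pivots[p]
            else:
                pivots[p] = cur
                total += sum(weights[e] for e in cyc)
                count += 1
                break
        if count == nu:
            break
    return total, nu


class TestMinimumCycleBasis:
    def test_tree_has_no_loops(self, y_trace):
        g = build_graph(y_trace)
        assert minimum_cycle_basis(g) == []

    def test_triangle(self, triangle_trace):
        g = build_graph(triangle_trace)
        loops = minimum_cycle_basis(g)
        assert len(loops) == 1
        assert np.isclose(loops[0].contour_length, 12.0, atol=1e-6)
        assert loops[0].node_count == 3

    def test_theta_graph_weights(self):
        # parallel edges weighted 2, 3, 9: minimum basis is {2+3, 3+9} = 17,
        # not {2+3, 2+9} = 16?  no: both {5, 12} and {5, 11} are bases; the
        # minimum uses the two lightest independent cycles 2+3 and 2+9 = 16
        edges = [(0, 1), (0, 1), (0, 1)]
        weights = [2.0, 3.0, 9.0]
        basis = minimum_cycle_basis_edges(edges, weights, 2)
        totals = sorted(sum(weights[e] for e in b) for b in basis)
        oracle_total, nu = brute_force_mcb_weight(edges, weights)
        assert len(basis) == nu == 2
        assert np.isclose(sum(totals), oracle_total)
        assert np.isclose(sum(totals), 16.0)  # {2,3} and {2,9}

    @pytest.mark.parametrize("trial", range(25))
    def test_random_graphs_match_brute_force(self, trial):
        rng = np.random.default_rng(200 + trial)
        n = int(rng.integers(4, 13))
        p = rng.uniform(0.25, 0.5)
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 30)))
        edges = list(g.edges)
        if not edges:
            return
        weights = list(rng.uniform(0.5, 10.0, size=len(edges)))
        basis = minimum_cycle_basis_edges(edges, weights, n)
        total = sum(sum(weights[e] for e in b) for b in basis)
        oracle_total, nu = brute_force_mcb_weight(edges, weights)
        assert len(basis) == nu
        assert np.isclose(total, oracle_total, rtol=1e-9)

    def test_matches_networkx_on_simple_graph(self):
        rng = np.random.default_rng(7)
        g = nx.gnp_random_graph(10, 0.4, seed=11)
        for u, v in g.edges:
            g.edges[u, v]["weight"] = float(rng.uniform(0.5, 5.0))
        edges = list(g.edges)
        weights = [g.edges[e]["weight"] for e in edges]
        mine = minimum_cycle_basis_edges(edges, weights, 10)
        my_total = sum(sum(weights[e] for e in b) for b in mine)
        nx_basis = nx.minimum_cycle_basis(g, weight="weight")
        nx_total = 0.0
        for cyc in nx_basis:
            # networkx returns node sets; the basis element is the lightest
            # simple cycle spanning exactly those nodes
            sub = nx.Graph(g.subgraph(cyc))
            spanning = [
                c for c in nx.simple_cycles(sub) if set(c) == set(cyc)
            ]
            nx_total += min(
                sum(g.edges[u, v]["weight"] for u, v in zip(c, c[1:] + c[:1]))
                for c in spanning
            )
        assert np.isclose(my_total, nx_total, rtol=1e-9)

    def test_cyclomatic_size_on_synthetic_networks(self):
        from arbornet.synthetic_data import generate_neuromast, preset_config

        for seed in (2, 3):
            _, trace, _, _ = generate_neuromast(preset_config("control_like", seed=seed))
            g = build_graph(trace)
            loops = minimum_cycle_basis(g)
            nu = g.n_edges - g.n_nodes + nx.number_connected_components(g.graph)
            assert len(loops) == nu


class TestBareTerminals:
    def test_y_graph_without_trunk_has_three_terminals(self, y_trace):
        g = build_graph(y_trace)
        assert len(extract_bare_terminals(g, compute_curvature=False)) == 3

    def test_trunk_leg_excluded(self):
        trunk = line_path("t", (-10, 0, 0), (0, 0, 0), is_trunk=True)
        a = line_path("a", (0, 0, 0), (5, 3, 0), parent_id="t")
        b = line_path("b", (0, 0, 0), (5, -3, 0), parent_id="t")
        g = build_graph(ArborTrace(paths=[trunk, a, b]))
        terms = extract_bare_terminals(g, compute_curvature=False)
        assert len(terms) == 2

    def test_pure_loop_has_no_terminals(self):
        arc1 = SkeletonPath("a1", np.array([[0.0, 0, 0], [5, 3, 0], [10, 0, 0]]))
        arc2 = SkeletonPath("a2", np.array([[0.0, 0, 0], [5, -3, 0], [10, 0, 0]]))
        g = build_graph(ArborTrace(paths=[arc1, arc2]))
        assert extract_bare_terminals(g, compute_curvature=False) == []

    def test_spur_length_is_arc_length(self):
        arc1 = SkeletonPath("a1", np.array([[0.0, 0, 0], [5, 3, 0], [10, 0, 0]]))
        arc2 = SkeletonPath("a2", np.array([[0.0, 0, 0], [5, -3, 0], [10, 0, 0]]))
        spur_pts = np.array([[10.0, 0, 0], [14.0, 0, 0], [14.0, 4.2, 0]])
        spur = SkeletonPath("s", spur_pts)
        g = build_graph(ArborTrace(paths=[arc1, arc2, spur]))
        terms = extract_bare_terminals(g, compute_curvature=False)
        assert len(terms) == 1
        assert np.isclose(terms[0].contour_length, 8.2, atol=1e-6)
        # polyline oriented branch node -> tip
        assert np.allclose(terms[0].polyline[0], [10, 0, 0])


class TestRelativeHeight:
    def test_apex_is_one_root_is_zero(self):
        root = np.zeros(3)
        apex = np.array([0.0, 0, 10])
        assert relative_height(apex, root, apex) == pytest.approx(1.0)
        assert relative_height(root, root, apex) == pytest.approx(0.0)

    def test_hand_computed_projection(self):
        # u=(3,4,5), v=(0,0,10): u.v/|v|^2 = 50/100
        h = relative_height((3, 4, 5), (0, 0, 0), (0, 0, 10))
        assert h == pytest.approx(0.5)

    def test_below_root_is_negative(self):
        h = relative_height((0, 0, -2), (0, 0, 0), (0, 0, 10))
        assert h == pytest.approx(-0.2)

    def test_degenerate_axis_raises(self):
        with pytest.raises(GeometryError):
            relative_height((1, 1, 1), (0, 0, 0), (0, 0, 0))

    @pytest.mark.parametrize(
        "h,region",
        [(0.05, "basal"), (-0.3, "basal"), (0.10, "basolateral"),
         (0.35, "basolateral"), (0.60, "apical"), (0.75, "apical"), (1.2, "apical")],
    )
    def test_region_classification(self, h, region):
        assert classify_region(h) == region


class TestOccurrence:
    def _fake(self, lengths):
        class F:
            def __init__(self, L):
                self.contour_length = L
        return [F(L) for L in lengths]

    def test_fractions_sum_to_one(self):
        loops = self._fake([35.0])
        terms = self._fake([33.0, 36.0, 38.0])
        tab = feature_length_occurrence(loops, terms)
        row = tab[tab.bin_lo == 30].iloc[0]
        assert row.fraction_terminal == pytest.approx(0.75)
        assert row.fraction_loop == pytest.approx(0.25)

    def test_empty_bin_is_nan_not_zero(self):
        tab = feature_length_occurrence(self._fake([35.0]), self._fake([]))
        row = tab[tab.bin_lo == 0].iloc[0]
        assert np.isnan(row.fraction_loop)

    def test_short_arbors_terminal_long_arbors_loop_in_control(self):
        """Control-condition pattern: < 10 µm only terminals, > 40 µm only loops."""
        from arbornet.synthetic_data import preset_config, sample_feature_plan

        rng = np.random.default_rng(0)
        cfg = preset_config("control_like")
        kinds, lengths = [], []
        for _ in range(60):
            plan = sample_feature_plan(cfg, rng)
            kinds += plan.kinds
            lengths += list(plan.lengths)
        lengths = np.asarray(lengths)
        kinds = np.asarray(kinds)
        short = lengths < 10
        long = lengths > 40
        assert short.any() and long.any()
        assert (kinds[short] == "terminal").all()
        assert (kinds[long] == "loop").all()


class TestNormalizedCounts:
    def test_min_max_endpoints(self):
        scaled = normalized_feature_counts([4, 8], [8, 8])
        assert list(scaled) == [0.0, 1.0]

    def test_hand_min_max(self):
        scaled = normalized_feature_counts([2, 3, 4], [4, 4, 4])
        assert np.allclose(scaled, [0.0, 0.5, 1.0])

    def test_degenerate_cohort_warns(self):
        with pytest.warns(UserWarning):
            scaled = normalized_feature_counts([5], [10])
        assert list(scaled) == [0.0]

    def test_zero_hair_cells_rejected(self):
        with pytest.raises(ValidationError):
            normalized_feature_counts([1, 2], [0, 4])


class TestCorrelation:
    def test_perfect_anticorrelation(self):
        slope, r2 = terminal_loop_correlation([1.0, 0.5, 0.0], [0.0, 0.5, 1.0])
        assert slope < 0
        assert r2 == pytest.approx(1.0)

    def test_matches_normal_equations_with_outlier(self):
        x = np.array([0.0, 1 / 3, 2 / 3, 1.0])
        y = -x + 1
        y[2] += 0.4  # outlier
        slope, r2 = terminal_loop_correlation(y, x)
        # closed-form least squares
        sxx = np.sum((x - x.mean()) ** 2)
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        syy = np.sum((y - y.mean()) ** 2)
        assert slope == pytest.approx(sxy / sxx)
        assert r2 == pytest.approx(sxy**2 / (sxx * syy))

    def test_constant_response_gives_zero_r2(self):
        slope, r2 = terminal_loop_correlation([0.5, 0.5, 0.5], [0.0, 0.5, 1.0])
        assert r2 == 0.0

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValidationError):
            terminal_loop_correlation([0, 1, 2], [0.5, 0.5, 0.5])


class TestPartition:
    def test_lengths_partition_total(self):
        from arbornet.synthetic_data import generate_neuromast, preset_config

        _, trace, _, _ = generate_neuromast(preset_config("control_like", seed=4))
        g = build_graph(trace)
        loops = minimum_cycle_basis(g)
        terms = extract_bare_terminals(g, compute_curvature=False)
        parts = partition_lengths(g, loops, terms)
        assert parts["loop"] > 0 and parts["bare_terminal"] > 0
        assert sum(parts.values()) == pytest.approx(g.total_length, rel=1e-9)
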