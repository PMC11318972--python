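"""Topological features of the arbor network: loops, bare terminals,
relative organ height and the occurrence statistics derived from them.

Loops are the elements of the *minimum cycle basis* of the junction graph
with edges weighted by contour length: |E| - |V| + C independent cycles of
minimum total geometric length.  Bare terminals are arbors ending in a free
(degree-1) tip.  The relative organ height of a node is the scalar
projection of its position onto the base-to-apex axis,
h = (u . v) / ||v||^2, with u the vector from the arborization initiation
point to the node and v the vector from the initiation point to the apex of
the hair-cell cluster; h = 0 at the base and 1 at the apex.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .arbor_graph import SpatialGraph
from .curvature import classify_curvature, total_curvature
from .errors import ValidationError

DEFAULT_LENGTH_BINS = (0.0, 10.0, 20.0, 30.0, 40.0, 70.0)  # µm
REGION_CUTS = (0.10, 0.60)  # relative-height boundaries basal | basolateral | apical

__all__ = [
    "Loop",
    "BareTerminal",
    "minimum_cycle_basis",
    "extract_bare_terminals",
    "relative_height",
    "classify_region",
    "feature_length_occurrence",
    "normalized_feature_counts",
    "terminal_loop_correlation",
    "partition_lengths",
    "DEFAULT_LENGTH_BINS",
]


@dataclass
class Loop:
    """A minimal arbor cycle (one element of the minimum cycle basis)."""

    loop_id: int
    node_ids: list[int]          # ordered walk around the cycle
    edge_ids: list[tuple[int, int, int]]
    contour_length: float        # µm, sum of member edge lengths
    node_count: int              # distinct junction (degree >= 3) nodes on the cycle

    def polyline(self, graph: SpatialGraph) -> np.ndarray:
        pts = []
        for u, v, k in self.edge_ids:
            seg = graph.graph.edges[u, v, k]["polyline"]
            pts.append(np.asarray(seg))
        return np.concatenate(pts, axis=0)


@dataclass
class BareTerminal:
    """An arbor with a free end, from its branching node to the tip."""

    terminal_id: int
    branch_node: int
    tip_node: int
    polyline: np.ndarray         # oriented branch node -> tip
    contour_length: float
    total_curvature: float = field(default=np.nan)
    curvature_class: str = field(default="")


# ---------------------------------------------------------------------------
# minimum cycle basis (Horton candidates + GF(2) greedy selection)
# ---------------------------------------------------------------------------

def _dijkstra_edges(adj, n_nodes, source, weights):
    """Shortest-path tree of a multigraph; returns per-node predecessor edge.

    Weights are perturbed by the caller to make shortest paths unique, which
    Horton's construction requires for correctness.
    """
    dist = {source: 0.0}
    pred = {source: None}  # node -> (prev node, edge index)
    heap = [(0.0, source)]
    done = set()
    while heap:
        d, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        for v, eidx in adj[u]:
            nd = d + weights[eidx]
            if v not in dist or nd < dist[v] - 1e-15:
                dist[v] = nd
                pred[v] = (u, eidx)
                heapq.heappush(heap, (nd, v))
    return dist, pred


def _path_edge_set(pred, node):
    out = set()
    while pred.get(node) is not None:
        prev, eidx = pred[node]
        out.add(eidx)
        node = prev
    return out


def _is_circuit(edge_set, edge_ends):
    """True iff the edge set forms a single connected cycle (all degrees 2)."""
    deg = {}
    nodes = set()
    for e in edge_set:
        u, v = edge_ends[e]
        if u == v:  # self-loop
            deg[u] = deg.get(u, 0) + 2
            nodes.add(u)
        else:
            deg[u] = deg.get(u, 0) + 1
            deg[v] = deg.get(v, 0) + 1
            nodes.update((u, v))
    if any(d != 2 for d in deg.values()):
        return False
    # connectivity over the edge set
    if not nodes:
        return False
    adj = {}
    for e in edge_set:
        u, v = edge_ends[e]
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    seen = set()
    stack = [next(iter(nodes))]
    while stack:
        n = stack.pop()
        if n in seen:
            continue
        seen.add(n)
        stack.extend(adj.get(n, ()))
    return seen == nodes


def minimum_cycle_basis_edges(edges, weights, n_nodes):
    """Minimum-weight cycle basis of an abstract multigraph.

    ``edges`` is a list of (u, v) pairs (self-loops and parallel edges
    allowed), ``weights`` the matching positive weights.  Returns a list of
    edge-index sets.  Candidates follow Horton's construction — for every
    vertex x and edge (u, v), the cycle SP(x,u) + (u,v) + SP(v,x) — with
    deterministic epsilon perturbation to make shortest paths unique, then a
    greedy GF(2) independence scan by weight.
    """
    m = len(edges)
    nodes = sorted({n for e in edges for n in e})
    # cyclomatic number
    comp_adj = {n: set() for n in nodes}
    for u, v in edges:
        comp_adj[u].add(v)
        comp_adj[v].add(u)
    seen, n_comp = set(), 0
    for n in nodes:
        if n in seen:
            continue
        n_comp += 1
        stack = [n]
        while stack:
            c = stack.pop()
            if c in seen:
                continue
            seen.add(c)
            stack.extend(comp_adj[c])
    nu = m - len(nodes) + n_comp
    if nu <= 0:
        return []

    eps = 1e-9 * max(weights, default=1.0)
    pert = [w + eps * (i + 1) / (m + 1) for i, w in enumerate(weights)]
    adj = {n: [] for n in nodes}
    for i, (u, v) in enumerate(edges):
        if u == v:
            continue
        adj[u].append((v, i))
        adj[v].append((u, i))

    candidates = {}  # frozenset(edge idx) -> perturbed weight
    for i, (u, v) in enumerate(edges):
        if u == v:
            candidates[frozenset([i])] = pert[i]
    for x in nodes:
        dist, pred = _dijkstra_edges(adj, len(nodes), x, pert)
        paths = {n: _path_edge_set(pred, n) for n in dist}
        for i, (u, v) in enumerate(edges):
            if u == v or u not in paths or v not in paths:
                continue
            cyc = paths[u] ^ paths[v]
            if i in cyc:
                continue
            cyc = cyc | {i}
            key = frozenset(cyc)
            if key not in candidates and _is_circuit(cyc, edges):
                candidates[key] = sum(pert[e] for e in cyc)

    ordered = sorted(candidates.items(), key=lambda kv: kv[1])
    basis = []
    pivots = {}  # pivot edge index -> reduced bitmask
    for cyc, _w in ordered:
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
                basis.append(set(cyc))
                break
        if len(basis) == nu:
            break
    return basis


def _order_cycle(edge_ids, graph):
    """Order a circuit's edges into a closed walk; returns (nodes, edges)."""
    remaining = list(edge_ids)
    u0, v0, _ = remaining[0]
    walk_edges = [remaining.pop(0)]
    walk_nodes = [u0, v0] if u0 != v0 else [u0]
    cur = walk_nodes[-1]
    while remaining:
        for i, (u, v, k) in enumerate(remaining):
            if u == cur or v == cur:
                walk_edges.append(remaining.pop(i))
                cur = v if u == cur else u
                walk_nodes.append(cur)
                break
        else:  # pragma: no cover - guarded by _is_circuit
            break
    if walk_nodes[0] == walk_nodes[-1] and len(walk_nodes) > 1:
        walk_nodes = walk_nodes[:-1]
    return walk_nodes, walk_edges


def minimum_cycle_basis(graph: SpatialGraph) -> list[Loop]:
    """Loops of the network: the minimum cycle basis of the junction graph
    weighted by contour length, sorted by contour length."""
    g = graph.graph
    edge_list = sorted(g.edges(keys=True))
    edges = [(u, v) for u, v, _ in edge_list]
    weights = [g.edges[e]["length"] for e in edge_list]
    basis = minimum_cycle_basis_edges(edges, weights, g.number_of_nodes())
    loops = []
    for cyc in basis:
        eids = [edge_list[i] for i in sorted(cyc)]
        length = float(sum(g.edges[e]["length"] for e in eids))
        nodes, ordered_edges = _order_cycle(eids, graph)
        junctions = [n for n in set(nodes) if g.degree(n) >= 3]
        loops.append(
            Loop(
                loop_id=-1,
                node_ids=nodes,
                edge_ids=ordered_edges,
                contour_length=length,
                node_count=len(junctions),
            )
        )
    loops.sort(key=lambda lp: lp.contour_length)
    for i, lp in enumerate(loops):
        lp.loop_id = i
    return loops


# ---------------------------------------------------------------------------
# bare terminals
# ---------------------------------------------------------------------------

def extract_bare_terminals(
    graph: SpatialGraph, compute_curvature: bool = True
) -> list[BareTerminal]:
    """One record per degree-1 tip that is not part of the trunk.

    After degree-2 collapse a terminal is a single edge from its branching
    node to the tip; the polyline is oriented branch node -> tip.
    """
    g = graph.graph
    terms = []
    for tip in graph.tips:
        (u, v, k) = next(iter(g.edges(tip, keys=True)))
        if graph.edge_touches_trunk(u, v, k):
            continue
        d = g.edges[u, v, k]
        branch = v if u == tip else u
        pts = np.asarray(d["polyline"])
        if np.linalg.norm(pts[0] - graph.position(branch)) > np.linalg.norm(
            pts[-1] - graph.position(branch)
        ):
            pts = pts[::-1]
        terms.append(
            BareTerminal(
                terminal_id=-1,
                branch_node=branch,
                tip_node=tip,
                polyline=pts,
                contour_length=float(d["length"]),
            )
        )
    terms.sort(key=lambda t: (t.branch_node, t.tip_node, t.contour_length))
    for i, t in enumerate(terms):
        t.terminal_id = i
        if compute_curvature:
            t.total_curvature = total_curvature(t.polyline)
            t.curvature_class = classify_curvature(t.total_curvature)
    return terms


# ---------------------------------------------------------------------------
# relative organ height
# ---------------------------------------------------------------------------

def relative_height(node_pos, root, apex) -> float:
    """Relative organ height h = (u . v) / ||v||^2 of a node.

    ``u`` runs from the arborization initiation point (``root``) to the node,
    ``v`` from the initiation point to the cluster apex.  h = 0 at the root,
    1 at the apex; arbors overshooting the apex may slightly exceed 1 and
    nodes below the root give negative values (retained, not clipped).
    """
    root = np.asarray(root, dtype=float)
    apex = np.asarray(apex, dtype=float)
    v = apex - root
    v2 = float(v @ v)
    if v2 < 1e-18:
        from .errors import GeometryError

        raise GeometryError("degenerate base-to-apex axis (apex == root)")
    u = np.asarray(node_pos, dtype=float) - root
    return float(u @ v / v2)


def classify_region(h: float) -> str:
    """Region of the organ from relative height.

    Half-open bins: basal [0, 0.10), basolateral [0.10, 0.60), apical
    [0.60, inf); negative heights clamp to basal.
    """
    if h < REGION_CUTS[0]:
        return "basal"
    if h < REGION_CUTS[1]:
        return "basolateral"
    return "apical"


# ---------------------------------------------------------------------------
# occurrence statistics
# ---------------------------------------------------------------------------

def feature_length_occurrence(
    loops, terminals, bins=DEFAULT_LENGTH_BINS
) -> pd.DataFrame:
    """Normalized occurrence of loops vs bare terminals by contour length.

    For each length bin the loop (terminal) fraction is the number of arbors
    of that length forming a loop (terminal) divided by the total number of
    arbors of either kind in the bin.  Empty bins report NaN fractions, not
    zero.
    """
    bins = np.asarray(bins, dtype=float)
    loop_len = np.asarray([lp.contour_length for lp in loops], dtype=float)
    term_len = np.asarray([t.contour_length for t in terminals], dtype=float)
    n_loop, _ = np.histogram(loop_len, bins=bins)
    n_term, _ = np.histogram(term_len, bins=bins)
    total = n_loop + n_term
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_loop = np.where(total > 0, n_loop / total, np.nan)
        frac_term = np.where(total > 0, n_term / total, np.nan)
    return pd.DataFrame(
        {
            "bin_lo": bins[:-1],
            "bin_hi": bins[1:],
            "n_loops": n_loop,
            "n_terminals": n_term,
            "fraction_loop": frac_loop,
            "fraction_terminal": frac_term,
        }
    )


def normalized_feature_counts(
    counts, hair_cell_counts, per_neuromast_density: bool = False
) -> np.ndarray:
    """Per-neuromast feature counts normalized by hair-cell number and
    min-max scaled to [0, 1] across the cohort.

    With ``per_neuromast_density`` the scaled values are additionally divided
    by the cohort size (the convention used for cohort density plots).  A
    single-neuromast or constant cohort scales to all zeros with a warning.
    """
    counts = np.asarray(counts, dtype=float)
    hc = np.asarray(hair_cell_counts, dtype=float)
    if counts.shape != hc.shape:
        raise ValidationError("counts and hair_cell_counts must align")
    if np.any(hc <= 0):
        raise ValidationError("hair-cell counts must be positive")
    ratio = counts / hc
    lo, hi = float(ratio.min()), float(ratio.max())
    if hi - lo < 1e-15:
        warnings.warn(
            "degenerate cohort (constant per-hair-cell ratio); scaled values set to 0",
            stacklevel=2,
        )
        scaled = np.zeros_like(ratio)
    else:
        scaled = (ratio - lo) / (hi - lo)
    if per_neuromast_density:
        scaled = scaled / len(counts)
    return scaled


def terminal_loop_correlation(scaled_terminals, scaled_loops):
    """Least-squares regression of scaled terminal count on scaled loop
    count across a cohort; returns (slope, r_squared)."""
    x = np.asarray(scaled_loops, dtype=float)
    y = np.asarray(scaled_terminals, dtype=float)
    if len(x) < 3:
        raise ValidationError("correlation requires at least 3 neuromasts")
    if np.ptp(x) < 1e-15:
        raise ValidationError("zero variance in loop counts: regression undefined")
    if np.ptp(y) < 1e-15:
        return 0.0, 0.0
    res = linregress(x, y)
    return float(res.slope), float(res.rvalue**2)


# ---------------------------------------------------------------------------
# skeleton partition
# ---------------------------------------------------------------------------

def partition_lengths(graph: SpatialGraph, loops, terminals) -> dict[str, float]:
    """Partition the total skeleton length into trunk, loop, bare-terminal
    and internal-connector contributions.

    Every collapsed edge belongs to exactly one class (an edge shared by two
    basis loops is still one edge; per-loop contour lengths may overlap, the
    partition does not).
    """
    g = graph.graph
    loop_edges = set()
    for lp in loops:
        for u, v, k in lp.edge_ids:
            loop_edges.add((min(u, v), max(u, v), k))
    term_edges = set()
    for t in terminals:
        u, v = t.branch_node, t.tip_node
        for uu, vv, k in g.edges(t.tip_node, keys=True):
            term_edges.add((min(uu, vv), max(uu, vv), k))
    out = {"trunk": 0.0, "loop": 0.0, "bare_terminal": 0.0, "connector": 0.0}
    for u, v, k, d in g.edges(keys=True, data=True):
        eid = (min(u, v), max(u, v), k)
        if graph.edge_touches_trunk(u, v, k):
            out["trunk"] += d["length"]
        elif eid in term_edges:
            out["bare_terminal"] += d["length"]
        elif eid in loop_edges:
            out["loop"] += d["length"]
        else:
            out["connector"] += d["length"]
    return out
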