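"""Conversion of skeleton traces into a rooted spatial junction graph.

Junctions are points where arbors branch, converge, or cross in 3D; chains of
degree-2 sample points are collapsed into single polyline edges so that the
graph nodes are exactly the junctions (degree >= 3) and the free ends
(degree 1).  Two skeleton segments from different paths passing within
``merge_tol`` of each other are fused into a crossing node, ``merge_tol``
defaulting to 0.5 µm — the average neurite radius.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyGraphError, RootNotFoundError
from .trace_io import ArborTrace, HairCellCluster

__all__ = [
    "SpatialGraph",
    "build_graph",
    "find_arborization_point",
    "contour_length_from_root",
    "node_degree_distribution",
]


@dataclass
class SpatialGraph:
    """Junction graph of an arbor network.

    ``graph`` is an undirected :class:`networkx.MultiGraph`; nodes carry a
    ``pos`` attribute (3-vector, µm) and edges carry ``polyline`` (m, 3),
    ``length`` (µm) and ``path_ids`` (frozenset of contributing trace paths).
    Node ids are assigned by lexicographic (x, y, z) order so construction is
    invariant to the ordering of paths in the input file.
    """

    graph: nx.MultiGraph
    root_id: int | None = None
    trunk_path_ids: frozenset = field(default_factory=frozenset)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def position(self, node_id: int) -> np.ndarray:
        return self.graph.nodes[node_id]["pos"]

    def degree(self, node_id: int) -> int:
        return self.graph.degree(node_id)

    @property
    def junctions(self) -> list[int]:
        """Nodes of the junction census (degree >= 3)."""
        return [n for n in sorted(self.graph.nodes) if self.graph.degree(n) >= 3]

    @property
    def tips(self) -> list[int]:
        """Degree-1 free ends (bare-terminal tips and the trunk end)."""
        return [n for n in sorted(self.graph.nodes) if self.graph.degree(n) == 1]

    @property
    def total_length(self) -> float:
        return float(sum(d["length"] for _, _, d in self.graph.edges(data=True)))

    def edge_is_trunk(self, u, v, key) -> bool:
        pids = self.graph.edges[u, v, key]["path_ids"]
        return bool(pids) and pids <= self.trunk_path_ids

    def edge_touches_trunk(self, u, v, key) -> bool:
        """True if any part of the collapsed edge comes from the trunk (a
        degree-2 collapse can chain trunk and arbor geometry into one edge)."""
        return bool(self.graph.edges[u, v, key]["path_ids"] & self.trunk_path_ids)

    # -- export ------------------------------------------------------------

    def to_json(self, path) -> None:
        doc = {
            "root_id": self.root_id,
            "trunk_path_ids": sorted(self.trunk_path_ids),
            "nodes": [
                {"id": int(n), "pos": list(map(float, d["pos"])), "degree": self.graph.degree(n)}
                for n, d in sorted(self.graph.nodes(data=True))
            ],
            "edges": [
                {
                    "u": int(u),
                    "v": int(v),
                    "key": int(k),
                    "length": float(d["length"]),
                    "path_ids": sorted(d["path_ids"]),
                    "polyline": np.asarray(d["polyline"]).tolist(),
                }
                for u, v, k, d in sorted(self.graph.edges(keys=True, data=True))
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @staticmethod
    def from_json(path) -> "SpatialGraph":
        with open(path) as fh:
            doc = json.load(fh)
        g = nx.MultiGraph()
        for n in doc["nodes"]:
            g.add_node(n["id"], pos=np.asarray(n["pos"], dtype=float))
        for e in doc["edges"]:
            g.add_edge(
                e["u"],
                e["v"],
                key=e["key"],
                length=e["length"],
                polyline=np.asarray(e["polyline"], dtype=float),
                path_ids=frozenset(e["path_ids"]),
            )
        return SpatialGraph(
            graph=g,
            root_id=doc["root_id"],
            trunk_path_ids=frozenset(doc["trunk_path_ids"]),
        )

    def to_graphml(self, path) -> None:
        g = nx.MultiGraph()
        for n, d in self.graph.nodes(data=True):
            x, y, z = d["pos"]
            g.add_node(n, x=float(x), y=float(y), z=float(z), degree=self.graph.degree(n))
        for u, v, k, d in self.graph.edges(keys=True, data=True):
            g.add_edge(u, v, key=k, length=float(d["length"]))
        nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# construction helpers
# ---------------------------------------------------------------------------

def _segment_closest_points(p0, p1, q0, q1):
    """Closest points between two 3D segments; returns (s, t, dist)."""
    u = p1 - p0
    v = q1 - q0
    w0 = p0 - q0
    a = u @ u
    b = u @ v
    c = v @ v
    d = u @ w0
    e = v @ w0
    denom = a * c - b * b
    if denom > 1e-12:
        s = np.clip((b * e - c * d) / denom, 0.0, 1.0)
    else:
        s = 0.0
    t = (b * s + e) / c if c > 1e-12 else 0.0
    t = np.clip(t, 0.0, 1.0)
    # re-clamp s for the clamped t
    if a > 1e-12:
        s = np.clip((b * t - d) / a, 0.0, 1.0)
    dist = float(np.linalg.norm((p0 + s * u) - (q0 + t * v)))
    return float(s), float(t), dist


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _find_crossings(polys, merge_tol):
    """Detect 3D near-crossings between segments of different paths.

    Returns per-path lists of (segment index, parameter) insertion requests
    plus fuse pairs between the inserted vertices.  Contacts lying within
    2 x merge_tol of a point where the two paths already touch (a shared
    branch vertex) are ignored: those are genuine junctions, not crossings.
    """
    events = []  # (ia, ib, arc_a, arc_b, seg_a, s, seg_b, t, dist)
    arclens = []
    for pts in polys:
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        arclens.append(np.concatenate([[0.0], np.cumsum(seg)]))
    # midpoint KD-tree prefilter over all segments
    mids = []
    seg_info = []  # (path index, segment index)
    half = []
    for ip, pts in enumerate(polys):
        m = 0.5 * (pts[:-1] + pts[1:])
        mids.append(m)
        half.extend(0.5 * np.linalg.norm(pts[1:] - pts[:-1], axis=1))
        seg_info.extend((ip, i) for i in range(len(pts) - 1))
    mids = np.concatenate(mids, axis=0)
    half = np.asarray(half)
    tree = cKDTree(mids)
    rmax = float(half.max(initial=0.0)) * 2 + merge_tol
    pairs = tree.query_pairs(rmax, output_type="ndarray")
    # exact touching points between path pairs (shared vertices)
    touch: dict[tuple[int, int], np.ndarray] = {}

    def touching(ia, ib):
        key = (min(ia, ib), max(ia, ib))
        if key not in touch:
            ta = cKDTree(polys[key[0]])
            d, idx = ta.query(polys[key[1]])
            touch[key] = polys[key[1]][d < 1e-6]
        return touch[key]

    for i, j in pairs:
        (ia, sa), (ib, sb) = seg_info[i], seg_info[j]
        if ia == ib:
            continue
        if np.linalg.norm(mids[i] - mids[j]) > half[i] + half[j] + merge_tol:
            continue
        pa, pb = polys[ia], polys[ib]
        s, t, dist = _segment_closest_points(pa[sa], pa[sa + 1], pb[sb], pb[sb + 1])
        if dist >= merge_tol:
            continue
        p = pa[sa] + s * (pa[sa + 1] - pa[sa])
        shared = touching(ia, ib)
        if len(shared) and np.min(np.linalg.norm(shared - p, axis=1)) < 2.0 * merge_tol:
            continue
        arc_a = arclens[ia][sa] + s * (arclens[ia][sa + 1] - arclens[ia][sa])
        arc_b = arclens[ib][sb] + t * (arclens[ib][sb + 1] - arclens[ib][sb])
        events.append((ia, ib, arc_a, arc_b, sa, s, sb, t, dist))

    # cluster contiguous events along the pair of paths: adjacent segments of
    # a genuine crossing all report sub-tol proximity; keep the closest
    events.sort(key=lambda e: e[8])
    selected = []
    for ev in events:
        dup = False
        for kept in selected:
            if kept[0] == ev[0] and kept[1] == ev[1]:
                if abs(kept[2] - ev[2]) < 2 * merge_tol and abs(kept[3] - ev[3]) < 2 * merge_tol:
                    dup = True
                    break
        if not dup:
            selected.append(ev)
    return selected


def build_graph(trace: ArborTrace, merge_tol: float = 0.5) -> SpatialGraph:
    """Build the junction graph of a trace.

    Branch points (shared path endpoints), convergence points and 3D
    crossings (segments of different paths within ``merge_tol``) become
    nodes; degree-2 chains are collapsed into polyline edges.
    """
    if not trace.paths:
        raise EmptyGraphError("cannot build a graph from an empty trace")
    order = np.argsort([p.path_id for p in trace.paths])
    paths = [trace.paths[i] for i in order]
    polys = [p.points.copy() for p in paths]

    fuse_requests: list[tuple[int, float, int, float]] = []
    if merge_tol > 0 and len(polys) > 1:
        for ia, ib, arc_a, arc_b, *_ in _find_crossings(polys, merge_tol):
            fuse_requests.append((ia, arc_a, ib, arc_b))

    # insert crossing vertices into the polylines
    inserts: dict[int, list[float]] = {}
    for ia, arc_a, ib, arc_b in fuse_requests:
        inserts.setdefault(ia, []).append(arc_a)
        inserts.setdefault(ib, []).append(arc_b)

    def _arc(pts):
        return np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])

    vertex_at_arc: dict[int, dict[float, int]] = {ip: {} for ip in range(len(polys))}
    new_polys = []
    for ip, pts in enumerate(polys):
        arcs = _arc(pts)
        extra = sorted(set(np.round(a, 9) for a in inserts.get(ip, [])))
        allarcs = sorted(set(np.round(arcs, 9)) | set(extra))
        out = np.empty((len(allarcs), 3))
        for d in range(3):
            out[:, d] = np.interp(allarcs, arcs, pts[:, d])
        new_polys.append(out)
        for a in extra:
            vertex_at_arc[ip][a] = int(np.searchsorted(allarcs, a))
    polys = new_polys

    # global vertex indexing
    offsets = np.cumsum([0] + [len(p) for p in polys])
    allpts = np.concatenate(polys, axis=0)
    uf = _UnionFind(len(allpts))

    # fuse crossing vertex pairs
    for ia, arc_a, ib, arc_b in fuse_requests:
        va = offsets[ia] + vertex_at_arc[ia][round(arc_a, 9)]
        vb = offsets[ib] + vertex_at_arc[ib][round(arc_b, 9)]
        uf.union(va, vb)

    # merge path endpoints onto nearby vertices of *other* paths
    tree = cKDTree(allpts)
    vert_path = np.concatenate([np.full(len(p), ip) for ip, p in enumerate(polys)])
    for ip, pts in enumerate(polys):
        for vi in (offsets[ip], offsets[ip] + len(pts) - 1):
            tol = max(merge_tol, 1e-6)
            cand = tree.query_ball_point(allpts[vi], tol)
            cand = [c for c in cand if vert_path[c] != ip]
            if cand:
                d = np.linalg.norm(allpts[cand] - allpts[vi], axis=1)
                uf.union(vi, cand[int(np.argmin(d))])
                # also fuse exactly-coincident vertices (multi-way anchors)
                for c, dd in zip(cand, d):
                    if dd < 1e-6:
                        uf.union(vi, c)
        # a closed path (first == last point) is a loop on itself
        if np.linalg.norm(pts[0] - pts[-1]) < max(merge_tol, 1e-6):
            uf.union(offsets[ip], offsets[ip] + len(pts) - 1)

    # vertex-level multigraph
    vg = nx.MultiGraph()
    rep_pos: dict[int, np.ndarray] = {}
    for vi in range(len(allpts)):
        r = uf.find(vi)
        if r not in rep_pos:
            rep_pos[r] = allpts[r]
    for ip, pts in enumerate(polys):
        for si in range(len(pts) - 1):
            u = uf.find(offsets[ip] + si)
            v = uf.find(offsets[ip] + si + 1)
            seg = np.array([pts[si], pts[si + 1]])
            length = float(np.linalg.norm(seg[1] - seg[0]))
            if u == v and length < 1e-12:
                continue
            vg.add_edge(u, v, polyline=seg, length=length, path_id=paths[ip].path_id)
    for n in vg.nodes:
        vg.nodes[n]["pos"] = rep_pos[n]

    collapsed = _collapse_degree_two(vg)
    trunk_ids = frozenset(p.path_id for p in paths if p.is_trunk)
    return SpatialGraph(graph=collapsed, trunk_path_ids=trunk_ids)


def _collapse_degree_two(vg: nx.MultiGraph) -> nx.MultiGraph:
    """Collapse degree-2 chains of the vertex graph into polyline edges,
    renumbering nodes canonically by (x, y, z)."""

    def keep(n):
        return vg.degree(n) != 2 or vg.number_of_edges(n, n) > 0

    kept = [n for n in vg.nodes if keep(n)]
    out = nx.MultiGraph()
    visited_edges = set()
    chains = []  # (u, v, polyline, length, path_ids)

    def walk(start, first_edge):
        """Follow a chain from a kept node through degree-2 vertices."""
        u, v, k = first_edge
        pts = [vg.nodes[start]["pos"]]
        pids = set()
        total = 0.0
        prev, cur, key = (u, v, k) if u == start else (v, u, k)
        while True:
            d = vg.edges[prev, cur, key]
            seg = d["polyline"]
            if np.linalg.norm(seg[0] - pts[-1]) > np.linalg.norm(seg[-1] - pts[-1]):
                seg = seg[::-1]
            pts.extend(seg[1:])
            total += d["length"]
            pids.add(d["path_id"])
            visited_edges.add((min(prev, cur), max(prev, cur), key))
            if keep(cur):
                return cur, np.asarray(pts), total, pids
            nxt = [
                (cur, w, kk)
                for w, keyd in vg.adj[cur].items()
                for kk in keyd
                if (min(cur, w), max(cur, w), kk) not in visited_edges
            ]
            if not nxt:
                return cur, np.asarray(pts), total, pids
            prev, cur, key = nxt[0][0], nxt[0][1], nxt[0][2]

    for start in kept:
        for v, keyd in list(vg.adj[start].items()):
            for k in list(keyd):
                eid = (min(start, v), max(start, v), k)
                if eid in visited_edges:
                    continue
                end, pts, total, pids = walk(start, (start, v, k))
                chains.append((start, end, pts, total, pids))

    # isolated cycles (every vertex degree 2): anchor at the min-pos vertex
    remaining = set(vg.nodes) - set(kept)
    seen = set()
    for u, v, k in visited_edges:
        seen.add(u)
        seen.add(v)
    remaining -= seen
    while remaining:
        comp_start = min(remaining, key=lambda n: tuple(vg.nodes[n]["pos"]))
        comp = nx.node_connected_component(vg, comp_start)
        remaining -= comp
        anchor = min(comp, key=lambda n: tuple(vg.nodes[n]["pos"]))
        edges = [(anchor, w, kk) for w, keyd in vg.adj[anchor].items() for kk in keyd]
        end, pts, total, pids = walk(anchor, edges[0])
        chains.append((anchor, end, pts, total, pids))
        kept.append(anchor)

    # canonical node ids by position
    kept = sorted(set(kept))
    pos_order = sorted(kept, key=lambda n: tuple(vg.nodes[n]["pos"]))
    relabel = {n: i for i, n in enumerate(pos_order)}
    for n in pos_order:
        out.add_node(relabel[n], pos=vg.nodes[n]["pos"])
    chains.sort(key=lambda c: (relabel[c[0]], relabel[c[1]], c[3], tuple(c[2][0])))
    for u, v, pts, total, pids in chains:
        ru, rv = relabel[u], relabel[v]
        if ru > rv:
            ru, rv = rv, ru
            pts = pts[::-1]
        out.add_edge(ru, rv, polyline=pts, length=float(total), path_ids=frozenset(pids))
    return out


# ---------------------------------------------------------------------------
# rooting and per-node quantities
# ---------------------------------------------------------------------------

def find_arborization_point(
    graph: SpatialGraph,
    trace: ArborTrace | None = None,
    cluster: HairCellCluster | None = None,
) -> int:
    """Identify the arborization point — the node where the lateral-line
    branch contacts the arbor network — and set it as the graph root.

    With a flagged trunk, candidates are the nodes joining trunk edges to
    non-trunk edges; with a cluster, the candidate nearest the cluster
    boundary wins.  Without a trunk the node nearest the cluster base point
    is used.  Ties break toward the lower node id (a warning is emitted).
    """
    g = graph.graph
    candidates: list[int] = []
    if graph.trunk_path_ids:
        for n in sorted(g.nodes):
            inc = [g.edges[u, v, k]["path_ids"] for u, v, k in g.edges(n, keys=True)]
            has_trunk = any(p & graph.trunk_path_ids for p in inc)
            has_arbor = any(p - graph.trunk_path_ids for p in inc)
            if has_trunk and has_arbor:
                candidates.append(n)
    if not candidates and cluster is not None:
        candidates = sorted(g.nodes)
    if not candidates:
        raise RootNotFoundError(
            "no trunk-to-arbor junction found and no cluster supplied"
        )
    if len(candidates) > 1:
        if cluster is not None:
            pos = np.array([graph.position(n) for n in candidates])
            d = cluster.distance_to_boundary(pos, spacing=0.2)
            best = np.min(d)
            # ties resolved at the boundary-sampling resolution
            tied = [n for n, dn in zip(candidates, d) if dn <= best + 0.1]
        else:
            tied = candidates
        if len(tied) > 1:
            warnings.warn(
                f"multiple equidistant arborization-point candidates {tied}; "
                "choosing the lowest node id",
                stacklevel=2,
            )
        root = min(tied)
    else:
        root = candidates[0]
    graph.root_id = root
    return root


def contour_length_from_root(graph: SpatialGraph) -> dict[int, float]:
    """Shortest along-skeleton contour length from the root to every node.

    Nodes disconnected from the root are reported as ``inf``.
    """
    if graph.root_id is None:
        raise RootNotFoundError("graph has no root; call find_arborization_point")
    dist = nx.single_source_dijkstra_path_length(
        graph.graph, graph.root_id, weight="length"
    )
    out = {}
    for n in sorted(graph.graph.nodes):
        out[n] = float(dist.get(n, np.inf))
    flagged = [n for n, d in out.items() if not np.isfinite(d)]
    if flagged:
        warnings.warn(f"nodes disconnected from root: {flagged}", stacklevel=2)
    return out


def node_degree_distribution(graph: SpatialGraph) -> dict[int, int]:
    """Degree histogram over junction nodes only (degree >= 3).

    Degree-1 free ends are bare-terminal tips, not junctions; retrieve them
    via :attr:`SpatialGraph.tips`.
    """
    return dict(sorted(Counter(graph.graph.degree(n) for n in graph.junctions).items()))
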