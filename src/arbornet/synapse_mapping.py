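"""Mapping synaptic puncta onto the arbor network.

Each punctum is assigned to the nearest skeleton point; the feature carrying
that point (loop vs bare terminal) determines the assignment, with a
distance cutoff (default 1.0 µm, about twice the neurite radius) beyond
which puncta remain unassigned.  Punctum-to-node distances are binned into
concentric equal-volume shells (default 100,000 shells to a 10 µm radius,
outer radii r_k = R (k/n)^(1/3)) around the nearest junction node.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .arbor_graph import SpatialGraph
from .errors import EmptyGraphError, ValidationError
from .trace_io import HairCellCluster, PunctaSet, resample_polyline

DEFAULT_ASSIGN_CUTOFF = 1.0   # µm
DEFAULT_N_SHELLS = 100_000
DEFAULT_SHELL_RADIUS = 10.0   # µm
SKELETON_SAMPLE_SPACING = 0.1  # µm

__all__ = [
    "PunctaAssignment",
    "ShellHistogram",
    "SkeletonIndex",
    "puncta_summary",
    "assign_puncta_to_features",
    "node_distance_shell_density",
    "loop_vs_terminal_counts",
]


@dataclass
class PunctaAssignment:
    punctum_id: int
    feature_kind: str  # "loop" | "bare_terminal" | "unassigned"
    feature_id: int    # -1 when unassigned
    skeleton_distance: float
    nearest_node_distance: float


@dataclass
class ShellHistogram:
    """Counts of puncta in concentric equal-volume shells around their
    nearest junction node."""

    n_shells: int
    radius: float
    counts: np.ndarray            # length n_shells
    overflow: int = 0             # puncta beyond ``radius``

    @property
    def shell_volume(self) -> float:
        return (4.0 / 3.0) * np.pi * self.radius**3 / self.n_shells

    def outer_radius(self, k) -> np.ndarray:
        """Outer radius of shell k (1-based): R (k/n)^(1/3)."""
        return self.radius * (np.asarray(k, dtype=float) / self.n_shells) ** (1.0 / 3.0)

    def density(self) -> np.ndarray:
        """Puncta per µm³ in each shell (independent of n_shells)."""
        return self.counts / self.shell_volume

    def to_dataframe(self, nonzero_only: bool = True) -> pd.DataFrame:
        k = np.arange(1, self.n_shells + 1)
        df = pd.DataFrame(
            {
                "shell": k,
                "r_outer_um": self.outer_radius(k),
                "count": self.counts,
                "density_per_um3": self.density(),
            }
        )
        return df[df["count"] > 0] if nonzero_only else df


def shell_index(distance, n_shells: int, radius: float) -> np.ndarray:
    """Shell (1-based) containing a node distance: k = ceil(n (d/R)^3)."""
    d = np.asarray(distance, dtype=float)
    k = np.ceil(n_shells * (d / radius) ** 3).astype(int)
    return np.maximum(k, 1)


# ---------------------------------------------------------------------------
# skeleton sampling index
# ---------------------------------------------------------------------------

class SkeletonIndex:
    """Dense arc-length samples of every collapsed edge with per-sample
    feature membership, KD-tree indexed.

    Precedence when an edge belongs to several categories: a bare terminal
    edge has a degree-1 end and thus cannot sit on a cycle; an edge shared by
    several basis loops is labelled with the lowest loop id; trunk and
    connector samples carry those labels and map to "unassigned" for puncta.
    """

    def __init__(self, graph: SpatialGraph, loops, terminals,
                 spacing: float = SKELETON_SAMPLE_SPACING):
        if graph.n_edges == 0:
            raise EmptyGraphError("cannot index an empty graph")
        g = graph.graph
        edge_label: dict[tuple[int, int, int], tuple[str, int]] = {}
        for u, v, k in g.edges(keys=True):
            eid = (min(u, v), max(u, v), k)
            if graph.edge_is_trunk(u, v, k):
                edge_label[eid] = ("trunk", -1)
            else:
                edge_label[eid] = ("connector", -1)
        for lp in sorted(loops, key=lambda l: l.loop_id, reverse=True):
            for u, v, k in lp.edge_ids:
                edge_label[(min(u, v), max(u, v), k)] = ("loop", lp.loop_id)
        for t in terminals:
            for u, v, k in g.edges(t.tip_node, keys=True):
                edge_label[(min(u, v), max(u, v), k)] = ("bare_terminal", t.terminal_id)
        samples = []
        kinds = []
        fids = []
        for (u, v, k), (kind, fid) in sorted(edge_label.items()):
            pts = resample_polyline(g.edges[u, v, k]["polyline"], spacing)
            samples.append(pts)
            kinds.extend([kind] * len(pts))
            fids.extend([fid] * len(pts))
        self.points = np.concatenate(samples, axis=0)
        self.kinds = np.asarray(kinds)
        self.feature_ids = np.asarray(fids, dtype=int)
        self.tree = cKDTree(self.points)

    def nearest(self, positions):
        d, idx = self.tree.query(np.atleast_2d(positions))
        return d, self.kinds[idx], self.feature_ids[idx]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def puncta_summary(
    puncta: PunctaSet,
    cluster: HairCellCluster,
    basal_radius: float = 3.0,
):
    """Per-hair-cell punctum counts and areas.

    Each punctum is assigned to the nearest cell base within
    ``basal_radius`` (the approximate hair-cell basal region); equidistant
    puncta go to the lower cell index with a warning.  Returns
    (counts per cell, list of per-cell area arrays, unassigned punctum ids).
    """
    n_cells = cluster.n_cells
    counts = np.zeros(n_cells, dtype=int)
    areas: list[list[float]] = [[] for _ in range(n_cells)]
    unassigned = []
    if len(puncta) == 0:
        return counts, [np.asarray(a) for a in areas], unassigned
    axis = cluster.base_point - cluster.apex_center
    axis = axis / np.linalg.norm(axis)
    bases = []
    for c in cluster.cells:
        # extent of the ellipsoid along the apex-to-base direction
        r_dir = 1.0 / np.sqrt(((axis / c.semi_axes) ** 2).sum())
        bases.append(c.center + axis * r_dir)
    bases = np.asarray(bases)
    for i, pos in enumerate(puncta.positions):
        d = np.linalg.norm(bases - pos, axis=1)
        j = int(np.argmin(d))
        ties = np.nonzero(np.isclose(d, d[j], atol=1e-9))[0]
        if len(ties) > 1:
            warnings.warn(
                f"punctum {i} equidistant to cells {ties.tolist()}; "
                "assigned to the lowest index",
                stacklevel=2,
            )
            j = int(ties.min())
        if d[j] <= basal_radius:
            counts[j] += 1
            areas[j].append(float(puncta.areas[i]))
        else:
            unassigned.append(i)
    return counts, [np.asarray(a) for a in areas], unassigned


def assign_puncta_to_features(
    puncta: PunctaSet,
    graph: SpatialGraph,
    loops,
    terminals,
    cutoff: float = DEFAULT_ASSIGN_CUTOFF,
    index: SkeletonIndex | None = None,
) -> list[PunctaAssignment]:
    """Assign each punctum to the nearest skeleton feature.

    The nearest skeleton sample wins outright; puncta whose nearest sample
    is farther than ``cutoff`` — or lies on the trunk or an internal
    connector — are reported unassigned.
    """
    if index is None:
        index = SkeletonIndex(graph, loops, terminals)
    junctions = graph.junctions
    jpos = np.array([graph.position(n) for n in junctions]) if junctions else None
    jtree = cKDTree(jpos) if jpos is not None else None
    out = []
    if len(puncta) == 0:
        return out
    d, kinds, fids = index.nearest(puncta.positions)
    if jtree is not None:
        nd, _ = jtree.query(puncta.positions)
    else:
        nd = np.full(len(puncta), np.inf)
    for i in range(len(puncta)):
        kind, fid = kinds[i], int(fids[i])
        if d[i] > cutoff or kind not in ("loop", "bare_terminal"):
            kind, fid = "unassigned", -1
        out.append(
            PunctaAssignment(
                punctum_id=i,
                feature_kind=str(kind),
                feature_id=fid,
                skeleton_distance=float(d[i]),
                nearest_node_distance=float(nd[i]),
            )
        )
    return out


def node_distance_shell_density(
    puncta: PunctaSet,
    graph: SpatialGraph,
    n_shells: int = DEFAULT_N_SHELLS,
    radius: float = DEFAULT_SHELL_RADIUS,
) -> ShellHistogram:
    """Histogram of punctum-to-nearest-node distances over equal-volume
    concentric shells.  Puncta beyond ``radius`` go to an overflow bucket."""
    junctions = graph.junctions
    if not junctions:
        raise EmptyGraphError("graph has no junction nodes")
    if n_shells < 1 or radius <= 0:
        raise ValidationError("need n_shells >= 1 and radius > 0")
    counts = np.zeros(n_shells, dtype=int)
    overflow = 0
    if len(puncta):
        tree = cKDTree(np.array([graph.position(n) for n in junctions]))
        d, _ = tree.query(puncta.positions)
        over = d > radius
        overflow = int(over.sum())
        if overflow:
            warnings.warn(
                f"{overflow} puncta beyond the {radius} µm shell radius",
                stacklevel=2,
            )
        k = shell_index(d[~over], n_shells, radius)
        counts = np.bincount(k - 1, minlength=n_shells).astype(int)
    return ShellHistogram(n_shells=n_shells, radius=radius, counts=counts, overflow=overflow)


def loop_vs_terminal_counts(assignments) -> tuple[int, int, int]:
    """Partition of puncta: (on loops, on bare terminals, unassigned)."""
    n_loop = sum(1 for a in assignments if a.feature_kind == "loop")
    n_term = sum(1 for a in assignments if a.feature_kind == "bare_terminal")
    return n_loop, n_term, len(assignments) - n_loop - n_term
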