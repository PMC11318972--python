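"""Readers, writers and core containers for skeleton traces, hair-cell cluster
geometry and synaptic puncta tables.

All coordinates are world micrometres in a right-handed frame with
X = anteroposterior (positive posterior), Y = dorsoventral (positive ventral)
and Z = medio-lateral depth.  No pixel or voxel units cross this module's
boundary; rasterisation is internal to the spatial-metrics operations.

Supported formats
-----------------
* SWC, the standard 7-column neuron-morphology exchange format.  Structure
  type 2 (axon) flags the lateral-line trunk.
* an SNT-export CSV dialect with header ``path_id,point_index,x,y,z,radius``.
* cluster geometry JSON (``apex_center``, ``base_point``, ``cells[]`` with
  per-cell ellipsoids, optional ``boundary_mesh``).
* puncta CSV with header ``x,y,z,area_um2,channel``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    TraceParseError,
    TraceStructureError,
    ValidationError,
)

DEFAULT_NEURITE_RADIUS = 0.5  # µm, the average neurite radius

__all__ = [
    "Point3D",
    "SkeletonPath",
    "ArborTrace",
    "HairCell",
    "HairCellCluster",
    "PunctaSet",
    "read_swc",
    "write_swc",
    "read_snt_csv",
    "write_snt_csv",
    "read_cluster_json",
    "write_cluster_json",
    "read_puncta_csv",
    "write_puncta_csv",
    "polyline_length",
    "resample_polyline",
]


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Point3D:
    """A point in world micrometres."""

    x: float
    y: float
    z: float

    def __post_init__(self):
        if not np.all(np.isfinite([self.x, self.y, self.z])):
            raise ValidationError(f"non-finite coordinates: {self}")

    def to_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @staticmethod
    def from_array(a) -> "Point3D":
        a = np.asarray(a, dtype=float)
        return Point3D(float(a[0]), float(a[1]), float(a[2]))


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValidationError(f"expected an (n, 3) point array, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValidationError("non-finite coordinates in polyline")
    return pts


def polyline_length(points) -> float:
    """Arc length of a polyline given as an (n, 3) array."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def resample_polyline(points, spacing: float) -> np.ndarray:
    """Resample a polyline at uniform arc-length ``spacing`` (µm).

    Both endpoints are always retained.
    """
    pts = _as_points(points)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        return pts[:1].copy()
    n = max(int(np.ceil(total / spacing)), 1)
    grid = np.linspace(0.0, total, n + 1)
    out = np.empty((len(grid), 3))
    for d in range(3):
        out[:, d] = np.interp(grid, s, pts[:, d])
    return out


@dataclass
class SkeletonPath:
    """One unbranched 3D skeleton segment.

    ``parent_id`` names the path this one branches from (its first point lies
    on the parent), or ``None`` for a root path.  ``is_trunk`` flags the
    lateral-line branch that carries the arborization.
    """

    path_id: str
    points: np.ndarray
    parent_id: str | None = None
    radius: float = DEFAULT_NEURITE_RADIUS
    is_trunk: bool = False

    def __post_init__(self):
        self.points = _as_points(self.points)
        if len(self.points) < 2:
            raise ValidationError(f"path {self.path_id!r} has fewer than 2 points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValidationError(
                f"path {self.path_id!r} has duplicate consecutive points"
            )
        if not self.radius > 0:
            raise ValidationError(f"path {self.path_id!r} has non-positive radius")

    @property
    def length(self) -> float:
        return polyline_length(self.points)


@dataclass
class ArborTrace:
    """A traced sensory arbor network: a set of skeleton paths plus metadata."""

    paths: list[SkeletonPath]
    genotype: str = "synthetic"
    age_dpf: float = 4.0
    neuromast_id: str = "nm0"

    def __post_init__(self):
        ids = [p.path_id for p in self.paths]
        if len(set(ids)) != len(ids):
            raise TraceStructureError("duplicate path ids in trace")
        idset = set(ids)
        for p in self.paths:
            if p.parent_id is not None and p.parent_id not in idset:
                raise TraceStructureError(
                    f"path {p.path_id!r} references missing parent {p.parent_id!r}"
                )
        trunks = [p for p in self.paths if p.is_trunk]
        if len(trunks) > 1:
            raise TraceStructureError("more than one path flagged as trunk")

    @property
    def trunk(self) -> SkeletonPath | None:
        for p in self.paths:
            if p.is_trunk:
                return p
        return None

    @property
    def total_length(self) -> float:
        return float(sum(p.length for p in self.paths))

    def translated(self, offset) -> "ArborTrace":
        offset = np.asarray(offset, dtype=float)
        return ArborTrace(
            paths=[
                SkeletonPath(
                    p.path_id, p.points + offset, p.parent_id, p.radius, p.is_trunk
                )
                for p in self.paths
            ],
            genotype=self.genotype,
            age_dpf=self.age_dpf,
            neuromast_id=self.neuromast_id,
        )


@dataclass
class HairCell:
    """One hair cell modelled as an axis-aligned ellipsoid."""

    center: np.ndarray
    semi_axes: np.ndarray
    polarity: str  # "rostral" | "caudal"

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.semi_axes = np.asarray(self.semi_axes, dtype=float).reshape(3)
        if np.any(self.semi_axes <= 0):
            raise ValidationError("hair-cell semi-axes must be positive")
        if self.polarity not in ("rostral", "caudal"):
            raise ValidationError(f"unknown polarity {self.polarity!r}")


@dataclass
class HairCellCluster:
    """Hair-cell cluster geometry: apex/base axis plus per-cell ellipsoids.

    The cluster boundary is the union-of-ellipsoids surface; an explicit
    triangle mesh may be attached (``boundary_mesh`` = (vertices, faces)) but
    inside/outside and distance queries use the implicit union together with a
    sampled surface point cloud.
    """

    apex_center: np.ndarray
    base_point: np.ndarray
    cells: list[HairCell]
    boundary_mesh: tuple[np.ndarray, np.ndarray] | None = None
    _boundary_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.apex_center = np.asarray(self.apex_center, dtype=float).reshape(3)
        self.base_point = np.asarray(self.base_point, dtype=float).reshape(3)
        if np.allclose(self.apex_center, self.base_point):
            raise ValidationError("apex_center must differ from base_point")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def ellipsoid_values(self, points) -> np.ndarray:
        """Min over cells of the ellipsoid quadratic form (<=1 means inside)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if not self.cells:
            return np.full(len(pts), np.inf)
        vals = np.full(len(pts), np.inf)
        for cell in self.cells:
            q = ((pts - cell.center) / cell.semi_axes) ** 2
            vals = np.minimum(vals, q.sum(axis=1))
        return vals

    def contains(self, points) -> np.ndarray:
        """Points inside (or exactly on) the union-of-ellipsoids boundary."""
        return self.ellipsoid_values(points) <= 1.0 + 1e-12

    def boundary_points(self, spacing: float = 0.2) -> np.ndarray:
        """Quasi-uniform samples of the union-of-ellipsoids surface.

        Each ellipsoid is sampled with a Fibonacci-sphere lattice at roughly
        one point per ``spacing``² of surface; samples falling strictly inside
        another cell are discarded, leaving the outer union surface.
        """
        key = round(spacing, 6)
        if key in self._boundary_cache:
            return self._boundary_cache[key]
        from .errors import GeometryError

        if not self.cells:
            raise GeometryError("cluster has no cells: boundary undefined")
        chunks = []
        golden = np.pi * (3.0 - np.sqrt(5.0))
        for ci, cell in enumerate(self.cells):
            a, b, c = cell.semi_axes
            # Thomsen approximation of the ellipsoid surface area
            p = 1.6075
            area = 4 * np.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3) ** (1 / p)
            n = max(int(area / spacing**2), 64)
            i = np.arange(n)
            zu = 1 - 2 * (i + 0.5) / n
            r = np.sqrt(np.maximum(1 - zu**2, 0.0))
            th = golden * i
            unit = np.stack([r * np.cos(th), r * np.sin(th), zu], axis=1)
            surf = cell.center + unit * cell.semi_axes
            keep = np.ones(len(surf), dtype=bool)
            for cj, other in enumerate(self.cells):
                if cj == ci:
                    continue
                q = (((surf - other.center) / other.semi_axes) ** 2).sum(axis=1)
                keep &= q >= 1.0 - 1e-9
            chunks.append(surf[keep])
        pts = np.concatenate(chunks, axis=0)
        self._boundary_cache[key] = pts
        return pts

    def distance_to_boundary(self, points, spacing: float = 0.1) -> np.ndarray:
        """Unsigned distance to the sampled union boundary surface."""
        from scipy.spatial import cKDTree

        cloud = self.boundary_points(spacing)
        tree = cKDTree(cloud)
        d, _ = tree.query(np.atleast_2d(np.asarray(points, dtype=float)))
        return d

    def translated(self, offset) -> "HairCellCluster":
        offset = np.asarray(offset, dtype=float)
        mesh = None
        if self.boundary_mesh is not None:
            mesh = (self.boundary_mesh[0] + offset, self.boundary_mesh[1])
        return HairCellCluster(
            apex_center=self.apex_center + offset,
            base_point=self.base_point + offset,
            cells=[
                HairCell(c.center + offset, c.semi_axes.copy(), c.polarity)
                for c in self.cells
            ],
            boundary_mesh=mesh,
        )


@dataclass
class PunctaSet:
    """Synaptic puncta: positions (n, 3), areas (µm²) and channel labels."""

    positions: np.ndarray
    areas: np.ndarray
    channels: list[str]

    def __post_init__(self):
        self.positions = _as_points(self.positions) if len(self.positions) else np.zeros((0, 3))
        self.areas = np.asarray(self.areas, dtype=float).reshape(-1)
        if len(self.areas) != len(self.positions) or len(self.channels) != len(self.positions):
            raise ValidationError("positions, areas and channels must align")
        if np.any(self.areas < 0):
            raise ValidationError("puncta areas must be non-negative")

    def __len__(self) -> int:
        return len(self.positions)

    def select_channel(self, channel: str) -> "PunctaSet":
        mask = np.array([c == channel for c in self.channels], dtype=bool)
        return PunctaSet(
            self.positions[mask],
            self.areas[mask],
            [c for c, m in zip(self.channels, mask) if m],
        )


# ---------------------------------------------------------------------------
# SWC
# ---------------------------------------------------------------------------

_TRUNK_SWC_TYPE = 2  # SWC structure code "axon" marks the lateral-line trunk


def read_swc(path, scale: float = 1.0) -> ArborTrace:
    """Read a 7-column SWC file into an :class:`ArborTrace`.

    The sample tree is cut into unbranched segments: a new path starts at
    every root and at every child of a branch point, and each non-root path's
    first point is its parent sample (so segment geometry is connected).
    Units are assumed µm; ``scale`` multiplies coordinates on input.
    """
    samples: dict[int, tuple[int, np.ndarray, float, int]] = {}
    order: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) != 7:
                raise TraceParseError(f"expected 7 columns, got {len(cols)}", lineno)
            try:
                sid = int(cols[0])
                stype = int(cols[1])
                xyz = np.array([float(cols[2]), float(cols[3]), float(cols[4])]) * scale
                radius = float(cols[5])
                parent = int(cols[6])
            except ValueError as exc:
                raise TraceParseError(str(exc), lineno) from None
            if sid in samples:
                raise TraceParseError(f"duplicate sample id {sid}", lineno)
            samples[sid] = (stype, xyz, radius, parent)
            order.append(sid)
    if not samples:
        raise TraceParseError("no samples in SWC file")
    children: dict[int, list[int]] = {sid: [] for sid in samples}
    roots = []
    for sid in order:
        parent = samples[sid][3]
        if parent == -1:
            roots.append(sid)
        else:
            if parent not in samples:
                raise TraceStructureError(
                    f"sample {sid} references missing parent {parent}"
                )
            children[parent].append(sid)

    # segment starts: roots, and every child of a node with >1 children
    paths: list[SkeletonPath] = []
    sample_to_path: dict[int, str] = {}
    stack = [(sid, None) for sid in reversed(roots)]  # (start sample, parent path)
    while stack:
        start, parent_path = stack.pop()
        pid = f"p{len(paths)}"
        seg_samples = []
        node = start
        if parent_path is not None:
            parent_sample = samples[start][3]
            seg_points = [samples[parent_sample][1]]
        else:
            seg_points = []
        types = []
        radii = []
        while True:
            seg_samples.append(node)
            stype, xyz, radius, _ = samples[node]
            seg_points.append(xyz)
            types.append(stype)
            radii.append(radius)
            ch = children[node]
            # a segment continues through single children of the same
            # structure type; branch points and type changes start new paths
            if len(ch) == 1 and samples[ch[0]][0] == stype:
                node = ch[0]
            else:
                for c in reversed(ch):
                    stack.append((c, pid))
                break
        pts = np.asarray(seg_points)
        # drop exact consecutive duplicates (SWC sometimes repeats samples)
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 0
        pts = pts[keep]
        if len(pts) < 2:
            # a lone root sample with a single child collapses into the child
            continue
        paths.append(
            SkeletonPath(
                path_id=pid,
                points=pts,
                parent_id=parent_path,
                radius=float(np.median(radii)) if np.median(radii) > 0 else DEFAULT_NEURITE_RADIUS,
                is_trunk=all(t == _TRUNK_SWC_TYPE for t in types),
            )
        )
        for s in seg_samples:
            sample_to_path[s] = pid
    return ArborTrace(paths=paths)


def write_swc(trace: ArborTrace, path) -> None:
    """Write an :class:`ArborTrace` as SWC.

    Each path is written as a sample chain; a child path's first point (which
    lies on its parent) is not re-emitted — its samples link to the matching
    parent sample instead, so ``read_swc(write_swc(t))`` reproduces ``t``.
    """
    lines = ["# SWC export (arbornet); coordinates in µm"]
    next_id = 1
    # map (path_id, point index) -> sample id for parent lookups
    sample_ids: dict[tuple[str, int], int] = {}
    by_id = {p.path_id: p for p in trace.paths}
    for p in trace.paths:
        stype = _TRUNK_SWC_TYPE if p.is_trunk else 0
        start = 0
        parent_sample = -1
        if p.parent_id is not None:
            parent = by_id[p.parent_id]
            d = np.linalg.norm(parent.points - p.points[0], axis=1)
            j = int(np.argmin(d))
            parent_sample = sample_ids[(parent.path_id, j)]
            start = 1
        prev = parent_sample
        for i in range(start, len(p.points)):
            x, y, z = (float(v) for v in p.points[i])
            lines.append(
                f"{next_id} {stype} {x!r} {y!r} {z!r} {float(p.radius)!r} {prev}"
            )
            sample_ids[(p.path_id, i)] = next_id
            prev = next_id
            next_id += 1
        if start == 1:
            sample_ids[(p.path_id, 0)] = parent_sample
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# SNT CSV dialect
# ---------------------------------------------------------------------------

_SNT_COLUMNS = ["path_id", "point_index", "x", "y", "z", "radius"]


def read_snt_csv(path, scale: float = 1.0) -> ArborTrace:
    """Read the SNT-export CSV dialect (columns ``path_id,point_index,x,y,z,radius``).

    ``scale`` converts voxel exports to µm when the tracing was not calibrated
    to world units.
    """
    df = pd.read_csv(path)
    missing = [c for c in _SNT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"SNT CSV missing columns: {missing}")
    paths = []
    for pid, grp in df.groupby("path_id", sort=True):
        idx = grp["point_index"].to_numpy()
        if np.any(np.diff(idx) <= 0):
            raise FormatError(f"non-monotone point_index in path {pid!r}")
        pts = grp[["x", "y", "z"]].to_numpy(dtype=float) * scale
        radius = float(grp["radius"].iloc[0])
        paths.append(SkeletonPath(path_id=str(pid), points=pts, radius=radius))
    return ArborTrace(paths=paths)


def write_snt_csv(trace: ArborTrace, path) -> None:
    rows = []
    for p in trace.paths:
        for i, (x, y, z) in enumerate(p.points):
            rows.append(
                (p.path_id, i, repr(float(x)), repr(float(y)), repr(float(z)),
                 repr(float(p.radius)))
            )
    with open(path, "w") as fh:
        fh.write(",".join(_SNT_COLUMNS) + "\n")
        for r in rows:
            fh.write(",".join(str(v) for v in r) + "\n")


# ---------------------------------------------------------------------------
# cluster JSON
# ---------------------------------------------------------------------------

def read_cluster_json(path) -> HairCellCluster:
    with open(path) as fh:
        doc = json.load(fh)
    try:
        apex = np.asarray(doc["apex_center"], dtype=float)
        base = np.asarray(doc["base_point"], dtype=float)
        cells = [
            HairCell(
                center=np.asarray(c["center"], dtype=float),
                semi_axes=np.asarray(c["semi_axes"], dtype=float),
                polarity=c["polarity"],
            )
            for c in doc["cells"]
        ]
    except (KeyError, TypeError) as exc:
        raise FormatError(f"cluster JSON schema violation: {exc}") from None
    mesh = None
    if doc.get("boundary_mesh") is not None:
        m = doc["boundary_mesh"]
        mesh = (
            np.asarray(m["vertices"], dtype=float),
            np.asarray(m["faces"], dtype=int),
        )
    return HairCellCluster(apex_center=apex, base_point=base, cells=cells, boundary_mesh=mesh)


def write_cluster_json(cluster: HairCellCluster, path) -> None:
    doc = {
        "apex_center": list(cluster.apex_center),
        "base_point": list(cluster.base_point),
        "cells": [
            {
                "center": list(c.center),
                "semi_axes": list(c.semi_axes),
                "polarity": c.polarity,
            }
            for c in cluster.cells
        ],
        "boundary_mesh": None
        if cluster.boundary_mesh is None
        else {
            "vertices": cluster.boundary_mesh[0].tolist(),
            "faces": cluster.boundary_mesh[1].tolist(),
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


# ---------------------------------------------------------------------------
# puncta CSV
# ---------------------------------------------------------------------------

_PUNCTA_COLUMNS = ["x", "y", "z", "area_um2", "channel"]


def read_puncta_csv(path) -> PunctaSet:
    df = pd.read_csv(path)
    missing = [c for c in _PUNCTA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"puncta CSV missing columns: {missing}")
    if len(df) and (df["area_um2"] < 0).any():
        raise ValidationError("negative area in puncta CSV")
    return PunctaSet(
        positions=df[["x", "y", "z"]].to_numpy(dtype=float),
        areas=df["area_um2"].to_numpy(dtype=float),
        channels=[str(c) for c in df["channel"]],
    )


def write_puncta_csv(puncta: PunctaSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(",".join(_PUNCTA_COLUMNS) + "\n")
        for (x, y, z), a, ch in zip(puncta.positions, puncta.areas, puncta.channels):
            fh.write(
                f"{float(x)!r},{float(y)!r},{float(z)!r},{float(a)!r},{ch}\n"
            )
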