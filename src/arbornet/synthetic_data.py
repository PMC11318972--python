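"""Synthetic neuromast arborizations with known ground truth.

The generator emulates the geometry this package analyses: a hair-cell
cluster (ellipsoidal cells on a rosette with alternating planar polarity), a
lateral-line trunk arriving at an arborization point beneath the cluster,
closed arbor loops hugging the cluster boundary, bare terminals radiating
outward with prescribed total curvature, synaptic puncta placed on known
features, and toy 2D+T stacks for dwell-time maps.

Two presets capture the two study conditions:

* ``control_like`` — loop-rich networks; short arbors (< 10 µm) always form
  bare terminals and long arbors (> 30 µm) always form loops; a slight
  majority (55.2%) of terminals is highly curved (total curvature > pi/6)
  and arbors stay within ~34 µm of the organ center.
* ``mutant_like`` — terminal-rich networks with a broader loop-length
  distribution, a majority (56.4%) of low-curvature terminals, and wayward
  projections extending to ~57 µm.

Every structure is built from exact parametric primitives (circles and
circular arcs), so loop counts/lengths, terminal lengths/curvatures, puncta
feature labels and the arbor-cluster contact fraction are known by
construction.  Placement is collision-checked: distinct structures keep a
clearance well above the 0.5 µm crossing-merge scale except near their
designed attachment points, so the analysis pipeline recovers the ground
truth exactly.  All randomness flows through one ``numpy`` PCG64 generator
seeded from ``config.seed``; a fixed seed reproduces the output bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .curvature import classify_curvature
from .errors import ConfigError
from .trace_io import (
    ArborTrace,
    HairCell,
    HairCellCluster,
    PunctaSet,
    SkeletonPath,
    polyline_length,
)

MIN_SEPARATION = 1.2     # µm clearance between unrelated structures
ATTACH_FREE_RADIUS = 2.5  # µm around an attachment point exempt from clearance
RING_SAMPLE_SPACING = 0.3  # µm along loop arcs
TERMINAL_SAMPLE_SPACING = 0.25
PUNCTA_NODE_CLEARANCE = 1.2  # µm min arc distance of a punctum from a junction

__all__ = [
    "GeneratorConfig",
    "FeaturePlan",
    "GroundTruth",
    "preset_config",
    "sample_feature_plan",
    "generate_cluster",
    "generate_arbor_network",
    "generate_puncta",
    "generate_dwell_stack",
    "generate_neuromast",
]


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic neuromast generator."""

    seed: int = 0
    preset: str = "custom"
    n_hair_cells: int = 12            # cohort mean; per-organ counts jitter
    cluster_radius: float = 10.0      # µm
    n_arbors: float = 9.3             # mean number of loop/terminal arbors
    arbor_length_range: tuple[float, float] = (5.0, 55.0)
    # probability that an arbor of a given contour length forms a loop
    loop_probability_by_length: dict[tuple[float, float], float] = field(
        default_factory=lambda: {
            (0.0, 10.0): 0.0,
            (10.0, 20.0): 0.3,
            (20.0, 30.0): 0.75,
            (30.0, 40.0): 1.0,
            (40.0, 70.0): 1.0,
        }
    )
    # (fraction of high-curvature terminals, high range, low range) [radians]
    terminal_curvature_mix: tuple[float, tuple[float, float], tuple[float, float]] = (
        0.552,
        (0.75, 2.6),
        (0.05, 0.42),
    )
    radial_extent: float = 34.0       # µm soft cap on terminal reach
    # radial offset of a loop's inner edge from the cluster boundary:
    # negative values let loops ride the basolateral surface (contact-rich)
    loop_surface_offset: float = -0.3
    nodes_per_loop: int = 4
    n_puncta: int = 36
    puncta_loop_fraction: float = 531.0 / 567.0
    puncta_jitter: float = 0.15       # µm positional noise

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def preset_config(preset: str, seed: int = 0, **overrides) -> GeneratorConfig:
    """Build a :class:`GeneratorConfig` for a named study condition."""
    if preset == "control_like":
        cfg = GeneratorConfig(seed=seed, preset=preset)
    elif preset == "mutant_like":
        cfg = GeneratorConfig(
            seed=seed,
            preset=preset,
            n_hair_cells=11,
            n_arbors=8.5,
            loop_probability_by_length={
                (0.0, 10.0): 0.0,
                (10.0, 20.0): 0.05,
                (20.0, 30.0): 0.3,
                (30.0, 40.0): 0.45,
                (40.0, 70.0): 0.55,
            },
            terminal_curvature_mix=(0.436, (0.75, 2.2), (0.05, 0.42)),
            radial_extent=57.0,
            loop_surface_offset=0.8,
            nodes_per_loop=3,
            n_puncta=18,
            puncta_loop_fraction=0.75,
        )
    elif preset == "custom":
        cfg = GeneratorConfig(seed=seed, preset=preset)
    else:
        raise ConfigError(f"unknown preset {preset!r}")
    return replace(cfg, **overrides) if overrides else cfg


def _validate(cfg: GeneratorConfig) -> None:
    if cfg.cluster_radius <= 0:
        raise ConfigError("cluster_radius must be positive")
    if cfg.n_hair_cells < 2:
        raise ConfigError("need at least 2 hair cells")
    for p in cfg.loop_probability_by_length.values():
        if not 0.0 <= p <= 1.0:
            raise ConfigError("loop probabilities must lie in [0, 1]")
    frac_high = cfg.terminal_curvature_mix[0]
    if not 0.0 <= frac_high <= 1.0:
        raise ConfigError("fraction of high-curvature terminals must lie in [0, 1]")


# ---------------------------------------------------------------------------
# feature plan (the statistical layer, geometry-free)
# ---------------------------------------------------------------------------

@dataclass
class FeaturePlan:
    """Sampled arbor features before geometric realization."""

    kinds: list[str]                 # "loop" | "terminal" per arbor
    lengths: np.ndarray              # planned contour length, µm
    curvatures: np.ndarray           # radians (NaN for loops)

    @property
    def n_loops(self) -> int:
        return sum(1 for k in self.kinds if k == "loop")

    @property
    def n_terminals(self) -> int:
        return sum(1 for k in self.kinds if k == "terminal")

    def loop_lengths(self) -> np.ndarray:
        return self.lengths[[k == "loop" for k in self.kinds]]

    def terminal_lengths(self) -> np.ndarray:
        return self.lengths[[k == "terminal" for k in self.kinds]]

    def terminal_curvatures(self) -> np.ndarray:
        return self.curvatures[[k == "terminal" for k in self.kinds]]


def sample_feature_plan(
    cfg: GeneratorConfig, rng: np.random.Generator | None = None
) -> FeaturePlan:
    """Draw the loop/terminal mix of one neuromast.

    Arbor contour lengths are uniform over ``arbor_length_range``; each arbor
    becomes a loop with the probability of its length bin, otherwise a bare
    terminal whose total curvature is drawn from the configured
    high/low-curvature mixture.
    """
    _validate(cfg)
    rng = cfg.rng() if rng is None else rng
    n = max(2, int(rng.poisson(cfg.n_arbors)))
    lo, hi = cfg.arbor_length_range
    lengths = rng.uniform(lo, hi, size=n)
    frac_high, high_rng, low_rng = cfg.terminal_curvature_mix
    kinds = []
    curvatures = np.full(n, np.nan)
    bins = sorted(cfg.loop_probability_by_length.items())
    for i, L in enumerate(lengths):
        p = 0.0
        for (b_lo, b_hi), pb in bins:
            if b_lo <= L < b_hi:
                p = pb
                break
        else:
            p = bins[-1][1] if L >= bins[-1][0][1] else bins[0][1]
        if rng.uniform() < p:
            kinds.append("loop")
        else:
            kinds.append("terminal")
            if rng.uniform() < frac_high:
                curvatures[i] = rng.uniform(*high_rng)
            else:
                curvatures[i] = rng.uniform(*low_rng)
    return FeaturePlan(kinds=kinds, lengths=lengths, curvatures=curvatures)


# ---------------------------------------------------------------------------
# ground truth container
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """What the generator actually built, measured on the emitted geometry.

    Lengths are realized polyline arc lengths (the quantity the analysis
    pipeline measures), not the planned analytic lengths.  The geometry
    fields (``loop_geometry``, ``terminal_geometry``) hold the realized
    polylines and anchor positions for puncta placement and are not
    serialized by :meth:`to_json`.
    """

    loop_lengths: list[float] = field(default_factory=list)
    loop_node_counts: list[int] = field(default_factory=list)
    terminal_lengths: list[float] = field(default_factory=list)
    terminal_curvatures: list[float] = field(default_factory=list)
    terminal_classes: list[str] = field(default_factory=list)
    contact_fraction: float = np.nan
    puncta_kinds: list[str] = field(default_factory=list)
    puncta_feature_ids: list[int] = field(default_factory=list)
    loop_geometry: list[dict] = field(default_factory=list, repr=False)
    terminal_geometry: list[dict] = field(default_factory=list, repr=False)

    @property
    def n_loops(self) -> int:
        return len(self.loop_lengths)

    @property
    def n_terminals(self) -> int:
        return len(self.terminal_lengths)

    def to_json(self, path) -> None:
        doc = {
            "n_loops": self.n_loops,
            "n_terminals": self.n_terminals,
            "loop_lengths": self.loop_lengths,
            "loop_node_counts": self.loop_node_counts,
            "terminal_lengths": self.terminal_lengths,
            "terminal_curvatures": self.terminal_curvatures,
            "terminal_classes": self.terminal_classes,
            "contact_fraction": self.contact_fraction,
            "puncta_kinds": self.puncta_kinds,
            "puncta_feature_ids": self.puncta_feature_ids,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


# ---------------------------------------------------------------------------
# cluster
# ---------------------------------------------------------------------------

def generate_cluster(
    cfg: GeneratorConfig, rng: np.random.Generator | None = None
) -> HairCellCluster:
    """Hair cells on a rosette with alternating rostral/caudal polarity.

    Cells are upright ellipsoids centered on a ring at ~55% of the cluster
    radius; the apex sits above the rosette centroid at the mean cell top,
    the base (arborization initiation point) symmetrically below.
    """
    _validate(cfg)
    rng = cfg.rng() if rng is None else rng
    n = max(2, int(round(rng.normal(cfg.n_hair_cells, 1.2) / 2.0)) * 2)
    ring = 0.55 * cfg.cluster_radius
    cells = []
    tops = []
    for i in range(n):
        phi = 2 * np.pi * i / n + rng.normal(0, 0.04)
        rad = ring * (1 + rng.normal(0, 0.05))
        center = np.array(
            [rad * np.cos(phi), rad * np.sin(phi), rng.normal(0, 0.3)]
        )
        semi = np.array([2.3, 2.3, 5.5]) * (1 + rng.uniform(-0.08, 0.08, size=3))
        cells.append(
            HairCell(center=center, semi_axes=semi,
                     polarity="rostral" if i % 2 == 0 else "caudal")
        )
        tops.append(center[2] + semi[2])
    top = float(np.mean(tops))
    return HairCellCluster(
        apex_center=np.array([0.0, 0.0, top]),
        base_point=np.array([0.0, 0.0, -top]),
        cells=cells,
    )


# ---------------------------------------------------------------------------
# geometric primitives
# ---------------------------------------------------------------------------

def _arc_polyline(start, direction, normal, length, turn, spacing):
    """Circular arc from ``start`` with initial unit ``direction``, turning
    by ``turn`` radians toward unit ``normal`` over ``length`` µm."""
    n_pts = max(int(np.ceil(length / spacing)), 4) + 1
    s = np.linspace(0.0, length, n_pts)
    if turn < 1e-6:
        return start + np.outer(s, direction)
    rho = length / turn
    ang = s / rho
    return start + rho * (
        np.outer(np.sin(ang), direction) + np.outer(1 - np.cos(ang), normal)
    )


def _ring_arcs(center, e1, e2, radius, anchor_angles, spacing):
    """Closed ring in the plane (e1, e2) split into arcs between anchors.

    Returns (list of arc polylines, anchor positions); consecutive arcs share
    their endpoint coordinates exactly.
    """
    anchors = [
        center + radius * (np.cos(a) * e1 + np.sin(a) * e2) for a in anchor_angles
    ]
    arcs = []
    m = len(anchor_angles)
    for i in range(m):
        a0 = anchor_angles[i]
        a1 = anchor_angles[(i + 1) % m]
        if a1 <= a0:
            a1 += 2 * np.pi
        arclen = radius * (a1 - a0)
        n_pts = max(int(np.ceil(arclen / spacing)), 6) + 1
        ang = np.linspace(a0, a1, n_pts)
        pts = center + radius * (
            np.outer(np.cos(ang), e1) + np.outer(np.sin(ang), e2)
        )
        pts[0] = anchors[i]
        pts[-1] = anchors[(i + 1) % m]
        arcs.append(pts)
    return arcs, anchors


class _CollisionField:
    """Accumulated point cloud of accepted structures for clearance checks.

    Two clearance tiers keep the analysis-time crossing detector (merge
    tolerance 0.5 µm, with contacts within 1 µm of a shared vertex treated
    as genuine junctions) from fusing structures the generator meant to be
    distinct:

    * points within 1 µm of the structure's own attachment anchor are exempt
      (the analysis skips those contacts as junction geometry);
    * points between 1 µm and ``ATTACH_FREE_RADIUS`` of the anchor must keep
      a reduced clearance (> the 0.5 µm merge scale);
    * points farther out must keep the full ``MIN_SEPARATION``.
    """

    # strictly inside the analysis skip window (2 x 0.5 µm) so boundary
    # contacts are still subject to the clearance requirement
    INNER_EXEMPT = 0.8
    NEAR_CLEARANCE = 0.70   # µm required in the near-anchor band
    NEAR_CLEARANCE_HARD = 0.62
    FAR_CLEARANCE_HARD = 0.85

    def __init__(self):
        self.points = np.zeros((0, 3))
        self.tree = None

    def margins(self, pts, exempt_centers):
        """(near-band clearance, far clearance) of a candidate structure."""
        if self.tree is None:
            return np.inf, np.inf
        pts = np.asarray(pts)
        danchor = np.full(len(pts), np.inf)
        for c in exempt_centers:
            danchor = np.minimum(danchor, np.linalg.norm(pts - c, axis=1))
        near = (danchor > self.INNER_EXEMPT) & (danchor <= ATTACH_FREE_RADIUS)
        far = danchor > ATTACH_FREE_RADIUS
        d_near = d_far = np.inf
        if near.any():
            d, _ = self.tree.query(pts[near])
            d_near = float(d.min())
        if far.any():
            d, _ = self.tree.query(pts[far])
            d_far = float(d.min())
        return d_near, d_far

    def accepts(self, pts, exempt_centers):
        d_near, d_far = self.margins(pts, exempt_centers)
        ok = d_near >= self.NEAR_CLEARANCE and d_far >= MIN_SEPARATION
        hard_ok = d_near >= self.NEAR_CLEARANCE_HARD and d_far >= self.FAR_CLEARANCE_HARD
        score = min(d_near - self.NEAR_CLEARANCE, d_far - MIN_SEPARATION)
        return ok, hard_ok, score

    def add(self, pts):
        self.points = np.concatenate([self.points, np.asarray(pts)], axis=0)
        self.tree = cKDTree(self.points)


# ---------------------------------------------------------------------------
# network generation
# ---------------------------------------------------------------------------

def generate_arbor_network(
    cfg: GeneratorConfig,
    cluster: HairCellCluster,
    rng: np.random.Generator | None = None,
    plan: FeaturePlan | None = None,
) -> tuple[ArborTrace, GroundTruth]:
    """Realize a feature plan as 3D skeleton geometry around a cluster.

    Loops become closed rings in vertical planes tangent to the cluster,
    threaded through ``nodes_per_loop`` anchor junctions and attached to the
    arborization point by one bridge each; bare terminals are circular arcs
    of prescribed total curvature attached at free ring anchors
    (neediest-ring first) or directly at the arborization point, oriented
    perpendicular to the ring plane so junction geometry stays unambiguous.
    """
    _validate(cfg)
    rng = cfg.rng() if rng is None else rng
    if plan is None:
        plan = sample_feature_plan(cfg, rng)
    base = cluster.base_point.copy()
    apex = cluster.apex_center.copy()

    loop_lengths = plan.loop_lengths()
    term_lengths = plan.terminal_lengths()
    term_curv = plan.terminal_curvatures()
    for L in loop_lengths:
        if L / (2 * np.pi) < 1.2:
            raise ConfigError(
                f"loop of length {L:.1f} µm is below the feasible ring size"
            )

    field_ = _CollisionField()
    paths: list[SkeletonPath] = []
    truth = GroundTruth()

    def add_path(pts, is_trunk=False, radius=0.5):
        pid = f"p{len(paths)}"
        paths.append(SkeletonPath(path_id=pid, points=pts, radius=radius, is_trunk=is_trunk))
        return pid

    # ---- trunk: posterior lateral-line branch arriving from anterior -----
    t_dir = np.array([-1.0, 0.12, -0.08])
    t_dir /= np.linalg.norm(t_dir)
    s = np.linspace(0.0, 42.0, 43)
    wiggle = 0.8 * np.sin(s / 9.0)
    perp = np.array([0.0, 0.0, 1.0])
    trunk_pts = base + np.outer(s, t_dir) + np.outer(wiggle, perp)
    trunk_pts[0] = base
    add_path(trunk_pts[::-1], is_trunk=True)
    field_.add(trunk_pts)

    # ---- attachment budget -----------------------------------------------
    # The base can only host a limited number of structures before their
    # launch directions converge too closely (risking spurious crossing
    # fusions at analysis time).  At most 5 ring bridges leave the base;
    # further rings chain from earlier rings' anchors.  Terminals prefer
    # free ring anchors, then base slots up to the budget, then attachment
    # points spaced along the trunk.
    n_loops = len(loop_lengths)
    n_terms = len(term_lengths)
    n_base_rings = min(n_loops, 5)
    n_chained = n_loops - n_base_rings
    free_ring_slots = n_loops * (cfg.nodes_per_loop - 1) - n_chained
    n_overflow = max(0, n_terms - max(free_ring_slots, 0))
    n_base_terms = min(n_overflow, max(0, 6 - n_base_rings))
    trunk_az = np.pi
    margin = np.deg2rad(50.0)
    avail = 2 * np.pi - 2 * margin
    # rings spread over the non-trunk arc; petal azimuths for chained rings
    # interleave between base slots
    k_base = n_base_rings + n_base_terms
    base_az = [
        (trunk_az + margin + (i + 0.5) * avail / max(k_base, 1)) % (2 * np.pi)
        for i in range(k_base)
    ]
    ring_az = base_az[:n_base_rings] + [
        (trunk_az + margin + (j + 1) * avail / max(n_chained + 1, 1)) % (2 * np.pi)
        for j in range(n_chained)
    ]
    slot_az = ring_az  # petal azimuth per ring index

    # ---- loops -----------------------------------------------------------
    # radial extent of the cluster surface vs height, so each ring's inner
    # edge can be placed just outside the boundary
    cloud = cluster.boundary_points(0.3)
    cloud_rad = np.linalg.norm(cloud[:, :2], axis=1)

    def surface_radius_at(z):
        band = np.abs(cloud[:, 2] - z) < 0.8
        return float(cloud_rad[band].max()) if band.any() else 0.55 * cfg.cluster_radius + 2.3

    # Each ring lies in the radial-vertical ("petal") plane of its azimuth
    # slot, tangent to the cluster from outside: petals at different azimuths
    # only approach each other near the organ axis, which the geometry keeps
    # clear, so even large loops coexist without fusing.
    ring_attach_counts = []   # attachments per ring (bridge + terminals)
    ring_free_anchors = []    # (anchor position, outward direction) still free
    ring_records = []
    for li, L in enumerate(loop_lengths):
        r = L / (2 * np.pi)
        best = (-np.inf, None)
        for attempt in range(90):
            phi = slot_az[li] + rng.normal(0, 0.04)
            z_c = rng.uniform(-1.5, 2.5) if li < n_base_rings else rng.uniform(-3.0, 4.0)
            e_r = np.array([np.cos(phi), np.sin(phi), 0.0])
            e_t = np.array([-np.sin(phi), np.cos(phi), 0.0])
            e_z = np.array([0.0, 0.0, 1.0])
            rho_c = surface_radius_at(z_c) + cfg.loop_surface_offset + r + rng.uniform(0, 0.4)
            if li >= n_base_rings:
                # chained rings occupy an outer tier between the base petals
                rho_c += 6.0 + rng.uniform(0, 2.0)
            center = rho_c * e_r + z_c * e_z
            start = rng.uniform(0, 2 * np.pi)
            angles = sorted((start + 2 * np.pi * j / cfg.nodes_per_loop) % (2 * np.pi)
                            for j in range(cfg.nodes_per_loop))
            arcs, anchors = _ring_arcs(center, e_r, e_z, r, angles, RING_SAMPLE_SPACING)
            if li < n_base_rings:
                origin = base
                parent = None
            else:
                # chain from the nearest free anchor of an earlier ring
                cand_anchors = [
                    (ri, ai, pos)
                    for ri in range(li)
                    for ai, (pos, _d) in enumerate(ring_free_anchors[ri])
                ]
                if not cand_anchors:
                    raise ConfigError("no free anchors left to chain a loop from")
                near = min(anchors, key=lambda a: np.linalg.norm(a - base))
                parent = min(
                    cand_anchors, key=lambda c: np.linalg.norm(c[2] - near)
                )
                origin = parent[2]
            bridge_anchor = min(anchors, key=lambda a: np.linalg.norm(a - origin))
            len_b = float(np.linalg.norm(bridge_anchor - origin))
            n_b = max(int(np.ceil(len_b / 0.25)), 2) + 1
            t_par = np.linspace(0.0, 1.0, n_b)
            # bow the bridge out of the petal plane so it cannot graze the
            # ring tangentially beyond the anchor's junction window; the bow
            # is tapered near the base so neighbouring bridges do not close
            # the azimuth gap where they all converge
            bow = (0.9 if rng.uniform() < 0.5 else -0.9) * np.sin(np.pi * t_par)
            bow *= np.clip(t_par * len_b / 2.5, 0.0, 1.0)
            bridge = origin + np.outer(t_par, bridge_anchor - origin) + np.outer(bow, e_t)
            bridge[0], bridge[-1] = origin, bridge_anchor
            cand = np.concatenate(arcs + [bridge], axis=0)
            ok, hard_ok, score = field_.accepts(cand, [origin, bridge_anchor])
            # bridge vs own ring: beyond the 1 µm junction window around the
            # shared anchor, keep them clearly apart
            ring_pts = np.concatenate(arcs, axis=0)
            bm = np.linalg.norm(bridge - bridge_anchor, axis=1) > _CollisionField.INNER_EXEMPT
            am = np.linalg.norm(ring_pts - bridge_anchor, axis=1) > _CollisionField.INNER_EXEMPT
            if bm.any() and am.any():
                d_self, _ = cKDTree(ring_pts[am]).query(bridge[bm])
                d_self = float(d_self.min())
            else:
                d_self = np.inf
            ok = ok and d_self >= _CollisionField.NEAR_CLEARANCE
            hard_ok = hard_ok and d_self >= _CollisionField.NEAR_CLEARANCE_HARD
            score = min(score, d_self - _CollisionField.NEAR_CLEARANCE)
            if score > best[0] and hard_ok:
                best = (score, (arcs, anchors, bridge, bridge_anchor, e_t, phi, parent))
            if ok:
                break
        if best[1] is None:
            raise ConfigError(f"could not place loop {li} without risking fusion")
        score, (arcs, anchors, bridge, bridge_anchor, e_t, phi, parent) = best
        if parent is not None:
            ring_free_anchors[parent[0]].pop(parent[1])
            ring_attach_counts[parent[0]] += 1
        # terminals leave the petal plane along its normal (into the azimuth
        # gap between petals), alternating side per anchor
        side = 1 if rng.uniform() < 0.5 else -1

        for a in arcs:
            add_path(a)
        add_path(bridge)
        field_.add(np.concatenate(arcs + [bridge], axis=0))
        realized = float(sum(polyline_length(a) for a in arcs))
        truth.loop_lengths.append(realized)
        ring_attach_counts.append(1)
        free = []
        for j, a in enumerate(anchors):
            if np.linalg.norm(a - bridge_anchor) <= 1e-9:
                continue
            free.append((a, side * (-1) ** j * e_t))
        ring_free_anchors.append(free)
        anchor_arcpos = _anchor_arc_positions(arcs, anchors)
        ring_records.append(
            {"arcs": arcs, "anchors": anchors, "azimuth": phi,
             "closed_polyline": np.concatenate(
                 [arcs[i][:-1] for i in range(len(arcs))] + [arcs[-1][-1:]], axis=0),
             "anchor_arcpos": anchor_arcpos}
        )
        truth.loop_geometry.append(ring_records[-1])

    # ---- terminals -------------------------------------------------------
    order = np.argsort(-term_lengths)  # place long terminals first
    base_slots = list(base_az[n_base_rings:])  # n_base_terms azimuths
    # overflow beyond the base budget sprouts from points along the trunk
    trunk_fwd = trunk_pts  # oriented base -> distal
    n_trunk_used = 0
    for rank, ti in enumerate(order):
        L = float(term_lengths[ti])
        turn = float(term_curv[ti])
        # fill rings toward nodes_per_loop junctions before overflowing to
        # the base: pick the lowest-index ring with a free anchor
        ring_choice = None
        candidates = [i for i in range(n_loops) if ring_free_anchors[i]]
        if candidates:
            ring_choice = candidates[0]
        if ring_choice is not None:
            anchor, out_dir = ring_free_anchors[ring_choice].pop(0)
        elif base_slots:
            anchor = base
            phi = base_slots.pop(0)
            # stagger launch elevations so neighbouring base terminals
            # diverge in 3D, not just in azimuth
            z_tilt = -0.45 + 0.35 * (rank % 3)
            out_dir = np.array([np.cos(phi), np.sin(phi), z_tilt])
            out_dir /= np.linalg.norm(out_dir)
        else:
            # attachment point on the trunk, 4 µm apart, launch directions
            # rotated around the trunk by a golden-angle schedule
            idx = 4 * (n_trunk_used + 1)
            if idx >= len(trunk_fwd) - 2:
                idx = (4 * (n_trunk_used + 1)) % (len(trunk_fwd) - 3) + 2
            anchor = trunk_fwd[idx]
            tdir = trunk_fwd[idx + 1] - trunk_fwd[idx - 1]
            tdir /= np.linalg.norm(tdir)
            ref = np.array([0.0, 0.0, 1.0])
            n1 = np.cross(tdir, ref)
            n1 /= np.linalg.norm(n1)
            n2 = np.cross(tdir, n1)
            psi = 2.399963 * n_trunk_used  # golden angle
            out_dir = np.cos(psi) * n1 + np.sin(psi) * n2
            n_trunk_used += 1
        pts = _place_terminal(cfg, rng, field_, anchor, out_dir, L, turn)
        add_path(pts)
        field_.add(pts)
        if ring_choice is not None:
            ring_attach_counts[ring_choice] += 1
        truth.terminal_lengths.append(float(polyline_length(pts)))
        truth.terminal_curvatures.append(turn)
        truth.terminal_classes.append(classify_curvature(turn))
        truth.terminal_geometry.append({"polyline": pts, "branch_point": anchor})

    truth.loop_node_counts = list(ring_attach_counts)
    trace = ArborTrace(
        paths=paths,
        genotype=cfg.preset,
        neuromast_id=f"synthetic-{cfg.seed}",
    )
    # dense-oracle contact fraction on the emitted geometry
    from .spatial_metrics import contact_fraction

    truth.contact_fraction = contact_fraction(
        trace, cluster, spacing=0.05, boundary_spacing=0.05
    )
    return trace, truth


def _anchor_arc_positions(arcs, anchors):
    """Arc-length position of each anchor along the concatenated ring."""
    pos = [0.0]
    run = 0.0
    for a in arcs[:-1]:
        run += polyline_length(a)
        pos.append(run)
    return np.asarray(pos)


def _place_terminal(cfg, rng, field_, anchor, out_dir, length, turn):
    """Collision-checked placement of one terminal arc.

    Retries rotate the osculating plane about the outward direction and tilt
    the launch direction until the tip respects ``radial_extent`` and the
    curve clears existing structures.
    """
    best = (-np.inf, None)
    for attempt in range(90):
        psi = rng.uniform(0, 2 * np.pi)
        # tilt toward vertical limits radial reach; capped at ~45 degrees so
        # ring-attached terminals stay well off the ring plane near the anchor
        tilt = rng.uniform(-0.3, 0.78)
        d = out_dir * np.cos(tilt) + np.array([0.0, 0.0, 1.0]) * np.sin(tilt)
        d /= np.linalg.norm(d)
        # osculating-plane normal: orthogonal to d, rotated by psi
        ref = np.array([0.0, 0.0, 1.0])
        if abs(d @ ref) > 0.9:
            ref = np.array([1.0, 0.0, 0.0])
        n1 = np.cross(d, ref)
        n1 /= np.linalg.norm(n1)
        n2 = np.cross(d, n1)
        normal = np.cos(psi) * n1 + np.sin(psi) * n2
        pts = _arc_polyline(anchor, d, normal, length, turn, TERMINAL_SAMPLE_SPACING)
        max_r = float(np.linalg.norm(pts[:, :2], axis=1).max())
        if max_r > cfg.radial_extent and attempt < 50:
            continue  # the reach cap is soft: dropped after enough attempts
        ok, hard_ok, score = field_.accepts(pts[1:], [anchor])
        if score > best[0] and hard_ok:
            best = (score, pts)
        if ok:
            return pts
    score, pts = best
    if pts is None:
        raise ConfigError(
            f"could not place a terminal of length {length:.1f} µm without "
            "risking fusion with existing structures"
        )
    return pts


# ---------------------------------------------------------------------------
# puncta
# ---------------------------------------------------------------------------

def generate_puncta(
    cfg: GeneratorConfig,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
    channel: str = "MAGUK",
) -> PunctaSet:
    """Place synaptic puncta on known features, recording true labels.

    Puncta on loops sit at exponentially decaying arc distances from the
    nearest anchor junction (aggregating near nodes), but never closer than
    ~1.2 µm so that positional jitter cannot flip the nearest-feature
    assignment; puncta on terminals are uniform along the arbor away from
    the branching node.  Labels and feature ids are appended to ``truth``.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    n = cfg.n_puncta
    if n > 0 and cfg.puncta_loop_fraction > 0 and truth.n_loops == 0:
        raise ConfigError("puncta_loop_fraction > 0 but the network has no loops")
    positions = []
    truth.puncta_kinds = []
    truth.puncta_feature_ids = []
    loop_w = np.asarray(truth.loop_lengths, dtype=float)
    term_w = np.asarray(truth.terminal_lengths, dtype=float)
    for _ in range(n):
        on_loop = rng.uniform() < cfg.puncta_loop_fraction and truth.n_loops > 0
        if not on_loop and truth.n_terminals == 0:
            on_loop = truth.n_loops > 0
        if on_loop:
            li = int(rng.choice(truth.n_loops, p=loop_w / loop_w.sum()))
            rec = truth.loop_geometry[li]
            poly = rec["closed_polyline"]
            total = polyline_length(poly)
            a_pos = rec["anchor_arcpos"]
            ai = int(rng.integers(len(a_pos)))
            off = PUNCTA_NODE_CLEARANCE + rng.exponential(1.5)
            off = min(off, total / 2 - 1e-6)
            sgn = 1 if rng.uniform() < 0.5 else -1
            s = (a_pos[ai] + sgn * off) % total
            pos = _point_at_arc(poly, s, closed=True)
            truth.puncta_kinds.append("loop")
            truth.puncta_feature_ids.append(li)
        else:
            ti = int(rng.choice(truth.n_terminals, p=term_w / term_w.sum()))
            poly = truth.terminal_geometry[ti]["polyline"]
            total = polyline_length(poly)
            lo = min(PUNCTA_NODE_CLEARANCE, total * 0.45)
            s = rng.uniform(lo, total - 0.2 * min(1.0, total))
            pos = _point_at_arc(poly, s, closed=False)
            truth.puncta_kinds.append("bare_terminal")
            truth.puncta_feature_ids.append(ti)
        positions.append(pos + rng.normal(0, cfg.puncta_jitter, size=3))
    areas = rng.lognormal(mean=np.log(0.28), sigma=0.4, size=n)
    return PunctaSet(
        positions=np.asarray(positions).reshape(n, 3),
        areas=areas,
        channels=[channel] * n,
    )


def _point_at_arc(poly, s, closed=False):
    pts = np.asarray(poly)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if closed:
        s = s % cum[-1]
    s = float(np.clip(s, 0.0, cum[-1]))
    out = np.empty(3)
    for d in range(3):
        out[d] = np.interp(s, cum, pts[:, d])
    return out


# ---------------------------------------------------------------------------
# dwell stacks
# ---------------------------------------------------------------------------

def generate_dwell_stack(
    seed: int = 0,
    n_frames: int = 12,
    shape: tuple[int, int] = (48, 48),
    blob_radius: float = 4.0,
    on_frames: tuple[int, int] | None = None,
    drift_px: float = 0.0,
):
    """Toy 2D+T intensity stack: a bright blob with known per-pixel on-times.

    A stationary bright spot in the corner anchors the per-frame min-max
    normalization (as an always-present structure would in a real recording),
    so frames in which the moving blob is absent do not stretch background
    noise to full range.  Returns (stack, truth_counts): truth_counts[y, x]
    is the number of frames in which the pixel is covered by a structure
    (blob or anchor).
    """
    rng = np.random.default_rng(seed)
    t0, t1 = on_frames if on_frames is not None else (0, n_frames)
    stack = np.zeros((n_frames,) + shape, dtype=float)
    truth = np.zeros(shape, dtype=int)
    cy, cx = shape[0] / 2.0, shape[1] / 2.0
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for t in range(n_frames):
        frame = rng.uniform(0.0, 0.05, size=shape)  # dim background texture
        frame[:2, :2] = 1.0  # stationary anchor structure
        if t0 <= t < t1:
            oy = cy + drift_px * (t - t0)
            inside = (yy - oy) ** 2 + (xx - cx) ** 2 <= blob_radius**2
            frame[inside] += 1.0
            truth += inside
        stack[t] = frame
    truth[:2, :2] = n_frames
    return stack, truth


# ---------------------------------------------------------------------------
# convenience
# ---------------------------------------------------------------------------

def generate_neuromast(cfg: GeneratorConfig):
    """Generate one complete synthetic neuromast.

    Returns (cluster, trace, puncta, truth); everything derives from
    ``cfg.seed`` alone.
    """
    last_err = None
    for k in range(6):
        # rejection sampling over sub-seeds: the rare feature plan whose
        # geometry cannot be placed without fusion risk is redrawn
        seed_k = cfg.seed if k == 0 else int(
            (cfg.seed * 9176 + 7 + k * 104729) % (2**31 - 1)
        )
        cfg_k = replace(cfg, seed=seed_k)
        rng = cfg_k.rng()
        try:
            cluster = generate_cluster(cfg_k, rng)
            trace, truth = generate_arbor_network(cfg_k, cluster, rng)
        except ConfigError as exc:
            last_err = exc
            continue
        pcfg = cfg_k
        if truth.n_loops == 0 and cfg_k.puncta_loop_fraction > 0:
            # a loop-free network can still carry puncta, all on terminals
            pcfg = replace(cfg_k, puncta_loop_fraction=0.0)
        puncta = generate_puncta(pcfg, truth, rng)
        return cluster, trace, puncta, truth
    raise ConfigError(f"could not realize a neuromast for seed {cfg.seed}: {last_err}")
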