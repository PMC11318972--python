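"""Spatial metrics: cluster registration, radial equal-area density
profiles, arbor-cluster contact, and ectopic-guidance distances.

The radial density profile divides the region from the cluster center to
60 µm into 3600 concentric sections of equal area (pi µm² each, outer radii
r_k = sqrt(k)); arbor density per section is log10(occupied area / section
area), computed on the anteroposterior-dorsoventral (X-Y) projection of the
skeletons dilated to tubes of the neurite radius.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.spatial import cKDTree

from .errors import GeometryError, RegistrationError, ValidationError
from .trace_io import (
    ArborTrace,
    HairCellCluster,
    SkeletonPath,
    resample_polyline,
)

DEFAULT_R_MAX = 60.0          # µm
DEFAULT_SECTION_AREA = np.pi  # µm²
DEFAULT_CONTACT_TOL = 0.5     # µm, the average neurite radius
CONTACT_SPACING = 0.2         # µm arc-length "voxel" spacing

__all__ = [
    "DensityProfile",
    "GuidanceMeasurement",
    "register_clusters",
    "n_equal_area_sections",
    "annulus_outer_radii",
    "radial_density_profile",
    "density_falloff_radius",
    "contact_fraction",
    "guidance_metrics",
]


@dataclass
class DensityProfile:
    """Equal-area radial arbor-density profile."""

    outer_radii: np.ndarray     # r_k = sqrt(k * section_area / pi), µm
    occupied_area: np.ndarray   # µm² per annulus
    log_density: np.ndarray     # log10(occupied / section area)
    section_area: float
    pixel: float
    empty: bool = False

    @property
    def n_sections(self) -> int:
        return len(self.outer_radii)

    def linear_density(self) -> np.ndarray:
        return self.occupied_area / self.section_area

    def smoothed_density(self, bandwidth_um: float = 2.0, grid_um: float = 0.05):
        """Gaussian-kernel smoothed linear density on a uniform radius grid
        (the density-trace representation)."""
        r = self.outer_radii
        grid = np.arange(0.0, r[-1] + grid_um, grid_um)
        dens = np.interp(grid, r, self.linear_density())
        return grid, gaussian_filter1d(dens, sigma=bandwidth_um / grid_um)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "k": np.arange(1, self.n_sections + 1),
                "r_outer_um": self.outer_radii,
                "occupied_area_um2": self.occupied_area,
                "log10_density": self.log_density,
            }
        )


@dataclass
class GuidanceMeasurement:
    """Distances characterising guidance toward an ectopic cue source.

    * ``source_path`` — linear distance from the arborization point to the
      source-cell boundary (the boundary point nearest the terminus).
    * ``projection_path`` — linear distance from the arborization point to
      the projection terminus.
    * ``projection_proximity`` — linear distance from the terminus to the
      nearest point of the source boundary.
    """

    source_path: float
    projection_path: float
    projection_proximity: float


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

def register_clusters(
    items: list[tuple[HairCellCluster, ArborTrace]],
) -> tuple[list[tuple[HairCellCluster, ArborTrace]], ArborTrace]:
    """Align neuromasts by the centers of their apices and overlay them.

    Each neuromast is translated so its apex center lands at the origin (no
    rotation or scaling); the combined trace concatenates all translated
    traces with namespaced path ids.
    """
    if not items:
        raise RegistrationError("no neuromasts to register")
    shifted = []
    combined_paths = []
    for i, (cluster, trace) in enumerate(items):
        if cluster is None or cluster.apex_center is None:
            raise RegistrationError(f"neuromast {i} lacks an apex center")
        offset = -cluster.apex_center
        c2 = cluster.translated(offset)
        t2 = trace.translated(offset)
        shifted.append((c2, t2))
        for p in t2.paths:
            combined_paths.append(
                SkeletonPath(
                    path_id=f"{trace.neuromast_id}:{p.path_id}",
                    points=p.points,
                    radius=p.radius,
                    is_trunk=False,
                )
            )
    combined = ArborTrace(paths=combined_paths, neuromast_id="combined")
    return shifted, combined


# ---------------------------------------------------------------------------
# radial density
# ---------------------------------------------------------------------------

def n_equal_area_sections(
    r_max: float = DEFAULT_R_MAX, section_area: float = DEFAULT_SECTION_AREA
) -> int:
    """Number of equal-area concentric sections covering a disc of radius
    ``r_max`` (3600 for a 60 µm disc with pi µm² sections)."""
    return int(round(np.pi * r_max**2 / section_area))


def annulus_outer_radii(
    n_sections: int, section_area: float = DEFAULT_SECTION_AREA
) -> np.ndarray:
    """Outer radii r_k = sqrt(k * A / pi); with A = pi, simply sqrt(k)."""
    k = np.arange(1, n_sections + 1, dtype=float)
    return np.sqrt(k * section_area / np.pi)


def radial_density_profile(
    trace: ArborTrace,
    center=(0.0, 0.0),
    r_max: float = DEFAULT_R_MAX,
    section_area: float = DEFAULT_SECTION_AREA,
    pixel: float = 0.1,
    tube_radius: float | None = None,
    exclude_trunk: bool = True,
    floor_log: float = -4.0,
) -> DensityProfile:
    """Equal-area radial density profile of a (combined) trace.

    The skeleton is projected onto the X-Y plane, dilated to a tube of the
    neurite radius, rasterized at ``pixel`` µm, and the occupied area is
    accumulated per annulus.  Empty annuli (and an entirely empty trace) take
    the floor log-density.
    """
    if pixel > 0.1 + 1e-12:
        raise ValidationError("pixel must be <= 0.1 µm for area accuracy")
    n_sections = n_equal_area_sections(r_max, section_area)
    radii = annulus_outer_radii(n_sections, section_area)
    center = np.asarray(center, dtype=float).reshape(2)

    paths = [p for p in trace.paths if not (exclude_trunk and p.is_trunk)]
    occupied = np.zeros(n_sections)
    empty = True
    if paths:
        half = int(np.ceil((r_max + 1.0) / pixel))
        size = 2 * half + 1
        mask = np.zeros((size, size), dtype=bool)
        dense = []
        for p in paths:
            pts = resample_polyline(p.points, pixel * 0.25)[:, :2] - center
            dense.append(pts)
            ij = np.round(pts / pixel).astype(int) + half
            ok = (ij >= 0).all(axis=1) & (ij < size).all(axis=1)
            mask[ij[ok, 1], ij[ok, 0]] = True
        if mask.any():
            empty = False
            from scipy.ndimage import binary_dilation

            r = tube_radius if tube_radius is not None else max(
                p.radius for p in paths
            )
            # candidate pixels from a generous dilation of the centerline,
            # then an unbiased center-within-radius test against densely
            # resampled skeleton points
            rp = int(np.ceil(r / pixel)) + 2
            yy, xx = np.mgrid[-rp : rp + 1, -rp : rp + 1]
            cand = binary_dilation(mask, structure=(xx**2 + yy**2) <= rp**2)
            ys, xs = np.nonzero(cand)
            px = (xs - half) * pixel
            py = (ys - half) * pixel
            tree = cKDTree(np.concatenate(dense, axis=0))
            d, _ = tree.query(np.stack([px, py], axis=1))
            hit = d <= r
            r2 = px[hit] ** 2 + py[hit] ** 2
            k = np.floor(r2 * np.pi / section_area).astype(int)  # annulus k+1
            inside = k < n_sections
            counts = np.bincount(k[inside], minlength=n_sections)
            occupied = counts * pixel**2
    if empty:
        warnings.warn("empty trace: density profile floored", stacklevel=2)
    with np.errstate(divide="ignore"):
        log_density = np.where(
            occupied > 0, np.log10(occupied / section_area), floor_log
        )
    return DensityProfile(
        outer_radii=radii,
        occupied_area=occupied,
        log_density=log_density,
        section_area=section_area,
        pixel=pixel,
        empty=empty,
    )


def density_falloff_radius(
    profile: DensityProfile,
    frac_of_peak: float = 0.05,
    bandwidth_um: float = 2.0,
) -> float:
    """Radius at which the arbor density falls off: the outermost radius at
    which the kernel-smoothed density still reaches ``frac_of_peak`` of its
    peak.  This fall-off criterion is this package's definition, exposed via
    ``frac_of_peak``.
    """
    if profile.empty or not np.any(profile.occupied_area > 0):
        raise ValidationError("fall-off radius undefined for an empty profile")
    grid, dens = profile.smoothed_density(bandwidth_um=bandwidth_um)
    peak = dens.max()
    above = np.nonzero(dens >= frac_of_peak * peak)[0]
    return float(grid[above[-1]])


# ---------------------------------------------------------------------------
# contact
# ---------------------------------------------------------------------------

def contact_fraction(
    trace: ArborTrace,
    cluster: HairCellCluster,
    tol: float = DEFAULT_CONTACT_TOL,
    spacing: float = CONTACT_SPACING,
    exclude_trunk: bool = True,
    boundary_spacing: float = 0.1,
) -> float:
    """Percentage of the arbor in contact with the hair-cell cluster.

    The skeleton (trunk excluded) is resampled at ``spacing`` µm arc length;
    sample points inside the cluster boundary, or within ``tol`` of it, count
    as contact.  Returns 100 x (contact points / total points).
    """
    if not cluster.cells:
        raise GeometryError("cluster has no boundary")
    pts = []
    for p in trace.paths:
        if exclude_trunk and p.is_trunk:
            continue
        pts.append(resample_polyline(p.points, spacing))
    if not pts:
        raise ValidationError("trace has no arbor paths")
    pts = np.concatenate(pts, axis=0)
    inside = cluster.contains(pts)
    near = np.zeros(len(pts), dtype=bool)
    outside = ~inside
    if outside.any() and tol > 0:
        tree = cKDTree(cluster.boundary_points(boundary_spacing))
        d, _ = tree.query(pts[outside])
        near[outside] = d <= tol
    return float(100.0 * np.mean(inside | near))


# ---------------------------------------------------------------------------
# ectopic guidance
# ---------------------------------------------------------------------------

def guidance_metrics(
    arborization_point, terminus, source_boundary
) -> GuidanceMeasurement:
    """Guidance distances toward an ectopic source.

    ``source_boundary`` is a point cloud sampling the source-cell surface;
    the cell is represented by its single boundary point nearest the
    projection terminus.
    """
    a = np.asarray(arborization_point, dtype=float).reshape(3)
    t = np.asarray(terminus, dtype=float).reshape(3)
    b = np.atleast_2d(np.asarray(source_boundary, dtype=float))
    if b.size == 0:
        raise GeometryError("empty source boundary")
    d = np.linalg.norm(b - t, axis=1)
    nearest = b[int(np.argmin(d))]
    return GuidanceMeasurement(
        source_path=float(np.linalg.norm(nearest - a)),
        projection_path=float(np.linalg.norm(t - a)),
        projection_proximity=float(d.min()),
    )
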