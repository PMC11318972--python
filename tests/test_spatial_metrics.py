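import numpy as np
import pytest

from arbornet.errors import RegistrationError, ValidationError
from arbornet.spatial_metrics import (
    DensityProfile,
    annulus_outer_radii,
    contact_fraction,
    density_falloff_radius,
    guidance_metrics,
    n_equal_area_sections,
    radial_density_profile,
    register_clusters,
)
from arbornet.trace_io import ArborTrace, SkeletonPath

from conftest import line_path


class TestRegistration:
    def test_single_neuromast_shifted_by_minus_apex(self, sphere_cluster):
        trace = ArborTrace(paths=[line_path("p", (0, 0, 0), (5, 0, 0))])
        shifted, combined = register_clusters([(sphere_cluster, trace)])
        cl, tr = shifted[0]
        assert np.allclose(cl.apex_center, 0)
        assert np.allclose(tr.paths[0].points[0], -sphere_cluster.apex_center)
        assert len(combined.paths) == 1

    def test_offset_copies_superpose(self, sphere_cluster):
        trace = ArborTrace(paths=[line_path("p", (0, 0, 0), (5, 0, 0))])
        moved_cluster = sphere_cluster.translated([5, 5, 0])
        moved_trace = trace.translated([5, 5, 0])
        moved_trace.neuromast_id = "nm1"
        shifted, combined = register_clusters(
            [(sphere_cluster, trace), (moved_cluster, moved_trace)]
        )
        a, b = combined.paths
        assert np.allclose(a.points, b.points)

    def test_point_count_conserved_and_distances_preserved(self, sphere_cluster):
        t1 = ArborTrace(paths=[line_path("p", (0, 0, 0), (5, 0, 0), n=7)])
        t2 = ArborTrace(
            paths=[line_path("q", (1, 1, 1), (9, 2, 1), n=11)], neuromast_id="nm1"
        )
        shifted, combined = register_clusters(
            [(sphere_cluster, t1), (sphere_cluster, t2)]
        )
        assert sum(len(p.points) for p in combined.paths) == 18
        _, tr2 = shifted[1]
        d_before = np.linalg.norm(t2.paths[0].points[0] - t2.paths[0].points[-1])
        d_after = np.linalg.norm(tr2.paths[0].points[0] - tr2.paths[0].points[-1])
        assert d_before == pytest.approx(d_after)

    def test_missing_input_is_registration_error(self):
        with pytest.raises(RegistrationError):
            register_clusters([])


class TestRadialDensity:
    def test_section_count_for_sixty_micron_disc(self):
        assert n_equal_area_sections(60.0, np.pi) == 3600

    def test_annulus_radii_and_area_conservation(self):
        r = annulus_outer_radii(3600)
        assert r[-1] == pytest.approx(60.0)
        assert r[0] == pytest.approx(1.0)
        # analytic construction: total area sums exactly to pi * 60^2
        areas = np.pi * np.diff(np.concatenate([[0.0], r**2]))
        assert areas.sum() == pytest.approx(np.pi * 60**2)
        assert np.allclose(areas, np.pi)

    def test_empty_trace_floored_with_flag(self):
        trace = ArborTrace(paths=[])
        with pytest.warns(UserWarning, match="empty"):
            prof = radial_density_profile(trace, r_max=20)
        assert prof.empty
        assert np.all(prof.occupied_area == 0)

    def test_radial_arbor_occupancy_matches_fine_pixel_oracle(self):
        # 1 µm-wide straight arbor from the center outward, deliberately
        # off-grid so pixel-boundary coincidences do not bias the count
        trace = ArborTrace(
            paths=[line_path("p", (0.043, 0.037, 0), (20.043, 0.037, 0),
                             n=101, radius=0.5)]
        )
        prof = radial_density_profile(trace, r_max=20, pixel=0.1)
        oracle = radial_density_profile(trace, r_max=20, pixel=0.02)
        r = prof.outer_radii
        # annuli further out are thinner than a pixel, so compare aggregated
        # 1 µm radial bands, where the strip area is the band width x 1 µm
        edges = np.arange(2.0, 18.1, 1.0)
        band = np.digitize(r, edges)
        rel_err = []
        for b in range(1, len(edges)):
            got = prof.occupied_area[band == b].sum()
            ora = oracle.occupied_area[band == b].sum()
            assert got == pytest.approx(1.0, rel=0.12)  # 1 µm² per band
            rel_err.append(abs(got / ora - 1))
        # agreement with the oracle up to single-pixel quantization jitter
        assert np.median(rel_err) < 0.02
        assert max(rel_err) < 0.08
        # occupied area never exceeds the annulus area
        assert np.all(prof.occupied_area <= np.pi + 0.1)

    def test_rotation_invariance_of_profile(self):
        th = np.deg2rad(37.0)
        rot = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        pts = np.linspace([2, 1, 0], [15, 8, 0], 80)
        t1 = ArborTrace(paths=[SkeletonPath("p", pts)])
        t2 = ArborTrace(paths=[SkeletonPath("p", pts @ rot.T)])
        p1 = radial_density_profile(t1, r_max=20)
        p2 = radial_density_profile(t2, r_max=20)
        assert np.allclose(p1.occupied_area, p2.occupied_area, atol=0.35)


class TestFalloff:
    def _profile(self, occupied):
        n = len(occupied)
        return DensityProfile(
            outer_radii=annulus_outer_radii(n),
            occupied_area=np.asarray(occupied, dtype=float),
            log_density=np.log10(np.maximum(occupied, 1e-12) / np.pi),
            section_area=np.pi,
            pixel=0.1,
        )

    def test_step_profile(self):
        n = 1600  # r_max = 40
        occupied = np.where(annulus_outer_radii(n) <= 30.0, np.pi, 0.0)
        prof = self._profile(occupied)
        # with light smoothing the edge stays at the step
        assert density_falloff_radius(prof, bandwidth_um=0.25) == pytest.approx(
            30.0, abs=0.6
        )
        # the default 2 µm kernel extends the tail by 1.645 sigma at the 5% cut
        assert density_falloff_radius(prof) == pytest.approx(
            30.0 + 1.645 * 2.0, abs=0.6
        )

    def test_geometric_decay_matches_analytic_crossing(self):
        n = 3600
        r = annulus_outer_radii(n)
        lam = 8.0
        prof = self._profile(np.pi * np.exp(-r / lam))
        expected = lam * np.log(1 / 0.05)  # 23.97 µm
        assert density_falloff_radius(prof, bandwidth_um=0.5) == pytest.approx(
            expected, abs=1.0
        )

    def test_flat_profile_returns_r_max(self):
        prof = self._profile(np.full(400, np.pi))
        assert density_falloff_radius(prof) == pytest.approx(20.0, abs=0.2)

    def test_empty_profile_undefined(self):
        prof = self._profile(np.zeros(400))
        prof.empty = True
        with pytest.raises(ValidationError):
            density_falloff_radius(prof)


class TestContact:
    def test_fully_inside_is_hundred_percent(self, sphere_cluster):
        trace = ArborTrace(paths=[line_path("p", (-5, 0, 0), (5, 0, 0))])
        assert contact_fraction(trace, sphere_cluster) == pytest.approx(100.0)

    def test_far_outside_is_zero(self, sphere_cluster):
        trace = ArborTrace(paths=[line_path("p", (20, 0, 0), (30, 0, 0))])
        assert contact_fraction(trace, sphere_cluster) == pytest.approx(0.0)

    def test_half_inside_sphere(self, sphere_cluster):
        # path from the center to 20 µm: exactly half the arc is inside
        trace = ArborTrace(paths=[line_path("p", (0, 0, 0), (20, 0, 0), n=11)])
        pct = contact_fraction(trace, sphere_cluster, tol=0.0)
        assert pct == pytest.approx(50.0, abs=1.5)  # +- one point spacing

    def test_monotone_in_tolerance(self, sphere_cluster):
        trace = ArborTrace(paths=[line_path("p", (0, 0, 0), (25, 0, 0), n=26)])
        pcts = [
            contact_fraction(trace, sphere_cluster, tol=t)
            for t in (0.0, 0.25, 0.5, 1.0, 2.0)
        ]
        assert all(b >= a for a, b in zip(pcts, pcts[1:]))

    def test_trunk_excluded(self, sphere_cluster):
        trunk = line_path("t", (-40, 0, 0), (0, 0, 0), is_trunk=True)
        arbor = line_path("a", (0, 0, 0), (5, 0, 0), parent_id="t")
        trace = ArborTrace(paths=[trunk, arbor])
        assert contact_fraction(trace, sphere_cluster) == pytest.approx(100.0)


class TestGuidance:
    def test_collinear_hand_example(self):
        m = guidance_metrics((0, 0, 0), (0, 0, 10), np.array([[0.0, 0, 12]]))
        assert (m.source_path, m.projection_path, m.projection_proximity) == (
            pytest.approx(12.0),
            pytest.approx(10.0),
            pytest.approx(2.0),
        )

    def test_terminus_on_boundary_has_zero_proximity(self):
        m = guidance_metrics((0, 0, 0), (3, 4, 0), np.array([[3.0, 4, 0], [9, 9, 9]]))
        assert m.projection_proximity == pytest.approx(0.0)
        assert m.source_path == pytest.approx(5.0)

    def test_terminus_at_arborization_point(self):
        m = guidance_metrics((1, 1, 1), (1, 1, 1), np.array([[4.0, 5, 1]]))
        assert m.projection_path == pytest.approx(0.0)
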