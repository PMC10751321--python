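"""Synthetic plaque geometry and conforming labeled meshing."""

import numpy as np
import pytest
from shapely.geometry import Point, Polygon
from shapely.prepared import prep

from athero_ifem import (
    InclusionSpec,
    PlaqueSpec,
    annulus_mesh,
    default_plaque_spec,
    generate_plaque,
    geometry_metrics,
    mesh_plaque,
)
from athero_ifem.geometry import MeshingError, PlacementError


def concentric_spec(**kw):
    return PlaqueSpec(outer_radius=2.0, lumen_radius=1.0,
                      lumen_offset=(0.0, 0.0), inclusions=(),
                      contour_noise_amplitude=0.0, **kw)


class TestGeneratePlaque:
    def test_concentric_annulus_is_circular(self):
        g = generate_plaque(concentric_spec())
        assert np.allclose(np.linalg.norm(g.outer_contour, axis=1), 2.0)
        assert np.allclose(np.linalg.norm(g.lumen_contour, axis=1), 1.0)
        assert g.inclusion_contours == ()

    def test_cap_distance_at_exact_minimum_accepted(self):
        cap, a = 0.25, 0.4
        spec = PlaqueSpec(
            outer_radius=2.4, lumen_radius=1.0, lumen_offset=(0.0, 0.0),
            inclusions=(InclusionSpec("lipid", (-(1.0 + cap + a), 0.0), (a, 0.2)),),
            min_cap_thickness=cap, min_clearance=0.1,
            contour_noise_amplitude=0.0)
        g = generate_plaque(spec)
        m = geometry_metrics(g)
        assert m["cap_thickness"] == pytest.approx(cap, abs=1e-9)

    def test_cap_violation_is_explicit_placement_failure(self):
        spec = PlaqueSpec(
            outer_radius=2.4, lumen_radius=1.0, lumen_offset=(0.0, 0.0),
            inclusions=(InclusionSpec("lipid", (-1.5, 0.0), (0.4, 0.2)),),
            min_cap_thickness=0.25, contour_noise_amplitude=0.0)
        with pytest.raises(PlacementError, match="cap"):
            generate_plaque(spec)

    def test_noisy_contours_differ_between_seeds(self):
        a = generate_plaque(default_plaque_spec(seed=1))
        b = generate_plaque(default_plaque_spec(seed=2))
        assert not np.allclose(a.outer_contour, b.outer_contour)

    def test_deterministic_for_fixed_seed(self):
        a = generate_plaque(default_plaque_spec(seed=5))
        b = generate_plaque(default_plaque_spec(seed=5))
        assert np.array_equal(a.outer_contour, b.outer_contour)

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError):
            PlaqueSpec(outer_radius=1.0, lumen_radius=0.9, lumen_offset=(0.3, 0))


class TestGeometryMetrics:
    def test_annulus_stenosis_from_circle_areas(self):
        g = generate_plaque(concentric_spec())
        m = geometry_metrics(g)
        assert m["stenosis_fraction"] == pytest.approx(0.75, abs=1e-3)
        assert m["cap_thickness"] is None
        assert m["lipid_area"] == 0.0

    def test_unit_square_lipid_area(self):
        from athero_ifem.geometry import PlaqueGeometry

        square = np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]])
        g = PlaqueGeometry(
            outer_contour=10 * np.array([[np.cos(t), np.sin(t)] for t in
                                         np.linspace(0, 2 * np.pi, 64, False)]),
            lumen_contour=np.array([[np.cos(t) - 5, np.sin(t)] for t in
                                    np.linspace(0, 2 * np.pi, 64, False)]),
            inclusion_contours=(("lipid", square),),
        )
        assert geometry_metrics(g)["lipid_area"] == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self):
        g = generate_plaque(default_plaque_spec(seed=7))
        m = geometry_metrics(g)
        # shoelace area of each lipid polygon
        area = 0.0
        for kind, poly in g.inclusion_contours:
            if kind != "lipid":
                continue
            x, y = poly[:, 0], poly[:, 1]
            area += 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        assert m["lipid_area"] == pytest.approx(area, rel=1e-9)
        # brute-force pairwise min distance between densified contours
        lipid = [p for k, p in g.inclusion_contours if k == "lipid"][0]
        d = Polygon(g.lumen_contour).distance(Polygon(lipid))
        assert m["cap_thickness"] == pytest.approx(d, rel=1e-9)

    def test_invariant_under_rigid_motion(self):
        g = generate_plaque(default_plaque_spec(seed=7))
        m0 = geometry_metrics(g)
        m1 = geometry_metrics(g.transformed(angle=0.7, shift=(3.2, -1.4)))
        assert m1["cap_thickness"] == pytest.approx(m0["cap_thickness"], abs=1e-9)
        assert m1["lipid_area"] == pytest.approx(m0["lipid_area"], abs=1e-9)
        assert m1["stenosis_fraction"] == pytest.approx(m0["stenosis_fraction"],
                                                        abs=1e-12)


class TestMeshPlaque:
    def test_refinement_increases_element_count(self):
        g = generate_plaque(concentric_spec(min_cap_thickness=0.3))
        counts = [mesh_plaque(g, h).n_elements for h in (0.3, 0.2, 0.1)]
        assert counts[0] < counts[1] < counts[2]

    def test_labels_match_point_in_polygon_oracle(self, plaque_mesh):
        g = generate_plaque(default_plaque_spec(seed=11))
        centroids = plaque_mesh.centroids()
        polys = {}
        counters = {"lipid": 0, "calcification": 0}
        for kind, poly in g.inclusion_contours:
            counters[kind] += 1
            polys[f"{kind}_{counters[kind]}"] = prep(Polygon(poly))
        for name, poly in polys.items():
            inside = np.fromiter((poly.contains(Point(c)) for c in centroids),
                                 bool, count=len(centroids))
            assert np.array_equal(inside, plaque_mesh.labels == name)

    def test_label_assignment_stable_under_refinement(self):
        g = generate_plaque(default_plaque_spec(seed=4))
        for h in (0.065, 0.05):
            mesh = mesh_plaque(g, h)
            centroids = mesh.centroids()
            lipid = [p for k, p in g.inclusion_contours if k == "lipid"][0]
            poly = prep(Polygon(lipid))
            inside = np.fromiter((poly.contains(Point(c)) for c in centroids),
                                 bool, count=len(centroids))
            assert np.array_equal(inside, mesh.labels == "lipid_1")

    def test_reference_scale_element_count(self, plaque_mesh):
        # ~4 mm plaque at ~0.065 mm edges: same order as the reference
        # models (3,173-7,945 elements)
        assert 3000 <= plaque_mesh.n_elements <= 8000

    def test_mesh_audit_passes(self, plaque_mesh):
        plaque_mesh.audit()  # raises on any violated invariant
        assert np.all(plaque_mesh.signed_areas() > 0)

    def test_cap_resolved_by_three_element_layers(self):
        g = generate_plaque(default_plaque_spec(seed=0))
        from athero_ifem.geometry import _cap_layers

        mesh = mesh_plaque(g, 0.065)
        assert _cap_layers(mesh) >= 3

    def test_fixed_nodes_well_separated(self, plaque_mesh):
        pts = plaque_mesh.nodes[plaque_mesh.fixed_nodes]
        ctr = plaque_mesh.nodes[plaque_mesh.outer_nodes].mean(axis=0)
        ang = np.sort(np.arctan2(*(pts - ctr).T[::-1]))
        gaps = np.diff(np.append(ang, ang[0] + 2 * np.pi))
        assert gaps.min() >= np.pi / 2 - 1e-9


class TestAnnulusMesh:
    def test_audit_and_radii(self, small_annulus):
        small_annulus.audit()
        r = np.linalg.norm(small_annulus.nodes[small_annulus.outer_nodes], axis=1)
        assert np.allclose(r, 4.0)

    def test_lumen_edges_on_inner_ring(self, small_annulus):
        r = np.linalg.norm(small_annulus.nodes[small_annulus.lumen_edges[:, 0]],
                           axis=1)
        assert np.allclose(r, 1.5)

    def test_invalid_radii_rejected(self):
        with pytest.raises(ValueError):
            annulus_mesh(4.0, 1.5)
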