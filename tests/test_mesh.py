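"""Synthetic slice generator and mesh-invariant checks."""

import numpy as np
import pytest

from atrophyfem.mesh import (GeometryError, SliceSpec, TriMesh, VentricleSpec,
                             chain_loops, dof_count, element_areas,
                             generate_slice, shoelace_area,
                             structured_rectangle_mesh, validate_mesh)
from atrophyfem.morphometry import cortical_thickness, ventricle_loops


class TestGenerateSlice:
    def test_default_coronal_structure(self, coronal_coarse):
        mesh = coronal_coarse
        assert set(np.unique(mesh.element_region)) == {"gray", "white"}
        assert set(mesh.boundary_edges) == {"pial", "ventricular", "brainstem"}
        assert (element_areas(mesh.elements, mesh.node_coords) > 0).all()
        assert validate_mesh(mesh) == []

    def test_sagittal_valid(self):
        mesh = generate_slice(SliceSpec.sagittal(target_edge_length=3.5))
        assert validate_mesh(mesh) == []
        assert mesh.sulci  # landmark pairs are defined

    def test_halving_edge_length_scales_element_count(self):
        coarse = generate_slice(SliceSpec.coronal(target_edge_length=4.4))
        fine = generate_slice(SliceSpec.coronal(target_edge_length=2.2))
        factor = fine.n_elements / coarse.n_elements
        assert 3.0 <= factor <= 5.0

    @pytest.mark.parametrize("overrides", [
        {"ribbon_thickness": 0.0},
        {"target_edge_length": -1.0},
        {"ventricles": (VentricleSpec((0.0, 0.0), (80.0, 60.0)),)},  # escapes slice
        {"ventricles": (VentricleSpec((0.0, 0.0), (10.0, 5.0)),
                        VentricleSpec((1.0, 0.0), (10.0, 5.0)))},  # overlap
        {"brainstem_width": 300.0},
    ])
    def test_infeasible_geometry_raises(self, overrides):
        overrides.setdefault("target_edge_length", 4.0)
        with pytest.raises(GeometryError):
            generate_slice(SliceSpec.coronal(**overrides))

    def test_deterministic_for_fixed_spec(self):
        spec = SliceSpec.coronal(target_edge_length=4.0, seed=3)
        m1, m2 = generate_slice(spec), generate_slice(spec)
        assert np.array_equal(m1.node_coords, m2.node_coords)
        assert np.array_equal(m1.elements, m2.elements)
        assert np.array_equal(m1.element_region, m2.element_region)

    def test_seed_changes_fold_phase(self):
        m1 = generate_slice(SliceSpec.coronal(target_edge_length=4.0, seed=0))
        m2 = generate_slice(SliceSpec.coronal(target_edge_length=4.0, seed=1))
        assert m1.node_coords.shape != m2.node_coords.shape or \
            not np.allclose(m1.node_coords, m2.node_coords)

    def test_ribbon_thickness_within_ten_percent(self, coronal_mesh):
        _, mean_t = cortical_thickness(coronal_mesh)
        spec_t = coronal_mesh.metadata["spec"]["ribbon_thickness"]
        assert abs(mean_t - spec_t) <= 0.1 * spec_t

    def test_deep_gray_present(self, coronal_coarse):
        assert (coronal_coarse.element_subregion == "deep-gray").any()
        deep = coronal_coarse.element_subregion == "deep-gray"
        assert (coronal_coarse.element_region[deep] == "gray").all()


class TestAreaBookkeeping:
    def test_total_area_matches_boundary_loops(self, coronal_coarse):
        mesh = coronal_coarse
        tissue = element_areas(mesh.elements, mesh.node_coords).sum()
        outer_edges = np.vstack([mesh.boundary_edges["pial"],
                                 mesh.boundary_edges["brainstem"]])
        closed, open_ = chain_loops(outer_edges)
        assert not open_ and len(closed) == 1
        outer = shoelace_area(mesh.node_coords[closed[0]])
        vents = sum(shoelace_area(mesh.node_coords[lp])
                    for lp in ventricle_loops(mesh))
        assert tissue == pytest.approx(outer - vents, rel=1e-6)


class TestValidateMesh:
    def test_flipped_element_reported(self, coronal_coarse):
        bad = TriMesh(coronal_coarse.node_coords.copy(),
                      coronal_coarse.elements.copy(),
                      coronal_coarse.element_region.copy(),
                      boundary_edges=coronal_coarse.boundary_edges)
        bad.elements[7] = bad.elements[7][[0, 2, 1]]
        report = validate_mesh(bad)
        assert any("element 7" in msg and "non-positive area" in msg
                   for msg in report)

    def test_missing_brainstem_reported(self, coronal_coarse):
        edges = {k: v for k, v in coronal_coarse.boundary_edges.items()
                 if k != "brainstem"}
        bad = TriMesh(coronal_coarse.node_coords, coronal_coarse.elements,
                      coronal_coarse.element_region, boundary_edges=edges)
        assert any("brainstem" in msg for msg in validate_mesh(bad))

    def test_unknown_region_label_reported(self, coronal_coarse):
        region = coronal_coarse.element_region.copy()
        region[0] = "csf"
        bad = TriMesh(coronal_coarse.node_coords, coronal_coarse.elements,
                      region, boundary_edges=coronal_coarse.boundary_edges)
        assert any("csf" in msg for msg in validate_mesh(bad))


class TestDofCount:
    @pytest.mark.parametrize("n_nodes, expected", [
        (6441, 12882),
        (11808, 23616),
        (1, 2),
    ])
    def test_two_unknowns_per_node(self, n_nodes, expected):
        mesh = TriMesh(np.zeros((n_nodes, 2)),
                       np.empty((0, 3), dtype=np.int64),
                       np.empty(0, dtype="U16"))
        assert dof_count(mesh) == expected

    def test_matches_generated_mesh(self, coronal_coarse):
        assert dof_count(coronal_coarse) == 2 * len(coronal_coarse.node_coords)


def test_structured_rectangle_mesh_valid():
    mesh = structured_rectangle_mesh(10.0, 5.0, 4, 2, crossed=True)
    assert (element_areas(mesh.elements, mesh.node_coords) > 0).all()
    assert mesh.boundary_edges["brainstem"].size > 0
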