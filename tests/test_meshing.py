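"""Synthetic head mesh generation: geometry, labeling, conductivities."""

import math

import numpy as np
import pytest

import ttfsim
from ttfsim import meshing
from ttfsim.meshing import InvalidGeometryError, MeshingError, TumorSpec
from ttfsim.tissues import TISSUE_IDS, TissueConductivityTable


def sphere_volume(r):
    return 4.0 / 3.0 * math.pi * r**3


class TestLayeredSphere:
    def test_total_volume_within_2_percent(self, layered_mesh):
        exact = sphere_volume(92.0)
        assert abs(layered_mesh.total_volume() - exact) / exact < 0.02

    def test_layer_volumes_reasonable(self, layered_mesh):
        lv = layered_mesh.label_volumes()
        exact = {
            "skin": sphere_volume(92) - sphere_volume(86),
            "skull_compact": sphere_volume(86) - sphere_volume(80),
            "csf": sphere_volume(80) - sphere_volume(78),
            "gm": sphere_volume(78),
        }
        for label, v in exact.items():
            assert abs(lv[label] - v) / v < 0.05, label

    def test_volume_conservation_exact(self, layered_mesh):
        lv = layered_mesh.label_volumes()
        assert math.isclose(
            sum(lv.values()), layered_mesh.total_volume(), rel_tol=1e-12
        )

    def test_single_layer_ball(self):
        mesh = ttfsim.build_layered_sphere_mesh((10.0,), resolution=3.0)
        assert mesh.label_names() == ["gm"]
        exact = sphere_volume(10.0)
        assert abs(mesh.total_volume() - exact) / exact < 0.05

    def test_refinement_improves_volume_and_count(self):
        exact = sphere_volume(92.0)
        coarse = ttfsim.build_layered_sphere_mesh((92, 86, 80, 78), resolution=12.0)
        fine = ttfsim.build_layered_sphere_mesh((92, 86, 80, 78), resolution=6.0)
        assert len(fine.elements) > len(coarse.elements)
        err_c = abs(coarse.total_volume() - exact) / exact
        err_f = abs(fine.total_volume() - exact) / exact
        assert err_f < err_c

    def test_label_nesting(self, layered_mesh):
        """No element labeled an outer tissue has centroid inside an inner
        compartment boundary."""
        rc = np.linalg.norm(layered_mesh.element_centroids(), axis=1)
        bounds = list(layered_mesh.layer_radii) + [0.0]
        for k, lab in enumerate(layered_mesh.layer_labels):
            sel = layered_mesh.labels == TISSUE_IDS[lab]
            assert (rc[sel] <= bounds[k] + 1e-6).all()
            assert (rc[sel] >= bounds[k + 1] - 1e-6).all()

    def test_positive_volumes_and_orientation(self, layered_mesh):
        assert (layered_mesh.element_volumes() > 0).all()
        p = layered_mesh.nodes[layered_mesh.elements]
        det = np.linalg.det(p[:, 1:] - p[:, :1])
        assert (det > 0).all()

    def test_boundary_normals_point_outward(self, layered_mesh):
        faces, normals = layered_mesh.boundary_triangles()
        cen = layered_mesh.nodes[faces].mean(axis=1)
        assert (np.einsum("ij,ij->i", normals, cen) > 0).all()

    def test_non_decreasing_radii_rejected(self):
        with pytest.raises(InvalidGeometryError):
            ttfsim.build_layered_sphere_mesh((80.0, 80.0, 78.0))
        with pytest.raises(InvalidGeometryError):
            ttfsim.build_layered_sphere_mesh((78.0, 80.0))

    def test_too_coarse_resolution_rejected(self):
        with pytest.raises(MeshingError):
            ttfsim.build_layered_sphere_mesh((92, 86, 80, 78), resolution=200.0)

    def test_deterministic_given_seed(self):
        a = ttfsim.build_layered_sphere_mesh((30.0, 25.0), resolution=6.0, seed=7)
        b = ttfsim.build_layered_sphere_mesh((30.0, 25.0), resolution=6.0, seed=7)
        assert np.array_equal(a.nodes, b.nodes)
        assert np.array_equal(a.elements, b.elements)


class TestTumorEmbedding:
    @pytest.fixture(scope="class")
    def brain_mesh(self):
        spec = TumorSpec(center=(0.0, 0.0, 0.0), shell_radius=10.0, core_radius=6.0)
        mesh = ttfsim.build_layered_sphere_mesh(
            (92, 86, 80, 78),
            resolution=7.0,
            refine_spheres=[(spec.center, r) for _, r in spec.nested_parts],
        )
        return mesh, spec

    def test_shell_volume_within_10_percent(self, brain_mesh):
        mesh, spec = brain_mesh
        out = ttfsim.embed_tumor(mesh, spec)
        lv = out.label_volumes()
        total = lv["tumor_shell"] + lv["tumor_core"]
        exact = sphere_volume(10.0)  # ~4189 mm^3
        assert abs(total - exact) / exact < 0.10

    def test_core_nested_inside_shell(self, brain_mesh):
        mesh, spec = brain_mesh
        out = ttfsim.embed_tumor(mesh, spec)
        lv = out.label_volumes()
        assert lv["tumor_core"] < lv["tumor_shell"]
        d = np.linalg.norm(out.element_centroids(), axis=1)
        assert (d[out.labels == TISSUE_IDS["tumor_core"]] <= spec.core_radius).all()
        shell_d = d[out.labels == TISSUE_IDS["tumor_shell"]]
        assert (shell_d <= spec.shell_radius).all()
        assert (shell_d >= spec.core_radius).all()

    def test_volume_conserved_by_relabeling(self, brain_mesh):
        mesh, spec = brain_mesh
        out = ttfsim.embed_tumor(mesh, spec)
        assert math.isclose(out.total_volume(), mesh.total_volume(), rel_tol=1e-12)

    def test_tumor_outside_brain_rejected(self, layered_mesh):
        bad = TumorSpec(center=(0.0, 0.0, 85.0), shell_radius=8.0)  # in the skull
        with pytest.raises(InvalidGeometryError):
            ttfsim.embed_tumor(layered_mesh, bad)

    def test_invalid_nesting_rejected(self):
        with pytest.raises(InvalidGeometryError):
            TumorSpec(center=(0, 0, 0), shell_radius=5.0, core_radius=5.0)
        with pytest.raises(InvalidGeometryError):
            TumorSpec(center=(0, 0, 0), shell_radius=-1.0)


class TestConductivity:
    def test_default_table_values(self):
        table = TissueConductivityTable.default()
        assert table["skin"] == 0.465
        assert table["skull_compact"] == 0.007
        assert table["skull_spongy"] == 0.025
        assert table["csf"] == 1.65
        assert table["gm"] == 0.276
        assert table["wm"] == 0.126
        assert table["tumor_core"] == 1.0
        assert table["tumor_shell"] == 0.24
        assert table["resection"] == table["csf"]

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            TissueConductivityTable({"csf": 0.0})

    def test_isotropic_tensors_match_table(self, layered_mesh):
        out = ttfsim.assign_conductivity(layered_mesh)
        csf = out.labels == TISSUE_IDS["csf"]
        assert np.allclose(out.conductivity[csf], 1.65 * np.eye(3))
        skull = out.labels == TISSUE_IDS["skull_compact"]
        assert np.allclose(out.conductivity[skull], 0.007 * np.eye(3))

    def test_tumor_core_tensor(self):
        spec = TumorSpec(center=(0, 0, 0), shell_radius=10.0, core_radius=6.0)
        mesh = ttfsim.build_layered_sphere_mesh(
            (92, 86, 80, 78),
            resolution=9.0,
            refine_spheres=[(spec.center, r) for _, r in spec.nested_parts],
        )
        out = ttfsim.assign_conductivity(ttfsim.embed_tumor(mesh, spec))
        core = out.labels == TISSUE_IDS["tumor_core"]
        assert np.allclose(out.conductivity[core], 1.0 * np.eye(3))

    def test_anisotropy_ratio_one_is_isotropic(self):
        mesh = ttfsim.build_layered_sphere_mesh(
            (92, 86, 80, 78, 60), resolution=10.0
        )
        iso = ttfsim.assign_conductivity(mesh)
        one = ttfsim.assign_conductivity(mesh, wm_anisotropy_ratio=1.0)
        assert np.allclose(iso.conductivity, one.conductivity)

    def test_anisotropic_wm_spd_with_preserved_geometric_mean(self):
        mesh = ttfsim.build_layered_sphere_mesh(
            (92, 86, 80, 78, 60), resolution=10.0
        )
        out = ttfsim.assign_conductivity(mesh, wm_anisotropy_ratio=3.0)
        wm = out.conductivity[out.labels == TISSUE_IDS["wm"]]
        eig = np.linalg.eigvalsh(wm)
        assert (eig > 0).all()
        gm_mean = np.prod(eig, axis=1) ** (1.0 / 3.0)
        assert np.allclose(gm_mean, 0.126, rtol=1e-10)
        # tensors symmetric
        assert np.allclose(wm, np.transpose(wm, (0, 2, 1)))

    def test_missing_label_raises_with_name(self):
        mesh = ttfsim.build_layered_sphere_mesh((92, 86, 80, 78), resolution=10.0)
        table = TissueConductivityTable({"skin": 0.465, "csf": 1.65, "gm": 0.276})
        with pytest.raises(KeyError, match="skull_compact"):
            ttfsim.assign_conductivity(mesh, table)


class TestStripToIntracranial:
    @pytest.fixture(scope="class")
    def full_head(self):
        return ttfsim.assign_conductivity(
            ttfsim.build_layered_sphere_mesh((92, 86, 80, 78), resolution=8.0)
        )

    def test_only_intracranial_labels_remain(self, full_head):
        stripped = ttfsim.strip_to_intracranial(full_head)
        assert set(stripped.label_names()) == {"csf", "gm"}

    def test_outer_boundary_is_former_csf_surface(self, full_head):
        stripped = ttfsim.strip_to_intracranial(full_head)
        assert abs(stripped.outer_radius() - 80.0) < 0.5

    def test_volume_conservation(self, full_head):
        stripped = ttfsim.strip_to_intracranial(full_head)
        lv = full_head.label_volumes()
        expected = lv["csf"] + lv["gm"]
        assert math.isclose(stripped.total_volume(), expected, rel_tol=1e-12)

    def test_idempotent(self, full_head):
        once = ttfsim.strip_to_intracranial(full_head)
        twice = ttfsim.strip_to_intracranial(once)
        assert np.array_equal(once.elements, twice.elements)
        assert np.array_equal(once.nodes, twice.nodes)

    def test_conductivity_carried_over(self, full_head):
        stripped = ttfsim.strip_to_intracranial(full_head)
        csf = stripped.labels == TISSUE_IDS["csf"]
        assert np.allclose(stripped.conductivity[csf], 1.65 * np.eye(3))

    def test_no_csf_raises(self):
        ball = ttfsim.build_layered_sphere_mesh((10.0,), resolution=4.0)
        with pytest.raises(InvalidGeometryError):
            ttfsim.strip_to_intracranial(ball)
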