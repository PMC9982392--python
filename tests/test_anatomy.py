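"""Parametric lumen geometry, virtual surgery, and voxel discretization."""

import numpy as np
import pytest

from gastroflow.anatomy import (
    AnatomyParams,
    GeometryError,
    SurgicalVariant,
    build_lumen,
    export_surface,
    load_surface,
)
from gastroflow.fixtures import box_lumen, straight_tube
from gastroflow.mesh import Tag, discretize


@pytest.fixture(scope="module")
def cgj():
    return build_lumen(AnatomyParams(), SurgicalVariant.CGJ)


@pytest.fixture(scope="module")
def spgj():
    return build_lumen(AnatomyParams(), SurgicalVariant.SPGJ)


class TestParams:
    @pytest.mark.parametrize(
        "kwargs,name",
        [
            ({"esophagus_length": -1.0}, "esophagus_length"),
            ({"stenosis_factor": 0.0}, "stenosis_factor"),
            ({"stenosis_factor": 1.5}, "stenosis_factor"),
            ({"anastomosis_length": 400.0}, "anastomosis_length"),
            ({"bowel_inner_diameter": 0.0}, "bowel_inner_diameter"),
        ],
    )
    def test_invariant_violations_name_the_field(self, kwargs, name):
        with pytest.raises(GeometryError, match=name):
            build_lumen(AnatomyParams(**kwargs), "cgj")

    def test_partition_wider_than_lumen_is_infeasible(self):
        with pytest.raises(GeometryError, match="partition_channel_width"):
            build_lumen(AnatomyParams(partition_channel_width=120.0), "spgj")

    def test_unconstructible_path_length(self):
        with pytest.raises(GeometryError, match="duodenojejunal_path_length"):
            build_lumen(AnatomyParams(duodenojejunal_path_length=3000.0), "cgj")


class TestSurgicalVariants:
    def test_cgj_has_no_partition(self, cgj):
        assert "partition plane" not in cgj.landmarks
        assert "partition" not in cgj._primitives

    def test_spgj_partition_channel_width(self, spgj):
        """The residual lesser-curvature channel is 20 mm wide (default)."""
        assert spgj.measure_partition_channel_width() == pytest.approx(20.0, abs=1.5)

    def test_partition_channel_width_follows_parameter(self):
        g = build_lumen(AnatomyParams(partition_channel_width=28.0), "spgj")
        assert g.measure_partition_channel_width() == pytest.approx(28.0, abs=1.5)

    def test_anastomosis_opening_length(self, cgj):
        assert cgj.measure_anastomosis_opening() == pytest.approx(45.0, abs=1.5)

    def test_variants_identical_outside_partition_region(self, cgj, spgj):
        """CGJ and SPGJ are the same lumen except near the partition plane."""
        q = np.asarray(spgj.landmarks["partition plane"]["point"])
        rng = np.random.default_rng(0)
        lo = np.array([b[0] for b in cgj.bbox])
        hi = np.array([b[1] for b in cgj.bbox])
        pts = lo + rng.random((4000, 3)) * (hi - lo)
        # the staple line runs anterior-posterior: exclude a slab around the
        # partition plane (any z), keep everything else
        far = np.linalg.norm(pts[:, :2] - q[:2], axis=1) > 45.0
        d_c = cgj.sdf(pts[far])
        d_s = spgj.sdf(pts[far])
        assert np.max(np.abs(d_c - d_s)) < 1e-9

    def test_duodenal_path_length_is_calibrated(self):
        for target in (350.0, 400.0, 480.0):
            g = build_lumen(AnatomyParams(duodenojejunal_path_length=target), "cgj")
            pts, _, _ = g._primitives["duodenum"]
            seg = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
            x_c, hx = g._primitives["connector"][0], g._primitives["connector"][2]
            total = seg + pts[-1][0] - (x_c + hx)  # loop + afferent limb
            assert total == pytest.approx(target, rel=0.01)


class TestDiscretize:
    def test_cube_volume_exact(self):
        mesh = discretize(box_lumen(10, 10, 10), 1.0)
        assert 1e9 * mesh.total_volume() == pytest.approx(1000.0, rel=0.01)

    def test_cylinder_volume_close_to_closed_form(self):
        r_mm, l_mm = 12.0, 100.0
        mesh = discretize(straight_tube(r_mm, l_mm), 1.0)
        analytic = np.pi * r_mm**2 * l_mm
        assert 1e9 * mesh.total_volume() == pytest.approx(analytic, rel=0.02)

    def test_volume_error_shrinks_with_refinement(self):
        analytic = np.pi * 12.0**2 * 100.0
        coarse, fine = (
            abs(1e9 * discretize(straight_tube(12.0, 100.0), h).total_volume() - analytic)
            for h in (4.0, 1.0)
        )
        assert fine < coarse
        assert fine / analytic < 0.02

    def test_anatomy_volume_matches_surface_integral(self, cgj):
        mesh = discretize(cgj, 5.0)
        surface_vol = cgj.lumen_volume(spacing=1.5)
        assert 1e9 * mesh.total_volume() == pytest.approx(surface_vol, rel=0.05)

    def test_cells_closed_and_positive(self, spgj):
        mesh = discretize(spgj, 5.0)
        assert mesh.cell_volume > 0
        # every fluid cell has exactly 6 faces (interior + boundary): the sum of
        # outward area vectors then cancels identically
        counts = np.zeros(mesh.n_cells, dtype=int)
        np.add.at(counts, mesh.face_owner, 1)
        np.add.at(counts, mesh.face_neigh, 1)
        np.add.at(counts, mesh.bnd_cell, 1)
        assert (counts == 6).all()
        vec = np.zeros((mesh.n_cells, 3))
        for a in range(3):
            m = mesh.face_axis == a
            np.add.at(vec[:, a], mesh.face_owner[m], +mesh.face_area)
            np.add.at(vec[:, a], mesh.face_neigh[m], -mesh.face_area)
            mb = mesh.bnd_axis == a
            np.add.at(vec[:, a], mesh.bnd_cell[mb], mesh.bnd_side[mb] * mesh.face_area)
        assert np.abs(vec).max() < 1e-9 * 6 * mesh.face_area

    def test_every_boundary_face_has_one_tag(self, cgj):
        mesh = discretize(cgj, 5.0)
        assert set(np.unique(mesh.bnd_tag)) <= {Tag.WALL, Tag.INLET, Tag.OUTLET}
        assert (mesh.bnd_tag == Tag.INLET).sum() > 0
        assert (mesh.bnd_tag == Tag.OUTLET).sum() > 0

    def test_sections_nonempty_and_disjoint(self, spgj):
        mesh = discretize(spgj, 5.0)
        pyl, _ = mesh.sections["PYLORUS"]
        ana, _ = mesh.sections["ANASTOMOSIS"]
        assert len(pyl) > 0 and len(ana) > 0
        assert not set(pyl) & set(ana)

    def test_refuses_cell_size_above_narrowest_channel(self, cgj):
        with pytest.raises(GeometryError, match="narrowest channel"):
            discretize(cgj, 9.0)

    def test_two_lumen_paths_between_inlet_and_outlet(self, cgj):
        """Inlet and outlet stay connected past either cut, but not past both."""
        mesh = discretize(cgj, 5.0)
        a = int(mesh.patch_cells(Tag.INLET)[0])
        b = int(mesh.patch_cells(Tag.OUTLET)[0])
        pyl, _ = mesh.sections["PYLORUS"]
        ana, _ = mesh.sections["ANASTOMOSIS"]
        assert mesh.connected(a, b)
        assert mesh.connected(a, b, blocked_faces=pyl)
        assert mesh.connected(a, b, blocked_faces=ana)
        assert not mesh.connected(a, b, blocked_faces=np.r_[pyl, ana])

    def test_pylorus_separates_stomach_from_duodenum(self, cgj):
        """Blocking the pyloric cut severs the direct stomach-duodenum route."""
        mesh = discretize(cgj, 5.0)
        pyl, _ = mesh.sections["PYLORUS"]
        ana, _ = mesh.sections["ANASTOMOSIS"]
        stomach_cell = int(mesh.face_owner[pyl[0]])
        duodenum_cell = int(mesh.face_neigh[pyl[0]])
        assert not mesh.connected(
            stomach_cell, duodenum_cell, blocked_faces=np.r_[pyl, ana]
        )


class TestSurfaceIO:
    def test_surface_is_watertight(self, cgj):
        surf = cgj.surface(spacing=2.5)
        assert len(surf.faces) > 0
        assert surf.is_watertight

    def test_stl_roundtrip_preserves_volume(self, tmp_path):
        geom = box_lumen(10, 10, 10)
        path = export_surface(geom, tmp_path / "cube.stl", spacing=0.5)
        back = load_surface(path)
        assert abs(back.volume) == pytest.approx(1000.0, rel=0.05)
        assert back.is_watertight

    def test_stl_roundtrip_preserves_vertices(self, cgj, tmp_path):
        surf = cgj.surface(spacing=3.0)
        path = tmp_path / "cgj.stl"
        surf.export(path)
        back = load_surface(path)
        assert abs(abs(back.volume) - abs(surf.volume)) < 1e-6 * abs(surf.volume) + 1e-9
        a = np.asarray(sorted(map(tuple, np.round(surf.vertices, 5))))
        b = np.asarray(sorted(map(tuple, np.round(back.vertices, 5))))
        assert a.shape == b.shape
        assert np.allclose(a, b, atol=1e-4)
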