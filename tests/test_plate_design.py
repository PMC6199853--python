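import json
import re

import numpy as np
import pytest

from osteokit.errors import (
    ConfigError,
    DuplicatePointError,
    HoleOffPlateError,
    HoleOverlapError,
    InsufficientCoverageError,
    NotWatertightError,
    SelfIntersectionError,
)
from osteokit.geometry3d import TriangleMesh, load_mesh
from osteokit.plate_design import (
    HoleSpec,
    PlateModel,
    PlateSpec,
    add_screw_holes,
    build_reference_line,
    export_plate,
    extract_contact_patch,
    solidify,
)

from conftest import flat_patch


class TestReferenceLine:
    def test_two_points_give_straight_segment(self):
        line = build_reference_line(np.array([[0., 0, 0], [30., 40, 0]]))
        seg = np.diff(line, axis=0)
        length = np.linalg.norm(seg, axis=1).sum()
        assert abs(length - 50.0) <= 1e-9
        # all points on the segment
        t = line @ np.array([0.6, 0.8, 0.0])
        assert np.abs(np.cross(line - line[0],
                               [0.6, 0.8, 0.0])).max() <= 1e-9

    def test_collinear_points_stay_on_line(self):
        pts = np.array([[0, 0, 0], [10, 0, 0], [25, 0, 0], [40, 0, 0]],
                       dtype=float)
        line = build_reference_line(pts)
        assert np.abs(line[:, 1:]).max() <= 1e-9

    def test_circular_arc_radial_deviation(self):
        th = np.linspace(0, np.pi / 2, 5)
        pts = np.column_stack([50 * np.cos(th), 50 * np.sin(th),
                               np.zeros(5)])
        line = build_reference_line(pts, samples_per_point=10)
        dev = np.abs(np.linalg.norm(line[:, :2], axis=1) - 50.0)
        assert dev.max() <= 0.05

    def test_duplicate_points_rejected(self):
        with pytest.raises(DuplicatePointError):
            build_reference_line(np.array([[0., 0, 0], [0., 0, 0],
                                           [1., 0, 0]]))


class TestContactPatch:
    def test_selection_predicate_and_structure(self):
        pts, line, patch = flat_patch()
        # every contact vertex is one of the supplied bone points, verbatim
        flat = patch.grid_points.reshape(-1, 3)
        src = {tuple(p) for p in pts}
        assert all(tuple(p) in src for p in flat)
        # and within the corridor
        from osteokit.plate_design import _project_to_polyline
        _, _, _, dist = _project_to_polyline(flat, line)
        assert dist.max() <= 8.5 + 1e-9

    def test_cylinder_corridor_vertex_count(self):
        # 13 slices x 21 angular positions; corridor spans +-2 columns
        r = 25.0
        ths = np.linspace(-0.5, 0.5, 21)      # 0.05 rad steps
        zs = np.linspace(0, 120, 13)
        pts = np.array([[[r * np.sin(a), r * np.cos(a), z] for a in ths]
                        for z in zs]).reshape(-1, 3)
        line = build_reference_line(
            np.array([[0, r, 0], [0, r, 60], [0, r, 120.]]))
        # chord distance of column k: 2 r sin(k*0.05/2)
        half_width = 2 * r * np.sin(2.5 * 0.05 / 2) + 0.01   # include +-2
        patch = extract_contact_patch(pts, line, half_width,
                                      outward_hint=np.array([0, 0, 60.]))
        assert (patch.nu, patch.nv) == (13, 5)

    def test_narrow_corridor_raises(self):
        pts, line, _ = flat_patch()
        with pytest.raises(InsufficientCoverageError):
            extract_contact_patch(pts, line, 1e-6)

    def test_unstructured_selection_raises(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform([0, -8, 0], [110, 8, 0], size=(80, 3))
        line = build_reference_line(np.array([[0., 0, 0], [110., 0, 0]]))
        with pytest.raises(InsufficientCoverageError):
            extract_contact_patch(pts, line, 8.5)


class TestSolidify:
    def test_flat_prism_volume(self):
        _, _, patch = flat_patch()
        t = 3.0
        solid = solidify(patch, t)
        area = patch.mesh.area
        assert abs(solid.volume - area * t) / (area * t) <= 1e-6
        tm = solid.as_trimesh()
        assert tm.is_watertight and tm.is_winding_consistent

    @pytest.mark.parametrize("thickness", [3.0, 1.5])
    def test_offset_distance_equals_thickness(self, thickness):
        from osteokit.plate_design import _patch_normals
        _, _, patch = flat_patch()
        N = _patch_normals(patch)
        offset = patch.grid_points + thickness * N
        d = np.linalg.norm(offset - patch.grid_points, axis=2)
        assert np.abs(d - thickness).max() <= 1e-9

    def test_cylindrical_patch_outer_radius(self):
        r, t = 25.0, 3.0
        ths = np.linspace(-0.5, 0.5, 11)
        zs = np.linspace(0, 120, 13)
        pts = np.array([[[r * np.sin(a), r * np.cos(a), z] for a in ths]
                        for z in zs]).reshape(-1, 3)
        line = build_reference_line(
            np.array([[0, r, 0], [0, r, 60], [0, r, 120.]]))
        patch = extract_contact_patch(pts, line, 14.0,
                                      outward_hint=np.array([0, 0, 60.]))
        from osteokit.plate_design import _patch_normals
        N = _patch_normals(patch)
        outer = patch.grid_points + t * N
        # interior vertices: two-sided normal averaging is exactly radial
        rad = np.linalg.norm(outer[1:-1, 1:-1, :2], axis=2)
        assert np.abs(rad - (r + t)).max() <= 1e-6
        # offset distance holds everywhere, boundary included
        d = np.linalg.norm(outer - patch.grid_points, axis=2)
        assert np.abs(d - t).max() <= 1e-9

    def test_excessive_thickness_raises(self):
        # concave side of a tight cylinder: offset collapses
        r = 8.0
        ths = np.linspace(-1.2, 1.2, 15)
        zs = np.linspace(0, 60, 9)
        pts = np.array([[[r * np.sin(a), r * np.cos(a), z] for a in ths]
                        for z in zs]).reshape(-1, 3)
        line = build_reference_line(np.array([[0, r, 0], [0, r, 30],
                                              [0, r, 60.]]))
        patch = extract_contact_patch(pts, line, 10.0,
                                      outward_hint=np.array([0, 50, 30.]))
        with pytest.raises(SelfIntersectionError):
            solidify(patch, 12.0)


class TestScrewHoles:
    def _plate(self, hole_spec=None):
        _, _, patch = flat_patch()
        spec = PlateSpec(["a", "b"], corridor_half_width=8.5, thickness=3.0,
                         hole_spec=hole_spec)
        solid = solidify(patch, 3.0)
        return PlateModel(contact_surface=patch.mesh, solid=solid,
                          spec=spec, patch=patch)

    def test_zero_holes_is_identity(self):
        plate = self._plate()
        assert add_screw_holes(plate) is plate

    def test_single_hole_volume_decrease(self):
        d, t = 4.5, 3.0
        plate = self._plate(HoleSpec(1, d, [0.5]))
        holed = add_screw_holes(plate)
        tm = holed.solid.as_trimesh()
        assert tm.is_watertight and tm.is_winding_consistent
        dv = plate.solid.volume - holed.solid.volume
        expected = np.pi * (d / 2) ** 2 * t
        assert abs(dv - expected) / expected <= 0.01

    def test_two_holes_watertight_single_component(self):
        plate = self._plate(HoleSpec(2, 4.5, [0.25, 0.75]))
        holed = add_screw_holes(plate)
        tm = holed.solid.as_trimesh()
        assert tm.is_watertight
        assert tm.body_count == 1

    def test_overlapping_holes_rejected(self):
        plate = self._plate(HoleSpec(2, 4.5, [0.5, 0.52]))
        with pytest.raises(HoleOverlapError):
            add_screw_holes(plate)

    def test_hole_off_plate_rejected(self):
        plate = self._plate(HoleSpec(1, 4.5, [0.0]))
        with pytest.raises(HoleOffPlateError):
            add_screw_holes(plate)


class TestExport:
    def test_binary_stl_round_trip_and_determinism(self, tmp_path):
        _, _, patch = flat_patch()
        spec = PlateSpec(["a", "b"], 8.5, 3.0, plate_label="t")
        solid = solidify(patch, 3.0)
        plate = PlateModel(patch.mesh, solid, spec, patch=patch)
        p1 = export_plate(plate, tmp_path / "a.stl")
        p2 = export_plate(plate, tmp_path / "b.stl")
        assert p1.read_bytes() == p2.read_bytes()
        back = load_mesh(p1)
        got = {tuple(v) for v in back.vertices}
        want = {tuple(v) for v in solid.vertices.astype(np.float32)}
        assert got == want
        manifest = json.loads(
            (tmp_path / "a.stl.manifest.json").read_text())
        assert manifest["thickness_mm"] == 3.0
        assert manifest["mesh"]["watertight"] is True

    def test_exported_plate_single_component(self, tmp_path):
        _, _, patch = flat_patch()
        spec = PlateSpec(["a", "b"], 8.5, 3.0,
                         hole_spec=HoleSpec(2, 4.5, [0.3, 0.7]))
        plate = PlateModel(patch.mesh, solidify(patch, 3.0), spec,
                           patch=patch)
        plate = add_screw_holes(plate)
        path = export_plate(plate, tmp_path / "p.stl")
        assert load_mesh(path).as_trimesh().body_count == 1

    def test_ascii_stl_grammar(self, tmp_path):
        tri = TriangleMesh(np.array([[0., 0, 0], [1., 0, 0], [0., 1, 0]]),
                           np.array([[0, 1, 2]]))
        path = tri.save(tmp_path / "tri.stl", ascii_stl=True)
        text = path.read_text()
        assert re.search(r"^solid", text)
        assert re.search(r"facet normal\s+\S+\s+\S+\s+\S+", text)
        assert len(re.findall(r"vertex\s+\S+\s+\S+\s+\S+", text)) == 3
        assert "endfacet" in text and "endsolid" in text

    def test_open_patch_export_rejected(self, tmp_path):
        _, _, patch = flat_patch()
        spec = PlateSpec(["a", "b"], 8.5, 3.0)
        plate = PlateModel(patch.mesh, patch.mesh, spec, patch=patch)
        with pytest.raises(NotWatertightError):
            export_plate(plate, tmp_path / "open.stl")


class TestSpecValidation:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            PlateSpec(["only_one"], 8.0, 3.0)
        with pytest.raises(ValueError):
            PlateSpec(["a", "b"], -1.0, 3.0)
        with pytest.raises(ValueError):
            PlateSpec(["a", "b"], 8.0, 0.0)
        with pytest.raises(ValueError):
            PlateSpec(["a", "b"], 2.0, 3.0, hole_spec=HoleSpec(1, 4.5, [0.5]))

    def test_json_round_trip(self, tmp_path):
        spec = PlateSpec(["a", "b", "c"], 8.0, 3.0,
                         hole_spec=HoleSpec(2, 4.0, [0.2, 0.8]),
                         plate_label="x", u_cluster_gap=5.0)
        spec.to_json(tmp_path / "s.json")
        back = PlateSpec.from_json(tmp_path / "s.json")
        assert back == spec

    def test_missing_field_named_in_error(self, tmp_path):
        (tmp_path / "bad.json").write_text(json.dumps(
            {"reference_point_ids": ["a", "b"], "thickness": 3.0}))
        with pytest.raises(ConfigError, match="corridor_half_width"):
            PlateSpec.from_json(tmp_path / "bad.json")
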