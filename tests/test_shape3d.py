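import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import cristoscope.phantom as ph
import cristoscope.shape3d as s3
from cristoscope.labels import Compartment
from tests.conftest import crista_masks


class TestCompartmentVolumes:
    def test_total_is_exact_sum(self, lamellar_phantom):
        _, _, labels, _ = lamellar_phantom
        rep = s3.compartment_volumes(labels, 2.2)
        assert rep.total_um3 == rep.matrix_um3 + rep.ims_um3 + rep.cl_um3
        ratios = rep.ratios()
        assert sum(ratios.values()) == pytest.approx(1.0)

    def test_phantom_volumes_match_closed_form(self):
        spec = ph.PhantomSpec(
            box_shape=(80, 80, 80), semi_axes_nm=(70, 75, 80),
            wedge_half_angle_deg=0.0,
        )
        _, labels, _ = ph.generate_phantom(spec)
        rep = s3.compartment_volumes(labels, spec.voxel_size_nm)
        analytic = ph.analytic_shell_volumes(spec)
        assert rep.matrix_um3 == pytest.approx(analytic["matrix_um3"], rel=0.02)
        assert rep.ims_um3 == pytest.approx(analytic["ims_um3"], rel=0.02)

    def test_empty_labels_give_zeros_and_guarded_ratios(self):
        rep = s3.compartment_volumes(np.zeros((10, 10, 10), np.int16), 1.0)
        assert rep.total_um3 == 0.0
        with pytest.raises(ZeroDivisionError):
            rep.ratios()

    def test_missing_label_classes_raise(self):
        with pytest.raises(KeyError, match="cl"):
            s3.compartment_volumes(
                np.zeros((4, 4, 4), np.int16), 1.0, label_map={"matrix": 4, "ims": 2}
            )


class TestCristaLength:
    def test_straight_two_point_line(self):
        line = np.array([[0, 0, 0], [0, 0, 100]], float)
        assert s3.crista_length(line, 2.2) == pytest.approx(220.0)

    def test_semicircle_matches_pi_r(self):
        theta = np.linspace(0, np.pi, 65)
        poly = np.stack([np.zeros_like(theta), 50 * np.sin(theta), 50 * np.cos(theta)], axis=1)
        assert s3.crista_length(poly, 1.0) == pytest.approx(np.pi * 50, rel=0.01)

    def test_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(5)
        poly = np.cumsum(rng.normal(size=(30, 3)), axis=0)
        rot = Rotation.from_euler("zyx", [0.3, -0.7, 1.1]).as_matrix()
        moved = poly @ rot.T + np.array([4.0, -2.0, 9.0])
        assert s3.crista_length(moved, 1.7) == pytest.approx(
            s3.crista_length(poly, 1.7)
        )

    def test_single_point_raises(self):
        with pytest.raises(ValueError):
            s3.crista_length(np.array([[0, 0, 0]]), 1.0)


class TestSkeletonizeCrista:
    def test_rod_centerline_length_within_5pct(self):
        rod = ph.CristaSpec("lamellar", width_nm=15, length_nm=150, height_nm=20,
                            orientation=(1, 0, 0))
        spec = ph.exemplar_phantom(rod)
        _, labels, _ = ph.generate_phantom(spec)
        solid, _ = crista_masks(labels)
        info = s3.skeletonize_crista(solid, spec.voxel_size_nm)
        length = s3.crista_length(info.centerline, spec.voxel_size_nm)
        assert length == pytest.approx(150.0, rel=0.05)

    def test_ring_topology_detected(self, exemplar_suite):
        spec, labels, _ = exemplar_suite["ring"]
        solid, _ = crista_masks(labels)
        info = s3.skeletonize_crista(solid, spec.voxel_size_nm)
        assert info.has_cycle

    def test_non_ring_has_no_cycle(self, exemplar_suite):
        spec, labels, _ = exemplar_suite["tubular"]
        solid, _ = crista_masks(labels)
        assert not s3.skeletonize_crista(solid, spec.voxel_size_nm).has_cycle

    def test_deterministic(self, exemplar_suite):
        spec, labels, _ = exemplar_suite["loop"]
        solid, _ = crista_masks(labels)
        a = s3.skeletonize_crista(solid, spec.voxel_size_nm)
        b = s3.skeletonize_crista(solid, spec.voxel_size_nm)
        np.testing.assert_array_equal(a.centerline, b.centerline)

    def test_tiny_component_raises(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        with pytest.raises(ValueError):
            s3.skeletonize_crista(mask, 1.0)


class TestDirectionality:
    def test_definition_cases(self):
        assert s3.classify_directionality(0, []) == "NAO"
        assert s3.classify_directionality(1, [90.0]) == "straight"
        assert s3.classify_directionality(1, [45.0]) == "tilted"
        assert s3.classify_directionality(2, [85.0, 100.0]) == "straight"

    def test_tolerance_monotone(self):
        """Widening the tolerance can only move cristae tilted -> straight."""
        angles = [60.0]
        narrow = s3.classify_directionality(1, angles, s3.ShapeConfig(tilt_tolerance_deg=10))
        wide = s3.classify_directionality(1, angles, s3.ShapeConfig(tilt_tolerance_deg=40))
        assert narrow == "tilted" and wide == "straight"


class TestClassifyShape:
    def test_planted_exemplars_recovered(self, exemplar_suite):
        """Confusion matrix on the one-exemplar-per-class suite is identity."""
        for name, (spec, labels, crista) in exemplar_suite.items():
            solid, lumen = crista_masks(labels)
            cls, sub = s3.classify_shape(
                solid, spec.voxel_size_nm,
                n_junctions=len(crista.junctions), lumen=lumen,
            )
            got = sub if cls == "unusual" else cls
            assert got == name, f"{name} classified as {cls}/{sub}"

    def test_fully_collapsed_lumen_is_zipped(self):
        crista = ph.CristaSpec("lamellar", width_nm=6.0, length_nm=120, height_nm=25,
                               orientation=(1, 0, 0))
        spec = ph.exemplar_phantom(crista)
        _, labels, _ = ph.generate_phantom(spec)
        solid, lumen = crista_masks(labels)
        assert s3.classify_shape(solid, spec.voxel_size_nm, 1, lumen=lumen) == (
            "unusual", "zipped",
        )

    def test_punctual_touch_is_pinched(self):
        """A rod whose membranes touch at one short spot is pinched."""
        solid = np.zeros((9, 13, 60), bool)
        solid[2:7, 3:10, 5:55] = True
        lumen = np.zeros_like(solid)
        lumen[3:6, 5:8, 5:55] = True
        lumen[:, :, 28:31] = False  # membranes touch over ~3 voxels
        cls, sub = s3.classify_shape(solid, 2.2, n_junctions=1, lumen=lumen)
        assert (cls, sub) == ("unusual", "pinched")

    def test_dark_lumen_content_is_vesicular(self, exemplar_suite):
        spec, labels, crista = exemplar_suite["globular"]
        solid, lumen = crista_masks(labels)
        density = ph.render_density(labels, spec)
        interior = np.argwhere(lumen)
        c = interior.mean(axis=0).astype(int)
        density[c[0] - 4 : c[0] + 5, c[1] - 4 : c[1] + 5, c[2] - 4 : c[2] + 5] = (
            spec.membrane_density
        )
        cls, sub = s3.classify_shape(
            solid, spec.voxel_size_nm, 0, lumen=lumen, density=density,
            solvent_density=spec.solvent_density,
            membrane_density=spec.membrane_density,
        )
        assert (cls, sub) == ("unusual", "vesicular")


class TestMultijunction:
    def test_single_junction_is_none(self):
        assert s3.classify_multijunction(1, 0.5) == "none"

    def test_straight_septum(self, exemplar_suite):
        spec, labels, crista = exemplar_suite["straight_across"]
        solid, _ = crista_masks(labels)
        info = s3.skeletonize_crista(solid, spec.voxel_size_nm)
        assert s3.classify_multijunction(2, info.straightness) == "straight"

    def test_curved_loop(self, exemplar_suite):
        spec, labels, crista = exemplar_suite["loop"]
        solid, _ = crista_masks(labels)
        info = s3.skeletonize_crista(solid, spec.voxel_size_nm)
        assert s3.classify_multijunction(2, info.straightness) == "loop"


class TestStacking:
    @staticmethod
    def _sheet(center, normal, extent=100.0, n=400, seed=0):
        """Point cloud of a square sheet with the given normal (nm)."""
        rng = np.random.default_rng(seed)
        normal = np.asarray(normal, float) / np.linalg.norm(normal)
        helper = np.zeros(3)
        helper[int(np.argmin(np.abs(normal)))] = 1.0
        a = np.cross(normal, helper)
        a /= np.linalg.norm(a)
        b = np.cross(normal, a)
        uv = rng.uniform(-extent / 2, extent / 2, size=(n, 2))
        return np.asarray(center) + uv[:, :1] * a + uv[:, 1:] * b

    def test_three_parallel_sheets_stack(self):
        sheets = [self._sheet((30 * i, 0, 0), (1, 0, 0), seed=i) for i in range(3)]
        assert s3.detect_stacking([(1, 0, 0)] * 3, sheets)

    def test_two_sheets_do_not_stack(self):
        sheets = [self._sheet((30 * i, 0, 0), (1, 0, 0), seed=i) for i in range(2)]
        assert not s3.detect_stacking([(1, 0, 0)] * 2, sheets)

    def test_one_rotated_sheet_breaks_the_stack(self):
        tilted = np.array([np.cos(np.pi / 4), 0, np.sin(np.pi / 4)])
        normals = [(1, 0, 0), (1, 0, 0), tuple(tilted)]
        sheets = [
            self._sheet((0, 0, 0), normals[0], seed=0),
            self._sheet((30, 0, 0), normals[1], seed=1),
            self._sheet((60, 0, 0), normals[2], seed=2),
        ]
        assert not s3.detect_stacking(normals, sheets)

    def test_non_overlapping_parallel_sheets_do_not_stack(self):
        sheets = [
            self._sheet((0, 0, 0), (1, 0, 0), seed=0),
            self._sheet((30, 300, 0), (1, 0, 0), seed=1),
            self._sheet((60, 600, 0), (1, 0, 0), seed=2),
        ]
        assert not s3.detect_stacking([(1, 0, 0)] * 3, sheets)


class TestMitoShape:
    @staticmethod
    def _ellipse(a, b, center=(128, 128), n=72):
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        return np.stack([center[0] + a * np.sin(t), center[1] + b * np.cos(t)], axis=1)

    def test_circle_is_round(self):
        assert s3.classify_mito_shape(self._ellipse(60, 60), (256, 256)) == "round"

    def test_two_to_one_ellipse_is_ellipsoidal(self):
        assert s3.classify_mito_shape(self._ellipse(100, 50), (256, 256)) == "ellipsoidal"

    def test_boundary_touching_outline_is_partial(self):
        assert s3.classify_mito_shape(self._ellipse(128, 60), (256, 256)) == "partial"

    def test_concave_outline_is_polygon(self):
        t = np.linspace(0, 2 * np.pi, 72, endpoint=False)
        r = 80 + 30 * np.cos(5 * t)  # five-lobed star
        verts = np.stack([128 + r * np.sin(t), 128 + r * np.cos(t)], axis=1)
        assert s3.classify_mito_shape(verts, (256, 256)) == "polygon"
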