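"""DIA morphometry: contour measurements, Feret extremes, shape factors."""

import numpy as np
import pytest

from granmorph import morphometry as mm, synthetic as syn
from granmorph.errors import MeasurementError, ValidationError
from granmorph.pipeline import cross_mask, disk_mask, ellipse_mask, square_mask

from conftest import brute_force_feret, ramanujan_perimeter, random_convex_polygon

PX = 0.01  # mm per pixel used throughout


class TestExtractParticleMasks:
    def test_two_disjoint_squares_give_two_masks(self):
        img = np.zeros((60, 60), dtype=bool)
        img[5:15, 5:15] = True
        img[30:45, 30:45] = True
        regions = mm.extract_particle_masks(img)
        assert len(regions) == 2
        assert sorted(r.mask.sum() for r in regions) == [100, 225]

    def test_background_image_gives_empty_list(self):
        assert mm.extract_particle_masks(np.zeros((10, 10), dtype=bool)) == []

    def test_plus_sign_is_one_component_of_five_pixels(self):
        img = np.zeros((7, 7), dtype=bool)
        img[3, 2:5] = True
        img[2:5, 3] = True
        regions = mm.extract_particle_masks(img)
        assert len(regions) == 1
        assert regions[0].mask.sum() == 5
        assert not regions[0].touches_border

    def test_border_touching_component_is_flagged(self):
        img = np.zeros((10, 10), dtype=bool)
        img[0:3, 4:7] = True
        (region,) = mm.extract_particle_masks(img)
        assert region.touches_border

    def test_diagonal_pixels_are_eight_connected(self):
        img = np.eye(5, dtype=bool)
        assert len(mm.extract_particle_masks(img)) == 1


class TestMeasureProjection:
    def test_square_area_and_feret_extremes(self, square100):
        m = mm.measure_projection(square100, PX)
        assert m.area == pytest.approx(1.0, rel=0.02)
        assert m.feret_min == pytest.approx(1.0, rel=0.02)
        assert m.feret_max == pytest.approx(np.sqrt(2), rel=0.02)

    def test_disk_perimeter_and_hull(self, disk100):
        m = mm.measure_projection(disk100, PX)
        assert m.perimeter == pytest.approx(2 * np.pi * 1.0, rel=0.01)
        assert m.chull_area == pytest.approx(m.area, rel=0.005)

    def test_cross_area_and_hull(self, cross_3x1):
        """Hull of the cross = 3x3 mm square minus four half-unit corners."""
        m = mm.measure_projection(cross_3x1, PX)
        assert m.area == pytest.approx(5.0, rel=0.02)
        assert m.chull_area == pytest.approx(7.0, rel=0.02)

    @pytest.mark.parametrize("a_mm,b_mm", [(1.0, 1.0), (1.0, 0.5), (1.2, 0.4), (1.2, 0.3)])
    def test_ellipse_descriptors_match_closed_forms(self, a_mm, b_mm):
        """Rasterised ellipses across aspect 1-4 vs closed-form A, P, F_L, F_T."""
        m = mm.measure_projection(ellipse_mask(a_mm / PX, b_mm / PX), PX)
        assert m.area == pytest.approx(np.pi * a_mm * b_mm, rel=0.02)
        assert m.perimeter == pytest.approx(ramanujan_perimeter(a_mm, b_mm), rel=0.02)
        assert m.feret_max == pytest.approx(2 * a_mm, rel=0.02)
        assert m.feret_min == pytest.approx(2 * b_mm, rel=0.02)

    def test_empty_mask_raises(self):
        with pytest.raises(MeasurementError):
            mm.measure_projection(np.zeros((5, 5), dtype=bool), PX)

    def test_scale_equivariance(self, cross_3x1):
        """Doubling pixel size doubles lengths and quadruples areas exactly."""
        m1 = mm.measure_projection(cross_3x1, PX)
        m2 = mm.measure_projection(cross_3x1, 2 * PX)
        assert m2.area == pytest.approx(4 * m1.area, rel=1e-12)
        assert m2.chull_area == pytest.approx(4 * m1.chull_area, rel=1e-12)
        assert m2.perimeter == pytest.approx(2 * m1.perimeter, rel=1e-12)
        assert m2.feret_max == pytest.approx(2 * m1.feret_max, rel=1e-12)
        assert m2.feret_min == pytest.approx(2 * m1.feret_min, rel=1e-12)

    @pytest.mark.parametrize("mask_name", ["disk", "cross", "ellipse"])
    def test_quarter_turn_rotation_invariance(self, mask_name):
        mask = {
            "disk": disk_mask(60),
            "cross": cross_mask(150, 50),
            "ellipse": ellipse_mask(90, 45),
        }[mask_name]
        m1 = mm.measure_projection(mask, PX)
        m2 = mm.measure_projection(np.rot90(mask), PX)
        assert m2.area == pytest.approx(m1.area, rel=1e-9)
        assert m2.perimeter == pytest.approx(m1.perimeter, rel=1e-9)
        assert m2.chull_area == pytest.approx(m1.chull_area, rel=1e-9)
        assert m2.feret_max == pytest.approx(m1.feret_max, rel=0.005)
        assert m2.feret_min == pytest.approx(m1.feret_min, rel=0.005)

    @pytest.mark.parametrize("mask_builder", [
        lambda: disk_mask(40),
        lambda: square_mask(70),
        lambda: cross_mask(120, 40),
        lambda: ellipse_mask(80, 25),
    ])
    def test_measurement_invariants(self, mask_builder):
        m = mm.measure_projection(mask_builder(), PX)
        assert m.chull_area >= m.area * (1 - 1e-9)
        assert m.feret_max >= m.feret_min > 0
        assert m.perimeter >= 2 * np.sqrt(np.pi * m.area) * 0.99  # isoperimetric

    def test_disk_descriptors_converge_with_resolution(self):
        """Discretisation error of the disk's shape factors shrinks ~ O(pixel)."""
        def shape_error(radius_px):
            frames = disk_mask(radius_px)[None]
            row = mm.morphometry_pipeline({"d": frames}, PX).iloc[0]
            return max(
                abs(row.sphericity - 1), abs(row.roundness - 1),
                abs(row.aspect_ratio - 1), row.concavity,
            )

        errors = [shape_error(r) for r in (25, 50, 100)]
        assert errors[2] < errors[0]
        assert errors[2] < 0.01


class TestFeretExtremes:
    def test_matches_brute_force_sweep_on_random_convex_polygons(self):
        """Calipers vs a 0.1-degree directional-width sweep, 100 polygons."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            poly = random_convex_polygon(rng)
            fmax, fmin = mm.feret_extremes(poly)
            bmax, bmin = brute_force_feret(poly)
            assert fmax == pytest.approx(bmax, rel=0.002)
            assert fmin == pytest.approx(bmin, rel=0.002)

    def test_degenerate_point_set_raises(self):
        with pytest.raises(MeasurementError):
            mm.feret_extremes(np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]))


class TestAggregation:
    def _meas(self, area=1.0, perimeter=4.0, chull=None, fmax=1.5, fmin=1.0):
        return mm.ProjectionMeasurement(
            area, perimeter, area if chull is None else chull, fmax, fmin
        )

    def test_single_frame_is_identity(self):
        m = self._meas()
        assert mm.aggregate_sequence([m]) == (1.0, 4.0, 1.0, 1.5, 1.0)

    def test_feret_length_is_max_over_frames(self):
        frames = [self._meas(fmax=f, fmin=0.5) for f in (1.0, 2.0, 3.0)]
        assert mm.aggregate_sequence(frames)[3] == 3.0

    def test_area_is_mean_over_frames(self):
        frames = [self._meas(area=1.0), self._meas(area=2.0)]
        assert mm.aggregate_sequence(frames)[0] == 1.5

    def test_empty_sequence_raises(self):
        with pytest.raises(MeasurementError):
            mm.aggregate_sequence([])


class TestShapeFactorFormulas:
    @pytest.mark.parametrize("area,expected", [
        (np.pi / 4, 1.0), (np.pi, 2.0), (0.5, 0.79788),
    ])
    def test_area_equivalent_diameter(self, area, expected):
        assert mm.area_equivalent_diameter(area) == pytest.approx(expected, abs=5e-6)

    def test_sphericity_formula(self):
        assert mm.sphericity(0.9, 1.0) == pytest.approx(0.9)
        assert mm.sphericity(1.0, 1.0) == 1.0

    def test_sphericity_of_ellipse_via_ramanujan_oracle(self):
        """2:1 ellipse: D_a = sqrt(4*pi*a*b/pi)=sqrt(2), D_p = P/pi from Ramanujan."""
        a, b = 1.0, 0.5
        d_a = mm.area_equivalent_diameter(np.pi * a * b)
        d_p = mm.perimeter_equivalent_diameter(ramanujan_perimeter(a, b))
        assert d_a == pytest.approx(1.41421, abs=1e-5)
        assert mm.sphericity(d_a, d_p) == pytest.approx(0.9172, abs=5e-4)

    def test_roundness_formula(self):
        assert mm.roundness(np.pi * 0.25, 1.0) == pytest.approx(1.0)  # circle R=0.5
        assert mm.roundness(np.pi / 8, 1.0) == pytest.approx(0.5)
        # single ellipse projection: r = 4*pi*a*b / (pi*(2a)^2) = b/a
        assert mm.roundness(np.pi * 1.0 * 0.5, 2.0) == pytest.approx(0.5)

    def test_aspect_ratio_formula(self):
        assert mm.aspect_ratio(0.5, 1.0) == 0.5
        assert mm.aspect_ratio(1.0, 1.0) == 1.0

    def test_concavity_formula(self):
        assert mm.concavity(7.0, 5.0) == pytest.approx(2 / 7)
        assert mm.concavity(1.0, 0.9) == pytest.approx(0.1)
        assert mm.concavity(1.0, 1.0) == 0.0

    @pytest.mark.parametrize("func,args", [
        (mm.area_equivalent_diameter, (0.0,)),
        (mm.sphericity, (1.0, 0.0)),
        (mm.roundness, (1.0, 0.0)),
        (mm.aspect_ratio, (1.0, 0.0)),
    ])
    def test_nonpositive_inputs_rejected(self, func, args):
        with pytest.raises(ValidationError):
            func(*args)

    def test_hull_smaller_than_area_is_inconsistent(self):
        with pytest.raises(MeasurementError):
            mm.concavity(0.9, 1.0)


class TestMorphometryPipeline:
    def test_disk_sequence_shape_factors_near_identity(self, disk100):
        """10 identical circular frames: phi, r, AR within 1% of 1; c <= 0.01."""
        stack = np.repeat(disk100[None], 10, axis=0)
        row = mm.morphometry_pipeline({"p0": stack}, PX).iloc[0]
        assert row.n_frames == 10
        assert row.sphericity == pytest.approx(1.0, abs=0.01)
        assert row.roundness == pytest.approx(1.0, abs=0.01)
        assert row.aspect_ratio == pytest.approx(1.0, abs=0.01)
        assert row.concavity <= 0.01

    def test_empty_input_gives_empty_table(self):
        table = mm.morphometry_pipeline({}, PX)
        assert len(table) == 0
        assert list(table.columns) == list(mm.MORPHOLOGY_COLUMNS)

    def test_two_particles_two_rows(self, disk100, square100):
        table = mm.morphometry_pipeline(
            {"a": disk100[None], "b": square100[None]}, PX
        )
        assert list(table.particle_id) == ["a", "b"]

    def test_prolate_ellipsoid_aspect_ratio_converges_to_axis_ratio(self):
        """Dense orientation sampling of a 2:1 prolate spheroid: AR -> b/a = 0.5.

        The thinnest projection is the 2b-wide silhouette seen along the long
        axis; the longest Feret belongs to a side-on view of length 2a.
        """
        surface = syn.make_particle_surface(
            syn.ParticleShapeSpec(semi_axes=(1.0, 0.5, 0.5))
        )
        seq = syn.ProjectionSequenceSpec(
            n_frames=60, pixel_size=PX, image_extent=256, orientation_seed=8
        )
        frames = syn.render_projection_sequence(surface, seq)
        row = mm.morphometry_pipeline({"e": frames}, PX).iloc[0]
        assert row.aspect_ratio == pytest.approx(0.5, rel=0.02)
        assert row.fl_mm == pytest.approx(2.0, rel=0.02)
        assert row.ft_mm == pytest.approx(1.0, rel=0.02)

    def test_descriptor_invariants_hold_for_measured_particles(self, disk100, cross_3x1):
        table = mm.morphometry_pipeline(
            {"a": disk100[None], "b": cross_3x1[None]}, PX
        )
        assert (table.sphericity.between(0, 1.02)).all()
        assert (table.roundness.between(0, 1.02)).all()
        assert (table.aspect_ratio.between(0, 1.02)).all()
        assert (table.concavity.between(0, 1, inclusive="left")).all()
        assert (table.fl_mm >= table.ft_mm).all()
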