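"""Organism-level geometry: outline, PA axis, Voronoi, costs, profiles."""

import math
import warnings

import numpy as np
import pytest

from cz3geom.geometry import FeatureRecord, Polygon2D, polygon_moments
from cz3geom.spheroid import (
    IdentityDistortion,
    OrthographicSphereDistortion,
    SpheroidOutline,
    SpheroidRecord,
    correct_distortion,
    covering_fraction,
    ecm_volume_estimate,
    estimate_pa_axis,
    feature_correlations,
    fit_outline,
    neighbor_stats,
    pa_profile,
    partition_cost,
    planar_voronoi,
    summarize_spheroid,
)
from conftest import regular_polygon


def square(x0, y0, s=1.0):
    return Polygon2D(np.array([[x0, y0], [x0 + s, y0],
                               [x0 + s, y0 + s], [x0, y0 + s]]))


class TestFitOutline:
    def test_circle(self):
        t = np.linspace(0, 2 * math.pi, 100, endpoint=False)
        pts = np.column_stack([50 * np.cos(t), 50 * np.sin(t)])
        o = fit_outline(pts)
        assert o.semi_major == pytest.approx(50.0, rel=1e-6)
        assert o.circular_radius == pytest.approx(50.0, rel=1e-6)
        assert o.aspect == pytest.approx(1.0, rel=1e-6)

    def test_axis_aligned_ellipse_recovered(self):
        t = np.linspace(0, 2 * math.pi, 80, endpoint=False)
        pts = np.column_stack([60 * np.cos(t), 40 * np.sin(t)])
        o = fit_outline(pts)
        assert o.semi_major == pytest.approx(60.0, abs=1e-6)
        assert o.semi_minor == pytest.approx(40.0, abs=1e-6)
        assert abs(math.sin(o.orientation)) == pytest.approx(0.0, abs=1e-6)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_outline(np.random.default_rng(0).normal(size=(5, 2)))

    def test_collinear_points(self):
        pts = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValueError, match="collinear"):
            fit_outline(pts)


class TestPAAxis:
    outline = SpheroidOutline(center=np.zeros(2), semi_major=100.0,
                              semi_minor=80.0, orientation=0.0)

    def test_normal_to_horizontal_offspring_line(self):
        offs = np.array([[-10.0, 40.0], [10.0, 40.0]])
        axis = estimate_pa_axis(self.outline, offs)
        assert abs(axis[1]) == pytest.approx(1.0)
        # anterior points away from the offspring centre of mass (+y here)
        assert axis[1] < 0

    def test_collinear_offspring_along_y(self):
        offs = np.array([[30.0, -20.0], [30.0, 0.0], [30.0, 20.0]])
        axis = estimate_pa_axis(self.outline, offs)
        assert abs(axis[0]) == pytest.approx(1.0)
        assert axis[0] < 0

    def test_line_at_30_degrees_gives_axis_at_120(self):
        t = np.linspace(-1, 1, 7)
        d = np.array([math.cos(math.pi / 6), math.sin(math.pi / 6)])
        offs = 30 * t[:, None] * d[None, :] + np.array([0.0, 10.0])
        axis = estimate_pa_axis(self.outline, offs)
        expect = np.array([math.cos(2 * math.pi / 3),
                           math.sin(2 * math.pi / 3)])
        assert min(np.abs(axis - expect).max(),
                   np.abs(axis + expect).max()) < 1e-9

    def test_fallback_to_major_axis_with_warning(self):
        with pytest.warns(UserWarning, match="fewer than 2"):
            axis = estimate_pa_axis(self.outline, np.array([[1.0, 1.0]]))
        assert abs(axis[0]) == pytest.approx(1.0)


class TestPlanarVoronoi:
    def test_two_generators_split_square_equally(self):
        win = square(0, 0, 2.0)
        cells = planar_voronoi(np.array([[0.5, 1.0], [1.5, 1.0]]), win)
        areas = [polygon_moments(c).area for c in cells]
        assert areas == pytest.approx([2.0, 2.0], rel=1e-9)

    def test_square_lattice_interior_cells_are_unit_squares(self):
        xs, ys = np.meshgrid(np.arange(5.0), np.arange(5.0))
        pts = np.column_stack([xs.ravel(), ys.ravel()]) + 0.5
        win = square(0, 0, 5.0)
        cells = planar_voronoi(pts, win)
        areas = np.array([polygon_moments(c).area for c in cells])
        assert areas == pytest.approx(np.ones(25), rel=1e-9)

    def test_partition_audit(self, rng):
        win = Polygon2D.from_shapely(regular_polygon(64, 10.0).to_shapely())
        pts = rng.uniform(-6, 6, size=(40, 2))
        cells = planar_voronoi(pts, win)
        total = sum(polygon_moments(c).area for c in cells)
        assert total == pytest.approx(polygon_moments(win).area, rel=1e-6)

    def test_against_nearest_neighbor_rasterization(self, rng):
        from scipy.spatial import cKDTree

        pts = rng.uniform(0.5, 9.5, size=(50, 2))
        win = square(0, 0, 10.0)
        cells = planar_voronoi(pts, win)
        res = 2048
        g = (np.arange(res) + 0.5) * (10.0 / res)
        gx, gy = np.meshgrid(g, g)
        _, lab = cKDTree(pts).query(np.column_stack([gx.ravel(), gy.ravel()]))
        pix_area = np.bincount(lab, minlength=50) * (10.0 / res) ** 2
        areas = np.array([polygon_moments(c).area for c in cells])
        assert np.max(np.abs(areas - pix_area) / areas) < 0.01

    def test_duplicate_centroids_rejected(self):
        win = square(0, 0, 4.0)
        pts = np.array([[1.0, 1.0], [1.0, 1.0], [3.0, 3.0]])
        with pytest.raises(ValueError, match="duplicate"):
            planar_voronoi(pts, win)


class TestCoveringFraction:
    def test_partition_covers_fully(self, rng):
        win = square(0, 0, 10.0)
        pts = rng.uniform(1, 9, size=(30, 2))
        cells = planar_voronoi(pts, win)
        assert covering_fraction(cells, win) == pytest.approx(1.0, abs=1e-3)

    def test_linear_shrink_scales_phi_quadratically(self, rng):
        win = square(0, 0, 10.0)
        pts = rng.uniform(1, 9, size=(30, 2))
        cells = planar_voronoi(pts, win)
        shrunk = []
        for c in cells:
            m = polygon_moments(c)
            shrunk.append(c.transformed(
                lambda v: m.centroid + 0.9 * (v - m.centroid)))
        assert covering_fraction(shrunk, win) == pytest.approx(0.81, rel=1e-3)

    def test_quarter_square(self):
        assert covering_fraction([square(0, 0, 1.0)], square(0, 0, 2.0)) == \
            pytest.approx(0.25)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            covering_fraction([], square(0, 0, 1.0))


class TestPartitionCost:
    def test_single_unit_square(self):
        m = polygon_moments(square(0, 0))
        assert partition_cost([m]) == pytest.approx(1.0 / 6.0)

    @pytest.mark.parametrize("n,scale", [(2, 1.0), (4, 3.0), (7, 0.2)])
    def test_square_tiling_invariance(self, n, scale):
        ms = [polygon_moments(square(i * scale, j * scale, scale))
              for i in range(n) for j in range(n)]
        assert partition_cost(ms) == pytest.approx(1.0 / 6.0, rel=1e-12)

    def test_hexagonal_tiling_beats_square(self):
        # 5*sqrt(3)/54: per-hexagon polar moment over squared area, n-invariant
        hexes = []
        s = 1.0
        for i in range(4):
            for j in range(4):
                cx = j * 1.5 * s
                cy = i * math.sqrt(3.0) * s + (j % 2) * math.sqrt(3.0) / 2 * s
                t = np.linspace(0, 2 * math.pi, 6, endpoint=False)
                hexes.append(polygon_moments(Polygon2D(
                    np.column_stack([cx + s * np.cos(t), cy + s * np.sin(t)]))))
        cost = partition_cost(hexes)
        assert cost == pytest.approx(5.0 * math.sqrt(3.0) / 54.0, rel=1e-12)
        assert cost < 1.0 / 6.0

    def test_area_polydispersity_increases_cost(self):
        sizes = [1.0, 1.5, 0.5, 2.0, 0.8]
        ms = [polygon_moments(square(0, 0, s)) for s in sizes]
        assert partition_cost(ms) > 1.0 / 6.0

    def test_lower_bound_disc(self):
        m = polygon_moments(regular_polygon(512))
        assert partition_cost([m]) >= 1.0 / (2.0 * math.pi) * (1 - 1e-4)

    def test_sq_sum_variant_differs(self):
        ms = [polygon_moments(square(0, 0, s)) for s in (1.0, 2.0)]
        assert partition_cost(ms, denominator="sq_sum") != \
            partition_cost(ms, denominator="sum_sq")


class TestNeighborStats:
    def test_hexagonal_lattice_interior_has_six_neighbors(self):
        pts = []
        for i in range(-6, 7):
            for j in range(-6, 7):
                pts.append([(j + 0.5 * (i % 2)), i * math.sqrt(3) / 2])
        stats = neighbor_stats(np.array(pts))
        assert stats["mean_interior_neighbors"] == pytest.approx(6.0, abs=0.2)

    def test_square_lattice_polygons_edge_adjacency(self):
        polys = [square(i, j) for i in range(4) for j in range(4)]
        stats = neighbor_stats(polys)
        # corner squares touch at corners too with distance adjacency; the
        # 4 central squares each touch 8 (4 edges + 4 corners)
        assert stats["counts"].max() == 8
        assert stats["counts"].min() == 3

    def test_random_voronoi_mean_six_neighbors(self, rng):
        pts = rng.uniform(0, 100, size=(500, 2))
        stats = neighbor_stats(pts)
        assert stats["mean_interior_neighbors"] == pytest.approx(6.0, rel=0.02)


class TestECMVolume:
    def test_sphere_only(self):
        v = ecm_volume_estimate(100.0, 1.0, 0, 1.0, 0)
        assert v == pytest.approx(4.0 / 3.0 * math.pi * 1e6 / 1e9, rel=1e-12)

    def test_monotonicity(self):
        base = ecm_volume_estimate(200.0, 20.0, 10, 3.0, 1000)
        assert ecm_volume_estimate(210.0, 20.0, 10, 3.0, 1000) > base
        assert ecm_volume_estimate(200.0, 25.0, 10, 3.0, 1000) < base
        assert ecm_volume_estimate(200.0, 20.0, 12, 3.0, 1000) < base

    def test_inconsistent_inputs_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            ecm_volume_estimate(10.0, 20.0, 10, 3.0, 1000)


def _record_with_gradient(n=600, c=0.5, seed=5, metric_noise=0.0):
    """Record whose a_cz3 follows a(u) = a0 (1 + c u) exactly."""
    rng = np.random.default_rng(seed)
    outline = SpheroidOutline(center=np.zeros(2), semi_major=100.0,
                              semi_minor=100.0, orientation=0.0)
    feats = []
    for i in range(n):
        ang = rng.uniform(0, 2 * math.pi)
        rad = 100.0 * math.sqrt(rng.uniform())
        pos = np.array([rad * math.cos(ang), rad * math.sin(ang)])
        u = (pos[1] / 100.0 + 1.0) / 2.0
        a = 50.0 * (1.0 + c * u) + metric_noise * rng.normal()
        feats.append(FeatureRecord(
            cell_id=i, a_cell=10.0, x_cell=pos, a_cz3=a, x_cz3=pos,
            l_cz3=4 * math.sqrt(a), alpha=1.2, q=0.9, dx=np.zeros(2),
            r=0.0, r_white=0.0, theta_offset=None))
    return SpheroidRecord(stage="T", outline=outline,
                          pa_axis=np.array([0.0, 1.0]), features=feats)


class TestPAProfile:
    def test_constant_metric_flat(self):
        rec = _record_with_gradient(c=0.0)
        prof = pa_profile(rec, "alpha")
        assert np.nanmax(prof.sd) < 1e-12
        assert np.nanstd(prof.mean) < 1e-12

    def test_metric_equal_to_coordinate(self):
        rec = _record_with_gradient(n=4000, c=0.0, seed=6)
        # overwrite metric with the PA coordinate itself
        for f in rec.features:
            f.alpha = (f.x_cz3[1] / 100.0 + 1.0) / 2.0
        prof = pa_profile(rec, "alpha")
        assert prof.mean == pytest.approx(prof.centers, abs=0.02)

    def test_gradient_slope_recovered(self):
        rec = _record_with_gradient(n=600, c=0.5)
        prof = pa_profile(rec, "a_cz3")
        slope = np.polyfit(prof.centers, prof.mean, 1)[0]
        assert slope == pytest.approx(50.0 * 0.5, rel=0.05)

    def test_rotation_equivariance(self):
        rec = _record_with_gradient(n=300, c=0.8, seed=7)
        prof0 = pa_profile(rec, "a_cz3")
        th = 1.1
        R = np.array([[math.cos(th), -math.sin(th)],
                      [math.sin(th), math.cos(th)]])
        for f in rec.features:
            f.x_cz3 = R @ f.x_cz3
        rec.pa_axis = R @ rec.pa_axis
        prof1 = pa_profile(rec, "a_cz3")
        assert prof1.mean == pytest.approx(prof0.mean, rel=1e-9, abs=1e-9)
        assert (prof1.count == prof0.count).all()

    def test_missing_metric_rejected(self):
        rec = _record_with_gradient(n=20)
        with pytest.raises(ValueError, match="not in FeatureRecord"):
            pa_profile(rec, "nope")

    def test_counts_conserved(self):
        rec = _record_with_gradient(n=123)
        prof = pa_profile(rec, "a_cz3")
        assert prof.count.sum() == 123


class TestDistortionCorrection:
    def _record_on_sphere(self, R=200.0, rho_frac=0.5):
        """Tangent-plane square compartment forward-projected orthographically."""
        rho = rho_frac * R
        cos_t = math.sqrt(1.0 - (rho / R) ** 2)
        center = np.array([rho, 0.0])  # anchor on the +x meridian
        # true tangent-frame square, side 10, cell disc offset (1.5, 1)
        sq = np.array([[-5.0, -5], [5, -5], [5, 5], [-5, 5.0]])
        cell = np.array([[1.0, 0.0], [2.0, 1.0], [1.0, 2.0], [0.0, 1.0]]) + 0.5
        # orthographic projection compresses the radial (x) component
        def fwd(v):
            return np.column_stack([center[0] + v[:, 0] * cos_t,
                                    center[1] + v[:, 1]])
        comp_p = Polygon2D(fwd(sq))
        cell_p = Polygon2D(fwd(cell))
        outline = SpheroidOutline(center=np.zeros(2), semi_major=R,
                                  semi_minor=R, orientation=0.0)
        feat = FeatureRecord.from_polygons(0, cell_p, comp_p)
        rec = SpheroidRecord(stage="T", outline=outline,
                             pa_axis=np.array([0.0, 1.0]), features=[feat],
                             compartment_polys=[comp_p], cell_polys=[cell_p])
        return rec, 100.0  # true tangent area of the square

    def test_identity_returns_input(self):
        rec, _ = self._record_on_sphere()
        assert correct_distortion(rec, "identity") is rec

    def test_center_compartment_unchanged(self):
        sq = Polygon2D(np.array([[-5.0, -5], [5, -5], [5, 5], [-5, 5.0]]))
        cell = Polygon2D(np.array([[0.0, 0], [1, 0], [1, 1], [0, 1.0]]))
        outline = SpheroidOutline(center=np.zeros(2), semi_major=200.0,
                                  semi_minor=200.0, orientation=0.0)
        rec = SpheroidRecord(
            stage="T", outline=outline, pa_axis=np.array([0.0, 1.0]),
            features=[FeatureRecord.from_polygons(0, cell, sq)],
            compartment_polys=[sq], cell_polys=[cell])
        out = correct_distortion(rec, OrthographicSphereDistortion(200.0))
        assert out.features[0].a_cz3 == pytest.approx(100.0, rel=1e-9)

    @pytest.mark.parametrize("rho_frac", [0.3, 0.5, 0.7])
    def test_projection_round_trip_recovers_tangent_area(self, rho_frac):
        rec, true_area = self._record_on_sphere(rho_frac=rho_frac)
        out = correct_distortion(rec, OrthographicSphereDistortion(200.0))
        assert out.features[0].a_cz3 == pytest.approx(true_area, rel=0.01)
        # offset distances also corrected toward the tangent-frame value
        assert out.features[0].r == pytest.approx(rec.features[0].r / 1.0,
                                                  abs=2.0)

    def test_beyond_silhouette_excluded(self):
        rec, _ = self._record_on_sphere(rho_frac=0.999)
        with pytest.warns(UserWarning, match="silhouette"):
            out = correct_distortion(rec, OrthographicSphereDistortion(200.0))
        assert out.features == []


class TestFeatureCorrelations:
    def test_exact_linear(self):
        import pandas as pd
        x = np.linspace(1, 10, 50)
        df = pd.DataFrame({"a": x, "b": 2 * x})
        out = feature_correlations(df, [{"x": "a", "y": "b"}])
        assert out.loc[0, "r2"] == pytest.approx(1.0)
        assert out.loc[0, "slope"] == pytest.approx(2.0)

    def test_power_law_in_loglog(self):
        import pandas as pd
        x = np.linspace(1, 100, 200)
        df = pd.DataFrame({"a": x, "b": x**0.5})
        out = feature_correlations(df, [{"x": "a", "y": "b",
                                         "x_transform": "log",
                                         "y_transform": "log"}])
        assert out.loc[0, "slope"] == pytest.approx(0.5, rel=1e-9)
        assert out.loc[0, "r2"] == pytest.approx(1.0)

    def test_uncorrelated_noise(self, rng):
        import pandas as pd
        df = pd.DataFrame({"a": rng.normal(size=5000),
                           "b": rng.normal(size=5000)})
        out = feature_correlations(df, [{"x": "a", "y": "b"}])
        assert out.loc[0, "r2"] < 0.05

    def test_nonfinite_rows_dropped_and_counted(self):
        import pandas as pd
        df = pd.DataFrame({"a": [1.0, 2, 3, -1, 4], "b": [1.0, 2, 3, 4, 5]})
        out = feature_correlations(df, [{"x": "a", "y": "b",
                                         "x_transform": "log"}])
        assert out.loc[0, "n_dropped"] == 1
        assert out.loc[0, "n"] == 4


class TestSummarize:
    def test_synthetic_summary_fields(self, preset_ii_spheroid):
        from cz3geom.pipeline import extract_record
        s = preset_ii_spheroid
        rec = extract_record(s.cell_polys, s.compartments, stage="II")
        summ = summarize_spheroid(rec)
        assert summ.n_features > 100
        assert summ.k_alpha is not None and summ.k_alpha > 0
        assert summ.k_area is not None and summ.k_area > 1
        assert summ.partition_cost >= 1.0 / (2.0 * math.pi)
        assert summ.median_e_v is not None and 0 <= summ.median_e_v < 0.5
        assert 0.9 < summ.covering_fraction <= 1.01
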