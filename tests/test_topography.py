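"""Stereology, kernel density maps, in-situ fractions and the cone mosaic."""

import numpy as np
import pandas as pd
import pytest
from shapely.affinity import rotate
from shapely.geometry import Point

from anemovis.topography import (CountGrid, RetinaOutline, TopographyError,
                                 coexpression_region, find_peak,
                                 fish_proportions, fractionator_total,
                                 kernel_map, mosaic_lattice, ratio_map,
                                 scheaffer_ce, site_density)


def make_grid(xy, counts, a=0.01, A=1.0, cls="ganglion"):
    xy = np.asarray(xy, dtype=float)
    return CountGrid(pd.DataFrame({"x_mm": xy[:, 0], "y_mm": xy[:, 1],
                                   cls: counts}), a, A)


@pytest.fixture
def disc_outline():
    return RetinaOutline(Point(0, 0).buffer(3.0, quad_segs=64))


class TestStereology:
    def test_site_density(self):
        assert site_density(10, 0.01) == 1000.0
        assert site_density(0, 0.01) == 0.0
        assert site_density(20, 0.01) == 2 * site_density(10, 0.01)

    def test_fractionator_arithmetic(self):
        g = make_grid([(0, 0), (1, 0), (0, 1), (1, 1)], [10, 10, 10, 10])
        assert fractionator_total(g, "ganglion") == 4000.0

    def test_fractionator_linear_in_counts(self):
        xy = [(0, 0), (1, 0), (0, 1)]
        g1 = make_grid(xy, [3, 5, 7])
        g2 = make_grid(xy, [6, 10, 14])
        assert fractionator_total(g2, "ganglion") == 2 * fractionator_total(
            g1, "ganglion")

    def test_missing_class_rejected(self):
        g = make_grid([(0, 0), (1, 1)], [1, 2])
        with pytest.raises(TopographyError):
            fractionator_total(g, "amacrine")

    def test_ce_zero_for_uniform_counts(self):
        g = make_grid([(0, 0), (1, 0), (0, 1)], [5, 5, 5])
        assert scheaffer_ce(g, "ganglion") == 0.0

    def test_ce_hand_value(self):
        # counts (0, 10): s = 7.071, SEM = 5, mean = 5 → CE = 1
        g = make_grid([(0, 0), (1, 0)], [0, 10])
        assert scheaffer_ce(g, "ganglion") == pytest.approx(1.0)

    def test_ce_shrinks_as_sqrt_n_under_replication(self):
        rng = np.random.default_rng(7)
        base = list(rng.poisson(20, 100))
        g1 = make_grid([(i, 0) for i in range(100)], base)
        g4 = make_grid([(i, 0) for i in range(400)], base * 4)
        ce1 = scheaffer_ce(g1, "ganglion")
        ce4 = scheaffer_ce(g4, "ganglion")
        assert ce4 == pytest.approx(ce1 / 2, rel=0.01)

    def test_rigid_rotation_leaves_totals_invariant(self, disc_outline):
        rng = np.random.default_rng(5)
        xy = rng.uniform(-2, 2, size=(40, 2))
        counts = rng.poisson(20, 40)
        g = make_grid(xy, counts, a=0.01, A=0.4)
        theta = np.deg2rad(35.0)
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        g_rot = make_grid(xy @ rot.T, counts, a=0.01, A=0.4)
        assert fractionator_total(g, "ganglion") == fractionator_total(
            g_rot, "ganglion")
        assert scheaffer_ce(g, "ganglion") == scheaffer_ce(g_rot, "ganglion")
        m = kernel_map(g, disc_outline, "ganglion", sigma_mm=0.5, step_mm=0.25)
        outline_rot = RetinaOutline(rotate(disc_outline.polygon, 35.0,
                                           origin=(0, 0)))
        m_rot = kernel_map(g_rot, outline_rot, "ganglion", sigma_mm=0.5,
                           step_mm=0.25)
        px, py, pk = find_peak(m)
        qx, qy, qk = find_peak(m_rot)
        assert pk == pytest.approx(qk, rel=0.05)  # peak value rotates with the map
        back = rot.T @ np.array([qx, qy])
        assert np.hypot(back[0] - px, back[1] - py) < 0.5


class TestKernelMap:
    def test_single_site_unimodal_at_site(self, disc_outline):
        g = make_grid([(0.8, -0.4)], [10], a=0.01, A=0.25)
        m = kernel_map(g, disc_outline, "ganglion", sigma_mm=0.5)
        px, py, _ = find_peak(m)
        assert abs(px - 0.8) <= m.step_mm and abs(py + 0.4) <= m.step_mm

    def test_two_separated_sites_give_two_equal_maxima(self, disc_outline):
        g = make_grid([(-1.5, 0), (1.5, 0)], [10, 10], a=0.01, A=0.25)
        m = kernel_map(g, disc_outline, "ganglion", sigma_mm=0.3, step_mm=0.1)
        # brute-force raster scan for local maxima
        d = m.density
        interior = d[1:-1, 1:-1]
        local_max = ((interior >= d[:-2, 1:-1]) & (interior >= d[2:, 1:-1])
                     & (interior >= d[1:-1, :-2]) & (interior >= d[1:-1, 2:])
                     & (interior > 0))
        peaks = interior[local_max]
        top_two = np.sort(peaks)[-2:]
        assert top_two[0] == pytest.approx(top_two[1], rel=1e-6)

    def test_mass_consistency_with_site_density(self, disc_outline):
        # area-weighted mean map density tracks the mean site density
        rng = np.random.default_rng(2)
        h = 0.5
        xs = np.arange(-3, 3.01, h)
        xx, yy = np.meshgrid(xs, xs)
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        pts = pts[np.hypot(pts[:, 0], pts[:, 1]) <= 3.0]
        counts = rng.poisson(25, len(pts))
        g = make_grid(pts, counts, a=0.01, A=h * h)
        m = kernel_map(g, disc_outline, "ganglion")
        mean_site_density = counts.mean() / 0.01
        assert m.masked_mean() == pytest.approx(mean_site_density, rel=0.05)

    def test_peak_bounded_by_max_site_density(self, disc_outline):
        rng = np.random.default_rng(3)
        h = 0.5
        xs = np.arange(-3, 3.01, h)
        xx, yy = np.meshgrid(xs, xs)
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        pts = pts[np.hypot(pts[:, 0], pts[:, 1]) <= 3.0]
        counts = rng.poisson(25, len(pts))
        g = make_grid(pts, counts, a=0.01, A=h * h)
        m = kernel_map(g, disc_outline, "ganglion", sigma_mm=h)
        _, _, peak = find_peak(m)
        assert peak <= counts.max() / 0.01 * 1.05

    def test_no_sites_inside_outline_rejected(self, disc_outline):
        g = make_grid([(10, 10)], [5], a=0.01, A=0.25)
        with pytest.raises(TopographyError):
            kernel_map(g, disc_outline, "ganglion")

    def test_flat_map_peak_ties_to_centroid_with_warning(self, disc_outline):
        m = kernel_map(make_grid([(0, 0)], [10], a=0.01, A=0.25),
                       disc_outline, "ganglion", sigma_mm=0.5)
        flat = m.density.copy()
        flat[m.mask] = 7.0
        flat_map = type(m)(m.x_mm, m.y_mm, flat, m.mask, m.sigma_mm)
        with pytest.warns(UserWarning, match="tie"):
            px, py, pk = find_peak(flat_map)
        assert pk == 7.0
        assert np.hypot(px, py) < 0.2  # near the disc centroid


class TestRatioMap:
    def test_constant_ratio(self, disc_outline):
        g = make_grid([(0, 0), (1, 1)], [10, 20], a=0.01, A=0.25)
        m1 = kernel_map(g, disc_outline, "ganglion", sigma_mm=0.5)
        m2 = type(m1)(m1.x_mm, m1.y_mm, m1.density / 2, m1.mask, m1.sigma_mm)
        r = ratio_map(m1, m2)
        assert np.allclose(r.density[r.mask], 2.0)

    def test_low_denominator_cells_masked(self, disc_outline):
        g = make_grid([(0, 0)], [10], a=0.01, A=0.25)
        m1 = kernel_map(g, disc_outline, "ganglion", sigma_mm=0.3)
        r = ratio_map(m1, m1, floor=1.0)
        assert r.mask.sum() < m1.mask.sum()

    def test_mismatched_rasters_rejected(self, disc_outline):
        g = make_grid([(0, 0)], [10], a=0.01, A=0.25)
        m1 = kernel_map(g, disc_outline, "ganglion", sigma_mm=0.5, step_mm=0.25)
        m2 = kernel_map(g, disc_outline, "ganglion", sigma_mm=0.5, step_mm=0.2)
        with pytest.raises(TopographyError):
            ratio_map(m1, m2)


def fish_grid(rows):
    df = pd.DataFrame(rows, columns=["x_mm", "y_mm", "single_cones", "sws1",
                                     "sws2b_coexp", "double_cones",
                                     "rh2_paired", "lws"])
    return CountGrid(df, 0.01, 0.25)


class TestFishProportions:
    def test_site_fractions(self):
        g = fish_grid([(0, 0, 10, 10, 3, 100, 99, 1)])
        per_site, pooled = fish_proportions(g)
        by_metric = per_site.set_index("metric")["fraction"]
        assert by_metric["rh2_pairing"] == pytest.approx(0.99)
        assert by_metric["sws_coexpression"] == pytest.approx(0.30)

    def test_pooled_is_count_weighted(self):
        g = fish_grid([(0, 0, 10, 10, 0, 100, 100, 0),
                       (1, 0, 30, 30, 30, 300, 270, 0)])
        _, pooled = fish_proportions(g)
        pairing = pooled.set_index("metric").loc["rh2_pairing"]
        assert pairing["fraction"] == pytest.approx(370 / 400)
        coexp = pooled.set_index("metric").loc["sws_coexpression"]
        assert coexp["fraction"] == pytest.approx(30 / 40)
        assert coexp["ci_low"] < coexp["fraction"] < coexp["ci_high"]

    def test_zero_denominator_sites_skipped_with_warning(self):
        g = fish_grid([(0, 0, 10, 10, 1, 0, 0, 0),
                       (1, 0, 10, 10, 2, 50, 49, 0)])
        with pytest.warns(UserWarning, match="skipped"):
            per_site, _ = fish_proportions(g)
        pairing_sites = per_site[per_site["metric"] == "rh2_pairing"]
        assert len(pairing_sites) == 1


class TestCoexpressionRegion:
    def grid_with_disc(self, fraction=0.5, center=(1.5, 0.0), radius=0.6):
        h = 0.3
        xs = np.arange(-3, 3.01, h)
        xx, yy = np.meshgrid(xs, xs)
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        pts = pts[np.hypot(pts[:, 0], pts[:, 1]) <= 3.0]
        n = np.full(len(pts), 40)
        inside = np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1]) <= radius
        coexp = np.where(inside, int(round(fraction * 40)), 0)
        df = pd.DataFrame({"x_mm": pts[:, 0], "y_mm": pts[:, 1],
                           "single_cones": n, "sws2b_coexp": coexp})
        return CountGrid(df, 0.01, h * h)

    def test_zero_coexpression_finds_nothing(self, disc_outline):
        g = self.grid_with_disc(fraction=0.0)
        assert coexpression_region(g, disc_outline) is None
        assert coexpression_region(g, disc_outline, threshold=0.2) is None

    def test_threshold_zero_covers_whole_retina(self, disc_outline):
        g = self.grid_with_disc()
        reg = coexpression_region(g, disc_outline, threshold=0.0)
        assert reg is not None
        assert reg.area_mm2 == pytest.approx(disc_outline.area_mm2, rel=0.05)

    def test_disc_recovered_at_half_peak(self, disc_outline):
        reg = coexpression_region(self.grid_with_disc(), disc_outline)
        assert reg is not None
        assert np.hypot(reg.centroid_mm[0] - 1.5, reg.centroid_mm[1]) < 0.25
        assert reg.area_mm2 == pytest.approx(np.pi * 0.6 ** 2, rel=0.3)
        assert reg.peak_fraction > 0.3


class TestMosaic:
    @pytest.mark.parametrize("rows,cols", [(2, 2), (3, 7), (10, 10)])
    def test_double_single_ratio_exactly_two(self, rows, cols):
        lat = mosaic_lattice(rows, cols)
        assert lat.double_single_ratio == 2.0

    def test_unit_cell_counting(self):
        lat = mosaic_lattice(10, 10)
        types = lat.positions["type"].value_counts()
        assert types["single"] == 100 and types["double"] == 200

    def test_every_single_cone_has_four_double_neighbours(self):
        assert mosaic_lattice(4, 5).audit_neighbors()

    def test_too_small_lattice_rejected(self):
        with pytest.raises(TopographyError):
            mosaic_lattice(1, 5)
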