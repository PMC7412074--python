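import numpy as np
import pytest
from shapely.geometry import Point

from clonescape.clones import assign_mlg, mismatch_matrix
from clonescape.geometry import (
    GenetFootprint,
    buffer_polygons,
    genet_footprints,
    genet_hulls,
    impute_agen,
    overlap_report,
    patch_areas,
    stadium_half_width,
)
from clonescape.io import Dataset
from tests.conftest import make_unit


def _units_with_clones(groups):
    """groups: list of lists of (x, y); each group one genet."""
    units = []
    for g, pts in enumerate(groups):
        for i, (x, y) in enumerate(pts):
            units.append(make_unit(f"g{g}r{i:02d}", x, y, "P", [(g + 1, g + 1)]))
    m = mismatch_matrix(units)
    return units, assign_mlg(m, [u.sample_id for u in units], 0)


class TestHulls:
    def test_triangle_area(self):
        units, part = _units_with_clones([[(0, 0), (1, 0), (0, 1)]])
        foots, degen = genet_hulls(units, part)
        assert not degen
        assert foots[0].area == pytest.approx(0.5)

    def test_unit_square(self):
        units, part = _units_with_clones([[(0, 0), (1, 0), (1, 1), (0, 1)]])
        foots, _ = genet_hulls(units, part)
        assert foots[0].area == pytest.approx(1.0)

    def test_matches_scipy_hull_oracle(self, rng):
        pts = rng.uniform(0, 10, size=(25, 2))
        units, part = _units_with_clones([[tuple(p) for p in pts]])
        foots, _ = genet_hulls(units, part)
        from scipy.spatial import ConvexHull

        assert foots[0].area == pytest.approx(ConvexHull(pts).volume)

    def test_collinear_rerouted(self):
        units, part = _units_with_clones([[(0, 0), (1, 0), (2, 0)]])
        with pytest.warns(UserWarning, match="collinear"):
            foots, degen = genet_hulls(units, part)
        assert foots == [] and degen == [0]


class TestImputation:
    def test_stated_divisors(self):
        units, part = _units_with_clones(
            [
                [(0, 0), (1.2, 0), (0, 1)],  # 3 ramets, hull area 0.6
                [(5, 5)],  # singleton
                [(8, 8), (9, 8)],  # pair
            ]
        )
        hulls, _ = genet_hulls(units, part)
        assert hulls[0].area == pytest.approx(0.6)
        agen = impute_agen(hulls, part)
        assert agen[hulls[0].mlg_id] == pytest.approx(0.6)
        sizes = part.clone_sizes()
        for g, a in agen.items():
            if sizes[g] == 1:
                assert a == pytest.approx(0.2)
            elif sizes[g] == 2:
                assert a == pytest.approx(0.4)

    def test_idempotent_on_complete_inputs(self):
        units, part = _units_with_clones(
            [[(0, 0), (1, 0), (0, 1)], [(4, 4), (6, 4), (4, 6), (6, 6)]]
        )
        hulls, _ = genet_hulls(units, part)
        agen = impute_agen(hulls, part)
        for f in hulls:
            assert agen[f.mlg_id] == f.area

    def test_no_calibration_genet_is_error(self):
        units, part = _units_with_clones([[(0, 0)], [(3, 3), (4, 3)]])
        with pytest.raises(ValueError, match="a3_override"):
            impute_agen([], part)
        agen = impute_agen([], part, a3_override=0.9)
        assert agen[part.mlg_of("g0r00")] == pytest.approx(0.3)


class TestBuffers:
    def test_disc_degenerate_quadratic(self):
        assert stadium_half_width(0.0, np.pi) == pytest.approx(1.0)

    def test_stadium_hand_value(self):
        # area pi w^2 + 2 d w with d = 2, w = 1 -> pi + 4
        assert stadium_half_width(2.0, np.pi + 4.0) == pytest.approx(1.0)

    def test_polygon_area_within_tolerance(self, rng):
        units, part = _units_with_clones([[(0, 0)], [(5, 5), (7, 6)]])
        targets = {g: t for g, t in zip(range(part.n_mlg), (2.5, 4.0))}
        foots = buffer_polygons(units, part, targets)
        for f in foots:
            assert abs(f.polygon.area - f.area) / f.area < 0.01
            assert f.area == pytest.approx(targets[f.mlg_id])

    def test_rotation_translation_equivariance(self):
        base = [(0.0, 0.0), (3.0, 0.0)]
        theta, shift = 0.7, np.array([10.0, -4.0])
        rot = [
            tuple(np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]) @ p + shift)
            for p in map(np.array, base)
        ]
        u1, p1 = _units_with_clones([base])
        u2, p2 = _units_with_clones([rot])
        f1 = buffer_polygons(u1, p1, {0: 5.0})[0]
        f2 = buffer_polygons(u2, p2, {0: 5.0})[0]
        assert f1.polygon.area == pytest.approx(f2.polygon.area, rel=1e-9)

    def test_nonpositive_target_is_error(self):
        units, part = _units_with_clones([[(0, 0)]])
        with pytest.raises(ValueError):
            buffer_polygons(units, part, {0: 0.0})


class TestOverlap:
    def _foot(self, mlg, poly):
        return GenetFootprint(mlg, poly, poly.area, "hull")

    def test_two_squares_hand_geometry(self):
        from shapely.geometry import box

        a, b = box(0, 0, 1, 1), box(0.5, 0, 1.5, 1)
        rep = overlap_report([self._foot(0, a), self._foot(1, b)])
        assert rep.percent == pytest.approx(100 * 0.5 / 1.5)
        assert rep.max_multiplicity == 2

    def test_disjoint(self):
        rep = overlap_report(
            [self._foot(0, Point(0, 0).buffer(1)), self._foot(1, Point(10, 0).buffer(1))]
        )
        assert rep.percent == 0.0 and rep.max_multiplicity == 1

    def test_monte_carlo_oracle_on_random_discs(self, rng):
        discs = [Point(*rng.uniform(0, 6, 2)).buffer(rng.uniform(0.5, 1.5)) for _ in range(6)]
        rep = overlap_report([self._foot(i, d) for i, d in enumerate(discs)])
        pts = rng.uniform(-2, 8, size=(100_000, 2))
        inside = np.zeros(len(pts), dtype=int)
        for d in discs:
            c = np.array(d.centroid.coords[0])
            r = np.sqrt(d.area / np.pi)
            inside += (np.sum((pts - c) ** 2, axis=1) <= r * r).astype(int)
        area_box = 100.0
        union_mc = np.mean(inside >= 1) * area_box
        multi_mc = np.mean(inside >= 2) * area_box
        pct_mc = 100 * multi_mc / union_mc
        se = 100 * 3 / np.sqrt(100_000)  # generous 3-sigma band on the percent
        assert abs(rep.percent - pct_mc) < se
        assert rep.union_area == pytest.approx(union_mc, rel=0.05)

    def test_union_bounds_and_pairwise_cap(self, rng):
        discs = [Point(*rng.uniform(0, 4, 2)).buffer(1.0) for _ in range(5)]
        foots = [self._foot(i, d) for i, d in enumerate(discs)]
        rep = overlap_report(foots)
        assert rep.union_area >= max(f.area for f in foots) - 1e-9
        assert sum(a for _, _, a in rep.pairwise) >= rep.multi_area - 1e-9
        for ga, gb, a in rep.pairwise:
            assert a <= min(foots[ga].polygon.area, foots[gb].polygon.area) + 1e-9


class TestPatchAreas:
    def test_known_shapes(self):
        ds = Dataset(
            ["L"],
            [make_unit("s", 0, 0, "P1", [(1, 1)])],
            patch_outlines={
                "P1": [(0, 0), (1, 0), (1, 1), (0, 1)],
                "P2": [(0, 0), (2, 0), (0, 2)],
            },
        )
        areas = patch_areas(ds)
        assert areas["P1"] == pytest.approx(1.0)
        assert areas["P2"] == pytest.approx(2.0)

    def test_shoelace_oracle_on_random_star_polygon(self, rng):
        ang = np.sort(rng.uniform(0, 2 * np.pi, 12))
        rad = rng.uniform(1, 3, 12)
        verts = [(r * np.cos(a), r * np.sin(a)) for r, a in zip(rad, ang)]
        ds = Dataset(["L"], [make_unit("s", 0, 0, "P", [(1, 1)])], patch_outlines={"P": verts})
        x, y = np.array([v[0] for v in verts]), np.array([v[1] for v in verts])
        shoelace = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        assert patch_areas(ds)["P"] == pytest.approx(shoelace)

    def test_self_intersection_names_patch(self):
        ds = Dataset(
            ["L"],
            [make_unit("s", 0, 0, "PX", [(1, 1)])],
            patch_outlines={"PX": [(0, 0), (1, 1), (1, 0), (0, 1)]},
        )
        with pytest.raises(ValueError, match="PX"):
            patch_areas(ds)


def test_full_footprint_set_mixes_methods():
    units, part = _units_with_clones(
        [
            [(0, 0), (1.2, 0), (0, 1)],
            [(5, 5)],
            [(8, 8), (9, 8)],
            [(0, 10), (1, 10), (2, 10)],  # collinear
        ]
    )
    with pytest.warns(UserWarning, match="collinear"):
        foots = genet_footprints(units, part)
    methods = {f.mlg_id: f.method for f in foots}
    assert sorted(methods.values()) == ["buffer_pair", "buffer_pair", "buffer_single", "hull"]
    assert len(foots) == part.n_mlg
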