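import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from conftest import grid_pattern, random_pattern
from _oracles import nearest_site_index, regular_polygon, shoelace_area
from vorogis.errors import (
    ContractError,
    DegenerateInputError,
    DuplicateSiteError,
    TooFewPointsError,
)
from vorogis.points import PointPattern, Rect
from vorogis.voronoi import (
    VoronoiCell,
    cell_metrics,
    convex_hull,
    exclude_marginal,
    population_indices,
    sociology,
    voronoi_cells,
)


def make_cell(ring):
    ring = np.asarray(ring, dtype=float)
    x, y = ring[:, 0], ring[:, 1]
    xs, ys = np.roll(x, -1), np.roll(y, -1)
    area = 0.5 * abs(np.sum(x * ys - xs * y))
    perim = float(np.sum(np.hypot(xs - x, ys - y)))
    return VoronoiCell(0, ring, area, perim, 4 * np.pi * area / perim**2, open=False)


class TestVoronoiCells:
    def test_3x3_grid_one_bounded(self):
        cells = voronoi_cells(grid_pattern(3))
        bounded = [c for c in cells if not c.open]
        assert len(cells) == 9 and len(bounded) == 1
        # the bounded cell is the center site's unit square
        assert bounded[0].site_index == 4
        assert bounded[0].area == pytest.approx(1.0)

    def test_too_few_points(self):
        pat = PointPattern(np.array([[0.0, 0.0], [1.0, 1.0]]), frame=Rect(0, 0, 1, 1))
        with pytest.raises(TooFewPointsError):
            voronoi_cells(pat)

    def test_duplicate_sites_rejected(self):
        pat = PointPattern(
            np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [0.0, 1.0]]),
            frame=Rect(0, 0, 1, 1),
        )
        with pytest.raises(DuplicateSiteError) as e:
            voronoi_cells(pat)
        assert (0, 1) in e.value.pairs

    def test_collinear_rejected(self):
        pat = PointPattern(
            np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]]), frame=Rect(0, 0, 2, 1)
        )
        with pytest.raises(DegenerateInputError):
            voronoi_cells(pat)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_open_plus_bounded_partition_sites(self, seed):
        cells = voronoi_cells(random_pattern(60, seed))
        assert sum(c.open for c in cells) + sum(not c.open for c in cells) == 60

    def test_partition_oracle_nearest_site(self, rng):
        """Every interior test point falls in the bounded cell of its
        nearest site."""
        pat = random_pattern(40, seed=11)
        cells = voronoi_cells(pat)
        polys = {c.site_index: Polygon(c.vertices) for c in cells if not c.open}
        sites = [tuple(p) for p in pat.xy]
        hits = 0
        for _ in range(1000):
            q = rng.uniform(10, 90, 2)
            for idx, poly in polys.items():
                if poly.contains(Point(q)):
                    assert nearest_site_index(q, sites) == idx
                    hits += 1
                    break
        assert hits > 500  # most interior draws land in bounded cells


class TestConvexHull:
    def test_interior_point_excluded(self):
        pat = PointPattern(
            np.array([[0.0, 0.0], [2.0, 0.0], [2.0, 2.0], [0.0, 2.0], [1.0, 1.0]]),
            frame=Rect(0, 0, 2, 2),
        )
        hull = convex_hull(pat)
        assert hull.shape == (4, 2)
        assert shoelace_area([tuple(v) for v in hull]) == pytest.approx(4.0)

    def test_circle_all_extreme(self):
        theta = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        pat = PointPattern(
            np.column_stack([np.cos(theta), np.sin(theta)]) + 2.0,
            frame=Rect(0, 0, 4, 4),
        )
        assert convex_hull(pat).shape == (12, 2)

    def test_degenerate_raises(self):
        pat = PointPattern(
            np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]), frame=Rect(0, 0, 2, 2)
        )
        with pytest.raises(DegenerateInputError):
            convex_hull(pat)


class TestExcludeMarginal:
    @pytest.mark.parametrize("k,expected", [(3, 1), (5, 9)])
    def test_lattice_retained_counts(self, k, expected):
        pat = grid_pattern(k)
        cells = voronoi_cells(pat)
        retained = exclude_marginal(cells, convex_hull(pat))
        assert len(retained) == expected

    def test_all_sites_on_circle_retains_none(self):
        theta = np.linspace(0, 2 * np.pi, 16, endpoint=False)
        pat = PointPattern(
            2.0 + np.column_stack([np.cos(theta), np.sin(theta)]),
            frame=Rect(0, 0, 4, 4),
        )
        assert exclude_marginal(voronoi_cells(pat), convex_hull(pat)) == []

    def test_monotone_in_eps(self):
        pat = random_pattern(80, seed=3)
        cells = voronoi_cells(pat)
        hull = convex_hull(pat)
        counts = [len(exclude_marginal(cells, hull, eps=e)) for e in (1e-12, 1e-6, 1.0, 10.0)]
        assert counts == sorted(counts)


class TestCellMetrics:
    def test_unit_square(self):
        a, l, rf = cell_metrics(make_cell([(0, 0), (1, 0), (1, 1), (0, 1)]))
        assert (a, l) == (1.0, 4.0)
        assert rf == pytest.approx(np.pi / 4)

    def test_regular_hexagon(self):
        a, l, rf = cell_metrics(make_cell(regular_polygon(6)))
        assert a == pytest.approx(3 * np.sqrt(3) / 2)
        assert l == pytest.approx(6.0)
        assert rf == pytest.approx(np.pi * np.sqrt(3) / 6)

    def test_elongation_drives_rf_to_zero(self):
        _, _, rf = cell_metrics(make_cell([(0, 0), (100, 0), (100, 1), (0, 1)]))
        assert rf == pytest.approx(400 * np.pi / 40804)

    def test_rf_of_regular_kgons_increases_toward_one(self):
        rfs = [cell_metrics(make_cell(regular_polygon(k)))[2] for k in (3, 4, 6, 12)]
        assert rfs == sorted(rfs) and rfs[-1] < 1.0
        # closed form: RF(k) = (π/k)/tan(π/k)
        for k, rf in zip((3, 4, 6, 12), rfs):
            assert rf == pytest.approx((np.pi / k) / np.tan(np.pi / k))

    def test_open_cell_rejected(self):
        with pytest.raises(ContractError):
            cell_metrics(VoronoiCell(0, None, None, None, None, open=True))


class TestPopulationIndices:
    def test_congruent_cells_perfect_order(self):
        cells = [make_cell(np.array(regular_polygon(6)) + 10 * i) for i in range(4)]
        idx = population_indices(cells)
        assert idx.area_disorder == pytest.approx(0.0, abs=1e-12)
        assert idx.rf_homogeneity == pytest.approx(1.0, abs=1e-12)

    def test_two_cell_area_disorder_formula(self):
        c1 = make_cell([(0, 0), (1, 0), (1, 1), (0, 1)])
        c3 = make_cell([(0, 0), (3, 0), (3, 1), (0, 1)])
        idx = population_indices([c1, c3])
        # areas {1, 3}: sample σ_A = √2, mean 2 → AD = 1 − 1/(1+√2/2)
        assert idx.area_disorder == pytest.approx(1 - 1 / (1 + np.sqrt(2) / 2))
        assert idx.area_disorder == pytest.approx(0.414214, abs=1e-6)

    def test_equal_rfs_give_unit_homogeneity(self):
        sq = [
            make_cell([(0, 0), (1, 0), (1, 1), (0, 1)]),
            make_cell([(0, 0), (2, 0), (2, 2), (0, 2)]),
        ]
        idx = population_indices(sq)  # both RF = π/4
        assert idx.rf_homogeneity == pytest.approx(1.0)

    def test_population_sd_option(self):
        c1 = make_cell([(0, 0), (1, 0), (1, 1), (0, 1)])
        c3 = make_cell([(0, 0), (3, 0), (3, 1), (0, 1)])
        idx = population_indices([c1, c3], ddof=0)
        assert idx.sd_area == pytest.approx(1.0)

    def test_too_few_cells(self):
        with pytest.raises(TooFewPointsError):
            population_indices([make_cell([(0, 0), (1, 0), (1, 1), (0, 1)])])

    def test_index_ranges_on_random_patterns(self):
        for seed in range(3):
            idx, _ = sociology(random_pattern(100, seed))
            assert 0 < idx.rf_av <= 1
            assert 0 <= idx.area_disorder < 1
            assert 0 < idx.rf_homogeneity <= 1


class TestHexLatticeLimit:
    def test_triangular_lattice_yields_regular_hexagons(self):
        """Interior Voronoi cells of a triangular site lattice are regular
        hexagons: RFav → π√3/6, AD → 0, RFH → 1."""
        rows = []
        for j in range(14):
            xs = np.arange(14, dtype=float) + (0.5 if j % 2 else 0.0)
            ys = np.full(14, j * np.sqrt(3) / 2)
            rows.append(np.column_stack([xs, ys]))
        xy = np.concatenate(rows)
        pat = PointPattern(xy, frame=Rect(-1, -1, 18, 16))
        idx, retained = sociology(pat)
        assert idx.rf_av == pytest.approx(np.pi * np.sqrt(3) / 6, abs=1e-6)
        assert idx.area_disorder == pytest.approx(0.0, abs=1e-6)
        assert idx.rf_homogeneity == pytest.approx(1.0, abs=1e-6)


class TestPhenotypePipeline:
    def test_sociology_orderings_on_triads(self):
        """Retained-polygon area is smallest and RFH highest for the compact
        central mass, with layered at the other extreme (20 seeds)."""
        from vorogis.synthetic import triad

        acc = {k: {"area": [], "rfh": []} for k in ("central_mass", "dispersing", "layered")}
        for s in range(20):
            for k, p in triad(seed=s).items():
                idx, _ = sociology(p)
                acc[k]["area"].append(idx.mean_area)
                acc[k]["rfh"].append(idx.rf_homogeneity)
        area = {k: np.mean(v["area"]) for k, v in acc.items()}
        rfh = {k: np.mean(v["rfh"]) for k, v in acc.items()}
        assert area["central_mass"] < area["dispersing"] < area["layered"]
        assert rfh["central_mass"] > rfh["dispersing"] > rfh["layered"]
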