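import numpy as np
import pytest

from conftest import random_pattern
from vorogis.errors import RangeError, TooFewPointsError, UndefinedStatisticError
from vorogis.globalstats import _k_function, ann, general_g, morans_i, ripleys_k
from vorogis.hexgrid import generate_hex_grid, spatial_join
from vorogis.points import PointPattern, Rect
from vorogis.synthetic import PatternSpec, generate
from vorogis.weights import build_weights, ensure_neighbor_threshold


def three_collinear():
    return np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])


class TestWeights:
    def test_inverse_distance_values(self):
        w = build_weights(three_collinear(), threshold=10.0)
        assert w.w[0, 1] == pytest.approx(1.0)
        assert w.w[1, 2] == pytest.approx(1.0)
        assert w.w[0, 2] == pytest.approx(0.5)
        np.testing.assert_allclose(w.w, w.w.T)  # symmetric before standardization

    def test_row_standardization(self):
        w = build_weights(three_collinear(), threshold=10.0, standardization="row")
        np.testing.assert_allclose(w.w[0], [0.0, 2 / 3, 1 / 3])
        np.testing.assert_allclose(w.w.sum(axis=1), 1.0, atol=1e-12)

    def test_fixed_band_cutoff(self):
        w = build_weights(three_collinear(), conceptualization="fixed_band", threshold=1.5)
        assert w.w[0, 1] == 1.0 and w.w[0, 2] == 0.0

    def test_default_threshold_guarantees_neighbors(self):
        coords = random_pattern(40, seed=1).xy
        w = build_weights(coords)
        offdiag = w.w.copy()
        np.fill_diagonal(offdiag, 0)
        assert np.all(offdiag.sum(axis=1) > 0)
        assert w.threshold == pytest.approx(ensure_neighbor_threshold(coords))

    def test_coincident_features_capped(self):
        coords = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0]])
        with pytest.warns(UserWarning, match="coincident"):
            w = build_weights(coords, threshold=2.0)
        assert w.w[0, 1] == pytest.approx(1e6)


class TestAnn:
    def test_two_point_closed_form(self):
        pat = PointPattern(np.array([[0.0, 0.0], [1.0, 0.0]]), frame=Rect(0, 0, 1, 1))
        res = ann(pat, area=1.0)
        assert res.meta["omd"] == pytest.approx(1.0)
        assert res.statistic == pytest.approx(2 * np.sqrt(2))

    def test_tight_cluster_is_strongly_clustered(self):
        rng = np.random.default_rng(0)
        xy = rng.normal(50, 0.01, (50, 2))
        pat = PointPattern(xy, frame=Rect(0, 0, 100, 100))
        res = ann(pat, area=10000.0)
        assert res.statistic < 0.01 and res.z_score < -10

    def test_requires_two_points(self):
        with pytest.raises(TooFewPointsError):
            ann(PointPattern(np.array([[1.0, 1.0]]), frame=Rect(0, 0, 2, 2)))

    def test_degenerate_area_rejected(self):
        pat = PointPattern(np.array([[0.0, 1.0], [0.0, 2.0]]), frame=Rect(0, 0, 5, 5))
        with pytest.raises(RangeError):
            ann(pat)  # enclosing rectangle has zero width


class TestGeneralG:
    def test_complete_graph_expectation(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, 0.8]])
        w = build_weights(coords, conceptualization="fixed_band", threshold=2.0)
        res = general_g(np.array([1.0, 2.0, 3.0]), w)
        assert res.expected == pytest.approx(1.0)  # S0=6 over n(n−1)=6
        assert res.statistic == pytest.approx(1.0)  # all pairs within band

    def test_two_positive_values_hand_evaluation(self):
        coords = np.array([[0.0, 0.0], [2.0, 0.0], [10.0, 0.0], [20.0, 0.0], [40.0, 0.0]])
        x = np.array([3.0, 3.0, 0.0, 0.0, 0.0])
        w = build_weights(coords, threshold=100.0)
        res = general_g(x, w)
        # only the (1,2) cross-product is nonzero: G = w_12 = 1/2
        assert res.statistic == pytest.approx(0.5)

    def test_constant_field_undefined(self):
        coords = random_pattern(10, seed=2).xy
        w = build_weights(coords)
        with pytest.raises(UndefinedStatisticError):
            general_g(np.ones(10), w)

    def test_clustered_high_values_positive_z(self):
        """High values concentrated in one corner give z > 0 in ≥95% of seeds."""
        xs, ys = np.meshgrid(np.arange(8.0), np.arange(8.0))
        coords = np.column_stack([xs.ravel(), ys.ravel()])
        w = build_weights(coords, conceptualization="fixed_band", threshold=1.1)
        block = (coords[:, 0] < 3) & (coords[:, 1] < 3)
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0.5, 1.5, 64)
            x[block] += 10
            hits += general_g(x, w).z_score > 0
        assert hits >= 95


class TestMoransI:
    def test_expected_value_closed_form(self):
        coords = random_pattern(26, seed=3).xy
        res = morans_i(np.arange(26.0), build_weights(coords))
        assert res.expected == pytest.approx(-0.04)

    def test_checkerboard_is_perfect_negative(self):
        xs, ys = np.meshgrid(np.arange(4.0), np.arange(4.0))
        coords = np.column_stack([xs.ravel(), ys.ravel()])
        w = build_weights(
            coords, conceptualization="fixed_band", threshold=1.0, standardization="row"
        )
        x = (-1.0) ** (xs + ys).ravel()
        res = morans_i(x, w)
        assert res.statistic == pytest.approx(-1.0)

    def test_affine_invariance(self):
        coords = random_pattern(30, seed=4).xy
        w = build_weights(coords)
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        a = morans_i(x, w).statistic
        b = morans_i(3.5 * x - 2.0, w).statistic
        assert a == pytest.approx(b, abs=1e-12)

    def test_rigid_motion_invariance(self):
        pat = random_pattern(40, seed=5)
        rng = np.random.default_rng(1)
        x = rng.poisson(3, 40).astype(float)
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = pat.xy @ rot.T + [500.0, 200.0]
        a = morans_i(x, build_weights(pat.xy))
        b = morans_i(x, build_weights(moved))
        assert a.statistic == pytest.approx(b.statistic, abs=1e-9)
        assert a.z_score == pytest.approx(b.z_score, abs=1e-6)

    def test_zero_variance_undefined(self):
        coords = random_pattern(10, seed=6).xy
        with pytest.raises(UndefinedStatisticError):
            morans_i(np.full(10, 2.0), build_weights(coords))

    def test_permutation_inference_seeded(self):
        coords = random_pattern(30, seed=7).xy
        w = build_weights(coords)
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        p1 = morans_i(x, w, inference="permutation", seed=42).p_value
        p2 = morans_i(x, w, inference="permutation", seed=42).p_value
        assert p1 == p2


class TestRipley:
    def test_two_point_count_formula(self):
        xy = np.array([[0.0, 0.0], [1.0, 0.0]])
        k = _k_function(xy, np.array([0.5, 1.5]), area=1.0)
        np.testing.assert_allclose(k, [0.0, 1.0])

    def test_distance_range_enforced(self):
        pat = random_pattern(20, seed=8)
        with pytest.raises(RangeError):
            ripleys_k(pat, distances=np.array([90.0]), n_perm=0)

    def test_central_mass_exceeds_csr_expectation(self):
        """Clustered patterns have K(d) > πd² at short range (d ≤ 2σ)."""
        hits = 0
        for seed in range(40):
            p = generate(PatternSpec(kind="central_mass", n=200, seed=seed))
            res = ripleys_k(p, distances=np.array([40.0, 80.0]), n_perm=0)
            hits += np.all(res.k > np.pi * res.distances**2)
        assert hits >= 38  # ≥95%

    def test_envelope_shape_and_determinism(self):
        p = generate(PatternSpec(kind="csr", n=80, seed=1))
        a = ripleys_k(p, n_perm=19, seed=3)
        b = ripleys_k(p, n_perm=19, seed=3)
        np.testing.assert_array_equal(a.envelope_lo, b.envelope_lo)
        assert np.all(a.envelope_lo <= a.envelope_hi)


class TestOrientationRobustness:
    def test_moran_z_stable_under_quarter_turn(self):
        """Rotating the pattern 90° (equivalent to a flat-top grid on the
        original) leaves the hexbin Moran's I conclusion unchanged."""
        p = generate(PatternSpec(kind="central_mass", n=300, seed=4))
        c = 450.0
        rot = PointPattern(
            np.column_stack([c - (p.xy[:, 1] - c), p.xy[:, 0]]), frame=p.frame
        )
        zs = []
        for q in (p, rot):
            grid = spatial_join(generate_hex_grid(q.frame), q)
            w = build_weights(grid.centers, standardization="row")
            zs.append(morans_i(grid.counts.astype(float), w).z_score)
        assert zs[0] > 3 and zs[1] > 3
        assert abs(zs[0] - zs[1]) / zs[0] < 0.25
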