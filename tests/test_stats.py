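import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate
from scipy.spatial.distance import cdist

from infilstat import (
    PointPattern,
    RadiusGrid,
    Window,
    j_function,
    nn_distribution,
    pair_correlation,
    spherical_contact,
    summary_features,
)
from infilstat.stats import CurveKind, InsufficientPointsError, disc_window_area  # noqa: F401
from infilstat.synthetic import GenerationParams, generate_pattern

from conftest import random_pattern


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def disc_window_area_numeric(x, y, radius, window):
    """Disc-window intersection area by 1-D adaptive quadrature per quadrant."""
    total = 0.0
    for a, b in [(x, y), (x, window.height - y),
                 (window.width - x, y), (window.width - x, window.height - y)]:
        if radius <= 0 or a <= 0 or b <= 0:
            continue

        def f(t):
            return min(b, np.sqrt(max(radius ** 2 - t ** 2, 0.0)))

        upper = min(a, radius)
        kink = np.sqrt(max(radius ** 2 - b ** 2, 0.0))
        pts = [kink] if 0 < kink < upper else None
        val, _ = integrate.quad(f, 0.0, upper, points=pts, limit=200)
        total += val
    return total


def pcf_oracle(pattern, grid):
    """Brute-force PCF: pair enumeration + quadrature edge correction."""
    xy = pattern.xy
    n = len(xy)
    lam = n / pattern.window.area
    edges = grid.bin_edges
    dist = cdist(xy, xy)
    values = []
    for k in range(len(grid.r_values)):
        lo, hi = edges[k], edges[k + 1]
        ratios = []
        for i in range(n):
            count = sum(1 for j in range(n)
                        if j != i and lo < dist[i, j] <= hi)
            area = (disc_window_area_numeric(*xy[i], hi, pattern.window)
                    - disc_window_area_numeric(*xy[i], lo, pattern.window))
            ratios.append(count / (lam * area))
        values.append(np.mean(ratios))
    return np.array(values)


def nn_cdf_oracle(xy, r_values):
    n = len(xy)
    nnd = [min(np.hypot(*(xy[i] - xy[j])) for j in range(n) if j != i)
           for i in range(n)]
    return np.array([np.mean([d <= r for d in nnd]) for r in r_values])


def scd_cdf_oracle(xy, refs, r_values):
    dists = [min(np.hypot(*(ref - p)) for p in xy) for ref in refs]
    return np.array([np.mean([d <= r for d in dists]) for r in r_values])


# ---------------------------------------------------------------------------
# edge-corrected PCF
# ---------------------------------------------------------------------------

class TestDiscWindowArea:
    @pytest.mark.parametrize("x,y,r", [
        (0.75, 0.75, 0.3),   # disc fully inside
        (0.05, 0.75, 0.3),   # clipped by one edge
        (0.05, 0.05, 0.3),   # clipped by a corner
        (0.0, 0.0, 0.75),    # centred on a corner
        (0.75, 0.75, 1.2),   # larger than the window half-diagonal
    ])
    def test_matches_quadrature(self, x, y, r, window):
        analytic = disc_window_area([[x, y]], np.array([[r]]), window)[0, 0]
        numeric = disc_window_area_numeric(x, y, r, window)
        assert analytic == pytest.approx(numeric, rel=1e-9, abs=1e-12)

    def test_interior_disc_is_full_circle(self, window):
        a = disc_window_area([[0.75, 0.75]], np.array([[0.2]]), window)[0, 0]
        assert a == pytest.approx(np.pi * 0.04, rel=1e-12)


class TestPairCorrelation:
    def test_csr_fluctuates_around_one(self, csr_pattern):
        g = pair_correlation(csr_pattern)
        assert 0.9 <= np.nanmean(g.values) <= 1.1

    def test_hard_core_bins_are_zero(self):
        pattern, _ = generate_pattern(GenerationParams(rho=1.0, d=333, l=0.3), seed=5)
        g = pair_correlation(pattern)
        below = pattern.xy is not None
        edges = g.grid.bin_edges
        fully_below = edges[1:] <= 0.02
        assert below and np.all(g.values[fully_below] == 0.0)

    def test_brute_force_oracle_five_points(self, window):
        xy = [[0.1, 0.1], [0.2, 0.15], [0.7, 0.8], [1.4, 1.45], [0.75, 0.12]]
        pattern = PointPattern(xy, window)
        grid = RadiusGrid(dr=0.2, r_max=0.6)
        g = pair_correlation(pattern, grid)
        expected = pcf_oracle(pattern, grid)
        np.testing.assert_allclose(g.values, expected, rtol=1e-6)

    def test_insufficient_points(self, window):
        with pytest.raises(InsufficientPointsError):
            pair_correlation(PointPattern([[0.5, 0.5]], window))


# ---------------------------------------------------------------------------
# G, F and J
# ---------------------------------------------------------------------------

class TestNearestNeighbour:
    def test_two_points(self, window):
        p = PointPattern([[0.5, 0.5], [0.6, 0.5]], window)
        G = nn_distribution(p, RadiusGrid(dr=0.05, r_max=0.3))
        expected = np.where(G.r >= 0.1, 1.0, 0.0)
        np.testing.assert_allclose(G.values, expected)

    def test_three_collinear_points(self, window):
        p = PointPattern([[0.1, 0.5], [0.2, 0.5], [0.4, 0.5]], window)
        G = nn_distribution(p, RadiusGrid(dr=0.1, r_max=0.3))
        # NN distances {0.1, 0.1, 0.2}
        np.testing.assert_allclose(G.values, [2 / 3, 1.0, 1.0])

    def test_square_lattice_single_jump(self, window):
        s = 0.25
        g = np.arange(s, 1.5, s)
        xy = np.array([[x, y] for x in g for y in g])
        G = nn_distribution(PointPattern(xy, window), RadiusGrid(dr=0.05, r_max=0.5))
        np.testing.assert_allclose(G.values, np.where(G.r >= s, 1.0, 0.0))


class TestSphericalContact:
    def test_reference_hook_gives_exact_cdf(self, window):
        p = PointPattern([[0.75, 0.75]], window)
        gx = np.linspace(0.25, 1.25, 3)
        refs = np.array([[x, y] for x in gx for y in gx])
        grid = RadiusGrid(dr=0.1, r_max=0.75)
        F = spherical_contact(p, grid, reference_points=refs)
        np.testing.assert_allclose(F.values, scd_cdf_oracle(p.xy, refs, grid.r_values))

    def test_dense_grid_saturates(self, window):
        s = 0.01
        g = np.arange(s / 2, 1.5, s)
        xy = np.array([[x, y] for x in g for y in g])
        F = spherical_contact(PointPattern(xy, window), RadiusGrid(dr=0.01, r_max=0.05),
                              n_reference=200, seed=0)
        bound = s * np.sqrt(2) / 2 + 1e-9
        assert np.all(F.values[F.r >= 0.01] == 1.0)
        assert F.observations.max() <= bound

    def test_same_seed_reproduces(self, csr_pattern):
        F1 = spherical_contact(csr_pattern, seed=77)
        F2 = spherical_contact(csr_pattern, seed=77)
        np.testing.assert_array_equal(F1.values, F2.values)

    def test_empty_pattern_error(self, window):
        with pytest.raises(InsufficientPointsError):
            spherical_contact(PointPattern(np.empty((0, 2)), window), seed=0)


class TestJFunction:
    def _curves(self, gvals, fvals, grid):
        from infilstat.stats import StatCurve
        G = StatCurve(CurveKind.NN_CDF, grid, np.asarray(gvals, float))
        F = StatCurve(CurveKind.SCD_CDF, grid, np.asarray(fvals, float))
        return G, F

    def test_equal_cdfs_give_unity(self, small_grid):
        vals = np.linspace(0.1, 0.9, len(small_grid.r_values))
        J = j_function(*self._curves(vals, vals, small_grid))
        np.testing.assert_allclose(J.values, 1.0)

    def test_arithmetic_cases(self):
        grid = RadiusGrid(dr=0.1, r_max=0.2)
        J = j_function(*self._curves([1.0, 0.5], [0.5, 0.75], grid))
        np.testing.assert_allclose(J.values, [0.0, 2.0])

    def test_undefined_beyond_f_max(self):
        grid = RadiusGrid(dr=0.1, r_max=0.2)
        J = j_function(*self._curves([0.5, 0.9], [0.9, 1.0], grid))
        assert np.isfinite(J.values[0]) and np.isnan(J.values[1])

    def test_mismatched_grids_rejected(self):
        g1 = RadiusGrid(dr=0.1, r_max=0.2)
        g2 = RadiusGrid(dr=0.05, r_max=0.2)
        G, _ = self._curves([0.1, 0.2], [0.1, 0.2], g1)
        from infilstat.stats import StatCurve
        F = StatCurve(CurveKind.SCD_CDF, g2, np.linspace(0, 1, len(g2.r_values)))
        with pytest.raises(ValueError, match="grid"):
            j_function(G, F)


# ---------------------------------------------------------------------------
# oracle equivalence on small patterns (all four statistics)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed,n", [(0, 5), (1, 8), (2, 12)])
def test_all_statistics_match_enumeration_oracle(seed, n, window):
    pattern = random_pattern(n, seed)
    grid = RadiusGrid(dr=0.15, r_max=0.6)
    rng = np.random.default_rng(seed + 100)
    refs = rng.uniform(0, 1.5, size=(n, 2))

    G = nn_distribution(pattern, grid)
    F = spherical_contact(pattern, grid, reference_points=refs)
    J = j_function(G, F)
    g = pair_correlation(pattern, grid)

    G_exp = nn_cdf_oracle(pattern.xy, grid.r_values)
    F_exp = scd_cdf_oracle(pattern.xy, refs, grid.r_values)
    with np.errstate(divide="ignore", invalid="ignore"):
        J_exp = np.where(F_exp < 1, (1 - G_exp) / (1 - F_exp), np.nan)
    np.testing.assert_allclose(G.values, G_exp, atol=1e-9)
    np.testing.assert_allclose(F.values, F_exp, atol=1e-9)
    np.testing.assert_allclose(J.values, J_exp, atol=1e-9)
    np.testing.assert_allclose(g.values, pcf_oracle(pattern, grid), rtol=1e-6)


# ---------------------------------------------------------------------------
# distributional properties
# ---------------------------------------------------------------------------

class TestCSREnsemble:
    def test_g_and_j_are_unity_on_average(self):
        """Mean g(r) and J(r) over 100 CSR patterns sit within 3 SE of 1."""
        reps, n = 100, 400
        grid = RadiusGrid(dr=0.01, r_max=0.75)
        gs, js = [], []
        for rep in range(reps):
            p = random_pattern(n, 1000 + rep)
            gs.append(pair_correlation(p, grid).values)
            G = nn_distribution(p, grid)
            F = spherical_contact(p, grid, seed=2000 + rep)
            js.append(j_function(G, F).values)
        # g is defined everywhere; J only while F < 1 (here up to ~0.1 mm)
        for curves, mid in ((np.array(gs), slice(20, 50)),   # r in [0.2, 0.5]
                            (np.array(js), slice(1, 8))):    # r in [0.02, 0.08]
            band = np.nanmean(curves[:, mid], axis=1)  # per-rep band mean
            se = band.std(ddof=1) / np.sqrt(reps)
            assert abs(band.mean() - 1.0) < 3 * se + 0.01


class TestHardCore:
    def test_exclusion_zeroes_small_radii(self):
        pattern, _ = generate_pattern(GenerationParams(rho=1.0, d=333, l=0.3), seed=11)
        grid = RadiusGrid(dr=0.005, r_max=0.2)
        g = pair_correlation(pattern, grid)
        G = nn_distribution(pattern, grid)
        F = spherical_contact(pattern, grid, seed=1)
        J = j_function(G, F)
        below = grid.bin_edges[1:] <= 0.02
        assert np.all(g.values[below] == 0.0)
        assert np.all(G.values[grid.r_values < 0.02] == 0.0)
        assert np.all(J.values[grid.r_values < 0.02] >= 1.0)


@settings(deadline=None, max_examples=20)
@given(st.integers(2, 30), st.integers(0, 10_000))
def test_cdf_monotone_in_unit_interval(n, seed):
    """G and F are non-decreasing with range in [0, 1] for any pattern."""
    pattern = random_pattern(n, seed)
    grid = RadiusGrid(dr=0.05, r_max=0.75)
    for curve in (nn_distribution(pattern, grid),
                  spherical_contact(pattern, grid, seed=seed)):
        v = curve.values
        assert np.all(np.diff(v) >= 0)
        assert v.min() >= 0 and v.max() <= 1


# ---------------------------------------------------------------------------
# summary features
# ---------------------------------------------------------------------------

class TestSummaryFeatures:
    def test_feature_definitions(self, csr_pattern):
        grid = RadiusGrid(dr=0.01, r_max=0.75)
        feats = summary_features(csr_pattern, grid, seed=9)
        g = pair_correlation(csr_pattern, grid)
        F = spherical_contact(csr_pattern, grid, seed=9)
        assert feats.g_max == pytest.approx(np.nanmax(g.values))
        assert feats.F_max == pytest.approx(F.observations.max())
        assert 0.0 <= feats.J_min <= 1.0
        assert feats.d == pytest.approx(csr_pattern.density)

    def test_j_min_matches_independent_enumeration(self):
        """J_min from the package equals a cdist-based re-implementation."""
        pattern, _ = generate_pattern(GenerationParams(rho=1.0, d=333, l=0.4), seed=21)
        grid = RadiusGrid(dr=0.01, r_max=0.75)
        feats = summary_features(pattern, grid, seed=33)
        refs = np.random.default_rng(33).uniform(0, 1.5, size=(pattern.n, 2))
        d_self = cdist(pattern.xy, pattern.xy)
        np.fill_diagonal(d_self, np.inf)
        nnd = d_self.min(axis=1)
        refd = cdist(refs, pattern.xy).min(axis=1)
        G = (nnd[:, None] <= grid.r_values).mean(axis=0)
        F = (refd[:, None] <= grid.r_values).mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            J = np.where(F < 1, (1 - G) / (1 - F), np.nan)
        # minimum restricted to where 1-F rests on >= 10 reference points
        J = np.where(F <= 1 - 10 / len(refs), J, np.nan)
        expected = float(np.clip(np.nanmin(J), 0, 1))
        assert feats.J_min == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_rotation(self):
        pattern = random_pattern(80, 7)
        grid = RadiusGrid(dr=0.02, r_max=0.5)
        refs = np.random.default_rng(17).uniform(0, 1.5, (80, 2))
        rot = pattern.rotated90()
        refs_rot = np.column_stack([refs[:, 1], 1.5 - refs[:, 0]])
        g1 = pair_correlation(pattern, grid).values
        g2 = pair_correlation(rot, grid).values
        np.testing.assert_allclose(g1, g2, rtol=1e-9)
        F1 = spherical_contact(pattern, grid, reference_points=refs)
        F2 = spherical_contact(rot, grid, reference_points=refs_rot)
        np.testing.assert_allclose(F1.values, F2.values, atol=1e-12)
        np.testing.assert_allclose(nn_distribution(pattern, grid).values,
                                   nn_distribution(rot, grid).values, atol=1e-12)

    def test_invariant_under_interior_translation(self):
        """With all annuli clear of the boundary, translation leaves g exact."""
        rng = np.random.default_rng(4)
        xy = rng.uniform(0.5, 1.0, size=(60, 2))
        grid = RadiusGrid(dr=0.02, r_max=0.1)
        p = PointPattern(xy)
        q = p.translated(0.2, -0.3)
        np.testing.assert_allclose(pair_correlation(p, grid).values,
                                   pair_correlation(q, grid).values, rtol=1e-12)
        np.testing.assert_allclose(nn_distribution(p, grid).values,
                                   nn_distribution(q, grid).values, atol=1e-12)
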