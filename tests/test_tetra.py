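import itertools

import numpy as np
import pytest
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm

from sidefx.errors import ConfigError
from sidefx.simulate import SimConfig, generate_cohort
from sidefx.tetra import (
    DistanceMatrix,
    bvn_cdf,
    corr_to_dist,
    summarize_cooccurrence,
    tetra_matrix,
    tetrachoric,
    ward_cluster,
)


def grid_search_tetrachoric(a, b, c, d, resolution=1e-4):
    """Brute-force ML oracle over rho at fixed thresholds."""
    cells = np.array([a, b, c, d], dtype=float)
    cells[cells == 0] += 0.5
    a, b, c, d = cells
    n = cells.sum()
    tx = norm.ppf((c + d) / n)
    ty = norm.ppf((b + d) / n)
    grid = np.arange(-0.9999, 0.9999 + resolution, resolution)
    p00 = np.array([bvn_cdf(tx, ty, r) for r in grid])
    px, py = norm.cdf(tx), norm.cdf(ty)
    p10 = py - p00
    p01 = px - p00
    p11 = 1 - px - py + p00
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = (
            a * np.log(p11) + b * np.log(p10) + c * np.log(p01) + d * np.log(p00)
        )
    ll[~np.isfinite(ll)] = -np.inf
    return float(grid[np.argmax(ll)])


def simulate_table(rng, rho, tx, ty, n):
    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
    x, y = z[:, 0] > tx, z[:, 1] > ty
    return (
        int(np.sum(x & y)),
        int(np.sum(x & ~y)),
        int(np.sum(~x & y)),
        int(np.sum(~x & ~y)),
    )


class TestBvnCdf:
    @pytest.mark.parametrize("rho", [-0.99, -0.9, -0.5, 0.0, 0.3, 0.7, 0.925, 0.99])
    def test_matches_scipy(self, rho):
        for h, k in [(0.3, -0.4), (-1.2, 1.5), (0.0, 0.0), (2.0, 2.0)]:
            ref = stats.multivariate_normal.cdf(
                [h, k], mean=[0, 0], cov=[[1, rho], [rho, 1]]
            )
            assert bvn_cdf(h, k, rho) == pytest.approx(ref, abs=1e-10)

    def test_vectorized_over_rho(self):
        rhos = np.linspace(-0.9, 0.9, 7)
        vals = bvn_cdf(0.1, -0.2, rhos)
        assert vals.shape == (7,)
        assert np.all(np.diff(vals) > 0)  # increasing in rho for these args


class TestTetrachoric:
    def test_independence_table(self):
        assert abs(tetrachoric(25, 25, 25, 25).rho) < 1e-6

    def test_recovery_rho_06(self):
        rng = np.random.default_rng(42)
        a, b, c, d = simulate_table(rng, 0.6, 0.0, 0.0, 50_000)
        assert tetrachoric(a, b, c, d).rho == pytest.approx(0.6, abs=0.02)

    @pytest.mark.parametrize(
        "table",
        [(50, 10, 5, 60), (3, 40, 22, 9), (100, 1, 7, 13), (12, 0, 5, 40)],
    )
    def test_matches_grid_oracle(self, table):
        est = tetrachoric(*table).rho
        oracle = grid_search_tetrachoric(*table)
        assert est == pytest.approx(oracle, abs=2e-4)

    def test_antisymmetry_under_recoding(self):
        for table in [(50, 10, 5, 60), (3, 40, 22, 9)]:
            a, b, c, d = table
            r1 = tetrachoric(a, b, c, d).rho
            r2 = tetrachoric(b, a, d, c).rho
            assert r1 == pytest.approx(-r2, abs=1e-6)

    def test_perfect_tables(self):
        assert tetrachoric(30, 0, 0, 30).rho == 1.0
        assert tetrachoric(0, 30, 30, 0).rho == -1.0

    def test_degenerate_margin_undefined(self):
        assert np.isnan(tetrachoric(0, 0, 30, 30).rho)

    def test_thresholds_from_margins(self):
        r = tetrachoric(25, 25, 25, 25)
        assert r.tau_x == pytest.approx(0.0, abs=1e-12)
        assert r.tau_y == pytest.approx(0.0, abs=1e-12)


class TestTetraMatrix:
    def test_duplicate_columns_rho_one(self):
        cfg = SimConfig(n_participants=800, seed=3,
                        exposure_probs={d: 1.0 for d in SimConfig().exposure_probs})
        cohort = generate_cohort(cfg)
        data = cohort.data.copy()
        # make venlafaxine's nausea a duplicate of sertraline's (keeping the
        # no-side-effects column consistent)
        data["se_venlafaxine_nausea"] = data["se_sertraline_nausea"]
        data.loc[data["se_venlafaxine_nausea"] == 1, "se_venlafaxine_no_side_effects"] = 0.0
        from sidefx.cohort import CohortTable

        m = tetra_matrix(
            CohortTable(data), effects=("nausea",),
            medications=("sertraline", "venlafaxine"), min_pair_n=10,
        )
        assert m.rho[0, 1] == 1.0

    def test_disjoint_exposures_undefined(self):
        cfg = SimConfig(n_participants=400, seed=4)
        cohort = generate_cohort(cfg)
        data = cohort.data.copy()
        # force disjoint exposure sets for two drugs
        half = np.arange(len(data)) < len(data) // 2
        data["taken_sertraline"] = half.astype(int)
        data["taken_venlafaxine"] = (~half).astype(int)
        for col in data.columns:
            if col.startswith("se_sertraline_"):
                data[col] = np.where(half, 0.0, np.nan)
            if col.startswith("se_venlafaxine_"):
                data[col] = np.where(~half, 0.0, np.nan)
        from sidefx.cohort import CohortTable

        m = tetra_matrix(
            CohortTable(data), effects=("nausea",),
            medications=("sertraline", "venlafaxine"), min_pair_n=10,
        )
        assert np.isnan(m.rho[0, 1])
        assert m.n_pair[0, 1] == 0

    def test_loading_product_structure(self):
        cfg = SimConfig(
            n_participants=6000, seed=5,
            general_loadings={"nausea": 0.7},
            exposure_probs={d: 1.0 for d in SimConfig().exposure_probs},
        )
        cohort = generate_cohort(cfg)
        m = tetra_matrix(cohort, effects=("nausea",), min_pair_n=30)
        off = m.rho[~np.eye(10, dtype=bool)]
        assert np.median(off) == pytest.approx(0.49, abs=0.08)

    def test_pair_n_bounded_by_exposures(self, small_cohort):
        m = tetra_matrix(small_cohort, effects=("nausea", "headache"), min_pair_n=5)
        for i, (di, _) in enumerate(m.labels):
            for j, (dj, _) in enumerate(m.labels):
                bound = min(small_cohort.exposure(di).sum(), small_cohort.exposure(dj).sum())
                assert m.n_pair[i, j] <= bound


class TestCorrToDist:
    def test_transform_bounds(self):
        labels = [("a", "x"), ("b", "x"), ("c", "x")]
        rho = np.array([[1.0, 1.0, -1.0], [1.0, 1.0, 0.5], [-1.0, 0.5, 1.0]])
        from sidefx.tetra import TetraMatrix

        m = TetraMatrix(labels, rho, np.full((3, 3), 100), np.zeros((3, 3, 4)))
        d = corr_to_dist(m)
        assert d.d[0, 1] == 0.0
        assert d.d[0, 2] == 2.0
        assert np.allclose(d.d, d.d.T) and np.all(np.diag(d.d) == 0)

    def test_imputation_of_undefined(self):
        labels = [("a", "x"), ("b", "x"), ("c", "x")]
        rho = np.array([[1.0, np.nan, 0.5], [np.nan, 1.0, 0.5], [0.5, 0.5, 1.0]])
        from sidefx.tetra import TetraMatrix

        m = TetraMatrix(labels, rho, np.full((3, 3), 100), np.zeros((3, 3, 4)))
        d = corr_to_dist(m)
        assert d.n_imputed == 1
        assert d.d[0, 1] == pytest.approx(0.5)  # median defined distance


def brute_force_ward(d):
    """Oracle: recompute the Ward objective from the original squared
    distances at every step via the centroid identity."""
    d = np.asarray(d, float)
    n = d.shape[0]
    D2 = d**2
    clusters = {i: [i] for i in range(n)}
    node_of = {i: i for i in range(n)}
    merges = []
    next_id = n

    def v_within(members):
        if len(members) == 1:
            return 0.0
        sub = D2[np.ix_(members, members)]
        return sub.sum() / (2 * len(members) ** 2)

    def delta(A, B):
        m = D2[np.ix_(A, B)].mean()
        return (len(A) * len(B) / (len(A) + len(B))) * (m - v_within(A) - v_within(B))

    for _ in range(n - 1):
        keys = sorted(clusters)
        best = None
        for i, j in itertools.combinations(keys, 2):
            dd = delta(clusters[i], clusters[j])
            if best is None or dd < best[0] - 1e-12:
                best = (dd, i, j)
        dd, i, j = best
        a, b = sorted((node_of[i], node_of[j]))
        merges.append((a, b, float(np.sqrt(2 * dd)), len(clusters[i]) + len(clusters[j])))
        clusters[i] = clusters[i] + clusters[j]
        node_of[i] = next_id
        next_id += 1
        del clusters[j]
        del node_of[j]
    return merges


class TestWardCluster:
    def test_two_leaves(self):
        d = np.array([[0.0, 0.7], [0.7, 0.0]])
        tree = ward_cluster(d)
        assert len(tree.merges) == 1
        a, b, h, s = tree.merges[0]
        assert (a, b, s) == (0, 1, 2) and h == pytest.approx(0.7)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_oracle_6pts(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(6, 2))
        d = squareform(pdist(pts))
        tree = ward_cluster(d)
        oracle = brute_force_ward(d)
        for got, exp in zip(tree.merges, oracle):
            assert got[0] == exp[0] and got[1] == exp[1]
            assert got[2] == pytest.approx(exp[2], rel=1e-9)
            assert got[3] == exp[3]

    def test_matches_scipy_on_euclidean_input(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(12, 3))
        tree = ward_cluster(squareform(pdist(pts)))
        ref = linkage(pdist(pts), method="ward")
        np.testing.assert_allclose(tree.to_scipy(), ref, rtol=1e-10)

    def test_heights_monotone(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(15, 2))
        tree = ward_cluster(squareform(pdist(pts)))
        h = [m[2] for m in tree.merges]
        assert np.all(np.diff(h) >= -1e-12)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(7, 2))
        d = squareform(pdist(pts))
        perm = rng.permutation(7)
        t1 = ward_cluster(d)
        t2 = ward_cluster(d[np.ix_(perm, perm)])
        # same multiset of merge heights
        np.testing.assert_allclose(
            sorted(m[2] for m in t1.merges), sorted(m[2] for m in t2.merges), rtol=1e-9
        )
        # cutting into 3 clusters induces the same partition after unpermuting
        c1 = t1.cut(3)
        c2 = t2.cut(3)[np.argsort(perm)]

        def canon(labels):
            seen = {}
            return tuple(seen.setdefault(x, len(seen)) for x in labels)

        assert canon(c1) == canon(c2)

    def test_nonfinite_rejected(self):
        d = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ConfigError):
            ward_cluster(d)


class TestSummarize:
    def test_constant_matrix(self):
        labels = [(d, e) for d in ("d1", "d2") for e in ("e1", "e2")]
        rho = np.full((4, 4), 0.5)
        np.fill_diagonal(rho, 1.0)
        from sidefx.tetra import TetraMatrix

        m = TetraMatrix(labels, rho, np.full((4, 4), 50), np.zeros((4, 4, 4)))
        s = summarize_cooccurrence(m)
        assert s["within_side_effect"] == 0.5
        assert s["within_medication"] == 0.5
        assert s["across"] == 0.5

    def test_empty_category_flagged(self):
        labels = [("d1", "e1"), ("d1", "e2")]
        rho = np.array([[1.0, 0.3], [0.3, 1.0]])
        from sidefx.tetra import TetraMatrix

        m = TetraMatrix(labels, rho, np.full((2, 2), 50), np.zeros((2, 2, 4)))
        s = summarize_cooccurrence(m)
        assert s["within_side_effect"] is None
        assert s["within_medication"] == 0.3

    def test_general_factor_ordering(self):
        cfg = SimConfig(
            n_participants=4000, seed=21,
            general_loadings={e: 0.65 for e in ("nausea", "headache", "dizziness")},
            general_cross_corr=0.5,
            exposure_probs={d: 0.8 for d in SimConfig().exposure_probs},
        )
        cohort = generate_cohort(cfg)
        m = tetra_matrix(
            cohort, effects=("nausea", "headache", "dizziness"),
            medications=("sertraline", "venlafaxine", "fluoxetine", "mirtazapine"),
            min_pair_n=30,
        )
        s = summarize_cooccurrence(m)
        assert s["within_side_effect"] > s["across"]
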