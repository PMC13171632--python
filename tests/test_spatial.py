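"""Moran's I, Ripley K/L/H, colony calling, colocalization and the
species–area curve."""

import numpy as np
import pandas as pd
import pytest

import gutbiogeo as gb
from gutbiogeo import (
    PointPattern,
    call_colonies,
    colocalization,
    csr_null,
    morans_i,
    ripley,
    ripley_z,
    sar_curve,
)
from gutbiogeo.spatial import knn_weights, _moran_stat


# ---------------------------------------------------------------- oracles

def ripley_oracle(pts, area, r_grid):
    """Literal double-loop evaluation of the K/L/H estimator."""
    n = len(pts)
    K = np.zeros(len(r_grid))
    for ri, r in enumerate(r_grid):
        s = 0
        for i in range(n):
            for j in range(i + 1, n):
                if np.hypot(*(pts[i] - pts[j])) <= r:
                    s += 1
        K[ri] = 2.0 * area / (n * (n - 1)) * s
    L = np.sqrt(K / np.pi)
    return K, L, L - r_grid


def moran_oracle(x, coords, k=4):
    """Brute-force Moran's I with independently constructed kNN weights."""
    n = len(x)
    d = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
    W = np.zeros((n, n))
    for i in range(n):
        order = sorted(range(n), key=lambda j: (d[i, j], j))
        for j in [o for o in order if o != i][:k]:
            W[i, j] = 1.0 / k
    zc = x - x.mean()
    num = sum(W[i, j] * zc[i] * zc[j] for i in range(n) for j in range(n))
    return n / W.sum() * num / (zc @ zc)


# ------------------------------------------------------------------ Moran

class TestMoransI:
    def test_constant_field_errors(self):
        coords = np.random.default_rng(0).random((10, 2))
        with pytest.raises(ValueError, match="variance"):
            morans_i(np.ones(10), coords)

    @pytest.mark.parametrize("n_side", [4, 10])
    def test_checkerboard_negative_matches_oracle(self, n_side):
        xs, ys = np.meshgrid(range(n_side), range(n_side), indexing="ij")
        coords = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
        vals = ((xs + ys) % 2).ravel().astype(float)
        res = morans_i(vals, coords, n_perm=99, seed=0)
        assert res.I < 0
        assert res.I == pytest.approx(moran_oracle(vals, coords), rel=1e-10)

    @pytest.mark.parametrize("n_side", [4, 10])
    def test_block_positive_matches_oracle(self, n_side):
        xs, ys = np.meshgrid(range(n_side), range(n_side), indexing="ij")
        coords = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
        vals = (xs < n_side // 2).ravel().astype(float)
        res = morans_i(vals, coords, n_perm=99, seed=0)
        assert res.I > 0
        assert res.I == pytest.approx(moran_oracle(vals, coords), rel=1e-10)

    def test_permutation_p_reproducible(self):
        rng = np.random.default_rng(1)
        coords = rng.random((30, 2)) * 10
        vals = rng.random(30)
        a = morans_i(vals, coords, n_perm=199, seed=5)
        b = morans_i(vals, coords, n_perm=199, seed=5)
        assert a.p == b.p and 0 < a.p <= 1

    def test_weights_row_standardized(self):
        coords = np.random.default_rng(2).random((20, 2))
        W = knn_weights(coords, k=4)
        np.testing.assert_allclose(W.sum(axis=1), 1.0)
        assert np.all(np.diag(W) == 0)


# ----------------------------------------------------------------- Ripley

class TestRipley:
    def test_two_point_closed_form(self):
        pp = PointPattern([(0, 0), (3, 0)], window=(0, 0, 10, 10), area=100.0)
        res = ripley(pp, np.array([5.0]))
        assert res.K[0] == pytest.approx(100.0)
        assert res.L[0] == pytest.approx(np.sqrt(100 / np.pi))
        assert res.H[0] == pytest.approx(np.sqrt(100 / np.pi) - 5.0)

    def test_r_below_minimum_distance(self):
        pp = PointPattern([(0, 0), (3, 0)], window=(0, 0, 10, 10), area=100.0)
        res = ripley(pp, np.array([1.0, 2.0]))
        assert np.all(res.K == 0)
        np.testing.assert_allclose(res.H, -res.r_grid)

    def test_single_point_errors(self):
        pp = PointPattern([(1, 1)], window=(0, 0, 10, 10))
        with pytest.raises(ValueError):
            ripley(pp, np.array([1.0]))

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(8)
        r_grid = np.linspace(1, 60, 12)
        for _ in range(5):
            n = int(rng.integers(5, 120))
            pts = rng.random((n, 2)) * 200
            pp = PointPattern(pts, window=(0, 0, 200, 200))
            res = ripley(pp, r_grid)
            K, L, H = ripley_oracle(pts, pp.window_area, r_grid)
            np.testing.assert_allclose(res.K, K, rtol=1e-12, atol=0)
            np.testing.assert_allclose(res.H, H, rtol=1e-12, atol=1e-12)

    def test_csr_mean_h_near_zero(self):
        # under CSR the expected H is ~0 well below the window scale
        r_grid = np.array([5.0, 10.0, 20.0])
        rng = np.random.default_rng(3)
        H = []
        for _ in range(200):
            pts = rng.random((500, 2)) * 1000
            H.append(ripley(PointPattern(pts, window=(0, 0, 1000, 1000)), r_grid).H)
        mean_h = np.mean(H, axis=0)
        sem = np.std(H, axis=0) / np.sqrt(200)
        assert np.all(np.abs(mean_h) < 4 * sem + 0.05)


class TestRipleyZ:
    def test_csr_calibration(self):
        w = (0.0, 0.0, 1000.0, 1000.0)
        r_grid = np.arange(2.0, 52.0, 2.0)
        null = csr_null(500, w, r_grid, n_sim=99, seed=0)
        rng = np.random.default_rng(1)
        zs = []
        for _ in range(50):
            pts = rng.random((500, 2)) * 1000
            zs.append(ripley_z(PointPattern(pts, window=w), r_grid, null=null).z)
        zs = np.concatenate(zs)
        assert np.mean(np.abs(zs[~np.isnan(zs)]) < 3) >= 0.99

    def test_thomas_clustered_signal_and_scale(self):
        w = (0.0, 0.0, 1000.0, 1000.0)
        r_grid = np.arange(1.0, 100.0, 1.0)
        rng = np.random.default_rng(5)
        pts = gb.sample_thomas(4e-5, 30, 10.0, w, rng)
        pp = PointPattern(pts, window=w)
        res = ripley_z(pp, r_grid, n_sim=49, seed=2)
        assert np.nanmax(res.z) > 5  # strong aggregation vs CSR
        # argmax-H scale for a Thomas process sits at 2–4.5x the
        # cluster dispersion sigma
        assert 20.0 <= res.colony_radius <= 45.0

    def test_sigma_ordering_recovered(self):
        w = (0.0, 0.0, 1000.0, 1000.0)
        r_grid = np.arange(2.0, 120.0, 2.0)
        ok = 0
        for s in range(20):
            radii = []
            for sig in (5.0, 30.0):
                rng = np.random.default_rng(1000 * s + int(sig))
                pts = gb.sample_thomas(4e-5, 30, sig, w, rng)
                radii.append(ripley(PointPattern(pts, window=w), r_grid).colony_radius)
            ok += radii[0] < radii[1]
        assert ok >= 19


# ---------------------------------------------------------------- colonies

class TestCallColonies:
    def test_three_separated_blobs(self):
        rng = np.random.default_rng(0)
        centers = [(100, 100), (300, 100), (200, 300)]
        pts = np.vstack([rng.normal(c, 5.0, size=(100, 2)) for c in centers])
        pp = PointPattern(pts, window=(-50, -50, 450, 450))
        res = call_colonies(pp)
        assert res.n_clusters == 3
        assert res.silhouette > 0.8
        assert res.flagged is None

    def test_sparse_uniform_flagged(self):
        rng = np.random.default_rng(1)
        pts = rng.random((20, 2)) * 1000
        pp = PointPattern(pts, window=(0, 0, 1000, 1000))
        res = call_colonies(pp, min_cluster_sizes=(25,), min_samples_grid=(5,))
        assert res.flagged == "no colony structure"
        assert np.all(res.labels == -1)

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        pts = np.vstack([
            rng.normal((100, 100), 5, (60, 2)),
            rng.normal((400, 400), 5, (60, 2)),
        ])
        pp = PointPattern(pts, window=(0, 0, 500, 500))
        a, b = call_colonies(pp), call_colonies(pp)
        assert np.array_equal(a.labels, b.labels)
        assert a.min_cluster_size == b.min_cluster_size


# ----------------------------------------------------------- colocalization

def _section_grid(pitch=10.0, side=60):
    xs, ys = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    spots = pd.DataFrame(
        {"x": xs.ravel() * pitch + pitch / 2, "y": ys.ravel() * pitch + pitch / 2,
         "region": "lumen"},
        index=pd.Index([f"B{i}" for i in range(side * side)], name="barcode"),
    )
    return gb.SpatialSection(spots=spots)


def _tm_from_patterns(section, patterns):
    from gutbiogeo.datamodel import RANKS, TaxonMatrix
    from scipy.spatial import cKDTree

    tree = cKDTree(section.coords())
    counts = np.zeros((section.n_spots, len(patterns)), dtype=np.int64)
    for j, pts in enumerate(patterns.values()):
        if len(pts):
            _, idx = tree.query(pts)
            np.add.at(counts[:, j], idx, 1)
    taxa = pd.DataFrame(
        {"name": list(patterns), "rank": "genus"}, index=pd.Index(list(patterns))
    )
    for r in RANKS:
        taxa[r] = ""
    taxa["superkingdom"] = "Bacteria"
    taxa["genus"] = list(patterns)
    return TaxonMatrix(counts=counts, spot_ids=section.barcodes, taxa=taxa,
                       section=section)


class TestColocalization:
    def test_self_correlation_unit_diagonal_symmetric(self):
        rng = np.random.default_rng(0)
        section = _section_grid()
        w = (0.0, 0.0, 600.0, 600.0)
        tm = _tm_from_patterns(section, {
            "A": rng.random((500, 2)) * 600,
            "B": rng.random((500, 2)) * 600,
        })
        cor = colocalization(tm, section, sigma_um=20, bin_size_um=10)
        np.testing.assert_allclose(np.diag(cor.to_numpy()), 1.0)
        np.testing.assert_allclose(cor.to_numpy(), cor.to_numpy().T)

    def test_independent_surfaces_uncorrelated(self):
        # smoothing reduces the effective number of independent bins, so
        # the null r spread is wider than 1/sqrt(n_bins); check the null
        # is centred on zero and never strong
        section = _section_grid()
        rng = np.random.default_rng(7)
        rs = []
        for rep in range(15):
            tm = _tm_from_patterns(section, {
                "A": rng.random((2000, 2)) * 600,
                "B": rng.random((2000, 2)) * 600,
            })
            rs.append(colocalization(tm, section, sigma_um=20, bin_size_um=10).loc["A", "B"])
        assert abs(np.mean(rs)) < 3 * np.std(rs) / np.sqrt(len(rs)) + 0.05
        assert np.max(np.abs(rs)) < 0.5

    def test_shared_parents_strongly_correlated(self):
        section = _section_grid()
        rng = np.random.default_rng(1)
        parents = rng.random((30, 2)) * 600
        def offspring():
            reps = np.repeat(parents, 40, axis=0)
            return np.clip(reps + rng.normal(0, 10, reps.shape), 0, 599.9)
        tm = _tm_from_patterns(section, {"A": offspring(), "B": offspring()})
        r = colocalization(tm, section, sigma_um=20, bin_size_um=10).loc["A", "B"]
        assert r > 0.5

    def test_zero_variance_masked(self):
        section = _section_grid(side=20)
        rng = np.random.default_rng(2)
        tm = _tm_from_patterns(section, {
            "A": rng.random((200, 2)) * 200,
            "B": rng.random((200, 2)) * 200,
        })
        tm.counts[:, 1] = 1  # spatially flat surface: nonzero but zero variance
        cor = colocalization(tm, section, sigma_um=20, bin_size_um=10)
        assert np.isnan(cor.loc["A", "B"]) and np.isnan(cor.loc["B", "B"])


# -------------------------------------------------------------------- SAR

class TestSARCurve:
    AREAS = np.geomspace(16.0, 0.16e6, 9)

    def test_single_genus_constant_curve(self):
        rng = np.random.default_rng(0)
        pts = rng.random((5000, 2)) * 600
        res = sar_curve(pts, np.zeros(5000), (0, 0, 600, 600),
                        area_grid=self.AREAS, n_quadrats=50, seed=1)
        dense = res.table["mean_genera"].to_numpy()[3:]  # areas large enough to hit points
        assert np.allclose(dense, 1.0)
        lx = np.log10(self.AREAS[3:])
        slope = np.polyfit(lx, np.log10(dense), 1)[0]
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_matches_analytic_csr_expectation(self):
        # equal-intensity independent CSR genera: E[S(a)] = S(1 - exp(-lambda a))
        S, lam = 12, 5e-4
        rng = np.random.default_rng(3)
        pts, marks = [], []
        for g in range(S):
            p = gb.sample_csr(lam, (0, 0, 600, 600), rng)
            pts.append(p)
            marks.extend([g] * len(p))
        pts = np.vstack(pts)
        res = sar_curve(pts, np.array(marks), (0, 0, 600, 600),
                        area_grid=self.AREAS, n_quadrats=200, seed=5)
        expected = S * (1 - np.exp(-lam * self.AREAS))
        got = res.table["mean_genera"].to_numpy()
        np.testing.assert_allclose(got, expected, rtol=0.25, atol=0.5)

    def test_monotone_for_every_seed(self):
        rng = np.random.default_rng(11)
        pts = rng.random((3000, 2)) * 600
        marks = rng.integers(0, 40, 3000)
        for seed in range(5):
            res = sar_curve(pts, marks, (0, 0, 600, 600),
                            area_grid=self.AREAS, n_quadrats=30, seed=seed)
            assert np.all(np.diff(res.table["mean_genera"].to_numpy()) >= 0)

    def test_oversized_quadrat_errors(self):
        with pytest.raises(ValueError, match="window"):
            sar_curve(np.zeros((10, 2)), np.zeros(10), (0, 0, 100, 100),
                      area_grid=np.array([1e6]))

    def test_calibrated_exponent_recovered(self):
        pts, marks, lam = gb.simulate_sar_community(
            250, (0, 0, 600, 600), self.AREAS, target_exponent=0.5, seed=21
        )
        res = sar_curve(pts, marks, (0, 0, 600, 600),
                        area_grid=self.AREAS, n_quadrats=100, seed=22)
        assert res.exponent == pytest.approx(0.5, abs=0.05)
        assert res.r2 > 0.95
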