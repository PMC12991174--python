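"""Point-pattern statistics: estimator contracts and rule traces."""

import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import Polygon

from striazone import pointpattern as pp
from striazone import syndata as sd
from striazone.pointpattern import _gaussian_intensity_at, _pcf_from_points


@pytest.fixture(scope="module")
def rect_window():
    return pp.Window(Polygon([(0, 0), (7000, 0), (7000, 10000),
                              (0, 10000)]))


def pcf_bruteforce(pts, window, sigma, r_grid, inner, kernel_bw=None):
    """O(n^2) direct pair-count estimator (explicit loops)."""
    n = len(pts)
    lam = _gaussian_intensity_at(pts, pts, sigma, window, leave_one_out=True)
    if kernel_bw is None:
        kernel_bw = 0.15 / np.sqrt(n / window.area)
    h = kernel_bw
    g = np.full(len(r_grid), np.nan)
    for k, r in enumerate(r_grid):
        if r <= 0 or r < inner:
            continue
        tot = 0.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                dx = pts[j, 0] - pts[i, 0]
                dy = pts[j, 1] - pts[i, 1]
                d = (dx * dx + dy * dy) ** 0.5
                u = (r - d) / h
                if abs(u) < 1:
                    C = window.set_covariance(np.array([dx]),
                                              np.array([dy]))[0]
                    tot += 0.75 * (1 - u * u) / h / (lam[i] * lam[j] * C)
        g[k] = tot / (2 * np.pi * r)
    return g


class TestPCF:
    def test_matches_bruteforce_oracle(self, rect_window):
        rng = np.random.default_rng(3)
        pts = rng.uniform([0, 0], [7000, 10000], (300, 2))
        r_grid = np.arange(0.0, 805.0, 100.0)
        fast = _pcf_from_points(pts, rect_window, 500.0, r_grid, 25.0)
        slow = pcf_bruteforce(pts, rect_window, 500.0, r_grid, 25.0)
        assert np.nanmax(np.abs(fast - slow)) < 1e-6

    def test_default_grid_has_101_values(self, rect_window):
        rng = np.random.default_rng(0)
        pts = rng.uniform([0, 0], [7000, 10000], (500, 2))
        res = pp.pcf_inhom(
            pp.PointPattern(pts, rect_window, np.full(500, "T")), "T",
            sigma=500.0)
        assert len(res.r_grid) == 101
        assert res.r_grid[0] == 0.0 and res.r_grid[-1] == 1000.0
        assert np.all(np.diff(res.r_grid) == 10.0)
        # values inside the 25 μm inner exclusion are undefined
        assert np.isnan(res.g_values[res.r_grid < 25.0]).all()

    def test_few_cells_skip_record(self, rect_window):
        rng = np.random.default_rng(0)
        pts = rng.uniform([0, 0], [7000, 10000], (29, 2))
        res = pp.pcf_inhom(
            pp.PointPattern(pts, rect_window, np.full(29, "T")), "T",
            sigma=500.0)
        assert res is None

    def test_zero_area_window_rejected(self):
        with pytest.raises(ValueError):
            pp.Window(Polygon())

    def test_envelope_requires_39_sims(self, rect_window):
        rng = np.random.default_rng(0)
        pts = rng.uniform([0, 0], [7000, 10000], (100, 2))
        pat = pp.PointPattern(pts, rect_window, np.full(100, "T"))
        with pytest.raises(ValueError):
            pp.mc_envelope(pat, "T", n_sims=10)


class TestRadius:
    def test_flat_unity_curve_undefined(self):
        r = np.arange(0.0, 1001.0, 10.0)
        res = pp.PCFResult(r_grid=r, g_values=np.ones_like(r), sigma=500.0,
                           inner_exclusion=25.0)
        assert pp.estimate_radius(res) is None

    def test_linear_interpolation_arithmetic(self):
        """g=2 at r=100 and g=0.8 at 110 crosses unity at ~108.3 μm."""
        r = np.arange(0.0, 1001.0, 10.0)
        g = np.ones_like(r) * 1.5
        g[r < 25] = np.nan
        g[r == 100] = 2.0
        g[r >= 110] = 0.8
        res = pp.PCFResult(r_grid=r, g_values=g, sigma=500.0,
                           inner_exclusion=25.0)
        est = pp.estimate_radius(res)
        assert est == pytest.approx(100 + 10 * (2 - 1) / (2 - 0.8),
                                    abs=1e-9)

    def test_global_gate_blocks_diffuse_calls(self):
        r = np.arange(0.0, 1001.0, 10.0)
        g = np.ones_like(r) * 1.2
        g[r >= 500] = 0.9
        res = pp.PCFResult(r_grid=r, g_values=g, sigma=500.0,
                           inner_exclusion=25.0, global_exceeds=False)
        assert pp.estimate_radius(res) is None
        res.global_exceeds = True
        assert pp.estimate_radius(res) is not None

    def test_thomas_radius_recovered(self, rect_window):
        """First unity crossing of a 300 μm Thomas pattern lands in
        [240, 360] μm (median over seeds)."""
        ests = []
        for seed in range(8):
            pts, _ = sd.thomas_pattern(300.0, seed=seed)
            pat = pp.PointPattern(pts, rect_window, np.full(len(pts), "T"))
            e = pp.estimate_radius(pp.pcf_inhom(pat, "T", sigma=480.0))
            if e is not None:
                ests.append(e)
        assert 240.0 <= np.median(ests) <= 360.0


class TestDBSCAN:
    def test_two_blobs_and_noise(self):
        rng = np.random.default_rng(1)
        a = rng.normal([0, 0], 10, (20, 2))
        b = rng.normal([500, 500], 10, (20, 2))
        noise = np.array([[250.0, 250.0]])
        pts = np.vstack([a, b, noise])
        labels = pp.dbscan(pts, eps=60.0, min_pts=5)
        assert len(set(labels[:20])) == 1 and labels[0] >= 0
        assert len(set(labels[20:40])) == 1
        assert labels[0] != labels[20]
        assert labels[40] == -1

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 100, (80, 2))
        l1 = pp.dbscan(pts, 15.0, 4)
        l2 = pp.dbscan(pts, 15.0, 4)
        assert np.array_equal(l1, l2)

    def test_min_pts_counts_self(self):
        # three collinear points within eps: each has 3 neighbors incl self
        pts = np.array([[0.0, 0], [1, 0], [2, 0]])
        assert (pp.dbscan(pts, 1.5, 3) == 0).all()
        assert (pp.dbscan(pts, 1.5, 4) == -1).all()


class TestCalibration:
    def test_pure_target_pattern_returns_upper_bound(self, rect_window):
        pts, _ = sd.thomas_pattern(300.0, seed=4)
        pat = pp.PointPattern(pts, rect_window,
                              np.full(len(pts), "D1_Striosome_MSN"))
        eps, purity = pp.calibrate_eps(pat, "D1_Striosome_MSN", 5,
                                       radius_hint=300.0)
        assert purity == 1.0
        assert eps == pytest.approx(600.0)  # 2 x radius hint

    def test_undefined_radius_hint_rejected(self, rect_window):
        pts, _ = sd.thomas_pattern(300.0, seed=4)
        pat = pp.PointPattern(pts, rect_window,
                              np.full(len(pts), "D1_Striosome_MSN"))
        with pytest.raises(ValueError):
            pp.calibrate_eps(pat, "D1_Striosome_MSN", 5,
                             radius_hint=float("nan"))

    def test_planted_blob_purity_matches_point_in_polygon_oracle(
            self, rect_window):
        rng = np.random.default_rng(5)
        blob = rng.normal([3000, 5000], 80, (20, 2))
        bg = rng.uniform([0, 0], [7000, 10000], (200, 2))
        pts = np.vstack([blob, bg])
        marks = np.array(["T"] * 20 + ["D1_Matrix_MSN"] * 200)
        pat = pp.PointPattern(pts, rect_window, marks)
        eps, purity = pp.calibrate_eps(pat, "T", 3, radius_hint=200.0,
                                       msn_types=("T", "D1_Matrix_MSN"))
        labels = pp.dbscan(pat.subset("T"), eps, 3)
        hulls = pp._cluster_hulls(pat.subset("T"), labels)
        inside = np.zeros(len(pts), bool)
        for h in hulls:
            inside |= shapely.contains_xy(h, pts[:, 0], pts[:, 1])
        oracle = (marks[inside] == "T").mean()
        assert purity == pytest.approx(oracle)
        target_in = inside[:20].mean()
        assert target_in >= 0.9


class TestAssignment:
    def test_overlapping_hulls_smallest_area_wins(self, rect_window):
        # small dense blob of type A inside a larger blob of type B
        rng = np.random.default_rng(6)
        a = rng.normal([3000, 5000], 40, (12, 2))
        b = np.vstack([rng.normal([3000, 5000], 400, (25, 2)),
                       a + rng.normal(0, 5, a.shape)])
        pts = np.vstack([a, b])
        marks = np.array(["A"] * len(a) + ["B"] * len(b))
        pat = pp.PointPattern(pts, rect_window, marks)
        cmap = pp.assign_compartments(
            pat, {"A": (150.0, 3), "B": (900.0, 3)}, matrix_types=())
        got = cmap.labels.to_numpy()[pat.marks == "A"]
        assert (got == "A").all()  # the smaller hull claims its cells

    def test_isolated_cell_unassigned(self, rect_window):
        pts = np.array([[3500.0, 5000.0], [6800.0, 9000.0]])
        marks = np.array(["X", "D1_Matrix_MSN"])
        pat = pp.PointPattern(pts, rect_window, marks)
        cmap = pp.assign_compartments(pat, {})
        # no matrix MSN within 150 μm -> unassigned
        assert cmap.labels.iloc[0] == "unassigned"

    def test_matrix_rule_thresholds(self, rect_window):
        # 3 matrix neighbors within 250, 1 within 150 -> Matrix
        target = np.array([[3500.0, 5000.0]])
        matrix = np.array([[3600.0, 5000.0], [3500.0, 5240.0],
                           [3270.0, 5000.0]])
        pts = np.vstack([target, matrix])
        marks = np.array(["X"] + ["D1_Matrix_MSN"] * 3)
        cmap = pp.assign_compartments(
            pp.PointPattern(pts, rect_window, marks), {})
        assert cmap.labels.iloc[0] == "Matrix"
        # only 2 within 250 -> fails '>2' -> unassigned
        cmap2 = pp.assign_compartments(
            pp.PointPattern(pts[:3], rect_window, marks[:3]), {})
        assert cmap2.labels.iloc[0] == "unassigned"


class TestComposition:
    def test_identical_composition_null(self):
        rng = np.random.default_rng(7)
        rows = []
        for d in range(4):
            for comp in ("D1_Striosome_MSN", "Matrix"):
                for t, n in (("A", 50), ("B", 30)):
                    for _ in range(n + rng.integers(0, 2)):
                        rows.append({"donor": f"d{d}", "cell_type": t,
                                     "compartment": comp})
        out = pp.compartment_composition(pd.DataFrame(rows))
        assert (out["p"] > 0.2).all()
        assert out["log2_fe"].abs().max() < 0.2

    def test_planted_depletion_detected(self):
        """Type A planted at 8x lower rate in striosomes; with a large
        shared filler population the proportion ratio tracks the rate
        ratio, so mean log2FE lands near -3 and the paired Wilcoxon is
        significant across 18 donors."""
        rng = np.random.default_rng(8)
        rows = []
        for d in range(18):
            for comp, a_rate in (("Matrix", 64), ("D1_Striosome_MSN", 8)):
                for t, n in (("A", a_rate), ("B", 64), ("F", 1000)):
                    for _ in range(rng.poisson(n)):
                        rows.append({"donor": f"d{d}", "cell_type": t,
                                     "compartment": comp})
        out = pp.compartment_composition(pd.DataFrame(rows))
        a = out[(out["cell_type"] == "A")].iloc[0]
        assert a["log2_fe"] == pytest.approx(-3.0, abs=0.7)
        assert a["padj"] < 0.05

    def test_single_donor_rejected(self):
        df = pd.DataFrame({"donor": ["d0"] * 10, "cell_type": ["A"] * 10,
                           "compartment": ["Matrix"] * 10})
        with pytest.raises(ValueError):
            pp.compartment_composition(df)
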