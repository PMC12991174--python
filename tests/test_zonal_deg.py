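"""Pseudobulk DE engine, block assignment and TWI."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from striazone import syndata as sd
from striazone import zonal_deg as zd


def simulate_pb(seed, G=200, D=6, zones=(1, 2, 3), lfc_map=None,
                depth=3e5, alpha=0.05):
    """Direct pseudobulk NB simulation with known per-zone log2 effects."""
    rng = np.random.default_rng(seed)
    base = rng.lognormal(0, 1.0, G)
    base /= base.sum()
    lfc_map = lfc_map or {}
    rows, cnts = [], []
    for d in range(D):
        for z in zones:
            w = base.copy()
            for gi, per_zone in lfc_map.items():
                w[gi] = w[gi] * 2.0 ** per_zone.get(z, 0.0)
            w /= w.sum()
            mu = w * depth * rng.lognormal(0, 0.15)
            cnts.append(rng.poisson(rng.gamma(1 / alpha, mu * alpha)))
            rows.append({"donor": f"d{d:02d}", "zone": z, "n_cells": 100})
    cdf = pd.DataFrame(np.column_stack(cnts),
                       index=[f"g{i}" for i in range(G)],
                       columns=[f"s{i}" for i in range(len(rows))])
    meta = pd.DataFrame(rows, index=cdf.columns)
    meta["low_cells"] = False
    return zd.PseudobulkMatrix(cdf, meta)


class TestPseudobulk:
    def test_single_cell_groups_equal_their_cells(self):
        X = sparse.csr_matrix(np.array([[1, 2, 3], [4, 5, 6]]))
        cells = pd.DataFrame({"donor": ["d0", "d1"], "zone": [1, 1]})
        pb = zd.pseudobulk(X, cells, gene_names=["a", "b", "c"])
        assert np.array_equal(pb.counts.to_numpy().T, X.toarray())

    def test_column_sums_conserve_counts(self, msn_subset):
        sub, X, genes = msn_subset
        pb = zd.pseudobulk(X, sub, gene_names=genes)
        assert pb.counts.to_numpy().sum() == X.sum()
        for sid, meta in pb.meta.iterrows():
            m = ((sub["donor"] == meta["donor"])
                 & (sub["zone"] == meta["zone"])).to_numpy()
            assert pb.counts[sid].sum() == X[np.flatnonzero(m)].sum()

    def test_low_count_genes_removed_from_testing(self):
        pb = simulate_pb(0, G=50)
        pb.counts.iloc[0] = 0
        pb.counts.iloc[0, 0] = 49  # 49 total counts -> filtered
        res = zd.de_zone_vs_rest(pb, 1)
        assert pb.counts.index[0] not in res.index

    def test_missing_group_key_rejected(self):
        X = sparse.csr_matrix(np.ones((2, 3)))
        with pytest.raises(ValueError):
            zd.pseudobulk(X, pd.DataFrame({"donor": ["a", "b"]}))


class TestDEEngine:
    def test_null_gene_unbiased(self):
        pb = simulate_pb(1)
        res = zd.de_zone_vs_rest(pb, 1)
        assert abs(res["lfc"].mean()) < 0.03
        assert (res["padj"] < 0.05).mean() < 0.05

    def test_planted_marker_recovered(self):
        lfc_map = {0: {2: 1.5}, 1: {2: 1.5}, 2: {2: 1.5}}
        pb = simulate_pb(2, D=18, lfc_map=lfc_map)
        res = zd.de_zone_vs_rest(pb, 2)
        for g in ("g0", "g1", "g2"):
            assert res.loc[g, "lfc"] == pytest.approx(1.5, abs=0.3)
            assert res.loc[g, "padj"] < 0.05

    def test_depth_invariance(self):
        """Doubling one donor's depth leaves LFC estimates unchanged."""
        pb = simulate_pb(3, G=150)
        res1 = zd.de_zone_vs_rest(pb, 1)
        boosted = pb.counts.copy()
        cols = pb.meta.index[pb.meta["donor"] == "d00"]
        boosted[cols] = boosted[cols] * 2
        res2 = zd.de_zone_vs_rest(zd.PseudobulkMatrix(boosted, pb.meta), 1)
        assert np.allclose(res1["lfc"], res2["lfc"], atol=0.05)

    def test_single_donor_rejected(self):
        pb = simulate_pb(4, D=1)
        with pytest.raises(ValueError):
            zd.de_zone_vs_rest(pb, 1)


class TestBlocks:
    @staticmethod
    def _de_tables(rows):
        """Build per-zone DE tables from dicts gene -> (lfc, padj)."""
        zones = sorted({z for r in rows.values() for z in r})
        genes = list(rows)
        out = {}
        for z in zones:
            out[z] = pd.DataFrame({
                "lfc": [rows[g][z][0] for g in genes],
                "padj": [rows[g][z][1] for g in genes],
                "se": 0.1, "p": [rows[g][z][1] for g in genes],
                "converged": True}, index=genes)
        return out

    def test_zone_specific_rule_trace(self):
        de = self._de_tables({"g": {1: (0.0, 1.0), 2: (1.0, 1e-4),
                                    3: (0.0, 1.0)}})
        det = pd.DataFrame({1: [0.05], 2: [0.25], 3: [0.05]}, index=["g"])
        tab = zd.assign_blocks(de, det).table
        assert tab.loc["g", "block"] == (2,)
        assert tab.loc["g", "class"] == "zone-specific"

    def test_outside_detection_half_rule(self):
        """Inside 20%, outside 15%: 15 > 20/2 fails the half rule."""
        de = self._de_tables({"g": {1: (0.0, 1.0), 2: (1.0, 1e-4),
                                    3: (0.0, 1.0)}})
        det = pd.DataFrame({1: [0.15], 2: [0.20], 3: [0.15]}, index=["g"])
        tab = zd.assign_blocks(de, det).table
        assert "g" not in tab.index

    def test_shorter_block_wins_ties(self):
        """Candidates (1,) and (1,2) tie on mean FC; the singleton wins
        by the fewer-zones rule."""
        de = self._de_tables({
            "g": {1: (1.0, 1e-3), 2: (1.0, 1e-3), 3: (-1.0, 1.0),
                  4: (-1.0, 1.0), 5: (-1.0, 1.0), 6: (-1.0, 1.0)}})
        det = pd.DataFrame({1: [0.4], 2: [0.12], 3: [0.01], 4: [0.01],
                            5: [0.01], 6: [0.01]}, index=["g"])
        tab = zd.assign_blocks(de, det).table
        assert tab.loc["g", "block"] == (1,)

    def test_candidate_blocks_wrap_option(self):
        no_wrap = zd.candidate_blocks(6, wrap=False)
        wrap = zd.candidate_blocks(6, wrap=True)
        assert len(no_wrap) == 21
        assert (1, 6) in wrap and (1, 6) not in no_wrap

    def test_assignment_is_deterministic(self, msn_subset):
        sub, X, genes = msn_subset
        pb = zd.pseudobulk(X, sub, gene_names=genes)
        de = zd.de_all_zones(pb)
        det = zd.detection_rates(X, sub, gene_names=genes)
        t1 = zd.assign_blocks(de, det).table
        t2 = zd.assign_blocks(de, det).table
        pd.testing.assert_frame_equal(t1, t2)


class TestGradientClassification:
    def test_flat_block_is_discrete_and_step_is_gradient(self):
        lfc_map = {0: {1: 2.0, 2: 2.0},  # discrete two-zone block
                   1: {1: 1.2, 2: 3.0}}  # within-block step
        pb = simulate_pb(5, D=10, zones=(1, 2, 3, 4), lfc_map=lfc_map)
        tab = pd.DataFrame({"block": [(1, 2), (1, 2)],
                            "class": ["multi-zone", "multi-zone"],
                            "block_lfc": [2.0, 2.0], "padj": [1e-4, 1e-4]},
                           index=["g0", "g1"])
        out = zd.classify_gradient(zd.BlockAssignment(tab), pb).table
        assert out.loc["g0", "class"] == "multi-zone discrete"
        assert out.loc["g1", "class"] == "multi-zone gradient"


class TestTWI:
    def test_null_twi_near_zero(self):
        pb = simulate_pb(6, zones=(1, 2))
        twi = zd.compute_twi(zd.de_zone_vs_rest(pb, 1))
        assert twi < 0.01

    def test_ci_centered_on_leave_one_out_mean(self):
        pb = simulate_pb(7, D=6, zones=(1, 2),
                         lfc_map={i: {1: 0.8} for i in range(40)})
        res = zd.twi_with_jackknife(pb, 1)
        lo, hi = res.ci
        assert np.isclose(0.5 * (lo + hi), res.loo_mean)
        assert lo <= res.loo_mean <= hi
        assert res.jackknife_se > 0

    def test_too_few_donors_no_jackknife(self):
        pb = simulate_pb(8, D=2, zones=(1, 2))
        res = zd.twi_with_jackknife(pb, 1)
        assert res.ci is None

    def test_dorsoventral_permutation_floor(self):
        """A strongly dorsal-biased contrast is detected and the
        empirical p respects its 1/n_iter resolution floor."""
        lfc1 = {i: {1: 1.5} for i in range(30)}
        pb = simulate_pb(9, G=60, D=8, zones=(1, 2, 4, 5), lfc_map=lfc1)
        res = zd.twi_dorsoventral_permutation(pb, n_iter=100, seed=0)
        assert res["p"] >= 1 / 100
        assert res["delta_twi"] > 0
        assert res["p"] <= 0.05


class TestComposition:
    def test_identical_composition_null(self):
        rng = np.random.default_rng(10)
        rows = []
        for d in range(6):
            for z in range(1, 4):
                for t, n in (("A", 40), ("B", 40)):
                    for _ in range(n + rng.integers(0, 2)):
                        rows.append({"donor": f"d{d}", "zone": z,
                                     "cell_type": t})
        out = zd.zone_composition_tests(pd.DataFrame(rows))
        assert (out["padj"] > 0.2).all()

    def test_planted_excess_detected(self):
        rng = np.random.default_rng(11)
        rows = []
        for d in range(10):
            for z, na in ((1, 30), (2, 60), (3, 30)):
                for t, n in (("D1", na), ("D2", 30)):
                    for _ in range(rng.poisson(n)):
                        rows.append({"donor": f"d{d}", "zone": z,
                                     "cell_type": t})
        out = zd.zone_composition_tests(pd.DataFrame(rows))
        hit = out[(out["cell_type"] == "D1") & (out["zone"] == 2)]
        assert hit["padj"].iloc[0] < 0.05
        ratios = zd.d1_d2_ratio(pd.DataFrame(rows), d1_types=("D1",),
                                d2_types=("D2",))
        r2 = ratios[ratios["zone"] == 2]["ratio"].mean()
        r1 = ratios[ratios["zone"] == 1]["ratio"].mean()
        assert r2 > 1.5 * r1

    def test_single_donor_rejected(self):
        df = pd.DataFrame({"donor": ["d0"] * 5, "zone": [1] * 5,
                           "cell_type": ["A"] * 5})
        with pytest.raises(ValueError):
            zd.zone_composition_tests(df)


class TestAxisSlopes:
    def test_constant_gene_zero_slope(self):
        rng = np.random.default_rng(12)
        n = 300
        cells = pd.DataFrame({"donor": "d0",
                              "x_um": rng.uniform(0, 5000, n),
                              "y_um": rng.uniform(0, 5000, n)})
        coords = pd.DataFrame({"dv_um": cells["y_um"] - 2500,
                               "cp_um": cells["x_um"] - 2500})
        E = np.column_stack([np.full(n, 2.0),
                             (cells["y_um"].to_numpy() - 2500) / 1000.0])
        out = zd.axis_slopes(E, cells, coords, ["flat", "grad"])
        assert out.loc["flat", "dv_slope"] == pytest.approx(0.0, abs=1e-9)
        assert out.loc["grad", "dv_slope"] == pytest.approx(1.0, abs=1e-6)
        assert out.loc["grad", "cp_slope"] == pytest.approx(0.0, abs=0.05)

    def test_median_across_donors(self):
        n = 90
        rng = np.random.default_rng(13)
        frames = []
        slopes = {"d0": 1.0, "d1": 1.0, "d2": 10.0}  # median robust to d2
        for d, s in slopes.items():
            y = rng.uniform(0, 1000, n)
            frames.append(pd.DataFrame({"donor": d, "x_um": 0.0, "y_um": y,
                                        "slope": s}))
        cells = pd.concat(frames, ignore_index=True)
        coords = pd.DataFrame({"dv_um": cells["y_um"],
                               "cp_um": rng.uniform(0, 1000, 3 * n)})
        E = (cells["slope"] * cells["y_um"] / 1000.0).to_numpy()[:, None]
        out = zd.axis_slopes(E, cells, coords, ["g"])
        assert out.loc["g", "dv_slope"] == pytest.approx(1.0, abs=1e-6)
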