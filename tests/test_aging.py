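"""Hierarchical mapping, age x zone modelling, consensus ICA, erosion."""

import numpy as np
import pandas as pd
import pytest

from striazone import aging as ag
from striazone import syndata as sd
from striazone import zonal_deg as zd


# ---------------------------------------------------------------------------
# Hierarchy
# ---------------------------------------------------------------------------

def _toy_reference(seed=0, n_per=120, centers=((0, 0), (4, 0), (10, 0))):
    rng = np.random.default_rng(seed)
    emb, labels, E = [], [], []
    for lv, c in enumerate(centers, start=1):
        emb.append(rng.normal(c, 0.3, (n_per, 2)))
        labels += [lv] * n_per
        prof = np.zeros(60)
        prof[(lv - 1) * 20:lv * 20] = 3.0
        E.append(np.clip(prof + rng.normal(0, 0.5, (n_per, 60)), 0, None))
    genes = [f"g{i}" for i in range(60)]
    return np.vstack(emb), np.array(labels), np.vstack(E), genes


class TestHierarchy:
    def test_two_clusters_single_merge(self):
        emb, labels, E, genes = _toy_reference(centers=((0, 0), (5, 0)))
        h = ag.build_hierarchy(emb, labels, E, genes)
        assert len(h.merge_trace) == 1
        assert h.root.left is not None and h.root.right is not None

    def test_closest_pair_merges_first(self):
        emb, labels, E, genes = _toy_reference()
        h = ag.build_hierarchy(emb, labels, E, genes)
        first = h.merge_trace[0]
        assert set(first[0] + first[1]) == {1, 2}  # distances 4 < 6 < 10

    def test_marker_count_clamped(self):
        rng = np.random.default_rng(1)
        emb = np.vstack([rng.normal(0, 0.2, (50, 2)),
                         rng.normal(5, 0.2, (50, 2))])
        labels = np.array([1] * 50 + [2] * 50)
        E = rng.lognormal(0, 1, (100, 500))
        genes = [f"g{i}" for i in range(500)]
        h = ag.build_hierarchy(emb, labels, E, genes)
        assert 30 <= len(h.root.markers) <= 100

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            ag.build_hierarchy(np.zeros((5, 2)), np.ones(5),
                               np.zeros((5, 3)), ["a", "b", "c"])


class TestMapping:
    def test_centroid_profiles_map_to_own_leaves(self):
        emb, labels, E, genes = _toy_reference()
        h = ag.build_hierarchy(emb, labels, E, genes)
        cents = np.stack([E[labels == lv].mean(axis=0) for lv in (1, 2, 3)])
        out = ag.map_labels(cents, h, n_boot=200, seed=0)
        assert out["label"].tolist() == [1, 2, 3]
        assert (out["confidence"] > 0.9).all()

    def test_self_mapping_accuracy(self):
        emb, labels, E, genes = _toy_reference()
        h = ag.build_hierarchy(emb, labels, E, genes)
        out = ag.map_labels(E, h, n_boot=50, seed=0)
        assert (out["label"].to_numpy() == labels).mean() >= 0.99

    def test_mapping_reproducible(self):
        emb, labels, E, genes = _toy_reference()
        h = ag.build_hierarchy(emb, labels, E, genes)
        a = ag.map_labels(E[:20], h, n_boot=50, seed=3)
        b = ag.map_labels(E[:20], h, n_boot=50, seed=3)
        pd.testing.assert_frame_equal(a, b)


# ---------------------------------------------------------------------------
# Age x zone model
# ---------------------------------------------------------------------------

def _aging_logcpm(seed=0, D=12, G=80, slope=-0.1, inter4=0.05):
    rng = np.random.default_rng(seed)
    ages = np.linspace(25, 75, D)
    genes = [f"g{i}" for i in range(G)]
    affected = np.zeros(G)
    affected[:15] = 1.0
    data, rows = {}, []
    for di, a in enumerate(ages):
        for z in range(1, 7):
            mu = (8 + slope * affected * (a / 10)
                  + (inter4 * affected * (a / 10) if z == 4 else 0)
                  + rng.normal(0, 0.08, G))
            data[f"d{di:02d}|{z}"] = mu
            rows.append({"donor": f"d{di:02d}", "zone": z, "age_years": a})
    logcpm = pd.DataFrame(data, index=genes)
    meta = pd.DataFrame(rows, index=logcpm.columns)
    return logcpm, meta


class TestAgeZoneModel:
    def test_uniform_slope_recovered_without_interactions(self):
        logcpm, meta = _aging_logcpm(inter4=0.0)
        fit = ag.fit_age_zone_model(logcpm, meta)
        assert fit["baseline"]["lfc_decade"][:15].mean() == \
            pytest.approx(-0.1, abs=0.02)
        for z, tab in fit["interactions"].items():
            assert abs(tab["lfc"][:15].mean()) < 0.03

    def test_zone_specific_deceleration(self):
        logcpm, meta = _aging_logcpm(inter4=0.05)
        fit = ag.fit_age_zone_model(logcpm, meta)
        assert fit["per_zone"][4]["lfc_decade"][:15].mean() == \
            pytest.approx(-0.05, abs=0.02)

    def test_reference_zone_effect_equals_baseline(self):
        logcpm, meta = _aging_logcpm()
        fit = ag.fit_age_zone_model(logcpm, meta)
        assert np.allclose(fit["per_zone"][1]["lfc_decade"],
                           fit["baseline"]["lfc_decade"])

    def test_age_is_scaled_per_decade(self):
        """Multiplying ages by 10 scales coefficients by 1/10 (the model
        divides age by 10 so effects read per decade)."""
        logcpm, meta = _aging_logcpm()
        fit1 = ag.fit_age_zone_model(logcpm, meta)
        meta10 = meta.copy()
        meta10["age_years"] = meta10["age_years"] * 10
        fit10 = ag.fit_age_zone_model(logcpm, meta10)
        assert np.allclose(fit10["baseline"]["lfc_decade"],
                           fit1["baseline"]["lfc_decade"] / 10, atol=1e-10)

    def test_rank_deficient_design_rejected(self):
        logcpm, meta = _aging_logcpm()
        meta = meta.copy()
        meta["dup"] = meta["age_years"] / 10.0
        with pytest.raises(ValueError):
            ag.fit_age_zone_model(logcpm, meta, covariates=["dup"])


# ---------------------------------------------------------------------------
# Consensus ICA
# ---------------------------------------------------------------------------

class TestPAM:
    def test_matches_exhaustive_on_small_instance(self):
        from itertools import combinations

        rng = np.random.default_rng(2)
        pts = np.vstack([rng.normal(0, 0.2, (5, 2)),
                         rng.normal(5, 0.2, (5, 2))])
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        med = ag.pam(D, 2)
        best = min(combinations(range(10), 2),
                   key=lambda m: D[:, m].min(axis=1).sum())
        assert D[:, med].min(axis=1).sum() == pytest.approx(
            D[:, list(best)].min(axis=1).sum())


class TestConsensusICA:
    @staticmethod
    def _planted(seed=0, G=400):
        rng = np.random.default_rng(seed)
        a1 = np.array([1, 1, 1, -1, -1, -1], float)
        a2 = np.array([1, -1, 1, -1, 1, -1], float)
        a1, a2 = a1 / np.linalg.norm(a1), a2 / np.linalg.norm(a2)
        s1, s2 = rng.laplace(0, 1, G), rng.laplace(0, 1, G)
        X = np.outer(s1, a1) + np.outer(s2, a2)
        return pd.DataFrame(X, index=[f"g{i}" for i in range(G)]), (a1, a2)

    def test_two_orthogonal_patterns_recovered(self):
        L, (a1, a2) = self._planted()
        dec = ag.consensus_ica(L, n_runs=60, seed=1)
        assert dec.k == 2
        assert not dec.flagged
        for a in (a1, a2):
            best = max(abs(np.corrcoef(a, dec.mixing[:, c])[0, 1])
                       for c in range(dec.k))
            assert best > 0.99
        assert (dec.stability > 0.99).all()

    def test_sp_formula_and_normalization(self):
        sp = ag.signed_proportions(pd.DataFrame([[2.0, -1.0, 1.0]]))
        assert np.allclose(sp.to_numpy(), [[0.5, -0.25, 0.25]])
        L, _ = self._planted(seed=3)
        dec = ag.consensus_ica(L, n_runs=30, seed=2)
        sums = dec.sp.abs().sum(axis=1).to_numpy()
        nz = np.abs(dec.sources).sum(axis=1) > 0
        assert np.allclose(sums[nz], 1.0)

    def test_consensus_sign_invariant_to_run_order(self):
        L, _ = self._planted(seed=4)
        d1 = ag.consensus_ica(L, n_runs=30, seed=5)
        d2 = ag.consensus_ica(L, n_runs=30, seed=6)
        C = np.abs(np.corrcoef(d1.mixing.T, d2.mixing.T))[:d1.k, d1.k:]
        assert np.allclose(C.max(axis=1), 1.0, atol=1e-3)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            ag.consensus_ica(pd.DataFrame(np.zeros((50, 6))))
        with pytest.raises(ValueError):
            ag.consensus_ica(pd.DataFrame(np.zeros((300, 1))))


# ---------------------------------------------------------------------------
# Erosion statistics
# ---------------------------------------------------------------------------

def _cohort_pb(erosion, seed, n_donors=12):
    ages = tuple(np.linspace(25, 85, n_donors))
    tspec = sd.TissueSpec(n_donors=n_donors, n_cells_per_donor=500,
                          rng_seed=seed)
    espec = sd.default_expression(n_genes=120, n_markers_per_zone=5,
                                  n_gradient=0)
    aspec = sd.AgingSpec(donor_ages=ages, erosion_rate=erosion)
    cells, X, genes = sd.generate_aging_cohort(tspec, espec, aspec)
    cells["zone"] = cells["truth_zone"]
    msn = cells["cell_type"].isin(
        ["D1_Matrix_MSN", "D2_Matrix_MSN"]).to_numpy()
    pb = zd.pseudobulk(X[np.flatnonzero(msn)],
                       cells[msn].reset_index(drop=True), gene_names=genes)
    ages_map = dict(zip(sorted(cells["donor"].unique()), ages))
    return pb, ag.log_cpm(pb.counts), ages_map, espec


class TestErosion:
    def test_variance_compression_expression_filter(self):
        pb, lc, ages, _ = _cohort_pb(0.2, seed=50)
        out = ag.variance_compression(lc, pb.meta, ages, n_perm=50, seed=0)
        young_cols = pb.meta.index[pb.meta["donor"].isin(out["young"])]
        means = lc.loc[out["delta_var"].index, young_cols].mean(axis=1)
        assert (means > 3.0).all()

    def test_quartile_groups_disjoint(self):
        pb, lc, ages, _ = _cohort_pb(0.0, seed=51)
        out = ag.variance_compression(lc, pb.meta, ages, n_perm=50, seed=0)
        assert not set(out["young"]) & set(out["old"])

    def test_too_few_donors_rejected(self):
        pb, lc, ages, _ = _cohort_pb(0.0, seed=52, n_donors=12)
        few = dict(list(ages.items())[:4])
        keep = pb.meta["donor"].isin(few).to_numpy()
        with pytest.raises(ValueError):
            ag.variance_compression(lc.loc[:, keep], pb.meta.loc[keep],
                                    few, n_perm=10)

    def test_erosion_converges_zone_pairs_with_age(self):
        pb, lc, ages, _ = _cohort_pb(0.2, seed=53)
        tr = ag.zone_correlation_trend(lc, pb.meta, ages)
        far = tr[(tr["zone_a"] == 1) & (tr["zone_b"] == 4)]
        assert far["age_correlation"].iloc[0] > 0.3

    def test_marker_erosion_enrichment_signs(self):
        """With global erosion, each zone's markers fall within their own
        zone (they lose their planted elevation) relative to non-markers."""
        pb, lc, ages, espec = _cohort_pb(0.25, seed=54)
        meta = pb.meta.copy()
        meta["age_years"] = meta["donor"].map(ages)
        fit = ag.fit_age_zone_model(lc, meta)
        markers = {z: [m.gene for m in espec.markers if m.block == (z,)]
                   for z in range(1, 7)}
        out = ag.marker_erosion_enrichment(fit["per_zone"], markers)
        diag = out[out["marker_zone"] == out["aging_zone"]]
        assert diag["mean_lfc"].mean() < 0
        off = out[out["marker_zone"] != out["aging_zone"]]
        assert diag["mean_lfc"].mean() < off["mean_lfc"].mean()
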