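"""Age-related zonal analyses.

Covers transferring zone labels onto dissociated (non-spatial) cohorts
via a bootstrapped hierarchical classifier, modelling per-decade aging
effects with zone x age interactions (OLS with donor-clustered robust
standard errors on donor x zone pseudobulk logCPM), decomposing the
zone-level aging fold-change matrix with consensus independent component
analysis (ICA), and quantifying the erosion of zonal identity with age:
marker enrichment among aging genes, between-zone variance compression
with a donor-quartile permutation test, and zone-pair expression
correlation trends over the lifespan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .zonal_deg import PseudobulkMatrix, bh_adjust

__all__ = [
    "LabelHierarchy",
    "build_hierarchy",
    "map_labels",
    "log_cpm",
    "fit_age_zone_model",
    "pam",
    "consensus_ica",
    "signed_proportions",
    "ICADecomposition",
    "marker_erosion_enrichment",
    "variance_compression",
    "zone_correlation_trend",
]


# ---------------------------------------------------------------------------
# Hierarchical label transfer
# ---------------------------------------------------------------------------

@dataclass
class _Node:
    members: tuple  # leaf labels under this node
    left: "_Node | None" = None
    right: "_Node | None" = None
    markers: tuple[str, ...] = ()
    left_profile: np.ndarray | None = None  # standardized marker profile
    right_profile: np.ndarray | None = None
    marker_cols: np.ndarray | None = None
    norm_mu: np.ndarray | None = None  # per-marker standardization
    norm_sd: np.ndarray | None = None


@dataclass
class LabelHierarchy:
    """Centroid-linkage merge tree with per-node marker panels."""

    root: _Node
    gene_names: list[str]
    merge_trace: list[tuple] = field(default_factory=list)


def _select_markers(E: np.ndarray, in_a: np.ndarray, in_b: np.ndarray,
                    lo: int = 30, hi: int = 100) -> np.ndarray:
    """Discriminative genes between two branches.

    Ranked by the product of detection-rate difference rank and mean
    log-expression difference rank (both by |difference|); panel size
    clamped to [30, 100] (capped by the number of genes available).
    """
    det_a = (E[in_a] > 0).mean(axis=0)
    det_b = (E[in_b] > 0).mean(axis=0)
    mu_a = E[in_a].mean(axis=0)
    mu_b = E[in_b].mean(axis=0)
    ddet = np.abs(det_a - det_b)
    dmu = np.abs(mu_a - mu_b)
    score = stats.rankdata(ddet) * stats.rankdata(dmu)
    n = int(np.clip(hi, lo, len(score)))
    order = np.argsort(score)[::-1]
    strong = order[: max(lo, int((score > np.median(score) * 2).sum()))]
    return np.sort(strong[:n])


def build_hierarchy(embedding: np.ndarray, labels: np.ndarray,
                    E: np.ndarray, gene_names: list[str]) -> LabelHierarchy:
    """Agglomerative centroid-linkage merge tree over leaf clusters.

    At each step the two clusters with the closest embedding centroids
    merge (ties by lowest label index); every merge is recorded.  Each
    internal node stores a 30-100 gene marker panel separating its two
    branches together with branch mean marker profiles, used later for
    bootstrapped top-down mapping.
    """
    leaves = sorted(pd.unique(labels).tolist())
    if len(leaves) < 2:
        raise ValueError("need >= 2 leaf clusters")
    nodes: dict[tuple, _Node] = {(lv,): _Node(members=(lv,)) for lv in leaves}
    cents = {(lv,): embedding[labels == lv].mean(axis=0) for lv in leaves}
    trace = []
    active = list(nodes)
    while len(active) > 1:
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                d = float(np.linalg.norm(cents[a] - cents[b]))
                key = (d, a, b)
                if best is None or key < best:
                    best = key
        d, a, b = best
        merged = tuple(sorted(a + b))
        in_a = np.isin(labels, a)
        in_b = np.isin(labels, b)
        cols = _select_markers(E, in_a, in_b)
        both = in_a | in_b
        mu = E[both][:, cols].mean(axis=0)
        sd = E[both][:, cols].std(axis=0)
        sd[sd == 0] = 1.0
        # standardize marker profiles so low-expressed discriminative
        # genes are not drowned out by housekeeping-scale genes
        node = _Node(members=merged, left=nodes[a], right=nodes[b],
                     markers=tuple(gene_names[c] for c in cols),
                     marker_cols=cols, norm_mu=mu, norm_sd=sd,
                     left_profile=(E[in_a][:, cols].mean(axis=0) - mu) / sd,
                     right_profile=(E[in_b][:, cols].mean(axis=0) - mu) / sd)
        nodes[merged] = node
        na, nb = in_a.sum(), in_b.sum()
        cents[merged] = (cents[a] * na + cents[b] * nb) / (na + nb)
        trace.append((a, b, d))
        active = [x for x in active if x not in (a, b)] + [merged]
    return LabelHierarchy(root=nodes[active[0]], gene_names=gene_names,
                          merge_trace=trace)


def map_labels(E_query: np.ndarray, hierarchy: LabelHierarchy,
               n_boot: int = 1000, boot_factor: float = 0.9,
               seed: int = 0) -> pd.DataFrame:
    """Bootstrapped top-down label assignment for query cells.

    At every internal node, each bootstrap draws ``boot_factor`` of the
    node's markers and votes for the branch whose mean marker profile is
    closer (Pearson correlation, Euclidean fallback); descent follows the
    majority branch and the vote fraction is the node confidence.  Cells
    reach a leaf unless all markers are missing, in which case the
    current (coarser) node label is returned.
    """
    rng = np.random.default_rng(seed)
    n = E_query.shape[0]
    labels = np.empty(n, dtype=object)
    confidence = np.ones(n)

    def descend(node: _Node, rows: np.ndarray):
        if node.left is None:
            labels[rows] = node.members[0]
            return
        cols = node.marker_cols
        if cols is None or len(cols) == 0:
            labels[rows] = [node.members] * len(rows)
            return
        m = len(cols)
        k = max(1, int(round(boot_factor * m)))
        Eq = (E_query[rows][:, cols] - node.norm_mu) / node.norm_sd
        votes_left = np.zeros(len(rows))
        for _ in range(n_boot):
            pick = rng.choice(m, size=k, replace=False)
            # matched filter: project on the branch-profile contrast and
            # split at the midpoint of the two branch projections
            d = node.left_profile[pick] - node.right_profile[pick]
            proj = Eq[:, pick] @ d
            mid = 0.5 * (node.left_profile[pick] @ d
                         + node.right_profile[pick] @ d)
            votes_left += proj >= mid
        frac = votes_left / n_boot
        go_left = frac >= 0.5
        conf = np.where(go_left, frac, 1 - frac)
        confidence[rows] = np.minimum(confidence[rows], conf)
        if go_left.any():
            descend(node.left, rows[go_left])
        if (~go_left).any():
            descend(node.right, rows[~go_left])

    descend(hierarchy.root, np.arange(n))
    return pd.DataFrame({"label": labels, "confidence": confidence})


# ---------------------------------------------------------------------------
# Zone x age interaction model
# ---------------------------------------------------------------------------

def log_cpm(counts: pd.DataFrame, pseudo: float = 1.0) -> pd.DataFrame:
    """log2 counts per million (genes x samples)."""
    lib = counts.sum(axis=0).to_numpy(float)
    return np.log2(counts / lib[None, :] * 1e6 + pseudo)


def fit_age_zone_model(logcpm: pd.DataFrame, meta: pd.DataFrame,
                       covariates: list[str] | None = None,
                       reference_zone: int = 1) -> dict:
    """Per-gene linear model with zone, age/decade and zone x age terms.

    Fit by OLS on donor x zone pseudobulk logCPM with donor-clustered
    (sandwich) standard errors; age enters divided by 10 so coefficients
    are per-decade log2 fold changes.  The reference zone's interaction
    is identically zero, so its absolute aging effect equals the baseline
    age coefficient; other zones' effects are baseline + interaction.
    Returns {'baseline': DataFrame, 'per_zone': DataFrame of per-zone
    effects/SE/p/padj, 'interactions': DataFrame}.
    """
    meta = meta.copy()
    zones = sorted(meta["zone"].unique())
    if reference_zone not in zones:
        raise ValueError("reference zone absent")
    donors = meta["donor"].to_numpy()
    age_dec = (meta["age_years"].to_numpy(float)) / 10.0
    n = len(meta)
    cols = [np.ones(n)]
    names = ["intercept"]
    for z in zones:
        if z == reference_zone:
            continue
        cols.append((meta["zone"].to_numpy() == z).astype(float))
        names.append(f"zone{z}")
    cols.append(age_dec)
    names.append("age")
    for z in zones:
        if z == reference_zone:
            continue
        cols.append(age_dec * (meta["zone"].to_numpy() == z))
        names.append(f"age_zone{z}")
    if covariates:
        for c in covariates:
            cols.append(meta[c].to_numpy(float))
            names.append(c)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design")
    Y = logcpm.to_numpy(float).T  # samples x genes
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y  # p x genes
    resid = Y - X @ B
    # cluster-robust (CR1) sandwich by donor
    p = X.shape[1]
    meat = np.zeros((Y.shape[1], p, p))
    udon = pd.unique(donors)
    for d in udon:
        m = donors == d
        Xc = X[m]
        Ec = resid[m]  # nc x genes
        s = np.einsum("cp,cg->gp", Xc, Ec)
        meat += np.einsum("gp,gq->gpq", s, s)
    G = len(udon)
    dfc = G / (G - 1) * (n - 1) / (n - p)
    cov = dfc * np.einsum("pq,gqr,rs->gps", XtX_inv, meat, XtX_inv)
    se = np.sqrt(np.maximum(np.diagonal(cov, axis1=1, axis2=2), 1e-30))
    tstat = B.T / se
    df = G - 1
    pvals = 2 * stats.t.sf(np.abs(tstat), df)
    name_idx = {nm: i for i, nm in enumerate(names)}
    genes = logcpm.index
    baseline = pd.DataFrame({
        "lfc_decade": B[name_idx["age"]],
        "se": se[:, name_idx["age"]],
        "p": pvals[:, name_idx["age"]],
    }, index=genes)
    baseline["padj"] = bh_adjust(baseline["p"].to_numpy())
    per_zone = {}
    inter = {}
    ai = name_idx["age"]
    for z in zones:
        if z == reference_zone:
            eff = B[ai]
            vse = se[:, ai]
        else:
            ii = name_idx[f"age_zone{z}"]
            eff = B[ai] + B[ii]
            var = (cov[:, ai, ai] + cov[:, ii, ii] + 2 * cov[:, ai, ii])
            vse = np.sqrt(np.maximum(var, 1e-30))
            inter[z] = pd.DataFrame({
                "lfc": B[ii], "se": se[:, ii],
                "p": pvals[:, ii]}, index=genes)
        pz = 2 * stats.t.sf(np.abs(eff / vse), df)
        per_zone[z] = pd.DataFrame({"lfc_decade": eff, "se": vse, "p": pz},
                                   index=genes)
        per_zone[z]["padj"] = bh_adjust(pz)
    return {"baseline": baseline, "per_zone": per_zone,
            "interactions": inter, "coef_names": names}


# ---------------------------------------------------------------------------
# Consensus ICA
# ---------------------------------------------------------------------------

def pam(D: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """Partitioning Around Medoids (classic build/swap) on a distance
    matrix; returns medoid indices (deterministic)."""
    n = D.shape[0]
    # BUILD
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        best_gain, best_j = -np.inf, None
        dmin = D[:, medoids].min(axis=1)
        for j in range(n):
            if j in medoids:
                continue
            gain = np.maximum(dmin - D[:, j], 0).sum()
            if gain > best_gain:
                best_gain, best_j = gain, j
        medoids.append(best_j)
    # SWAP
    for _ in range(max_iter):
        assign = D[:, medoids].min(axis=1).sum()
        best = (0.0, None, None)
        for mi, m in enumerate(medoids):
            for j in range(n):
                if j in medoids:
                    continue
                cand = medoids[:mi] + [j] + medoids[mi + 1:]
                cost = D[:, cand].min(axis=1).sum()
                delta = assign - cost
                if delta > best[0] + 1e-12:
                    best = (delta, mi, j)
        if best[1] is None:
            break
        medoids[best[1]] = best[2]
    return np.array(sorted(medoids))


@dataclass
class ICADecomposition:
    """Consensus ICA of the zones x genes aging fold-change matrix."""

    k: int
    mixing: np.ndarray  # zones x k (cluster medoids)
    sources: np.ndarray  # genes x k (pseudoinverse refactorization)
    stability: np.ndarray  # per component
    variance_explained: np.ndarray
    sp: pd.DataFrame | None = None
    source_se: np.ndarray | None = None
    flagged: bool = False
    stability_by_k: dict = field(default_factory=dict)


def consensus_ica(L: pd.DataFrame, k_range=range(2, 7), n_runs: int = 100,
                  stability_min: float = 0.99, seed: int = 0
                  ) -> ICADecomposition:
    """Consensus ICA over repeated randomized runs.

    ``L`` is genes x zones (per-zone aging log fold changes).  For each
    candidate component count k, FastICA runs ``n_runs`` times with
    random initialization; the pooled mixing columns are clustered with
    PAM under absolute-Pearson-correlation distance, and per-cluster
    stability is the mean pairwise |r|.  The selected k* is the highest k
    whose clusters all exceed the stability threshold; consensus mixing
    vectors are the cluster medoids and the consensus source matrix is
    obtained by Moore-Penrose pseudoinverse refactorization.  If no k
    passes, the k with the best minimum stability is returned flagged.
    """
    from sklearn.decomposition import FastICA

    X = L.to_numpy(float)  # genes x zones
    if X.shape[0] < 200:
        raise ValueError("need >= 200 genes")
    if X.shape[1] < 2:
        raise ValueError("need >= 2 zones")
    rng = np.random.default_rng(seed)
    # components beyond the numerical rank of the LFC matrix would whiten
    # against zero eigenvalues and return arbitrary directions
    sv = np.linalg.svd(X - X.mean(axis=0), compute_uv=False)
    rank = int((sv > sv[0] * 1e-6).sum())
    results = {}
    max_iter = 1000
    for k in k_range:
        if k > min(X.shape[1], rank):
            continue
        mix_cols = []
        run_of = []
        for r in range(n_runs):
            ica = FastICA(n_components=k, whiten="unit-variance",
                          max_iter=max_iter, tol=1e-10,
                          random_state=int(rng.integers(2**31 - 1)))
            try:
                import warnings
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    ica.fit(X)
            except Exception:
                continue
            if ica.n_iter_ >= max_iter or ica.n_iter_ <= 2:
                # drop non-converged runs and spurious immediate fixed
                # points (tolerance met by the initial random rotation)
                continue
            A = ica.mixing_  # zones x k
            for c in range(k):
                col = A[:, c]
                nrm = np.linalg.norm(col)
                if nrm > 0:
                    mix_cols.append(col / nrm)
                    run_of.append(r)
        if len(mix_cols) < 2 * k:
            continue
        M = np.column_stack(mix_cols)  # zones x m
        C = np.corrcoef(M.T)
        D = 1.0 - np.abs(C)
        np.fill_diagonal(D, 0.0)
        med = pam(D, k)
        assign = np.argmin(D[:, med], axis=1)
        stab = np.empty(k)
        for c in range(k):
            members = np.flatnonzero(assign == c)
            if len(members) < 2:
                stab[c] = 0.0
            else:
                sub = np.abs(C[np.ix_(members, members)])
                stab[c] = (sub.sum() - len(members)) / \
                    (len(members) * (len(members) - 1))
        results[k] = {"medoids": M[:, med], "stability": stab,
                      "M": M, "assign": assign, "C": C}
    if not results:
        raise RuntimeError("no successful ICA runs")
    passing = [k for k, r in results.items()
               if (r["stability"] > stability_min).all()]
    flagged = not passing
    if passing:
        k_star = max(passing)
    else:
        k_star = max(results, key=lambda k: results[k]["stability"].min())
    r = results[k_star]
    A = r["medoids"]  # zones x k
    S = X @ np.linalg.pinv(A.T)  # genes x k
    # per-component variance explained by rank-1 reconstruction
    tot = (X**2).sum()
    ve = np.array([((np.outer(S[:, c], A[:, c]))**2).sum() / tot
                   for c in range(k_star)])
    # SEs across sign-aligned member runs
    se = np.zeros_like(S)
    for c in range(k_star):
        members = np.flatnonzero(r["assign"] == c)
        vals = []
        for m in members:
            col = r["M"][:, m]
            sgn = np.sign(col @ A[:, c]) or 1.0
            vals.append(X @ np.linalg.pinv(col[None, :] * sgn)[:, 0])
        if len(vals) > 1:
            se[:, c] = np.std(np.stack(vals), axis=0)
    dec = ICADecomposition(
        k=k_star, mixing=A, sources=S, stability=r["stability"],
        variance_explained=ve, source_se=se, flagged=flagged,
        stability_by_k={k: v["stability"] for k, v in results.items()})
    dec.sp = signed_proportions(pd.DataFrame(S, index=L.index))
    return dec


def signed_proportions(sources: pd.DataFrame) -> pd.DataFrame:
    """Signed Proportion: loading divided by the sum of absolute loadings
    across components; rows with any nonzero loading satisfy
    sum(|SP|) = 1."""
    S = sources.to_numpy(float)
    denom = np.abs(S).sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        sp = np.where(denom > 0, S / denom, 0.0)
    return pd.DataFrame(sp, index=sources.index, columns=sources.columns)


# ---------------------------------------------------------------------------
# Zonal erosion statistics
# ---------------------------------------------------------------------------

def marker_erosion_enrichment(per_zone_aging: dict[int, pd.DataFrame],
                              zone_markers: dict[int, list[str]]
                              ) -> pd.DataFrame:
    """Mean aging LFC of each zone's markers within each zone's aging
    profile, with a two-sided Wilcoxon rank-sum test vs non-markers and
    FDR adjustment across the matrix cells."""
    rows = []
    for mz, markers in zone_markers.items():
        for dz, de in per_zone_aging.items():
            mk = [g for g in markers if g in de.index]
            if not mk:
                continue
            vals = de.loc[mk, "lfc_decade"].to_numpy()
            other = de.loc[~de.index.isin(mk), "lfc_decade"].to_numpy()
            if len(other) < 2 or len(vals) < 2:
                p = np.nan
            else:
                p = float(stats.mannwhitneyu(
                    vals, other, alternative="two-sided").pvalue)
            rows.append({"marker_zone": mz, "aging_zone": dz,
                         "mean_lfc": float(vals.mean()), "p": p,
                         "n_markers": len(mk)})
    out = pd.DataFrame(rows)
    if len(out):
        out["padj"] = bh_adjust(out["p"].to_numpy())
    return out


def _between_zone_variance(logcpm: pd.DataFrame, meta: pd.DataFrame
                           ) -> pd.DataFrame:
    """Per donor, sample variance of each gene across its zone columns."""
    out = {}
    for d in meta["donor"].unique():
        cols = meta.index[meta["donor"] == d]
        sub = logcpm[cols]
        if sub.shape[1] < 2:
            continue
        out[d] = sub.var(axis=1, ddof=1)
    return pd.DataFrame(out)


def variance_compression(logcpm: pd.DataFrame, meta: pd.DataFrame,
                         donor_ages: dict[str, float], n_perm: int = 10000,
                         expr_min: float = 3.0, seed: int = 0) -> dict:
    """Age-related compression of between-zone expression variance.

    For every gene, between-zone variance of pseudobulk logCPM is
    computed per donor and averaged within the young (bottom age
    quartile) and old (top quartile) donor groups; delta_var = old -
    young.  Genes are filtered to mean young-quartile expression above
    ``expr_min`` logCPM.  The statistic is the fraction of genes with
    negative delta_var; shuffling young/old membership (same group
    sizes, without replacement) ``n_perm`` times yields the empirical
    two-sided p.
    """
    ages = pd.Series(donor_ages)
    donors = [d for d in ages.index if d in set(meta["donor"])]
    if len(donors) < 8:
        raise ValueError("need >= 8 donors for quartile groups")
    q25, q75 = np.percentile(ages[donors], [25, 75])
    young = [d for d in donors if ages[d] <= q25]
    old = [d for d in donors if ages[d] >= q75]
    if set(young) & set(old):
        raise ValueError("age quartiles overlap")
    bzv = _between_zone_variance(logcpm, meta)
    young_cols = meta.index[meta["donor"].isin(young)]
    keep = logcpm[young_cols].mean(axis=1) > expr_min
    bzv = bzv.loc[keep]

    def frac_negative(yg, og):
        delta = bzv[og].mean(axis=1) - bzv[yg].mean(axis=1)
        return float((delta < 0).mean()), delta

    obs_frac, delta = frac_negative(young, old)
    pool = young + old
    rng = np.random.default_rng(seed)
    perm = np.empty(n_perm)
    for b in range(n_perm):
        sel = rng.permutation(pool)
        perm[b] = frac_negative(list(sel[:len(young)]),
                                list(sel[len(young):]))[0]
    p_hi = float(np.mean(perm >= obs_frac))
    p_lo = float(np.mean(perm <= obs_frac))
    p = min(1.0, max(2.0 * min(p_hi, p_lo), 1.0 / n_perm))
    return {"fraction_negative": obs_frac, "p": p, "delta_var": delta,
            "n_genes": int(keep.sum()), "young": young, "old": old,
            "null": perm}


def zone_correlation_trend(logcpm: pd.DataFrame, meta: pd.DataFrame,
                           donor_ages: dict[str, float],
                           expr_min: float = 3.0) -> pd.DataFrame:
    """Age trend of between-zone transcriptomic similarity.

    Per donor and zone pair, the Pearson correlation of the two zones'
    pseudobulk logCPM vectors over expressed genes (young-quartile mean
    logCPM > ``expr_min``, matching the variance-compression filter);
    then, per zone pair, the Pearson correlation of that similarity with
    donor age.  Positive values mean the zones converge with age.
    """
    ages = pd.Series(donor_ages)
    donors = [d for d in ages.index if d in set(meta["donor"])]
    if len(donors) < 3:
        raise ValueError("need >= 3 donors")
    q25 = np.percentile(ages[donors], 25)
    young_cols = meta.index[meta["donor"].isin(
        [d for d in donors if ages[d] <= q25])]
    keep = logcpm[young_cols].mean(axis=1) > expr_min
    sub = logcpm.loc[keep]
    zones = sorted(meta["zone"].unique())
    rows = []
    for i, za in enumerate(zones):
        for zb in zones[i + 1:]:
            rs, age_v = [], []
            for d in donors:
                ca = meta.index[(meta["donor"] == d) & (meta["zone"] == za)]
                cb = meta.index[(meta["donor"] == d) & (meta["zone"] == zb)]
                if len(ca) != 1 or len(cb) != 1:
                    continue
                r = stats.pearsonr(sub[ca[0]], sub[cb[0]]).statistic
                rs.append(r)
                age_v.append(ages[d])
            if len(rs) < 3:
                continue
            trend = stats.pearsonr(age_v, rs)
            rows.append({"zone_a": za, "zone_b": zb,
                         "age_correlation": float(trend.statistic),
                         "p": float(trend.pvalue), "n_donors": len(rs)})
    return pd.DataFrame(rows)
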