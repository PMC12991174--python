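"""Mesoscale zone discovery and spatial validation.

Zones are transcriptomic clusters of a single reference cell type
(matrix MSNs) whose spatial footprints recur across donors.  The module
covers: expression clustering to an exact target cluster count (Leiden on
a shared-nearest-neighbor graph), KDE highest-density regions (HDR) and
their pairwise overlap, granularity selection by spatial
contiguity/non-overlap/representation, alignment of per-donor zone
centroids to a common dorsoventral (D-V) / caudate-putamen (C-P) frame,
and spatial transfer of zone labels to the remaining cell types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage, sparse, stats
from scipy.spatial import cKDTree

__all__ = [
    "EmbeddingSpec",
    "HDRGrid",
    "ZoneModel",
    "log_normalize",
    "embed_cells",
    "cluster_zones",
    "kde_hdr",
    "hdr_overlap",
    "hdr_mass",
    "select_granularity",
    "align_axes",
    "project_dv_cp",
    "transfer_zone_labels",
    "placement_accuracy",
]


@dataclass
class EmbeddingSpec:
    """Expression embedding used for zone clustering."""

    n_hvg: int = 2000
    n_pcs: int = 30
    n_neighbors: int = 20
    resolution_range: tuple[float, float] = (0.01, 3.0)
    batch_hook: Callable | None = None  # callable(cells, pcs) -> pcs

    def __post_init__(self) -> None:
        if self.n_pcs > self.n_hvg:
            raise ValueError("n_pcs must be <= n_hvg")


@dataclass
class HDRGrid:
    """Boolean HDR mask on a fixed evaluation grid."""

    mask: np.ndarray  # (nx, ny) bool
    xs: np.ndarray
    ys: np.ndarray
    threshold: float
    density: np.ndarray | None = None


@dataclass
class ZoneModel:
    """Zone labels with per-donor geometry."""

    labels: pd.Series
    centroids: dict[str, dict[int, tuple[float, float]]] = field(default_factory=dict)
    dv_axis: dict[str, np.ndarray] = field(default_factory=dict)
    cp_axis: dict[str, np.ndarray] = field(default_factory=dict)
    hdr_masks: dict = field(default_factory=dict)
    resolution_trace: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Expression embedding
# ---------------------------------------------------------------------------

def log_normalize(X: sparse.spmatrix, scale: float = 1e4) -> np.ndarray:
    """Library-size normalize to ``scale`` counts per cell, then log1p."""
    X = sparse.csr_matrix(X, dtype=float)
    tot = np.asarray(X.sum(axis=1)).ravel()
    tot[tot == 0] = 1.0
    Xn = X.multiply(scale / tot[:, None]).tocsr()
    Xn.data = np.log1p(Xn.data)
    return np.asarray(Xn.todense())


def _scale_per_gene_per_donor(E: np.ndarray, donors: np.ndarray,
                              clip: float = 10.0) -> np.ndarray:
    """Standardize each gene to mean 0, variance 1 within every donor."""
    out = np.empty_like(E)
    for d in np.unique(donors):
        m = donors == d
        mu = E[m].mean(axis=0)
        sd = E[m].std(axis=0)
        sd[sd == 0] = 1.0
        out[m] = np.clip((E[m] - mu) / sd, -clip, clip)
    return out


def embed_cells(X: sparse.spmatrix, cells: pd.DataFrame,
                spec: EmbeddingSpec) -> np.ndarray:
    """Log-normalize, select HVGs, per-donor scale, PCA.

    Principal-component scores are weighted by the variance explained by
    each component; an optional ``batch_hook`` may replace the embedding
    (e.g. with externally corrected components).
    """
    from sklearn.decomposition import PCA

    E = log_normalize(X)
    var = E.var(axis=0)
    hvg = np.argsort(var)[::-1][: min(spec.n_hvg, E.shape[1])]
    E = E[:, np.sort(hvg)]
    E = _scale_per_gene_per_donor(E, cells["donor"].to_numpy())
    n_pcs = min(spec.n_pcs, min(E.shape) - 1)
    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=0)
    pcs = pca.fit_transform(E)
    pcs = pcs * pca.explained_variance_ratio_[None, :]
    if spec.batch_hook is not None:
        pcs = spec.batch_hook(cells, pcs)
    return pcs


def _snn_graph(pcs: np.ndarray, k: int, prune: float = 1 / 15):
    """Shared-nearest-neighbor graph (Jaccard weights) as an igraph."""
    import igraph as ig

    n = len(pcs)
    k = min(k, n - 1)
    tree = cKDTree(pcs)
    _, idx = tree.query(pcs, k=k + 1)
    neigh = [set(row) for row in idx]  # includes self
    edges, weights = [], []
    seen = set()
    for i in range(n):
        for j in idx[i]:
            j = int(j)
            key = (min(i, j), max(i, j))
            if j == i or key in seen:
                continue
            seen.add(key)
            inter = len(neigh[i] & neigh[j])
            jac = inter / (2 * (k + 1) - inter)
            if jac >= prune:
                edges.append(key)
                weights.append(jac)
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    return g


def _leiden(graph, resolution: float, seed: int = 0) -> np.ndarray:
    import leidenalg

    part = leidenalg.find_partition(
        graph, leidenalg.RBConfigurationVertexPartition,
        weights="weight", resolution_parameter=resolution, seed=seed)
    return np.asarray(part.membership)


def cluster_zones(X: sparse.spmatrix | None, cells: pd.DataFrame,
                  spec: EmbeddingSpec | None = None, k_target: int = 6,
                  seed: int = 0, pcs: np.ndarray | None = None,
                  graph=None) -> np.ndarray:
    """Cluster one cell type's expression into exactly ``k_target`` zones.

    Leiden resolution is titrated by bisection on the same SNN graph until
    the partition has exactly ``k_target`` clusters.  Returned labels are
    1..k, renumbered dorsal to ventral by decreasing mean y coordinate.
    """
    if spec is None:
        spec = EmbeddingSpec()
    if k_target == 1:
        return np.ones(len(cells), dtype=int)
    if graph is None:
        if pcs is None:
            pcs = embed_cells(X, cells, spec)
        graph = _snn_graph(pcs, spec.n_neighbors)
    lo, hi = spec.resolution_range
    labels = None
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        lab = _leiden(graph, mid, seed=seed)
        k = lab.max() + 1
        if k == k_target:
            labels = lab
            break
        if k < k_target:
            lo = mid
        else:
            hi = mid
    if labels is None:
        raise RuntimeError(
            f"could not reach {k_target} clusters in resolution range")
    y = cells["y_um"].to_numpy(float)
    order = np.argsort([-y[labels == c].mean() for c in range(k_target)])
    remap = np.empty(k_target, dtype=int)
    remap[order] = np.arange(1, k_target + 1)
    return remap[labels]


# ---------------------------------------------------------------------------
# KDE highest-density regions
# ---------------------------------------------------------------------------

def make_grid(xy: np.ndarray, n: int = 151, pad: float = 0.0
              ) -> tuple[np.ndarray, np.ndarray]:
    xs = np.linspace(xy[:, 0].min() - pad, xy[:, 0].max() + pad, n)
    ys = np.linspace(xy[:, 1].min() - pad, xy[:, 1].max() + pad, n)
    return xs, ys


def kde_hdr(points: np.ndarray, p: float = 0.50, bandwidth_scale: float = 0.9,
            xs: np.ndarray | None = None, ys: np.ndarray | None = None,
            grid_n: int = 151) -> HDRGrid:
    """Highest-density region of a bivariate Gaussian KDE.

    Bandwidth: multivariate normal-reference matrix (data covariance,
    factor n^(-1/6)) with its Cholesky factor scaled by
    ``bandwidth_scale``.  The HDR threshold follows the
    descending-cumulative rule: grid densities are sorted in descending
    order and thresholded where the cumulative probability mass reaches
    ``p``; the mask is every grid cell at or above the threshold.
    """
    points = np.asarray(points, float)
    if len(points) < 20:
        raise ValueError("need >= 20 points for an HDR")
    factor = bandwidth_scale * len(points) ** (-1.0 / 6.0)
    kde = stats.gaussian_kde(points.T, bw_method=factor)
    if np.linalg.det(kde.covariance) <= 0:
        raise np.linalg.LinAlgError("singular bandwidth matrix")
    if xs is None or ys is None:
        bw = np.sqrt(np.diag(kde.covariance))
        pad = 3.0 * bw
        xs = np.linspace(points[:, 0].min() - pad[0],
                         points[:, 0].max() + pad[0], grid_n)
        ys = np.linspace(points[:, 1].min() - pad[1],
                         points[:, 1].max() + pad[1], grid_n)
    XX, YY = np.meshgrid(xs, ys, indexing="ij")
    dens = kde(np.vstack([XX.ravel(), YY.ravel()])).reshape(XX.shape)
    if p >= 1.0:
        mask = dens > 0
        threshold = 0.0
    else:
        order = np.argsort(dens.ravel())[::-1]
        mass = np.cumsum(dens.ravel()[order])
        mass /= mass[-1]
        cut_idx = min(int(np.searchsorted(mass, p)), len(order) - 1)
        threshold = dens.ravel()[order[cut_idx]]
        mask = dens >= threshold
    return HDRGrid(mask=mask, xs=xs, ys=ys, threshold=float(threshold),
                   density=dens)


def hdr_overlap(a: HDRGrid, b: HDRGrid) -> float:
    """Percentage of A's HDR grid cells also inside B's HDR (asymmetric)."""
    if a.mask.shape != b.mask.shape:
        raise ValueError("HDR grids must share geometry")
    na = a.mask.sum()
    if na == 0:
        raise ValueError("empty HDR mask A")
    return 100.0 * float((a.mask & b.mask).sum()) / float(na)


def hdr_mass(h: HDRGrid) -> float:
    """KDE probability mass enclosed by the mask (grid integration)."""
    return float(h.density[h.mask].sum() / h.density.sum())


# ---------------------------------------------------------------------------
# Granularity selection
# ---------------------------------------------------------------------------

def _contiguity(h: HDRGrid) -> float:
    lab, nlab = ndimage.label(h.mask)
    if nlab == 0:
        return 0.0
    sizes = ndimage.sum_labels(np.ones_like(lab, dtype=float), lab,
                               range(1, nlab + 1))
    return float(sizes.max() / h.mask.sum())


def select_granularity(X: sparse.spmatrix, cells: pd.DataFrame,
                       spec: EmbeddingSpec | None = None,
                       k_range=range(3, 10), contiguity_min: float = 0.9,
                       overlap_max: float = 25.0, represent_min: float = 0.01,
                       seed: int = 0) -> tuple[int, list[dict]]:
    """Pick the zone count: the largest k that is spatially valid.

    For each k, clusters are formed on the shared SNN graph, then per
    donor each cluster's HDR is computed.  k passes when (i) every HDR is
    contiguous (largest connected component >= ``contiguity_min`` of the
    mask), (ii) same-donor HDR pairs overlap below ``overlap_max`` %, and
    (iii) every cluster holds >= ``represent_min`` of every donor's cells.
    Returns (selected k, per-k diagnostics trace); when no k passes, the
    smallest k in the range is returned with the trace for inspection.
    """
    if spec is None:
        spec = EmbeddingSpec()
    donors = cells["donor"].unique()
    if len(donors) < 2:
        import warnings
        warnings.warn("single donor: representation criterion is trivial")
    pcs = embed_cells(X, cells, spec)
    graph = _snn_graph(pcs, spec.n_neighbors)
    trace: list[dict] = []
    passing = []
    for k in k_range:
        try:
            labels = cluster_zones(None, cells, spec, k_target=k, seed=seed,
                                   graph=graph)
        except RuntimeError:
            trace.append({"k": k, "ok": False, "reason": "unreachable"})
            continue
        ok, min_contig, max_ov, min_rep = True, 1.0, 0.0, 1.0
        for d in donors:
            dm = cells["donor"].to_numpy() == d
            frac = np.array([(labels[dm] == z).mean() for z in range(1, k + 1)])
            min_rep = min(min_rep, float(frac.min()))
            if (frac < represent_min).any():
                ok = False
            xy_d = cells.loc[dm, ["x_um", "y_um"]].to_numpy()
            xs, ys = make_grid(xy_d)
            hdrs = {}
            for z in range(1, k + 1):
                pts = xy_d[labels[dm] == z]
                if len(pts) < 20:
                    ok = False
                    continue
                hdrs[z] = kde_hdr(pts, xs=xs, ys=ys)
            for z, h in hdrs.items():
                c = _contiguity(h)
                min_contig = min(min_contig, c)
                if c < contiguity_min:
                    ok = False
            zs = sorted(hdrs)
            for i, za in enumerate(zs):
                for zb in zs[i + 1:]:
                    ov = max(hdr_overlap(hdrs[za], hdrs[zb]),
                             hdr_overlap(hdrs[zb], hdrs[za]))
                    max_ov = max(max_ov, ov)
                    if ov > overlap_max:
                        ok = False
        trace.append({"k": k, "ok": ok, "min_contiguity": min_contig,
                      "max_overlap": max_ov, "min_representation": min_rep})
        if ok:
            passing.append(k)
    if passing:
        return max(passing), trace
    return min(k_range), trace


# ---------------------------------------------------------------------------
# Axis alignment
# ---------------------------------------------------------------------------

def spatial_outliers(xy: np.ndarray, k: int = 10, n_sd: float = 3.0
                     ) -> np.ndarray:
    """Cells whose median distance to k spatial NN exceeds mean + 3 SD."""
    tree = cKDTree(xy)
    d, _ = tree.query(xy, k=min(k, len(xy) - 1) + 1)
    med = np.median(d[:, 1:], axis=1)
    return med > med.mean() + n_sd * med.std()


def align_axes(cells: pd.DataFrame, zone_col: str = "zone",
               anchor: tuple[int, int] = (1, 4), positive_zone: int = 2,
               ) -> ZoneModel:
    """Common D-V / C-P coordinate frame per donor.

    After spatial outlier removal (k=10 NN rule), zone centroids are cell
    means; the D-V axis is the unit vector from the zone-1 centroid to
    the zone-4 centroid and the C-P axis its 90° rotation, signed so zone
    2 projects positive.
    """
    model = ZoneModel(labels=cells[zone_col])
    for d, sub in cells.groupby("donor"):
        xy = sub[["x_um", "y_um"]].to_numpy(float)
        keep = ~spatial_outliers(xy)
        zs = sub[zone_col].to_numpy(int)
        cents = {}
        for z in np.unique(zs):
            m = keep & (zs == z)
            if m.sum():
                cents[int(z)] = (float(xy[m, 0].mean()),
                                 float(xy[m, 1].mean()))
        for z in (*anchor, positive_zone):
            if z not in cents:
                raise ValueError(f"donor {d}: anchor zone {z} missing")
        a = np.array(cents[anchor[0]])
        b = np.array(cents[anchor[1]])
        dv = (b - a) / np.linalg.norm(b - a)
        cp = np.array([-dv[1], dv[0]])
        mid = 0.5 * (a + b)
        if np.dot(np.array(cents[positive_zone]) - mid, cp) < 0:
            cp = -cp
        model.centroids[d] = cents
        model.dv_axis[d] = dv
        model.cp_axis[d] = cp
    return model


def project_dv_cp(cells: pd.DataFrame, model: ZoneModel) -> pd.DataFrame:
    """Per-cell D-V / C-P coordinates, origin at the donor's zone-1/zone-4
    centroid midpoint."""
    out = np.full((len(cells), 2), np.nan)
    for d, sub in cells.groupby("donor"):
        if d not in model.dv_axis:
            continue
        xy = sub[["x_um", "y_um"]].to_numpy(float)
        c = model.centroids[d]
        origin = 0.5 * (np.array(c[1]) + np.array(c[4]))
        rel = xy - origin
        i = cells.index.get_indexer(sub.index)
        out[i, 0] = rel @ model.dv_axis[d]
        out[i, 1] = rel @ model.cp_axis[d]
    return pd.DataFrame(out, columns=["dv_um", "cp_um"], index=cells.index)


# ---------------------------------------------------------------------------
# Label transfer and placement accuracy
# ---------------------------------------------------------------------------

def _majority_vote(cand_zones: np.ndarray, cand_dist: np.ndarray) -> int:
    """Majority; ties by summed inverse distance, then lowest zone index."""
    zones, counts = np.unique(cand_zones, return_counts=True)
    best = counts.max()
    tied = zones[counts == best]
    if len(tied) == 1:
        return int(tied[0])
    inv = np.array([np.sum(1.0 / np.maximum(cand_dist[cand_zones == z], 1e-9))
                    for z in tied])
    return int(tied[np.lexsort((tied, -inv))[0]])


def transfer_zone_labels(cells: pd.DataFrame, reference: pd.DataFrame,
                         zone_col: str = "zone", k_gmwm: int = 5,
                         k_zone: int = 15, max_dist: float = 750.0
                         ) -> pd.DataFrame:
    """Two-stage spatial zone transfer for all cell types, per donor.

    Stage 1: each cell is called GM or WM by majority among its k=5
    nearest neighbors that carry a GM/WM hint (MSNs count as GM; glial
    subtypes suffixed _GM / _WM count as their suffix).  Stage 2: GM
    cells take the majority zone among the k=15 nearest reference cells
    (the zone-labeled matrix MSNs) within 750 μm; GM cells with no
    reference within that distance stay unassigned (zone 0).
    """
    from .syndata import MSN_TYPES

    if len(reference) == 0:
        raise ValueError("reference must be nonempty")
    out_zone = np.zeros(len(cells), dtype=int)
    out_terr = np.empty(len(cells), dtype=object)
    for d in cells["donor"].unique():
        dm = cells["donor"].to_numpy() == d
        sub = cells[dm]
        xy = sub[["x_um", "y_um"]].to_numpy(float)
        ct = sub["cell_type"].astype(str).to_numpy().astype("U")
        hint_gm = np.isin(ct, list(MSN_TYPES)) | np.char.endswith(ct, "_GM")
        hint_wm = np.char.endswith(ct, "_WM")
        hinted = hint_gm | hint_wm
        terr = np.empty(len(sub), dtype=object)
        if hinted.sum() >= k_gmwm:
            tree = cKDTree(xy[hinted])
            _, idx = tree.query(xy, k=k_gmwm)
            idx = np.atleast_2d(idx)
            votes_gm = hint_gm[hinted][idx].sum(axis=1)
            terr[:] = np.where(votes_gm * 2 > k_gmwm, "GM", "WM")
        else:
            terr[:] = "GM"  # MSN-presence fallback
        ref = reference[reference["donor"] == d]
        rxy = ref[["x_um", "y_um"]].to_numpy(float)
        rz = ref[zone_col].to_numpy(int)
        zl = np.zeros(len(sub), dtype=int)
        if len(ref):
            k = min(k_zone, len(ref))
            tree = cKDTree(rxy)
            dist, idx = tree.query(xy, k=k)
            dist = np.atleast_2d(dist.reshape(len(sub), -1))
            idx = np.atleast_2d(idx.reshape(len(sub), -1))
            for i in np.flatnonzero(terr == "GM"):
                near = dist[i] <= max_dist
                if not near.any():
                    continue
                zl[i] = _majority_vote(rz[idx[i][near]], dist[i][near])
        out_zone[dm] = zl
        out_terr[dm] = terr
    return pd.DataFrame({"zone": out_zone, "territory_call": out_terr},
                        index=cells.index)


def placement_accuracy(cells: pd.DataFrame, territory_col: str = "territory",
                       k: int = 50, confident: int = 40,
                       astro_thresh: float = 0.8) -> dict:
    """Spatial placement accuracy from high-confidence territory votes.

    A cell sits in a high-confidence territory when more than ``confident``
    of its ``k`` spatial neighbors share one territory label; otherwise it
    is an edge cell and excluded.  MSN accuracy is the fraction of MSNs in
    high-confidence territories whose voted territory is GM.  Astrocyte
    concordance requires > 80% of neighbors to agree with the cell's own
    GM/WM subtype call.
    """
    from .syndata import MSN_TYPES

    if len(cells) < k:
        raise ValueError("need at least k cells")
    res = {"msn_total": 0, "msn_in_gm": 0, "astro_total": 0, "astro_ok": 0}
    for d in cells["donor"].unique():
        sub = cells[cells["donor"] == d]
        xy = sub[["x_um", "y_um"]].to_numpy(float)
        terr = sub[territory_col].astype(str).to_numpy()
        kk = min(k, len(sub) - 1)
        tree = cKDTree(xy)
        _, idx = tree.query(xy, k=kk + 1)
        idx = idx[:, 1:]
        neigh_terr = terr[idx]
        labs = np.unique(terr)
        counts = np.stack([(neigh_terr == t).sum(axis=1) for t in labs],
                          axis=1)
        top = counts.max(axis=1)
        top_lab = labs[counts.argmax(axis=1)]
        high_conf = top > confident * kk / k
        ct = sub["cell_type"].astype(str).to_numpy().astype("U")
        is_msn = np.isin(ct, list(MSN_TYPES)) & (ct != "STRv_NUDAP_MSN")
        m = is_msn & high_conf
        res["msn_total"] += int(m.sum())
        res["msn_in_gm"] += int((top_lab[m] == "GM").sum())
        is_astro = np.char.startswith(ct, "Astrocyte")
        own = np.where(np.char.endswith(ct, "_WM"), "WM", "GM")
        agree = (neigh_terr == own[:, None]).sum(axis=1) / kk
        a = is_astro & high_conf
        res["astro_total"] += int(a.sum())
        res["astro_ok"] += int((agree[a] > astro_thresh).sum())
    res["msn_accuracy"] = (100.0 * res["msn_in_gm"] / res["msn_total"]
                           if res["msn_total"] else np.nan)
    res["astro_concordance"] = (100.0 * res["astro_ok"] / res["astro_total"]
                                if res["astro_total"] else np.nan)
    return res
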