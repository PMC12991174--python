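"""Rank-based signature scoring and spatial ligand-receptor analysis.

Signature activity is scored per cell with a Mann-Whitney U statistic on
expression ranks (invariant to monotone transforms), neighborhoods are
fixed-radius (200 μm) spatial balls, and ligand-receptor interactions are
scored per sender cell as ligand expression times the 10%-trimmed mean of
receptor (complex) expression among receiver-type neighbors.  Zone 1 vs
zone 4 contrasts use donor-level paired t-tests with BH correction, and
significant interactions must additionally survive a per-donor sender
permutation test (99th percentile of the absolute null, sign concordant
with the cross-donor consensus) in at least 65% of donors.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .zonal_deg import bh_adjust

__all__ = [
    "LRPair",
    "load_lr_pairs",
    "signature_score",
    "neighborhood_delta",
    "complex_expression",
    "trimmed_mean",
    "detection_filter",
    "lr_score",
    "lr_zone_test",
    "lr_robustness",
]


@dataclass(frozen=True)
class LRPair:
    """A ligand paired with a (possibly multi-subunit) receptor."""

    ligand: str
    receptor_subunits: tuple[str, ...]
    pathway: str = ""
    category: str = "secreted"  # or "contact"

    def __post_init__(self) -> None:
        if len(self.receptor_subunits) < 1:
            raise ValueError("receptor needs >= 1 subunit")

    @property
    def name(self) -> str:
        return f"{self.ligand}->{'+'.join(self.receptor_subunits)}"


def load_lr_pairs(path=None) -> list[LRPair]:
    """Load LR pairs from CSV (ligand, subunits ';'-joined, pathway,
    category); defaults to the packaged curated fixture."""
    if path is None:
        src = resources.files("striazone").joinpath("data/lr_pairs.csv")
        with resources.as_file(src) as f:
            df = pd.read_csv(f)
    else:
        df = pd.read_csv(path)
    return [LRPair(r.ligand, tuple(str(r.subunits).split(";")),
                   r.pathway, r.category) for r in df.itertuples()]


# ---------------------------------------------------------------------------
# Rank-based signature scoring
# ---------------------------------------------------------------------------

def signature_score(E: np.ndarray, gene_names: list[str],
                    gene_set, max_rank: int = 1500) -> np.ndarray:
    """Per-cell rank-based signature score in [0, 1].

    Genes are ranked per cell by decreasing expression (average ties);
    ranks beyond ``max_rank`` are clamped to max_rank + 1.  The score is
    1 - U / U_max with U the Mann-Whitney statistic of the signature
    ranks, normalized so that a signature occupying the cell's top ranks
    scores exactly 1 and an entirely undetected signature scores 0.
    """
    idx = {g: i for i, g in enumerate(gene_names)}
    cols = [idx[g] for g in gene_set if g in idx]
    if not cols:
        raise ValueError("empty signature-universe intersection")
    n_sig = len(cols)
    ranks = np.apply_along_axis(stats.rankdata, 1, -E)
    ranks = np.minimum(ranks, max_rank + 1)
    u = ranks[:, cols].sum(axis=1) - n_sig * (n_sig + 1) / 2.0
    u_max = n_sig * (max_rank + 1) - n_sig * (n_sig + 1) / 2.0
    return np.clip(1.0 - u / u_max, 0.0, 1.0)


def high_low_split(scores: np.ndarray, donors: np.ndarray) -> np.ndarray:
    """Boolean high-activity flag split at each donor's median score."""
    flag = np.zeros(len(scores), bool)
    for d in np.unique(donors):
        m = donors == d
        flag[m] = scores[m] > np.median(scores[m])
    return flag


# ---------------------------------------------------------------------------
# Neighborhood expression deltas
# ---------------------------------------------------------------------------

def neighborhood_delta(cells: pd.DataFrame, E: np.ndarray,
                       gene_names: list[str], anchor_mask: np.ndarray,
                       high_flag: np.ndarray, genes: list[str],
                       neighbor_types: list[str] | None = None,
                       radius: float = 200.0) -> pd.DataFrame:
    """High-minus-low neighborhood expression deltas with one-sample t.

    For every donor, cells within ``radius`` of high- and of low-flag
    anchor cells are pooled per neighbor cell type; each gene's mean
    expression in the two pools is z-scored against the donor-level pool
    of that cell type, and the per-donor delta (high - low) is tested
    against zero with a one-sample t-test across donors.
    """
    idx = {g: i for i, g in enumerate(gene_names)}
    cols = {g: idx[g] for g in genes if g in idx}
    if neighbor_types is None:
        neighbor_types = sorted(cells["cell_type"].unique())
    deltas: dict[tuple[str, str], list[float]] = {}
    for d in cells["donor"].unique():
        dm = (cells["donor"] == d).to_numpy()
        sub_idx = np.flatnonzero(dm)
        xy = cells.loc[dm, ["x_um", "y_um"]].to_numpy(float)
        ct = cells.loc[dm, "cell_type"].to_numpy()
        anchors = np.flatnonzero(anchor_mask[dm])
        if len(anchors) == 0:
            continue
        tree = cKDTree(xy)
        neigh = tree.query_ball_point(xy[anchors], radius)
        hi_pool, lo_pool = set(), set()
        for a, nb in zip(anchors, neigh):
            nb = [i for i in nb if i != a]
            (hi_pool if high_flag[sub_idx[a]] else lo_pool).update(nb)
        for t in neighbor_types:
            tmask = ct == t
            pool_rows = sub_idx[tmask]
            if len(pool_rows) < 3:
                continue
            for g, c in cols.items():
                vals = E[pool_rows, c]
                mu, sd = vals.mean(), vals.std()
                if sd == 0:
                    sd = 1.0
                hi = [i for i in hi_pool if tmask[i]]
                lo = [i for i in lo_pool if tmask[i]]
                if not hi or not lo:
                    continue
                zhi = (E[sub_idx[hi], c].mean() - mu) / sd
                zlo = (E[sub_idx[lo], c].mean() - mu) / sd
                deltas.setdefault((t, g), []).append(zhi - zlo)
    rows = []
    for (t, g), vals in deltas.items():
        v = np.asarray(vals)
        if len(v) < 2:
            p = np.nan
        elif np.allclose(v, v[0]):
            p = 1.0 if np.allclose(v, 0) else np.nan
        else:
            p = float(stats.ttest_1samp(v, 0.0).pvalue)
        rows.append({"cell_type": t, "gene": g, "delta": float(v.mean()),
                     "p": p, "n_donors": len(v)})
    out = pd.DataFrame(rows)
    if len(out):
        out["padj"] = bh_adjust(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Ligand-receptor scoring
# ---------------------------------------------------------------------------

def complex_expression(E: np.ndarray, gene_names: list[str],
                       subunits: tuple[str, ...]) -> np.ndarray:
    """Geometric mean of subunit expression; zero if any subunit is zero.

    A single-subunit complex equals that subunit's expression.
    """
    idx = {g: i for i, g in enumerate(gene_names)}
    cols = [idx[s] for s in subunits if s in idx]
    if len(cols) < len(subunits):
        return np.zeros(E.shape[0])
    sub = E[:, cols]
    anyzero = (sub <= 0).any(axis=1)
    with np.errstate(divide="ignore"):
        gm = np.exp(np.where(anyzero, -np.inf,
                             np.log(np.maximum(sub, 1e-300)).mean(axis=1)))
    gm[anyzero] = 0.0
    return gm


def trimmed_mean(values: np.ndarray, trim: float = 0.1) -> float:
    """Symmetric trimmed mean: drop floor(trim*n) values from each tail."""
    v = np.sort(np.asarray(values, float))
    k = int(np.floor(trim * len(v)))
    v = v[k: len(v) - k] if k else v
    return float(v.mean()) if len(v) else np.nan


def detection_filter(X, cells: pd.DataFrame, gene_names: list[str],
                     genes, zone_col: str = "zone",
                     min_rate: float = 0.05) -> set[str]:
    """Genes detected in >= 5% of cells in at least one cell-type x zone
    combination in every donor (per-donor filter; a gene failing in every
    combination within a donor is dropped for that donor's analysis —
    here summarized cohort-wide as: pass in all donors)."""
    from scipy import sparse

    X = sparse.csr_matrix(X)
    idx = {g: i for i, g in enumerate(gene_names)}
    cols = {g: idx[g] for g in genes if g in idx}
    passing = set(cols)
    for d in cells["donor"].unique():
        dm = cells["donor"].to_numpy() == d
        ok_d = set()
        for (t, z), grp in cells[dm].groupby(["cell_type", zone_col]):
            if z == 0 or len(grp) < 5:
                continue
            rows = cells.index.get_indexer(grp.index)
            det = np.asarray((X[rows] > 0).mean(axis=0)).ravel()
            for g, c in cols.items():
                if det[c] >= min_rate:
                    ok_d.add(g)
        passing &= ok_d
    return passing


def lr_score(cells: pd.DataFrame, E: np.ndarray, gene_names: list[str],
             pair: LRPair, sender_type: str, receiver_type: str,
             contrast_zones=(1, 4), radius: float = 200.0,
             trim: float = 0.1, zone_col: str = "zone") -> pd.DataFrame:
    """Per-sender-cell interaction scores for one LR pair.

    Sender cells are restricted to the contrast zones; receivers of the
    specified type contribute from all zones.  Score = sender ligand
    expression x 10%-trimmed mean of receiver complex expression within
    the spatial radius; senders with no receiver in range are excluded.
    Returns donor, zone, score per scored sender cell.
    """
    idx = {g: i for i, g in enumerate(gene_names)}
    if pair.ligand not in idx:
        raise ValueError(f"unknown ligand {pair.ligand!r}")
    lig_col = idx[pair.ligand]
    rows = []
    for d in cells["donor"].unique():
        dm = (cells["donor"] == d).to_numpy()
        sub_idx = np.flatnonzero(dm)
        sub = cells.loc[dm]
        xy = sub[["x_um", "y_um"]].to_numpy(float)
        ct = sub["cell_type"].to_numpy()
        zones = sub[zone_col].to_numpy()
        recv_local = np.flatnonzero(ct == receiver_type)
        if len(recv_local) == 0:
            continue
        recv_expr = complex_expression(E[sub_idx[recv_local]], gene_names,
                                       pair.receptor_subunits)
        send_local = np.flatnonzero((ct == sender_type)
                                    & np.isin(zones, contrast_zones))
        if len(send_local) == 0:
            continue
        tree = cKDTree(xy[recv_local])
        neigh = tree.query_ball_point(xy[send_local], radius)
        for s, nb in zip(send_local, neigh):
            if not nb:
                continue
            tm = trimmed_mean(recv_expr[nb], trim)
            rows.append({"donor": d, "zone": int(zones[s]),
                         "score": float(E[sub_idx[s], lig_col] * tm)})
    return pd.DataFrame(rows)


def lr_zone_test(cells: pd.DataFrame, E: np.ndarray, gene_names: list[str],
                 pairs: list[LRPair], sender_types: list[str],
                 receiver_types: list[str], zones=(1, 4),
                 radius: float = 200.0, zone_col: str = "zone"
                 ) -> pd.DataFrame:
    """Zone contrast of interaction scores for all (sender, receiver, pair)
    triples.

    Scores are averaged over sender cells per zone per donor; the
    donor-level delta (zone 1 minus zone 4) is tested with a paired t
    across donors and BH-corrected across all tested triples.
    """
    if cells["donor"].nunique() < 2:
        raise ValueError("need >= 2 donors")
    rows = []
    for pair in pairs:
        for st in sender_types:
            for rt in receiver_types:
                try:
                    sc = lr_score(cells, E, gene_names, pair, st, rt,
                                  contrast_zones=zones, radius=radius,
                                  zone_col=zone_col)
                except ValueError:
                    continue
                if len(sc) == 0:
                    continue
                per = sc.groupby(["donor", "zone"])["score"].mean().unstack()
                if not all(z in per.columns for z in zones):
                    continue
                per = per.dropna(subset=list(zones))
                if len(per) < 2:
                    continue
                delta = per[zones[0]] - per[zones[1]]
                if np.allclose(delta, 0):
                    p = 1.0
                else:
                    p = float(stats.ttest_rel(per[zones[0]],
                                              per[zones[1]]).pvalue)
                rows.append({"pair": pair.name, "sender": st, "receiver": rt,
                             "pathway": pair.pathway,
                             "delta": float(delta.mean()), "t_p": p,
                             "n_donors": len(per),
                             "deltas": tuple(delta.to_numpy())})
    out = pd.DataFrame(rows)
    if len(out):
        out["padj"] = bh_adjust(out["t_p"].to_numpy())
    return out


def lr_robustness(cells: pd.DataFrame, E: np.ndarray, gene_names: list[str],
                  significant: pd.DataFrame, pairs_by_name: dict[str, LRPair],
                  zones=(1, 4), radius: float = 200.0, n_perm: int = 1000,
                  percentile: float = 99.0, donor_fraction: float = 0.65,
                  zone_col: str = "zone", seed: int = 0) -> pd.DataFrame:
    """Per-donor sender-permutation robustness of significant interactions.

    For each donor: sender zone labels (zone 1 vs zone 4) are shuffled
    among the sender cells ``n_perm`` times and the zone delta recomputed,
    giving a donor null.  The donor is robust iff the observed |delta|
    exceeds the 99th percentile of the absolute null AND the delta's sign
    matches the cross-donor consensus.  An interaction is retained iff
    the robust fraction reaches ``donor_fraction`` (>= 12 of 18 donors at
    defaults).  Adds per-row robustness columns to the table.
    """
    rng = np.random.default_rng(seed)
    out = significant.copy()
    out["robust_donors"] = 0
    out["tested_donors"] = 0
    out["robust_fraction"] = 0.0
    out["retained"] = False
    out["exceed_count"] = 0  # donors beating the percentile, sign ignored
    for ridx, row in significant.iterrows():
        pair = pairs_by_name[row["pair"]]
        sc = lr_score(cells, E, gene_names, pair, row["sender"],
                      row["receiver"], contrast_zones=zones, radius=radius,
                      zone_col=zone_col)
        consensus = np.sign(row["delta"])
        robust = tested = exceed = 0
        for d, sub in sc.groupby("donor"):
            z = sub["zone"].to_numpy()
            s = sub["score"].to_numpy()
            if not ((z == zones[0]).any() and (z == zones[1]).any()):
                continue
            tested += 1
            obs = s[z == zones[0]].mean() - s[z == zones[1]].mean()
            null = np.empty(n_perm)
            for b in range(n_perm):
                zp = rng.permutation(z)
                null[b] = s[zp == zones[0]].mean() - s[zp == zones[1]].mean()
            thresh = np.percentile(np.abs(null), percentile)
            if abs(obs) > thresh:
                exceed += 1
                if np.sign(obs) == consensus:
                    robust += 1
        out.loc[ridx, ["robust_donors", "tested_donors", "exceed_count"]] = \
            robust, tested, exceed
        frac = robust / tested if tested else 0.0
        out.loc[ridx, "robust_fraction"] = frac
        out.loc[ridx, "retained"] = bool(tested and frac >= donor_fraction)
    return out
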