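"""Preranked gene-set enrichment and leading-edge redundancy consolidation.

Enrichment uses the weighted Kolmogorov-Smirnov running-sum statistic on a
ranked gene list (weight = |ranking statistic|), with gene-permutation
null distributions and BH adjustment.  Redundancy among significant sets
is reduced two ways: a leading-edge overlap network in which hubs are
removed and one winner is kept per connected component, and a greedy
Jaccard prune for ranked term lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .zonal_deg import bh_adjust

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "enrichment_score",
    "preranked_gsea",
    "consolidate_le_network",
    "jaccard_prune",
]


@dataclass
class GeneSetCollection:
    """Named gene sets with size filtering against a gene universe."""

    sets: dict[str, set[str]]
    min_size: int = 5
    max_size: int = 500

    def restrict(self, universe) -> "GeneSetCollection":
        uni = set(universe)
        kept = {}
        for name, members in self.sets.items():
            inter = members & uni
            if self.min_size <= len(inter) <= self.max_size:
                kept[name] = inter
        return GeneSetCollection(kept, self.min_size, self.max_size)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (name <tab> description <tab> genes...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return GeneSetCollection(sets)


# ---------------------------------------------------------------------------
# Weighted KS enrichment
# ---------------------------------------------------------------------------

def enrichment_score(ranked_genes: np.ndarray, stats_sorted: np.ndarray,
                     member_mask: np.ndarray) -> tuple[float, int]:
    """Running-sum enrichment score and the index of its extremum.

    Genes are assumed sorted by decreasing statistic.  Hits advance the
    running sum proportionally to |statistic|, misses retreat by
    1/(N - n_hits); the score is the running-sum value of largest
    magnitude.
    """
    n = len(ranked_genes)
    nh = int(member_mask.sum())
    if nh == 0 or nh == n:
        return 0.0, 0
    w = np.abs(stats_sorted) * member_mask
    tot = w.sum()
    if tot == 0:
        w = member_mask.astype(float)
        tot = w.sum()
    step = w / tot - (~member_mask) / (n - nh)
    run = np.cumsum(step)
    i = int(np.argmax(np.abs(run)))
    return float(run[i]), i


def preranked_gsea(ranks: pd.Series, collection: GeneSetCollection,
                   n_perm: int = 500, seed: int = 0) -> pd.DataFrame:
    """Preranked GSEA over a gene -> statistic mapping.

    Permutation p-values come from shuffling gene labels (``n_perm``
    draws shared across sets of equal size); NES is the score divided by
    the mean magnitude of same-signed permutation scores.  The leading
    edge is the member genes up to (for positive scores) or after (for
    negative) the running-sum extremum.
    """
    if ranks.index.duplicated().any():
        raise ValueError("duplicate gene names in ranks")
    vals = ranks.to_numpy(float)
    if not np.isfinite(vals).all():
        raise ValueError("ranks must be finite")
    order = np.argsort(vals)[::-1]
    genes = ranks.index.to_numpy()[order]
    svals = vals[order]
    coll = collection.restrict(genes)
    rng = np.random.default_rng(seed)
    gene_pos = {g: i for i, g in enumerate(genes)}
    n = len(genes)

    # shared permutation scores per set size
    perm_cache: dict[int, np.ndarray] = {}

    def perm_scores(size: int) -> np.ndarray:
        if size not in perm_cache:
            out = np.empty(n_perm)
            for b in range(n_perm):
                idx = rng.choice(n, size=size, replace=False)
                mask = np.zeros(n, bool)
                mask[idx] = True
                out[b], _ = enrichment_score(genes, svals, mask)
            perm_cache[size] = out
        return perm_cache[size]

    rows = []
    for name, members in coll.sets.items():
        mask = np.zeros(n, bool)
        mask[[gene_pos[g] for g in members]] = True
        es, ext = enrichment_score(genes, svals, mask)
        null = perm_scores(int(mask.sum()))
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if len(same) == 0:
            nes, p = 0.0, 1.0
        else:
            nes = es / np.abs(same).mean()
            p = (1 + np.sum(np.abs(same) >= abs(es))) / (1 + len(same))
        if es >= 0:
            le = [g for g in genes[: ext + 1] if g in members]
        else:
            le = [g for g in genes[ext:] if g in members]
        rows.append({"set": name, "es": es, "nes": float(nes),
                     "p": float(p), "size": int(mask.sum()),
                     "leading_edge": tuple(le)})
    if not rows:
        return pd.DataFrame(columns=["es", "nes", "p", "size",
                                     "leading_edge", "padj"])
    out = pd.DataFrame(rows).set_index("set")
    out["padj"] = bh_adjust(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Leading-edge redundancy consolidation
# ---------------------------------------------------------------------------

def consolidate_le_network(results: pd.DataFrame,
                           overlap_threshold: float = 0.21,
                           hub_degree: int = 12, nes_min: float = 1.0,
                           fdr_max: float = 0.05) -> pd.DataFrame:
    """Leading-edge overlap-network pruning of redundant gene sets.

    Significant sets (|NES| >= 1, FDR < 0.05) are processed separately by
    NES sign.  Edges join sets whose leading-edge overlap fraction
    |LE_i ∩ LE_j| / min(|LE_i|, |LE_j|) strictly exceeds the threshold.
    While any node's degree exceeds ``hub_degree`` the current
    highest-degree node (ties by name) is removed; then one winner per
    connected component is kept, chosen by highest degree, lowest
    adjusted p, then highest |NES|.  Returns the results table with
    ``status`` in {kept, pruned, hub, not-significant} and the
    representative set each pruned term grouped with.
    """
    out = results.copy()
    out["status"] = "not-significant"
    out["representative"] = ""
    sig = out[(out["nes"].abs() >= nes_min) & (out["padj"] < fdr_max)]
    for sign in (1, -1):
        names = [s for s in sig.index if np.sign(sig.loc[s, "nes"]) == sign]
        if not names:
            continue
        le = {s: set(out.loc[s, "leading_edge"]) for s in names}
        G = nx.Graph()
        G.add_nodes_from(names)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                denom = min(len(le[a]), len(le[b]))
                if denom == 0:
                    continue
                frac = len(le[a] & le[b]) / denom
                if frac > overlap_threshold:
                    G.add_edge(a, b)
        hubs = []
        while True:
            degs = dict(G.degree())
            over = {v: d for v, d in degs.items() if d > hub_degree}
            if not over:
                break
            worst = sorted(over, key=lambda v: (-over[v], v))[0]
            G.remove_node(worst)
            hubs.append(worst)
        out.loc[hubs, "status"] = "hub"
        for comp in nx.connected_components(G):
            comp = sorted(comp)
            winner = sorted(
                comp, key=lambda s: (-G.degree(s), out.loc[s, "padj"],
                                     -abs(out.loc[s, "nes"]), s))[0]
            out.loc[winner, "status"] = "kept"
            losers = [s for s in comp if s != winner]
            out.loc[losers, "status"] = "pruned"
            out.loc[losers, "representative"] = winner
    return out


def jaccard_prune(results: pd.DataFrame, threshold: float = 0.7
                  ) -> pd.DataFrame:
    """Greedy leading-edge Jaccard filter on a padj-ordered term list.

    Terms are scanned in ascending adjusted-p order; a term is dropped
    when its leading edge has Jaccard similarity > ``threshold`` with any
    already-kept term's leading edge.
    """
    order = results.sort_values("padj").index
    kept: list[str] = []
    kept_le: list[set] = []
    status = pd.Series("kept", index=results.index)
    for s in order:
        le = set(results.loc[s, "leading_edge"])
        drop = False
        for other in kept_le:
            union = len(le | other)
            if union and len(le & other) / union > threshold:
                drop = True
                break
        if drop:
            status.loc[s] = "pruned"
        else:
            kept.append(s)
            kept_le.append(le)
    out = results.copy()
    out["jaccard_status"] = status
    return out
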