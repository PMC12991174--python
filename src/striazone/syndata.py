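"""Synthetic zonated striatal tissue generator.

Produces multi-donor 2D point patterns plus negative-binomial count
matrices that emulate the structure of spatially resolved striatal
single-nucleus data: dorsoventrally ordered mesoscale zones with discrete
and gradient marker genes, tightly clustered micro-compartments
(striosome-like patches) embedded in a diffuse matrix, a white-matter band
dominated by oligodendrocyte-lineage cells, compartment-biased interneuron
composition, donor batch effects, zone-structured ligand/receptor
programs, and an age-dependent compression of zonal expression contrasts.

Every generated object carries its ground truth (``truth_zone``,
``truth_compartment``, planted effects) so downstream recovery can be
asserted exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "TissueSpec",
    "CompartmentSpec",
    "MarkerSpec",
    "LRProgram",
    "ExpressionSpec",
    "AgingSpec",
    "generate_positions",
    "generate_counts",
    "generate_lr_truth",
    "generate_aging_cohort",
    "default_tissue",
    "default_compartments",
    "default_expression",
]


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------

@dataclass
class TissueSpec:
    """Geometry and sampling plan for one synthetic cohort.

    The domain is a ``width_um`` x ``height_um`` rectangle with a vertical
    white-matter band (fraction ``wm_fraction`` of the width) separating two
    gray-matter lobes, a caudate-like lobe on the left and a putamen-like
    lobe on the right.  Zones are isotropic Gaussian density fields whose
    centroids are ordered dorsal (high y) to ventral (low y); one zone sits
    off-axis in the right lobe, emulating the caudate/putamen split.
    """

    n_donors: int = 3
    n_cells_per_donor: int = 5000
    width_um: float = 7000.0
    height_um: float = 10000.0
    zone_count: int = 6
    off_axis_zone: int = 2
    zone_sigma_um: float = 950.0
    wm_fraction: float = 0.12
    donor_jitter_um: float = 150.0
    donor_rotation_deg: float = 3.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.width_um <= 0 or self.height_um <= 0:
            raise ValueError("empty domain")
        if self.zone_count < 1:
            raise ValueError("zone_count must be >= 1")
        if not 0.0 <= self.wm_fraction < 1.0:
            raise ValueError("wm_fraction must lie in [0, 1)")

    # -- geometry helpers ---------------------------------------------------

    def wm_band(self) -> tuple[float, float]:
        """x-interval occupied by the white-matter band."""
        half = 0.5 * self.wm_fraction * self.width_um
        mid = 0.55 * self.width_um
        return mid - half, mid + half

    def zone_centroids(self) -> np.ndarray:
        """(zone_count, 2) centroids, zone order dorsal -> ventral."""
        lo, hi = self.wm_band()
        x_left = 0.5 * lo
        x_right = 0.5 * (hi + self.width_um)
        ys = np.linspace(0.92, 0.08, self.zone_count) * self.height_um
        cents = np.column_stack([np.full(self.zone_count, x_left), ys])
        k = self.off_axis_zone - 1
        if 0 <= k < self.zone_count:
            cents[k, 0] = x_right
        return cents


@dataclass
class CompartmentSpec:
    """A Thomas cluster process for one compartmental cell type."""

    type_name: str
    parent_radius_um: float = 300.0
    points_per_cluster: float = 25.0
    cluster_intensity: float = 0.35  # parents per mm^2 of gray matter

    def __post_init__(self) -> None:
        if self.parent_radius_um <= 0:
            raise ValueError("parent_radius_um must be > 0")
        if self.cluster_intensity < 0:
            raise ValueError("negative intensities not allowed")


@dataclass
class MarkerSpec:
    """A planted zonal marker: elevated in ``block`` zones.

    ``mode`` 'discrete' applies a constant log2 effect inside the block;
    'gradient' scales the effect linearly with the dorsal-ventral position
    within the block's span (0 at the dorsal edge, full effect ventrally).
    """

    gene: str
    block: tuple[int, ...]
    mode: str = "discrete"
    log2_effect: float = 2.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.log2_effect):
            raise ValueError("effects must be finite")
        if self.mode not in ("discrete", "gradient"):
            raise ValueError(f"unknown marker mode {self.mode!r}")


@dataclass
class LRProgram:
    """A planted ligand-receptor program.

    Ligand expression is raised in ``sender_type`` cells inside
    ``enriched_zone``; every receptor subunit is raised in
    ``receiver_type`` cells in all zones.
    """

    ligand: str
    receptor_subunits: tuple[str, ...]
    sender_type: str
    receiver_type: str
    enriched_zone: int
    log2_boost: float = 2.0

    def __post_init__(self) -> None:
        if len(self.receptor_subunits) < 1:
            raise ValueError("every LR complex needs >= 1 subunit")


@dataclass
class ExpressionSpec:
    """Count-model parameters for the synthetic transcriptome."""

    n_genes: int = 1000
    markers: tuple[MarkerSpec, ...] = ()
    nb_dispersion: float = 0.15
    donor_shift_sd: float = 0.10
    depth_mean: float = 3000.0
    depth_sigma: float = 0.35  # log-normal sigma of library sizes
    marker_base_count: float = 0.08  # expected off-block counts per cell
    background_zone_sd: float = 0.15  # log2 SD of pervasive weak zonation
    lr_programs: tuple[LRProgram, ...] = ()
    baseline_seed: int = 7

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("non-positive dispersion")
        for m in self.markers:
            if any(z < 1 for z in m.block):
                raise ValueError("zone blocks must be subsets of {1..zone_count}")

    def gene_names(self) -> list[str]:
        names = [f"G{i:04d}" for i in range(self.n_genes)]
        for j, m in enumerate(self.markers):
            names[j] = m.gene
        return names


@dataclass
class AgingSpec:
    """Aging-cohort parameters.

    ``erosion_rate`` is the per-decade fractional convergence of every
    zonal marker's log effect toward the cross-zone grand mean; 0.2 means a
    donor one decade older than the youngest retains 80% of the planted
    zonal contrast.  ``aging_up``/``aging_down`` genes shift monotonically
    with age at ``lfc_per_decade`` scaled by a per-zone vulnerability
    multiplier.
    """

    donor_ages: tuple[float, ...] = (25, 35, 45, 55, 65, 75)
    erosion_rate: float = 0.2
    aging_up: tuple[str, ...] = ()
    aging_down: tuple[str, ...] = ()
    lfc_per_decade: float = 0.15
    zone_vulnerability: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.donor_ages) < 2:
            raise ValueError("need at least 2 donors")
        if not 0.0 <= self.erosion_rate <= 1.0:
            raise ValueError("erosion_rate must lie in [0, 1] per decade")
        if any(v < 0 for v in self.zone_vulnerability.values()):
            raise ValueError("vulnerability multipliers must be >= 0")


# ---------------------------------------------------------------------------
# Default cohort composition
# ---------------------------------------------------------------------------

#: fraction of gray-matter cells per diffuse type (rest go to compartments)
_DIFFUSE_GM = {
    "D1_Matrix_MSN": 0.30,
    "D2_Matrix_MSN": 0.24,
    "Astrocyte": 0.16,
    "OPC": 0.05,
    "Microglia": 0.05,
    "Vascular": 0.04,
    "TAC3_Interneuron": 0.02,
    "VIP_Interneuron": 0.02,
    "Oligodendrocyte_GM": 0.12,
}

#: white-matter band composition
_WM_TYPES = {
    "Oligodendrocyte_WM": 0.78,
    "Astrocyte_WM": 0.12,
    "OPC": 0.05,
    "Microglia": 0.05,
}

#: fraction of all cells placed in the WM band (beyond wm area share)
_WM_CELL_FRACTION = 0.12

#: interneuron striosome bias: fraction of the type's cells drawn from the
#: striosome cluster process instead of the diffuse field
_STRIOSOME_BIAS = {"TAC3_Interneuron": 0.55}

MSN_TYPES = (
    "D1_Matrix_MSN",
    "D2_Matrix_MSN",
    "D1_Striosome_MSN",
    "STRv_NUDAP_MSN",
    "D1_KCNJ6_MSN",
)


def default_tissue(**kw) -> TissueSpec:
    return TissueSpec(**kw)


def default_compartments() -> list[CompartmentSpec]:
    """Striosome-, NUDAP- and KCNJ6-like cluster processes."""
    return [
        CompartmentSpec("D1_Striosome_MSN", parent_radius_um=380.0,
                        points_per_cluster=20.0, cluster_intensity=0.45),
        CompartmentSpec("STRv_NUDAP_MSN", parent_radius_um=300.0,
                        points_per_cluster=14.0, cluster_intensity=0.30),
        CompartmentSpec("D1_KCNJ6_MSN", parent_radius_um=250.0,
                        points_per_cluster=12.0, cluster_intensity=0.30),
    ]


def default_expression(n_genes: int = 1000, zone_count: int = 6,
                       n_markers_per_zone: int = 8,
                       n_gradient: int = 12,
                       log2_effect: float = 2.0,
                       gradient_effect: float = 4.0) -> ExpressionSpec:
    """Zone-specific discrete markers plus multi-zone gradient genes."""
    markers: list[MarkerSpec] = []
    g = 0
    for z in range(1, zone_count + 1):
        for _ in range(n_markers_per_zone):
            markers.append(MarkerSpec(f"Z{z}M{g:03d}", (z,), "discrete",
                                      log2_effect))
            g += 1
    # gradient markers span two adjacent zones: with a longer ramp the
    # dorsal-most member zone cannot individually beat the pooled rest,
    # which is what the zone-vs-rest significance filter requires of every
    # block member
    blocks = [(s, s + 1) for s in range(1, zone_count)]
    for i in range(n_gradient):
        blk = blocks[i % len(blocks)]
        markers.append(MarkerSpec(f"GRAD{g:03d}", blk, "gradient",
                                  gradient_effect))
        g += 1
    return ExpressionSpec(n_genes=n_genes, markers=tuple(markers))


# ---------------------------------------------------------------------------
# Position generation
# ---------------------------------------------------------------------------

def _in_gm(spec: TissueSpec, xy: np.ndarray) -> np.ndarray:
    lo, hi = spec.wm_band()
    inside = ((xy[:, 0] >= 0) & (xy[:, 0] <= spec.width_um)
              & (xy[:, 1] >= 0) & (xy[:, 1] <= spec.height_um))
    return inside & ((xy[:, 0] < lo) | (xy[:, 0] > hi))


def _sample_zone_positions(spec: TissueSpec, zones: np.ndarray,
                           rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample positions from each cell's zone Gaussian, truncated
    to the gray matter."""
    cents = spec.zone_centroids()
    xy = np.empty((len(zones), 2))
    pending = np.arange(len(zones))
    while len(pending):
        prop = cents[zones[pending] - 1] + rng.normal(
            scale=spec.zone_sigma_um, size=(len(pending), 2))
        ok = _in_gm(spec, prop)
        xy[pending[ok]] = prop[ok]
        pending = pending[~ok]
    return xy


def _truth_zone_of(spec: TissueSpec, xy: np.ndarray) -> np.ndarray:
    """Zone whose Gaussian field has the highest density at each point."""
    cents = spec.zone_centroids()
    d2 = ((xy[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1) + 1


def _thomas_points(spec: TissueSpec, comp: CompartmentSpec,
                   rng: np.random.Generator, avoid_xy=None, avoid_r=None,
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Thomas process in the GM: Poisson parents, Gaussian offspring.

    Parents landing within ``avoid_r`` of existing parents of other
    compartment classes are rejected (distinct compartment systems occupy
    distinct patches of tissue).  Returns (points, parent_idx, parents).
    """
    gm_area_mm2 = spec.width_um * spec.height_um * (1 - spec.wm_fraction) / 1e6
    n_parents = max(1, rng.poisson(comp.cluster_intensity * gm_area_mm2))
    parents = np.empty((n_parents, 2))
    got = 0
    tries = 0
    while got < n_parents and tries < 200:
        tries += 1
        prop = rng.uniform([0, 0], [spec.width_um, spec.height_um],
                           size=(n_parents - got, 2))
        ok = _in_gm(spec, prop)
        if avoid_xy is not None and len(avoid_xy):
            d = np.hypot(prop[:, 0, None] - avoid_xy[None, :, 0],
                         prop[:, 1, None] - avoid_xy[None, :, 1])
            ok &= (d > avoid_r[None, :]).all(axis=1)
        take = prop[ok]
        parents[got:got + len(take)] = take
        got += len(take)
    parents = parents[:got] if got else parents[:1]
    n_parents = len(parents)
    counts = rng.poisson(comp.points_per_cluster, size=n_parents)
    parent_idx = np.repeat(np.arange(n_parents), counts)
    # sigma = R/sqrt(6) puts 95% of offspring within the parent radius,
    # so the radius parameter is the 95% containment radius of a patch
    pts = parents[parent_idx] + rng.normal(
        scale=comp.parent_radius_um / np.sqrt(6.0),
        size=(len(parent_idx), 2))
    inside = ((pts[:, 0] >= 0) & (pts[:, 0] <= spec.width_um)
              & (pts[:, 1] >= 0) & (pts[:, 1] <= spec.height_um))
    return pts[inside], parent_idx[inside], parents


def _donor_affine(spec: TissueSpec, rng: np.random.Generator
                  ) -> tuple[np.ndarray, np.ndarray]:
    th = np.deg2rad(rng.uniform(-spec.donor_rotation_deg,
                                spec.donor_rotation_deg))
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    t = rng.uniform(-spec.donor_jitter_um, spec.donor_jitter_um, size=2)
    return R, t


def generate_positions(spec: TissueSpec,
                       compartments: Sequence[CompartmentSpec] = (),
                       ) -> pd.DataFrame:
    """Generate the multi-donor spatial cell table.

    Returns a DataFrame with columns cell_id, x_um, y_um, donor, cell_type,
    truth_zone, truth_compartment, truth_parent (cluster parent index for
    compartmental cells, -1 otherwise) and territory ('GM'/'WM').  Zone
    layout is identical across donors up to a small per-donor affine jitter.
    """
    rng = np.random.default_rng(spec.rng_seed)
    # compartment intensities are calibrated for 5000 cells/donor; scale
    # with the cell budget so composition stays stable across cohort sizes
    comp_scale = spec.n_cells_per_donor / 5000.0
    compartments = [CompartmentSpec(c.type_name, c.parent_radius_um,
                                    c.points_per_cluster,
                                    c.cluster_intensity * comp_scale)
                    for c in compartments]
    comp_by_name = {c.type_name: c for c in compartments}
    frames = []
    for d in range(spec.n_donors):
        donor = f"donor{d:02d}"
        R, t = _donor_affine(spec, rng)
        n = spec.n_cells_per_donor
        n_wm = int(round(_WM_CELL_FRACTION * n)) if spec.wm_fraction > 0 else 0

        # compartmental cells via Thomas processes
        comp_rows = []
        placed_xy: list[np.ndarray] = []
        placed_r: list[float] = []
        for comp in compartments:
            if placed_xy:
                axy = np.vstack(placed_xy)
                ar = 0.6 * (np.array(placed_r) + comp.parent_radius_um)
            else:
                axy, ar = None, None
            pts, pidx, parents = _thomas_points(spec, comp, rng, axy, ar)
            placed_xy.extend(list(parents))
            placed_r.extend([comp.parent_radius_um] * len(parents))
            comp_rows.append(pd.DataFrame({
                "x_um": pts[:, 0], "y_um": pts[:, 1],
                "cell_type": comp.type_name,
                "truth_compartment": comp.type_name,
                "truth_parent": pidx,
                "_parent_x": parents[pidx, 0], "_parent_y": parents[pidx, 1],
            }))
        comp_df = (pd.concat(comp_rows, ignore_index=True)
                   if comp_rows else pd.DataFrame())
        n_comp = len(comp_df)

        # diffuse gray-matter cells
        n_gm = max(0, n - n_wm - n_comp)
        gm_types = list(_DIFFUSE_GM)
        gm_p = np.array(list(_DIFFUSE_GM.values()))
        gm_p = gm_p / gm_p.sum()
        types = rng.choice(gm_types, size=n_gm, p=gm_p)
        comp_field = rng.integers(1, spec.zone_count + 1, size=n_gm)
        xy = _sample_zone_positions(spec, comp_field, rng)
        # matrix MSNs are excluded from compartment patches: striosome-like
        # compartments are dense patches that displace the surrounding
        # matrix, so diffuse MSNs inside a patch core are resampled
        if n_comp:
            is_matrix_msn = np.isin(types,
                                    ["D1_Matrix_MSN", "D2_Matrix_MSN"])
            patch_xy = comp_df[["_parent_x", "_parent_y"]].to_numpy()
            patch_r = np.array([comp_by_name[t].parent_radius_um
                                for t in comp_df["cell_type"]])
            from scipy.spatial import cKDTree
            ptree = cKDTree(patch_xy)
            for _ in range(25):
                near = ptree.query_ball_point(xy, patch_r.max())
                inside = np.array(
                    [any(np.hypot(*(xy[i] - patch_xy[j])) < patch_r[j]
                         for j in nb) for i, nb in enumerate(near)])
                redo = inside & is_matrix_msn
                if not redo.any():
                    break
                xy[redo] = _sample_zone_positions(spec, comp_field[redo], rng)
        # ground-truth zone is the dominant density field at the cell's
        # position (a spatial territory), not the mixture component that
        # generated it: zones are regions of tissue, and adjacent fields
        # overlap
        zones = _truth_zone_of(spec, xy)
        gm_df = pd.DataFrame({
            "x_um": xy[:, 0], "y_um": xy[:, 1], "cell_type": types,
            "truth_zone": zones, "truth_compartment": "Matrix-truth",
            "truth_parent": -1,
        })

        # striosome-biased interneurons: relocate a fraction into clusters
        strio = comp_by_name.get("D1_Striosome_MSN")
        if strio is not None and n_comp:
            par_xy = comp_df.loc[comp_df.cell_type == "D1_Striosome_MSN",
                                 ["_parent_x", "_parent_y"]].drop_duplicates().to_numpy()
            for tname, bias in _STRIOSOME_BIAS.items():
                idx = gm_df.index[gm_df.cell_type == tname]
                move = idx[rng.random(len(idx)) < bias]
                if len(move) and len(par_xy):
                    par = par_xy[rng.integers(0, len(par_xy), len(move))]
                    off = rng.normal(scale=strio.parent_radius_um / np.sqrt(6.0),
                                     size=(len(move), 2))
                    moved = par + off
                    moved[:, 0] = np.clip(moved[:, 0], 0.0, spec.width_um)
                    moved[:, 1] = np.clip(moved[:, 1], 0.0, spec.height_um)
                    gm_df.loc[move, ["x_um", "y_um"]] = moved
                    gm_df.loc[move, "truth_compartment"] = "D1_Striosome_MSN"

        # white-matter band cells
        lo, hi = spec.wm_band()
        if n_wm:
            wm_types = list(_WM_TYPES)
            wm_p = np.array(list(_WM_TYPES.values()))
            wm_xy = rng.uniform([lo, 0], [hi, spec.height_um], size=(n_wm, 2))
            wm_df = pd.DataFrame({
                "x_um": wm_xy[:, 0], "y_um": wm_xy[:, 1],
                "cell_type": rng.choice(wm_types, size=n_wm,
                                        p=wm_p / wm_p.sum()),
                "truth_zone": 0, "truth_compartment": "WM",
                "truth_parent": -1,
            })
        else:
            wm_df = pd.DataFrame()

        df = pd.concat([gm_df, comp_df, wm_df], ignore_index=True)
        if "truth_zone" not in df or df["truth_zone"].isna().any():
            miss = df["truth_zone"].isna() if "truth_zone" in df else None
            xy_all = df[["x_um", "y_um"]].to_numpy()
            tz = _truth_zone_of(spec, xy_all)
            if miss is None:
                df["truth_zone"] = tz
            else:
                df.loc[miss, "truth_zone"] = tz[miss.to_numpy()]
        df["truth_zone"] = df["truth_zone"].astype(int)
        in_band = (df.x_um >= lo) & (df.x_um <= hi) & (spec.wm_fraction > 0)
        df["territory"] = np.where(in_band, "WM", "GM")
        df.loc[df.truth_compartment == "WM", "territory"] = "WM"

        xy_all = df[["x_um", "y_um"]].to_numpy() @ R.T + t
        df["x_um"], df["y_um"] = xy_all[:, 0], xy_all[:, 1]
        if "_parent_x" in df:
            pxy = df[["_parent_x", "_parent_y"]].to_numpy() @ R.T + t
            df["_parent_x"], df["_parent_y"] = pxy[:, 0], pxy[:, 1]
        df["donor"] = donor
        frames.append(df)

    out = pd.concat(frames, ignore_index=True)
    out["truth_compartment"] = out["truth_compartment"].astype(str)
    out.insert(0, "cell_id", [f"cell{i:07d}" for i in range(len(out))])
    return out


def thomas_pattern(radius_um: float, width_um: float = 7000.0,
                   height_um: float = 10000.0,
                   cluster_strength: float = 0.063,
                   points_per_cluster: float | None = None,
                   seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Standalone Thomas cluster pattern in a rectangle (scale family).

    Parent intensity is ``cluster_strength / radius_um^2`` (constant
    dimensionless clustering across radii); offspring are Gaussian with
    sigma = radius/2.  ``points_per_cluster`` defaults to ``radius/10`` so
    total point counts stay desk-scale.  Returns (points, parent index).
    """
    rng = np.random.default_rng(seed)
    kappa = cluster_strength / radius_um**2  # per μm²
    n_par = max(3, rng.poisson(kappa * width_um * height_um))
    parents = rng.uniform([0, 0], [width_um, height_um], size=(n_par, 2))
    if points_per_cluster is None:
        points_per_cluster = radius_um / 10.0
    cnt = rng.poisson(points_per_cluster, size=n_par)
    pidx = np.repeat(np.arange(n_par), cnt)
    pts = parents[pidx] + rng.normal(scale=radius_um / np.sqrt(6.0),
                                     size=(len(pidx), 2))
    ok = ((pts[:, 0] >= 0) & (pts[:, 0] <= width_um)
          & (pts[:, 1] >= 0) & (pts[:, 1] <= height_um))
    return pts[ok], pidx[ok]


# ---------------------------------------------------------------------------
# Count generation
# ---------------------------------------------------------------------------

def _dv_fraction(cells: pd.DataFrame) -> np.ndarray:
    """Per-cell dorsal->ventral position in [0, 1] (1 = most ventral)."""
    y = cells["y_um"].to_numpy(float)
    lo, hi = np.quantile(y, [0.01, 0.99])
    return np.clip((hi - y) / max(hi - lo, 1e-9), 0.0, 1.0)


def _log2_effect_matrix(cells: pd.DataFrame, espec: ExpressionSpec,
                        zone_count: int,
                        erosion_shrink: np.ndarray | None = None,
                        ) -> np.ndarray:
    """(n_cells, n_markers) planted log2 effects.

    ``erosion_shrink`` (per-cell in [0,1]) multiplies the *centered* zonal
    effect, pulling zonal means toward the cross-zone grand mean.
    """
    zones = cells["truth_zone"].to_numpy(int)
    dv = _dv_fraction(cells)
    n = len(cells)
    eff = np.zeros((n, len(espec.markers)))
    for j, m in enumerate(espec.markers):
        inblock = np.isin(zones, m.block)
        e = np.zeros(n)
        if m.mode == "discrete":
            e[inblock] = m.log2_effect
        else:
            blk = np.asarray(m.block)
            # gradient: ramp across the block's dorsoventral span
            span_lo = (blk.min() - 1) / zone_count
            span_hi = blk.max() / zone_count
            tt = np.clip((dv - span_lo) / max(span_hi - span_lo, 1e-9), 0, 1)
            # ramp from half to full effect across the block span: adjacent
            # zones inside a gradient block differ by a 2x step at the
            # default effect while every member zone stays above the
            # detection floor
            e[inblock] = m.log2_effect * (0.5 + 0.5 * tt[inblock])
        if erosion_shrink is not None:
            gm = e.mean()  # grand mean over all cells approximates zone mean
            e = gm + (e - gm) * erosion_shrink
        eff[:, j] = e
    return eff


def generate_lr_truth(cells: pd.DataFrame, espec: ExpressionSpec
                      ) -> np.ndarray:
    """Multiplicative ligand-receptor overlay, shape (n_cells, n_genes).

    Identity when ``espec.lr_programs`` is empty.  Raises ligand expression
    in sender cells inside the enriched zone and receptor subunits in
    receiver cells everywhere.
    """
    names = espec.gene_names()
    gidx = {g: i for i, g in enumerate(names)}
    overlay = np.ones((len(cells), espec.n_genes))
    ctype = cells["cell_type"].to_numpy()
    zones = cells["truth_zone"].to_numpy(int)
    known = set(ctype)
    for prog in espec.lr_programs:
        for t in (prog.sender_type, prog.receiver_type):
            if t not in known:
                raise ValueError(f"unknown cell type {t!r} in LR program")
        boost = 2.0 ** prog.log2_boost
        send = (ctype == prog.sender_type) & (zones == prog.enriched_zone)
        if prog.ligand in gidx:
            overlay[send, gidx[prog.ligand]] *= boost
        recv = ctype == prog.receiver_type
        for sub in prog.receptor_subunits:
            if sub in gidx:
                overlay[recv, gidx[sub]] *= boost
    return overlay


def generate_counts(cells: pd.DataFrame, espec: ExpressionSpec,
                    zone_count: int = 6, seed: int | None = None,
                    erosion_shrink: np.ndarray | None = None,
                    extra_log2: np.ndarray | None = None,
                    ) -> tuple[sparse.csr_matrix, list[str]]:
    """Draw the genes x cells NB count matrix for a cell table.

    Per-cell mean vector: baseline gene weights x 2^(planted effects)
    x donor shift x LR overlay, renormalized so expected per-cell totals
    equal the drawn log-normal library size.  Returns (counts CSR with
    cells as rows, gene names); transpose for a genes x cells layout.

    ``extra_log2`` adds arbitrary per-cell, per-marker log2 effects
    (used by the aging cohort); ``erosion_shrink`` compresses zonal
    contrasts toward the grand mean.
    """
    if "truth_zone" not in cells:
        raise ValueError("every cell needs a ground-truth zone")
    rng = np.random.default_rng(seed if seed is not None else espec.baseline_seed)
    base_rng = np.random.default_rng(espec.baseline_seed)
    names = espec.gene_names()
    n_cells, n_genes = len(cells), espec.n_genes

    # baseline relative expression, heavy-tailed like real transcriptomes;
    # marker genes sit near silence outside their block, as zonal markers
    # do in tissue, so detection-rate filters behave realistically
    base = base_rng.lognormal(mean=0.0, sigma=1.2, size=n_genes)
    n_mark = len(espec.markers)
    if n_mark:
        bg_sum = base[n_mark:].sum()
        frac = espec.marker_base_count / espec.depth_mean
        base[:n_mark] = frac * bg_sum / max(1.0 - n_mark * frac, 0.5)

    donors = cells["donor"].astype("category")
    d_codes = donors.cat.codes.to_numpy()
    shift = base_rng.normal(scale=espec.donor_shift_sd,
                            size=(len(donors.cat.categories), n_genes))
    log_w = np.log(base)[None, :] + shift[d_codes] * np.log(2.0)

    if espec.markers:
        eff = _log2_effect_matrix(cells, espec, zone_count, erosion_shrink)
        if extra_log2 is not None:
            eff = eff + extra_log2
        log_w[:, :eff.shape[1]] += eff * np.log(2.0)
    if espec.background_zone_sd > 0:
        # weak pervasive zonal modulation of every gene: real striatal
        # transcriptomes show broad low-amplitude zonation beyond the
        # discrete marker panel, and age-related erosion acts on it too
        zb = base_rng.normal(scale=espec.background_zone_sd,
                             size=(zone_count + 1, n_genes))
        zones_all = np.clip(cells["truth_zone"].to_numpy(int), 0, zone_count)
        bg = zb[zones_all]
        if erosion_shrink is not None:
            bg = bg * erosion_shrink[:, None]
        log_w += bg * np.log(2.0)
    if espec.lr_programs:
        log_w += np.log(generate_lr_truth(cells, espec))

    w = np.exp(log_w - log_w.max(axis=1, keepdims=True))
    w /= w.sum(axis=1, keepdims=True)
    lib = rng.lognormal(np.log(espec.depth_mean), espec.depth_sigma,
                        size=n_cells)
    mu = w * lib[:, None]

    # gamma-Poisson mixture == NB with dispersion alpha (Var = mu + a mu^2)
    a = espec.nb_dispersion
    lam = rng.gamma(shape=1.0 / a, scale=mu * a)
    counts = rng.poisson(lam)
    X = sparse.csr_matrix(counts)
    return X, names


# ---------------------------------------------------------------------------
# Aging cohort
# ---------------------------------------------------------------------------

def generate_aging_cohort(spec: TissueSpec, espec: ExpressionSpec,
                          aspec: AgingSpec, compartments: Sequence[CompartmentSpec] = (),
                          ) -> tuple[pd.DataFrame, sparse.csr_matrix, list[str]]:
    """Cohort with age-dependent zonal erosion and aging gene programs.

    A donor of age ``a`` retains ``1 - erosion_rate * (a - min_age)/10``
    (floored at 0) of the planted zonal contrast for every zonal marker;
    genes in ``aging_up``/``aging_down`` drift by ``lfc_per_decade`` per
    decade, scaled by the zone's vulnerability multiplier.
    """
    ages = np.asarray(aspec.donor_ages, float)
    if len(ages) < 2:
        raise ValueError("fewer than 2 donors")
    tspec = TissueSpec(**{**asdict(spec), "n_donors": len(ages)})
    cells = generate_positions(tspec, compartments)
    donor_order = sorted(cells["donor"].unique())
    age_of = dict(zip(donor_order, ages))
    cells["age_years"] = cells["donor"].map(age_of)

    dec = (cells["age_years"].to_numpy(float) - ages.min()) / 10.0
    shrink = np.clip(1.0 - aspec.erosion_rate * dec, 0.0, 1.0)

    names = espec.gene_names()
    marker_idx = {names[j]: j for j in range(len(espec.markers))}
    extra = np.zeros((len(cells), len(espec.markers)))
    zones = cells["truth_zone"].to_numpy(int)
    vuln = np.array([aspec.zone_vulnerability.get(z, 1.0)
                     for z in zones])
    for g in aspec.aging_up:
        if g in marker_idx:
            extra[:, marker_idx[g]] += aspec.lfc_per_decade * dec * vuln
    for g in aspec.aging_down:
        if g in marker_idx:
            extra[:, marker_idx[g]] -= aspec.lfc_per_decade * dec * vuln

    X, names = generate_counts(cells, espec, zone_count=spec.zone_count,
                               seed=spec.rng_seed + 1,
                               erosion_shrink=shrink, extra_log2=extra)
    return cells, X, names
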