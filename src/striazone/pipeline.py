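"""Pipeline orchestration: staged runs with manifests.

Stages execute in dependency order (simulate -> compartments -> zones ->
deg); each stage writes its outputs plus a manifest recording the
parameters, seed, package version and content hashes of its inputs, so a
re-run with the same configuration is reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io, pointpattern, syndata, zonal_deg, zonation

__all__ = ["default_config", "run_pipeline", "export_report"]

STAGES = ("simulate", "compartments", "zones", "deg")


def default_config(seed: int = 0) -> dict:
    return {
        "seed": seed,
        "stages": list(STAGES),
        "simulate": {"n_donors": 3, "n_cells_per_donor": 5000,
                     "n_genes": 1000},
        "compartments": {"n_sims": 199, "types": ["D1_Striosome_MSN",
                                                  "STRv_NUDAP_MSN",
                                                  "D1_KCNJ6_MSN"]},
        "zones": {"k": 6},
        "deg": {},
    }


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _manifest(outdir: Path, stage: str, params: dict, seed: int,
              inputs: list[Path], t0: float) -> None:
    io.write_json({
        "stage": stage, "params": params, "seed": seed,
        "version": __version__,
        "inputs": {str(p): _hash_file(p) for p in inputs if p.exists()},
        "elapsed_s": round(time.time() - t0, 2),
    }, outdir / f"manifest_{stage}.json")


def run_pipeline(config: dict, outdir) -> Path:
    """Execute the configured stages; returns the artifact directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = config.get("stages", list(STAGES))
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
    cells_path = outdir / "cells.csv"
    counts_dir = outdir / "counts"

    if "simulate" in stages:
        t0 = time.time()
        p = config.get("simulate", {})
        tspec = syndata.TissueSpec(
            n_donors=p.get("n_donors", 3),
            n_cells_per_donor=p.get("n_cells_per_donor", 5000),
            rng_seed=seed)
        cells = syndata.generate_positions(tspec,
                                           syndata.default_compartments())
        espec = syndata.default_expression(n_genes=p.get("n_genes", 1000))
        X, genes = syndata.generate_counts(cells, espec, seed=seed + 1)
        io.write_cells(cells.drop(columns=[c for c in cells
                                           if c.startswith("_")]),
                       cells_path)
        io.write_counts_mtx(X, genes, cells["cell_id"].tolist(), counts_dir)
        _manifest(outdir, "simulate", p, seed, [], t0)

    if "compartments" in stages:
        t0 = time.time()
        p = config.get("compartments", {})
        if not cells_path.exists():
            raise FileNotFoundError(
                "compartments stage needs cells.csv — run 'simulate' first "
                "or point the config at existing artifacts")
        cells = io.read_cells(cells_path)
        rows = []
        for d, sub in cells.groupby("donor"):
            win = pointpattern.make_msn_window(sub)
            pat = pointpattern.PointPattern(
                sub[["x_um", "y_um"]].to_numpy(), win,
                sub["cell_type"].to_numpy())
            calib = {}
            pcf_rows = []
            for ctype in p.get("types", []):
                env = pointpattern.mc_envelope(
                    pat, ctype, n_sims=p.get("n_sims", 199), seed=seed)
                if env is None:
                    continue
                pcf_rows.append(pd.DataFrame({
                    "donor": d, "cell_type": ctype, "r": env.r_grid,
                    "g": env.g_values, "lo": env.envelope_lo,
                    "hi": env.envelope_hi}))
                if env.radius_estimate is None:
                    continue
                mp = pointpattern.DEFAULT_MINPTS.get(ctype, 3)
                cal = pointpattern.calibrate_eps(pat, ctype, mp,
                                                 env.radius_estimate)
                if cal is not None:
                    calib[ctype] = (cal[0], mp)
            cmap = pointpattern.assign_compartments(pat, calib)
            comp = pd.Series("unassigned", index=sub.index, dtype=object)
            inside = pat.window.contains(sub[["x_um", "y_um"]].to_numpy())
            comp.loc[sub.index[inside]] = cmap.labels.to_numpy()
            rows.append(pd.DataFrame({"cell_id": sub["cell_id"],
                                      "compartment": comp}))
            if pcf_rows:
                io.atomic_write(
                    outdir / f"pcf_{d}.csv",
                    lambda t, df=pd.concat(pcf_rows): df.to_csv(t,
                                                                index=False))
        comp_all = pd.concat(rows)
        cells = cells.merge(comp_all, on="cell_id", how="left")
        io.write_cells(cells, cells_path)
        _manifest(outdir, "compartments", p, seed, [cells_path], t0)

    if "zones" in stages:
        t0 = time.time()
        p = config.get("zones", {})
        cells, X, genes = io.read_inputs(cells_path, counts_dir)
        ref_mask = (cells["cell_type"] == "D1_Matrix_MSN").to_numpy()
        ref_cells = cells[ref_mask].reset_index(drop=True)
        labels = zonation.cluster_zones(X[np.flatnonzero(ref_mask)],
                                        ref_cells, k_target=p.get("k", 6),
                                        seed=seed)
        ref_cells = ref_cells.assign(zone=labels)
        transfer = zonation.transfer_zone_labels(cells, ref_cells)
        cells["zone"] = transfer["zone"].to_numpy()
        cells["territory_call"] = transfer["territory_call"].to_numpy()
        model = zonation.align_axes(ref_cells)
        cent_rows = [{"donor": d, "zone": z, "x": c[0], "y": c[1]}
                     for d, cz in model.centroids.items()
                     for z, c in cz.items()]
        io.atomic_write(outdir / "zone_centroids.csv",
                        lambda t: pd.DataFrame(cent_rows).to_csv(t,
                                                                 index=False))
        io.write_cells(cells, cells_path)
        _manifest(outdir, "zones", p, seed, [cells_path], t0)

    if "deg" in stages:
        t0 = time.time()
        p = config.get("deg", {})
        cells, X, genes = io.read_inputs(cells_path, counts_dir)
        msn = (cells["cell_type"] == "D1_Matrix_MSN").to_numpy() \
            & (cells["zone"].to_numpy() > 0)
        sub = cells[msn].reset_index(drop=True)
        Xs = X[np.flatnonzero(msn)]
        pb = zonal_deg.pseudobulk(Xs, sub, gene_names=genes)
        de = zonal_deg.de_all_zones(pb)
        det = zonal_deg.detection_rates(Xs, sub, gene_names=genes)
        for z, tab in de.items():
            io.atomic_write(outdir / f"de_zone{z}_vs_rest.csv",
                            lambda t, df=tab: df.to_csv(t))
        blocks = zonal_deg.assign_blocks(de, det)
        blocks = zonal_deg.classify_gradient(blocks, pb)
        io.atomic_write(outdir / "block_assignments.csv",
                        lambda t: blocks.table.to_csv(t))
        _manifest(outdir, "deg", p, seed,
                  [cells_path, outdir / "manifest_zones.json"], t0)
    return outdir


def export_report(outdir) -> Path:
    """Static figures and tables from pipeline artifacts.

    Missing stages are noted rather than fatal; the report always
    completes.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    rep = outdir / "report"
    rep.mkdir(exist_ok=True)
    notes = []
    pcfs = sorted(outdir.glob("pcf_*.csv"))
    if pcfs:
        fig, ax = plt.subplots(figsize=(6, 4))
        for f in pcfs[:3]:
            df = pd.read_csv(f)
            for ct, sub in df.groupby("cell_type"):
                ax.plot(sub["r"], sub["g"], label=f"{f.stem[4:]}:{ct}",
                        lw=1)
                from .pointpattern import PCFResult, estimate_radius
                res = PCFResult(sub["r"].to_numpy(), sub["g"].to_numpy(),
                                0.0, 25.0, sub["lo"].to_numpy(),
                                sub["hi"].to_numpy())
                rad = estimate_radius(res)
                if rad is not None:
                    ax.axvline(rad, ls=":", color="gray")
        ax.axhline(1.0, color="k", lw=0.5)
        ax.set_xlabel("r (μm)")
        ax.set_ylabel("g_inhom(r)")
        ax.legend(fontsize=6)
        fig.savefig(rep / "pcf_curves.png", dpi=120)
        plt.close(fig)
    else:
        notes.append("no PCF curves found")
    cells_path = outdir / "cells.csv"
    if cells_path.exists():
        cells = pd.read_csv(cells_path)
        if "zone" in cells:
            fig, ax = plt.subplots(figsize=(5, 6))
            d0 = cells[cells["donor"] == cells["donor"].iloc[0]]
            sc = ax.scatter(d0["x_um"], d0["y_um"], c=d0["zone"], s=2,
                            cmap="tab10")
            fig.colorbar(sc, ax=ax, label="zone")
            fig.savefig(rep / "zone_map.png", dpi=120)
            plt.close(fig)
        else:
            notes.append("no zone labels in cell table")
    else:
        notes.append("no cell table found")
    io.write_json({"notes": notes}, rep / "report_notes.json")
    return rep
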