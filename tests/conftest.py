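"""Shared synthetic fixtures (generated at session start, never stored)."""

import numpy as np
import pytest

from striazone import syndata as sd


@pytest.fixture(scope="session")
def small_tissue():
    """3 donors x 2500 cells with compartments, plus NB counts."""
    spec = sd.TissueSpec(n_donors=3, n_cells_per_donor=2500, rng_seed=11)
    cells = sd.generate_positions(spec, sd.default_compartments())
    espec = sd.default_expression(n_genes=300, n_markers_per_zone=5,
                                  n_gradient=6)
    X, genes = sd.generate_counts(cells, espec, seed=12)
    cells = cells.copy()
    cells["zone"] = cells["truth_zone"]
    return {"spec": spec, "cells": cells, "X": X, "genes": genes,
            "espec": espec}


@pytest.fixture(scope="session")
def msn_subset(small_tissue):
    """Matrix-MSN cells with counts, for pseudobulk work."""
    cells = small_tissue["cells"]
    mask = cells["cell_type"].isin(["D1_Matrix_MSN", "D2_Matrix_MSN"])
    sub = cells[mask].reset_index(drop=True)
    X = small_tissue["X"][np.flatnonzero(mask.to_numpy())]
    return sub, X, small_tissue["genes"]
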