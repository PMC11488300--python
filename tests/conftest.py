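"""Shared fixtures: small simulated datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from senosig import (BulkExpression, BulkSimConfig, ScSimConfig,
                     simulate_bulk, simulate_cells)

SMALL_BULK = BulkSimConfig(
    n_genes=600,
    n_shared_up=20,
    n_shared_down=30,
    n_model_specific=40,
    n_ifn_overlap_up=5,
    n_ifn_overlap_down=3,
    n_ifn_specific_up=20,
    n_ifn_specific_down=10,
    seed=11,
)

SMALL_CELLS = ScSimConfig(
    n_genes=400,
    groups=(("EP_prolif", 120, 0.02), ("mid", 120, 0.3), ("late", 120, 0.8)),
    n_signature_genes=25,
    n_sasp_genes=25,
    max_genes=380,
    qc_violators=(4, 4, 4, 4),
    seed=5,
)


@pytest.fixture(scope="session")
def small_bulk():
    return simulate_bulk(SMALL_BULK)


@pytest.fixture(scope="session")
def small_cells():
    return simulate_cells(SMALL_CELLS)


@pytest.fixture
def tiny_expression():
    """A 3-gene, paired 3+3-sample dataset with one planted up gene, one
    planted down gene, and one null gene."""
    genes = ["Gdown", "Gnull", "Gup"]
    samples = ["m_EP_d1", "m_EP_d2", "m_EP_d3",
               "m_senescent_d1", "m_senescent_d2", "m_senescent_d3"]
    values = pd.DataFrame(
        [
            [5.0, 5.1, 4.9, 3.0, 3.2, 2.8],  # down in senescence
            [7.0, 7.2, 6.9, 7.1, 6.95, 7.05],  # null
            [1.0, 1.1, 0.9, 3.0, 3.2, 2.8],  # up in senescence
        ],
        index=genes,
        columns=samples,
    )
    annot = pd.DataFrame(
        {
            "donor": ["d1", "d2", "d3"] * 2,
            "model": ["m"] * 6,
            "condition": ["EP"] * 3 + ["senescent"] * 3,
        },
        index=samples,
    )
    return BulkExpression(values=values, samples=annot)


def make_de_frame(genes, up=(), down=(), log2fc=None):
    """Assemble a DEResult-style frame directly from flag sets."""
    up, down = set(up), set(down)
    if log2fc is None:
        log2fc = {g: (2.0 if g in up else -2.0 if g in down else 0.0)
                  for g in genes}
    return pd.DataFrame(
        {
            "gene": list(genes),
            "log2fc": [log2fc[g] for g in genes],
            "t_stat": [0.0] * len(genes),
            "p_value": [0.01 if (g in up or g in down) else 0.9
                        for g in genes],
            "significant_up": [g in up for g in genes],
            "significant_down": [g in down for g in genes],
        }
    )
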