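from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from vascrisk import CellType, ContrastResult, SyntheticConfig, generate_database


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """A database small enough for fast unit tests (underpowered on purpose)."""
    return SyntheticConfig(
        n_compounds=12,
        n_risk=4,
        n_genes=400,
        n_pathways=10,
        pathway_size_range=(6, 14),
        n_risk_pathways=3,
        n_side_effects=2,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_db(small_cfg):
    return generate_database(small_cfg)


@pytest.fixture(scope="session")
def default_cfg() -> SyntheticConfig:
    """The study-scale configuration: 111 compounds, 33 risk-flagged."""
    return SyntheticConfig(seed=42)


@pytest.fixture(scope="session")
def default_db(default_cfg):
    return generate_database(default_cfg)


def make_contrast(
    gene_ids,
    log_fc,
    p_value=None,
    fdr=None,
    mean_expr=None,
    treatment="T@1e-06",
    cell_type=CellType.SMC,
) -> ContrastResult:
    """Hand-built contrast for targeted tests."""
    n = len(gene_ids)
    p = np.full(n, 0.01) if p_value is None else np.asarray(p_value, dtype=float)
    f = p if fdr is None else np.asarray(fdr, dtype=float)
    m = np.full(n, 100.0) if mean_expr is None else np.asarray(mean_expr, dtype=float)
    df = pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "log_fc": np.asarray(log_fc, dtype=float),
            "p_value": p,
            "fdr": f,
            "mean_expr": m,
        }
    )
    return ContrastResult(treatment_id=treatment, cell_type=cell_type, data=df)
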