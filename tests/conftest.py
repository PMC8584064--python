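"""Shared fixtures: synthetic cohorts and small on-disk tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import panelscan as ps

# The eight discovery-cohort SDE genes with their published log2 fold
# changes and BH-adjusted p-values; one gene (DNTT) is down-regulated.
# POLN's fold change prints as 1.00 at two decimals but passed the strict
# |log2FC| > 1 filter, so its unrounded estimate was strictly above 1; it
# is represented here by a synthetic stand-in value consistent with both.
SDE_TABLE_ROWS = [
    ("RAD51", 1.02, 5.92e-11),
    ("RPA4", 1.18, 1.83e-6),
    ("SLX1B", 1.02, 2.2e-3),
    ("POLN", 1.002, 7.16e-19),
    ("EME2", 1.29, 1.16e-18),
    ("EXO1", 1.27, 2.82e-11),
    ("DNTT", -1.20, 1.1e-2),
    ("NEIL3", 1.93, 1.21e-18),
]


@pytest.fixture(scope="session")
def small_cohort():
    """A modest planted cohort shared by read-only tests."""
    cfg = ps.planted_panel_config(seed=11, n_tumor=150, n_normal=40, n_genes=40)
    return ps.generate_cohort(cfg)


@pytest.fixture()
def sde_table_path(tmp_path):
    """External DE table TSV with the eight known SDE rows."""
    df = pd.DataFrame(SDE_TABLE_ROWS, columns=["gene_id", "log2FC", "p_adj"])
    path = tmp_path / "sde_table.tsv"
    df.to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture()
def simple_expr():
    """A tiny deterministic raw-count matrix (4 genes x 6 samples)."""
    rng = np.random.default_rng(3)
    vals = rng.poisson(100, size=(4, 6)).astype(float)
    return ps.ExpressionMatrix([f"g{i}" for i in range(4)],
                               [f"s{i}" for i in range(6)],
                               vals, ps.ExpressionUnit.raw_counts)


def spawn_seeds(base: int, n: int) -> list[int]:
    """Independent child seeds below 2^31 derived from one base seed."""
    ss = np.random.SeedSequence(base)
    return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n)]
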