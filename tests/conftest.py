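"""Shared fixtures: small simulated datasets and PSM-table builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from vesiquant.synthetic import PSM_COLUMNS, SyntheticConfig, simulate


def make_psms(rows: list[dict]) -> pd.DataFrame:
    """Build a PSM table from partial row dicts, filling sane defaults."""
    defaults = {"peptide": "PEPTIDEK", "proteins": "P1", "charge": 2,
                "score": 20.0, "spi": 90.0, "fraction": "soluble",
                "replicate": 1, "slice": 1, "is_decoy": False,
                "is_noise": False}
    return pd.DataFrame([{**defaults, **row} for row in rows],
                        columns=PSM_COLUMNS)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A fast simulation: 40 proteins, modest depth, small database."""
    return SyntheticConfig(n_proteins=40, n_isoform_clusters=34,
                           depth=3000, database_excess=3, seed=11)


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate(small_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_250_920)
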