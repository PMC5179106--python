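"""Shared fixtures: toy link tables and a small synthetic bundle on disk."""

from __future__ import annotations

import pandas as pd
import pytest

from adrepo.synthetic_data import GeneratorConfig, generate_bundle


@pytest.fixture
def toy_links() -> pd.DataFrame:
    """Six metabolite->protein links: P1 has partners {A,B,C}, P2 {A}, P3 {D,E}."""
    return pd.DataFrame({
        "metabolite_id": ["A", "B", "C", "A", "D", "E"],
        "uniprot_id": ["P1", "P1", "P1", "P2", "P3", "P3"],
    })


@pytest.fixture
def toy_changes() -> pd.DataFrame:
    """Altered metabolites {A, B, E} with signed fold changes."""
    return pd.DataFrame({
        "metabolite_id": ["A", "B", "E"],
        "name": ["met-a", "met-b", "met-e"],
        "fold_change": [2.0, -3.0, 1.5],
        "sample_type": ["CSF", "CSF", "CSF"],
    })


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    return GeneratorConfig(seed=7, n_targets=40, n_metabolites=20, n_drugs=30,
                           planted_targets=3, n_multiplatform=2)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_bundle(small_config)


@pytest.fixture(scope="session")
def small_bundle_dir(small_bundle, tmp_path_factory):
    return small_bundle.write(tmp_path_factory.mktemp("bundle"))
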