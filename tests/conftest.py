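import warnings

import numpy as np
import pandas as pd
import pytest

from hetcirc import (
    SimConfig,
    generate_counts,
    generate_phenotypes,
)
from hetcirc.config import ModuleSpec


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A reduced study: one tissue, modest feature count, fast to simulate."""
    return SimConfig(
        seed=0,
        group_sizes={"WW": 40, "YY": 40, "WY": 40, "YW": 40},
        tissues=("hypothalamus", "liver"),
        n_circ=80,
        n_gene=160,
        module_spec=ModuleSpec(n_members=40, n_circ_members=6),
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    """Phenotypes, counts, metadata and truth for the reduced study."""
    phen, truth = generate_phenotypes(small_config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        circ, gene, meta, truth = generate_counts(
            small_config, phen, truth)
    return {"phenotypes": phen, "circ": circ, "gene": gene,
            "meta": meta, "truth": truth, "config": small_config}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def make_meta(groups: list[str], tissue: str = "t",
              mapped: int = 1_000_000) -> pd.DataFrame:
    """Minimal sample metadata for hand-built count matrices."""
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(len(groups))],
        "bird_id": [f"b{i}" for i in range(len(groups))],
        "tissue": tissue,
        "group": groups,
        "mapped_reads": mapped,
    })
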