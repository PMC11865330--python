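import numpy as np
import pandas as pd
import pytest

import acidonet as an


@pytest.fixture(scope="session")
def small_spec():
    return an.CommunitySpec(n_samples=24, n_taxa=60, coop_block_size=8,
                            sequencing_depth=10_000, seed=7)


@pytest.fixture(scope="session")
def bundle(small_spec):
    """One fully generated synthetic survey reused across read-only tests."""
    return an.generate_all(small_spec)


@pytest.fixture()
def tiny_table():
    """Hand-sized 4-taxon x 5-sample count table."""
    counts = pd.DataFrame(
        {
            "S1": [10, 0, 5, 85],
            "S2": [20, 5, 5, 70],
            "S3": [5, 10, 5, 80],
            "S4": [50, 20, 5, 25],
            "S5": [30, 10, 5, 55],
        },
        index=pd.Index(["T1", "T2", "T3", "T4"], name="taxon_id"),
    )
    tax = pd.DataFrame(
        {
            "domain": "Bacteria",
            "phylum": ["P1", "P1", "P2", "P2"],
            "class": "c",
            "order": "o",
            "family": ["F1", "F1", "F2", "F2"],
            "genus": ["G1", "G2", "G3", "G4"],
            "species": ["unclassified", "sp2", "unclassified", "unclassified"],
        },
        index=counts.index,
    )
    return an.AbundanceTable(counts, tax)


def rng(seed=0):
    return np.random.default_rng(seed)
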