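import numpy as np
import pandas as pd
import pytest

from thermopath import (
    AnnotationDB,
    Lineage,
    OtuTable,
    Pathway,
    PathwayCatalog,
    SyntheticConfig,
    generate_coupled_dataset,
)


@pytest.fixture
def small_counts_table() -> OtuTable:
    """3 samples x 4 OTUs, two OTUs sharing a genus."""
    data = pd.DataFrame(
        [[60, 40, 0, 10], [5, 5, 80, 10], [0, 0, 0, 50]],
        index=["A", "B", "C"],
        columns=["otu1", "otu2", "otu3", "otu4"],
        dtype=float,
    )
    taxonomy = {
        "otu1": Lineage.parse("k__Bacteria; p__Actinobacteria; g__Rhodococcus; s__ruber"),
        "otu2": Lineage.parse("k__Bacteria; p__Actinobacteria; g__Rhodococcus"),
        "otu3": Lineage.parse("k__Bacteria; p__Proteobacteria; g__Pseudomonas"),
        "otu4": Lineage.parse("k__Bacteria; p__Firmicutes; g__Bacillus"),
    }
    return OtuTable(data=data, unit="counts", taxonomy=taxonomy)


@pytest.fixture
def tiny_db() -> AnnotationDB:
    return AnnotationDB(
        {
            "g__rhodococcus": frozenset({"K00001", "K00002"}),
            "g__pseudomonas": frozenset({"K00002", "K00003"}),
        }
    )


@pytest.fixture
def tiny_catalog() -> PathwayCatalog:
    return PathwayCatalog(
        (
            Pathway("p1", "Pathway one", frozenset({"K00001"})),
            Pathway("p2", "Pathway two", frozenset({"K00001", "K00099"})),
            Pathway("p3", "Pathway three", frozenset({"K00001", "K00002", "K00003", "K00004"})),
        )
    )


@pytest.fixture(scope="session")
def coupled_dataset():
    """Default-condition coupled dataset shared across read-only tests."""
    return generate_coupled_dataset(SyntheticConfig(seed=11))
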