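import numpy as np
import pandas as pd
import pytest

from lactoswitch.circuit import CircuitParams
from lactoswitch.feature_table import FeatureTable


@pytest.fixture(scope="session")
def params() -> CircuitParams:
    return CircuitParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture()
def tiny_table() -> FeatureTable:
    """Four samples x three features with full metadata and taxonomy."""
    counts = pd.DataFrame(
        [[10, 5, 0], [8, 0, 2], [0, 12, 3], [4, 4, 4]],
        index=["s1", "s2", "s3", "s4"],
        columns=["ASV0", "ASV1", "ASV2"],
    )
    metadata = pd.DataFrame({
        "group": ["untreated", "model", "control", "test"],
        "day": [1, 1, 3, 3],
        "mouse_id": ["m1", "m2", "m3", "m4"],
        "cage": ["c1", "c1", "c2", "c2"],
    }, index=counts.index)
    taxonomy = pd.DataFrame({
        "lineage": [
            "Bacteria;Bacteroidota;Bacteroidia;Bacteroidales;Bacteroidaceae;Bacteroides;Bacteroides acidifaciens",
            "Bacteria;Firmicutes;Bacilli;Lactobacillales;Lactobacillaceae;Lactobacillus;Lactobacillus murinus",
            "Bacteria;Firmicutes;Clostridia;Oscillospirales;Ruminococcaceae;Oscillibacter;Oscillibacter sp",
        ],
        "confidence": [0.9, 0.92, 0.8],
    }, index=counts.columns)
    return FeatureTable(counts, metadata, taxonomy)
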