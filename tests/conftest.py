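import numpy as np
import pytest

from otunet import OtuTable, SampleMetadata
from otunet.tables_io import SampleRecord


@pytest.fixture
def tiny_table() -> OtuTable:
    """3 taxa x 4 samples with taxonomy, hand-set counts."""
    counts = np.array(
        [
            [10, 20, 0, 5],
            [1, 0, 3, 2],
            [100, 80, 120, 90],
        ]
    )
    taxonomy = {
        "OtuA": "Bacteria;Firmicutes;Bacilli;Bacillales;Staphylococcaceae;Staphylococcus",
        "OtuB": "Bacteria;Firmicutes;Bacilli;Bacillales;Staphylococcaceae;Staphylococcus",
        "OtuC": "Bacteria;Actinobacteria;Actinomycetia;Micrococcales;Micrococcaceae;Micrococcus",
    }
    return OtuTable(["OtuA", "OtuB", "OtuC"], ["S1", "S2", "S3", "S4"], counts, taxonomy)


@pytest.fixture
def tiny_metadata() -> SampleMetadata:
    return SampleMetadata(
        {
            "S1": SampleRecord("P1", "synbiotic", 0),
            "S2": SampleRecord("P1", "synbiotic", 9),
            "S3": SampleRecord("P2", "synbiotic", 0),
            "S4": SampleRecord("P3", "placebo", 0),
        }
    )


@pytest.fixture
def random_table() -> OtuTable:
    """20 taxa x 12 samples of seeded lognormal-ish counts."""
    rng = np.random.default_rng(42)
    counts = rng.poisson(np.exp(rng.normal(2.0, 1.5, size=(20, 12))))
    return OtuTable(
        [f"Otu{i:03d}" for i in range(20)],
        [f"S{j:02d}" for j in range(12)],
        counts,
    )
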