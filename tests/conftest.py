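import numpy as np
import pandas as pd
import pytest

from paraflux.io import ComplexCatalog, ExpressionDataset, GenePair


@pytest.fixture
def small_dataset() -> ExpressionDataset:
    """5 genes x 6 samples, log2 scale, one condition per sample."""
    genes = ["g1", "g2", "g3", "g4", "g5"]
    samples = [f"s{i}" for i in range(6)]
    rng = np.random.default_rng(11)
    values = pd.DataFrame(rng.normal(8, 1, (5, 6)), index=genes, columns=samples)
    meta = pd.DataFrame(
        {
            "condition": [f"c{i}" for i in range(6)],
            "replicate": "1",
            "layer": "rna",
            "species": "toy",
        },
        index=samples,
    )
    return ExpressionDataset(values, meta, "log2")


@pytest.fixture
def toy_pairs() -> list[GenePair]:
    return [GenePair("g1", "g2", 80.0, 90.0), GenePair("g3", "g4", 55.0, 60.0)]


@pytest.fixture
def toy_catalog() -> ComplexCatalog:
    return ComplexCatalog({"cpx1": frozenset({"g1", "g2", "g3", "g4", "g5"})})
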