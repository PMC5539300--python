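import numpy as np
import pandas as pd
import pytest

from retroscope import (
    Contrast,
    ExpressionMatrix,
    SampleMetadata,
    TEAnnotation,
    default_scenario,
    simulate,
)


@pytest.fixture(scope="session")
def default_bundle():
    """One seeded dataset from the default AML-like scenario."""
    return simulate(default_scenario(seed=7))


@pytest.fixture()
def small_counts():
    rng = np.random.default_rng(11)
    values = pd.DataFrame(
        rng.integers(0, 200, size=(12, 6)).astype(float),
        index=[f"F{i:02d}" for i in range(12)],
        columns=[f"S{i}" for i in range(6)],
    )
    return ExpressionMatrix(values, unit="count")


@pytest.fixture()
def small_annotation():
    rows = []
    for i in range(6):
        rows.append({"feature_id": f"F{i:02d}", "kind": "coding", "te_type": "",
                     "te_class": "", "gene_symbol": f"GENE{i}",
                     "effective_length": 1000.0 + 100 * i})
    te_types = [("Alu", "SINE"), ("Alu", "SINE"), ("MIR", "SINE"),
                ("L1", "LINE"), ("ERVK", "LTR"), ("ERVK", "LTR")]
    for i, (t, c) in enumerate(te_types, start=6):
        rows.append({"feature_id": f"F{i:02d}", "kind": "repeat", "te_type": t,
                     "te_class": c, "gene_symbol": "",
                     "effective_length": 300.0 + 50 * i})
    return TEAnnotation(pd.DataFrame(rows))


@pytest.fixture()
def two_group_meta():
    return SampleMetadata(pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(6)],
        "group": ["A", "A", "A", "B", "B", "B"],
        "patient_id": ["p1", "p2", "p3", "p1", "p2", "p3"],
    }))


@pytest.fixture()
def paired_contrast():
    return Contrast("A", "B", paired=True)
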