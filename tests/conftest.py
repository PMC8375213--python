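import numpy as np
import pytest

from prfbio import (
    ActivityRecord,
    FeatureMatrix,
    LabelConfig,
    SyntheticSpec,
    generate,
    label_dataset,
)


@pytest.fixture
def replicate_records():
    """Activity table with replicates across two assays and readout types."""
    rows = [
        ("C1", "T1", 5.6, "A1", "IC50"),
        ("C1", "T1", 6.3, "A2", "IC50"),
        ("C2", "T1", 5.0, "A1", "Ki"),
        ("C2", "T1", 5.0, "A1", "Ki"),
        ("C2", "T1", 6.0, "A2", "Ki"),
        ("C3", "T2", 7.1, "A3", "EC50"),
    ]
    return [
        ActivityRecord(c, t, p, assay_id=a, measurement_type=m)
        for c, t, p, a, m in rows
    ]


@pytest.fixture
def tiny_features():
    values = np.array(
        [
            [1, 0, 1, 0],
            [0, 1, 1, 0],
            [1, 1, 0, 0],
            [0, 0, 0, 1],
        ]
    )
    return FeatureMatrix(values, ["C1", "C2", "C3", "C4"], ["f0", "f1", "f2", "f3"])


@pytest.fixture(scope="session")
def default_dataset():
    """One realisation of the generator's default study conditions."""
    return generate(SyntheticSpec(seed=7))


@pytest.fixture(scope="session")
def default_soft_labels(default_dataset):
    ds = default_dataset
    return label_dataset(
        ds.to_activity_records(),
        ds.features,
        LabelConfig(p_threshold=5.0, sigma=0.3),
        ds.putative_ids(),
    )
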