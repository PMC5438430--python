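import numpy as np
import pandas as pd
import pytest

from oosda.table import FeatureTable, validate_sample_metadata


def make_table(values, scale="raw", sample_ids=None, charges=None):
    """Small FeatureTable from a (features x samples) array; NaN = missing."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    if sample_ids is None:
        sample_ids = [f"S{j + 1}" for j in range(n_samp)]
    meta = pd.DataFrame(
        {
            "feature_id": [f"F{i + 1}" for i in range(n_feat)],
            "mz": np.linspace(150.0, 800.0, n_feat),
            "rt": np.linspace(10.0, 1000.0, n_feat),
            "charge": charges if charges is not None else [1] * n_feat,
        }
    )
    return FeatureTable(values, meta, sample_ids, scale)


def make_meta(rows):
    """Sample metadata from (sample_id, sample_type, batch, order,
    replicate_group, compound, class_label) tuples."""
    df = pd.DataFrame(
        rows,
        columns=[
            "sample_id", "sample_type", "batch", "injection_order",
            "replicate_group", "compound", "class_label",
        ],
    )
    return validate_sample_metadata(df.astype(str))


@pytest.fixture
def small_sim():
    """A small but complete simulated experiment shared across tests."""
    import oosda

    cfg = oosda.SimConfig(n_features=120, seed=11)
    return oosda.simulate_experiment(cfg)
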