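import logging

import numpy as np
import pandas as pd
import pytest

from sahpanel.datasets import ExpressionDataset
from sahpanel.simulate import RNASEQ_GROUPS, SimulationConfig

logging.getLogger("sahpanel").setLevel(logging.WARNING)


@pytest.fixture
def small_chip_config():
    """A chip arm small enough for fast tests but with clear planted signal."""
    return SimulationConfig(
        n_genes=1000,
        n_de_genes=50,
        log2_effect=2.0,
        sigma=0.25,
        n_per_group=5,
        biomarker_panel_size=9,
        seed=1,
    )


@pytest.fixture
def small_rnaseq_config():
    return SimulationConfig(
        n_genes=2000,
        arm="rnaseq",
        group_labels=RNASEQ_GROUPS,
        n_de_genes=100,
        log2_effect=1.5,
        biomarker_panel_size=9,
        top_subset_size=3,
        n_lcn2_specific=20,
        seed=2,
    )


def toy_dataset(values, groups, dialect="log"):
    """Build an ExpressionDataset from a 2-D array and per-sample groups."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    samples = [f"s{i}" for i in range(n_samples)]
    meta = pd.DataFrame(
        {
            "sample_id": samples,
            "group": list(groups),
            "time": "na",
            "treatment": "none",
        }
    )
    frame = pd.DataFrame(values, index=[f"g{i}" for i in range(n_genes)], columns=samples)
    if dialect == "counts":
        frame = frame.astype(np.int64)
    return ExpressionDataset(frame, meta, dialect=dialect)


@pytest.fixture
def make_dataset():
    return toy_dataset
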