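import numpy as np
import pandas as pd
import pytest

import toxsig as ts


@pytest.fixture(scope="session")
def training6():
    """Small training-arm 6 h dataset with the six default planted shapes."""
    return ts.simulate_study(
        "training", 6, templates=ts.default_templates(n_genes=40),
        n_background_genes=300, noise_sd=0.1, seed=11,
    )


@pytest.fixture(scope="session")
def training6_extract(training6):
    return ts.run_extract(training6["expression"], training6["metadata"])


@pytest.fixture()
def two_group_structure():
    """Two inter-groups of 4 columns each."""
    return ts.GroupStructure(indices=[0] * 4 + [1] * 4, names=("a", "b"))


def expand_template(template, metadata, exclude_vehicle=True):
    """Noise-free per-array profile of a template under a sample table."""
    meta = metadata
    if exclude_vehicle:
        meta = meta[meta["dose_class"] != "vehicle"]
    return np.array(
        [template.cell_mean(t, d) for t, d in zip(meta["tissue"], meta["dose_class"])]
    )
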