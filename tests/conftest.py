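import numpy as np
import pandas as pd
import pytest

from metaboclass import (
    AbundanceTable,
    GeneratorConfig,
    SampleClasses,
    cutoff_filter,
    generate_abundance,
)

# Canonical demonstration seed of the paper-like preset, used across tests.
PRESET_SEED = 1


@pytest.fixture(scope="session")
def paper_like():
    """12-sample, 61-feature two-class dataset with 13 major features."""
    return generate_abundance(GeneratorConfig(seed=PRESET_SEED))


@pytest.fixture(scope="session")
def paper_like_filtered(paper_like):
    """The preset after the 10% cutoff: X (samples x features), y, table."""
    table, classes = paper_like
    filtered = cutoff_filter(table)
    y = classes.label_vector(filtered.sample_ids)
    return filtered, filtered.values.T, y, classes


@pytest.fixture
def small_table():
    return AbundanceTable(
        pd.DataFrame(
            {
                "s1": [50.0, 20.0, 5.0],
                "s2": [30.0, 10.0, 5.0],
            },
            index=["linoleic acid", "clionasterol", "vitamin E"],
        )
    )


@pytest.fixture
def two_class_labels():
    return SampleClasses(
        labels={"s1": 0, "s2": 1},
        class_names={0: "Thai", 1: "Foreign"},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
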