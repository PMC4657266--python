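import numpy as np
import pandas as pd
import pytest

from hhsort import quantify, simdata


@pytest.fixture(scope="session")
def small_experiment():
    """One modest synthetic factorial experiment shared across tests."""
    config = simdata.SimulationConfig(
        n_genes=400,
        seed=11,
        library_size=4e5,
        baseline_log2_mean_range=(5.0, 9.0),
    )
    counts, truth = simdata.generate_experiment(config)
    return config, counts, truth


@pytest.fixture()
def tiny_counts():
    """Hand-built 3-gene counts matrix with easy round numbers."""
    values = pd.DataFrame(
        {
            "ctrl_1": [500, 1000, 0],
            "ctrl_2": [500, 1000, 0],
            "hh_1": [2000, 1000, 10],
            "hh_2": [2000, 1000, 10],
            "esrrb_1": [500, 1000, 0],
            "esrrb_2": [500, 1000, 0],
            "esrrb_hh_1": [2000, 1000, 10],
            "esrrb_hh_2": [2000, 1000, 10],
        },
        index=["ga", "gb", "gc"],
    )
    return quantify.ExpressionMatrix(
        values=values,
        gene_lengths_bp=pd.Series([2000, 1000, 500], index=values.index),
        library_sizes=pd.Series(1e7, index=values.columns),
        units="counts",
    )
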