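import numpy as np
import pandas as pd
import pytest

from synaptomics import ExpressionMatrix, SimParams, simulate_study


@pytest.fixture(scope="session")
def study():
    """Default synthetic study (the fixed study conditions, seed 1)."""
    return simulate_study(SimParams(seed=1))


@pytest.fixture(scope="session")
def null_study():
    """Same design with every programmed effect zeroed (global null)."""
    return simulate_study(SimParams(seed=1).null())


def make_matrix(values, layer="rna", compartment="TH", age_group="5m",
                lengths=None, ages=None, compartments=None):
    """Small ExpressionMatrix from a gene -> list-of-values dict."""
    df = pd.DataFrame(values).T.astype(float)
    n = df.shape[1]
    df.columns = [f"s{i}" for i in range(n)]
    ages = ages or [age_group] * n
    compartments = compartments or [compartment] * n
    from synaptomics.data import AGE_DAYS
    meta = pd.DataFrame({
        "compartment": compartments,
        "age_group": ages,
        "age_numeric": [AGE_DAYS[a] for a in ages],
        "layer": layer,
        "replicate": list(range(1, n + 1)),
    }, index=df.columns)
    if lengths is not None:
        lengths = pd.Series(lengths, dtype=float)
    return ExpressionMatrix(df, meta, layer, lengths)
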