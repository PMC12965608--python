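import numpy as np
import pandas as pd
import pytest

from dualnet.schema import CohortTable, VariableSchema
from dualnet.transforms import TransformedDataset


def continuous_view(x, names=None, kind="npn"):
    """Wrap a numeric array as a continuous TransformedDataset."""
    x = np.asarray(x, dtype=float)
    if names is None:
        names = [f"v{j}" for j in range(x.shape[1])]
    schema = [VariableSchema(n) for n in names]
    table = CohortTable(pd.DataFrame(x, columns=names), schema)
    return TransformedDataset(kind=kind, table=table)


def discrete_view(codes, names=None, kind="disc3"):
    """Wrap integer codes as a discrete TransformedDataset."""
    codes = np.asarray(codes, dtype=float)
    if names is None:
        names = [f"v{j}" for j in range(codes.shape[1])]
    schema = [VariableSchema(n) for n in names]
    table = CohortTable(pd.DataFrame(codes, columns=names), schema)
    return TransformedDataset(kind=kind, table=table)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def simple_schema():
    return [
        VariableSchema("bmi", "continuous", admissible_range=(13, 90)),
        VariableSchema("mets", "continuous", admissible_range=(1, 15000)),
        VariableSchema("alcohol", "continuous"),
        VariableSchema(
            "gender", "categorical", ordinal_levels=("women", "men"),
            discretization_exempt=True, blacklist_sink_forbidden=True,
        ),
    ]
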