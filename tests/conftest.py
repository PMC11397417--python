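import numpy as np
import pandas as pd
import pytest

from phytoscore import MeasurementTable, SimulationConfig, generate_study
from phytoscore.cli_report import reference_study


@pytest.fixture(scope="session")
def ref():
    return reference_study()


@pytest.fixture(scope="session")
def default_study():
    return generate_study(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_table(default_study):
    return default_study[0]


def make_table(values: dict, regions=None, species=None, units=None) -> MeasurementTable:
    """Build a MeasurementTable from {variable: list_of_values}."""
    n = len(next(iter(values.values())))
    df = pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(n)],
            "region": regions if regions is not None else ["R1"] * n,
            "species": species if species is not None else ["sp"] * n,
            **{k: np.asarray(v, dtype=float) for k, v in values.items()},
        }
    )
    return MeasurementTable(df, units=units or {})


@pytest.fixture
def two_group_table():
    return make_table(
        {"x": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]},
        regions=["A"] * 3 + ["B"] * 3,
    )
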