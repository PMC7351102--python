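import numpy as np
import pandas as pd
import pytest

from gformula.dgp import generate_dataset, get_dgp


@pytest.fixture(scope="session")
def toy_dgp():
    return get_dgp("survival_toy", n=2000)


@pytest.fixture(scope="session")
def toy_table(toy_dgp):
    return generate_dataset(toy_dgp, seed=42)


@pytest.fixture(scope="session")
def basic_dgp():
    return get_dgp("survival_basic", n=1200)


@pytest.fixture(scope="session")
def basic_table(basic_dgp):
    return generate_dataset(basic_dgp, seed=7)


@pytest.fixture()
def tiny_survival_frame():
    """Hand-written three-subject survival table: one event, one censored
    early, one followed to the end."""
    rows = []
    # subject a: event in interval 3 (last row k=2, Y=1)
    for k, y in [(0, 0.0), (1, 0.0), (2, 1.0)]:
        rows.append({"id": "a", "t0": k, "L": k % 2, "A": 0.0, "B0": 1.5, "Y": y})
    # subject b: censored after k=1 (last Y missing)
    for k, y in [(0, 0.0), (1, np.nan)]:
        rows.append({"id": "b", "t0": k, "L": 1.0, "A": 1.0, "B0": -0.5, "Y": y})
    # subject c: survives all 4 intervals
    for k in range(4):
        rows.append({"id": "c", "t0": k, "L": 0.0, "A": 1.0, "B0": 0.0, "Y": 0.0})
    return pd.DataFrame(rows)
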