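import numpy as np
import pandas as pd
import pytest

import seedflux as sf


@pytest.fixture(scope="session")
def default_model():
    return sf.build_default_model()


@pytest.fixture(scope="session")
def reference_inputs(default_model):
    return sf.reference_expression(default_model)


@pytest.fixture(scope="session")
def wt_traj(default_model, reference_inputs):
    """Reference wild-type trajectory at default solver settings."""
    return sf.simulate(default_model, reference_inputs)


@pytest.fixture(scope="session")
def fixture_model():
    return sf.fixture_model()


@pytest.fixture(scope="session")
def fixture_inputs(fixture_model):
    return sf.reference_expression(fixture_model)


@pytest.fixture()
def toy_atlas():
    """Three genes over the seven stages, plus one ribosomal gene."""
    stages = list(sf.DEFAULT_STAGE_GRID.stage_names)
    data = {
        "g1": [2000.0, 4000.0, 1000.0, 2000.0, 2000.0, 2000.0, 2000.0],
        "g2": [1000.0, 3000.0, 1000.0, 1000.0, 1000.0, 1000.0, 1000.0],
        "g3": [1000.0, 1000.0, 1000.0, 1000.0, 1000.0, 1000.0, 1000.0],
        "r1": [5000.0, 5000.0, 5000.0, 5000.0, 5000.0, 5000.0, 5000.0],
    }
    return pd.DataFrame.from_dict(data, orient="index", dtype=float).set_axis(
        stages, axis=1
    )
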