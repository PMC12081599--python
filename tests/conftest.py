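import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from microcast.io import AbundanceSeries, SampleMetadata


@pytest.fixture
def tiny_series() -> AbundanceSeries:
    """3 samples × 2 genera with integer-day timestamps."""
    return AbundanceSeries(
        data=pd.DataFrame(
            {"Blautia": [0, 10, 2], "Coprobacter": [5, 0, 3]},
            index=["0", "1", "2"],
        ),
        subject_id="subjA",
    )


@pytest.fixture
def longer_series() -> AbundanceSeries:
    rng = np.random.default_rng(7)
    T, G = 40, 4
    data = pd.DataFrame(
        rng.integers(0, 500, size=(T, G)),
        index=[str(t) for t in range(T)],
        columns=[f"g{j}" for j in range(G)],
    )
    return AbundanceSeries(data=data, subject_id="subjB")


@pytest.fixture
def meta_for(tiny_series):
    def _build(flags, sample_ids=None, **covariates):
        ids = sample_ids or tiny_series.sample_ids
        table = pd.DataFrame(
            {"timestamp": range(len(ids)), "health_flag": flags, **covariates},
            index=ids,
        )
        return SampleMetadata(table=table)

    return _build


@pytest.fixture(scope="session")
def gut_prepared():
    """Prepared gut-dense synthetic scenario, shared across skill tests."""
    from microcast.pipeline import prepare
    from microcast.simulate import generate, scenario_library

    truth = scenario_library()["gut-dense"]
    series, meta, _ = generate(truth)
    return prepare(series, meta)
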