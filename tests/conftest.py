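import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from cohortmsm import (  # noqa: E402
    MultistateModelSpec,
    PanelDataset,
    ParameterVector,
    build_psa_onset_model,
)


@pytest.fixture
def two_state_spec() -> MultistateModelSpec:
    return MultistateModelSpec(
        n_states=2, transitions=((0, 1),), absorbing=frozenset({1}), baseline={(0, 1): "lam"}
    )


@pytest.fixture
def two_state_params() -> ParameterVector:
    return ParameterVector(log_baseline={"lam": [math.log(0.5)]})


@pytest.fixture
def table1_spec() -> MultistateModelSpec:
    return build_psa_onset_model()


@pytest.fixture
def table1_params() -> ParameterVector:
    return ParameterVector(
        log_baseline={"lambda12": [-4.379]},
        coefficients={"theta1": -0.011, "theta2": 0.117, "theta3": -0.724},
    )


@pytest.fixture
def male_cov() -> dict:
    return {"V1": 0.0, "V2": 1.0, "V3": 0.0}


@pytest.fixture
def female_cov() -> dict:
    return {"V1": 0.0, "V2": 0.0, "V3": 0.0}


def make_panel(rows) -> PanelDataset:
    return PanelDataset(pd.DataFrame(rows, columns=["subject_id", "time", "state"]))


@pytest.fixture
def simulate_two_state_panel():
    """Panel data from the two-state chain with a fixed visit schedule."""

    def _make(lam: float, n: int, visits: np.ndarray, seed: int) -> PanelDataset:
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            fail = rng.exponential(1.0 / lam)
            for t in visits:
                rows.append({"subject_id": i, "time": float(t), "state": int(t >= fail)})
                if t >= fail:
                    break
        return PanelDataset(pd.DataFrame(rows))

    return _make
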