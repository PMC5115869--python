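import numpy as np
import pytest

from zmwbind import table1_preset
from zmwbind.process import IdealizedTrace
from zmwbind.simulate import simulate_binary_cohort


@pytest.fixture(scope="session")
def presets():
    return {mid: table1_preset(mid) for mid in range(1, 8)}


@pytest.fixture(scope="session")
def model1(presets):
    return presets[1]


@pytest.fixture(scope="session")
def model2(presets):
    return presets[2]


@pytest.fixture(scope="session")
def model4(presets):
    return presets[4]


@pytest.fixture(scope="session")
def m4_cohort(model4):
    """Mid-size model-4 cohort at 1 uM, reused by dwell/heterogeneity tests."""
    return simulate_binary_cohort(
        model4, concentrations=[1e-6], n_per_conc=300, duration=120.0, seed=7
    )


def ideals_from_binary(cohort):
    """Wrap noise-free binary traces as accepted idealizations."""
    ids = cohort.molecule_ids or [f"m{i}" for i in range(len(cohort.traces))]
    return [
        IdealizedTrace(mid, np.asarray(tr, np.int8), 1.0, np.inf, None, 1,
                       True, "", c, cohort.frame_period)
        for mid, tr, c in zip(ids, cohort.traces, cohort.concentrations)
    ]


@pytest.fixture(scope="session")
def m4_ideals(m4_cohort):
    return ideals_from_binary(m4_cohort)
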