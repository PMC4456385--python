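import numpy as np
import pytest

from bgrl import CircuitParams, SubjectCondition, TaskConfig, task_circuit_params


@pytest.fixture(scope="session")
def task():
    return TaskConfig()


@pytest.fixture(scope="session")
def circuit():
    """Circuit parameters used by the behavioural simulations (accumulator)."""
    return task_circuit_params()


@pytest.fixture(scope="session")
def leaky_circuit():
    """Leaky-integrator parameters for closed-form crossing checks."""
    return CircuitParams(dt_thal=0.1, thal_leak=1.0)


@pytest.fixture(scope="session")
def conditions():
    return {g: SubjectCondition.from_group(g) for g in
            ("HC", "PD-ON-ICD", "PD-ON-nonICD", "PD-OFF")}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
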