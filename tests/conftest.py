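import numpy as np
import pytest

from lactpbpk import DrugParams, build_adult_subject, compute_partition_set
from lactpbpk.core import MaternalModel
from lactpbpk.scenarios import make_scenario, run_mother


@pytest.fixture(scope="session")
def drug():
    return DrugParams.from_file()


@pytest.fixture(scope="session")
def typical_mother():
    return build_adult_subject(0, 28.0, 78.0, 27.7)


@pytest.fixture(scope="session")
def partitions(drug):
    return compute_partition_set(drug)


@pytest.fixture(scope="session")
def maternal_model(typical_mother, drug):
    return MaternalModel(typical_mother, drug)


@pytest.fixture(scope="session")
def single_joint_result():
    """Typical-subject single-joint simulation, reused across tests."""
    return run_mother(make_scenario("smoke_single_joint"))
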