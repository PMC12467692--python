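from pathlib import Path

import pytest
from hypothesis import settings

from porecall import build_transitions, synth_pore_model

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture(scope="session")
def model_k2():
    return synth_pore_model(2, seed=7)


@pytest.fixture(scope="session")
def model_k3():
    return synth_pore_model(3, seed=7)


@pytest.fixture(scope="session")
def struct_k2():
    return build_transitions(2)


@pytest.fixture(scope="session")
def struct_k3():
    return build_transitions(3)
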