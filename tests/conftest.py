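import numpy as np
import pytest

from spherout import angles_from_table, load_eye_data


@pytest.fixture(scope="session")
def eye_table():
    return load_eye_data()


@pytest.fixture(scope="session")
def eye_table_modified():
    return load_eye_data(modified=True)


@pytest.fixture(scope="session")
def eye_vectors(eye_table):
    return angles_from_table(eye_table)


@pytest.fixture(scope="session")
def eye_vectors_modified(eye_table_modified):
    return angles_from_table(eye_table_modified)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)


def random_unit_vectors(n, rng):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)
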