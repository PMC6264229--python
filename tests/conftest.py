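import pytest

from esteropt import dataset, doe


@pytest.fixture(scope="session")
def reference_records():
    return dataset.load_reference()


@pytest.fixture(scope="session")
def reference_split(reference_records):
    return dataset.split_records(reference_records)


@pytest.fixture(scope="session")
def factors():
    return doe.esterification_factors()
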