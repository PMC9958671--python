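import pytest

import urometab as um


@pytest.fixture(scope="session")
def study():
    """Deterministic small paired study used across the suite."""
    return um.fixture_small()


@pytest.fixture(scope="session")
def proc(study):
    return um.prep.preprocess(study.urine, study.samples, study.annotation)


@pytest.fixture(scope="session")
def design(study):
    return um.mixedfx.LmmDesign.from_samples(study.samples)


@pytest.fixture(scope="session")
def lmm_results(proc, study):
    return um.mixedfx.contrast_table(proc, study.samples)
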