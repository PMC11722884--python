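import pytest

from dietwf import SynthConfig, gen_food_db, gen_pattern, load_fixture


@pytest.fixture(scope="session")
def italy():
    return load_fixture("italy")


@pytest.fixture(scope="session")
def usa():
    return load_fixture("usa")


@pytest.fixture(scope="session")
def spain():
    return load_fixture("spain")


@pytest.fixture()
def synth_cfg():
    return SynthConfig(seed=42, n_foods=30, n_categories=12)


@pytest.fixture()
def synth_db(synth_cfg):
    return gen_food_db(synth_cfg)


@pytest.fixture()
def synth_pattern(synth_cfg, synth_db):
    pattern, _spec = gen_pattern(synth_cfg, synth_db)
    return pattern
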