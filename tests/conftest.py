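import pytest
from hypothesis import settings

import carecascade as cc

settings.register_profile("suite", derandomize=True, max_examples=100, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def depression_config():
    return cc.builtin_depression_scenarios()


@pytest.fixture(scope="session")
def depression_report(depression_config):
    return cc.run_model(depression_config)
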