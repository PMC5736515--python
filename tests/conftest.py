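import pytest

from rxnspace.derive import derive_rules
from rxnspace.fixtures import generate_fixtures


@pytest.fixture(scope="session")
def rules19():
    return derive_rules()


@pytest.fixture(scope="session")
def rule_r1(rules19):
    (r1,) = [r for r in rules19 if r.rule_id == "R1"]
    return r1


@pytest.fixture(scope="session")
def fixture_set():
    return generate_fixtures(seed=0)
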