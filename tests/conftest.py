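import datetime as dt

import pytest

from sdli import (
    DeathRecord,
    SeizureRecord,
    SubstanceMapping,
    generate_market,
    ohio2017_like,
)


@pytest.fixture(scope="session")
def identity_mapping():
    return SubstanceMapping.default()


@pytest.fixture(scope="session")
def small_market():
    """One reduced-size ohio-like market realization, shared across tests."""
    params = ohio2017_like(seed=11, scale=0.1)
    seizures, deaths, log = generate_market(params)
    return params, seizures, deaths, log


def make_seizure(sid, year, substances, month=6, day=15):
    return SeizureRecord(sid, dt.date(year, month, day), frozenset(substances))


def make_death(did, year, substances, icd10="X42", month=6, day=15):
    return DeathRecord(did, dt.date(year, month, day), icd10, frozenset(substances))
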