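import logging

import pytest

from biodeduce import csc_death_fixture, tp53_fixture


@pytest.fixture(autouse=True)
def _quiet_engine_warnings():
    """Self-pair deletions log a deliberate warning; keep bulk runs quiet."""
    logger = logging.getLogger("biodeduce.zsyntax")
    old = logger.level
    logger.setLevel(logging.ERROR)
    yield
    logger.setLevel(old)


@pytest.fixture
def tp53_problem():
    return tp53_fixture()


@pytest.fixture
def csc_problem():
    return csc_death_fixture()
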