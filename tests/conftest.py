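import numpy as np
import pytest

from codonopt import CodonPairScoreTable, CodonUsageTable, GeneticCode


@pytest.fixture(scope="session")
def code():
    return GeneticCode.standard()


@pytest.fixture(scope="session")
def rule_table():
    return CodonPairScoreTable.from_rules()


@pytest.fixture(scope="session")
def uniform_usage(code):
    return CodonUsageTable.uniform(code)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
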