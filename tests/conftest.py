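import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from polytg.synthetic import fixture_set, grammar_smiles  # noqa: E402


@pytest.fixture(scope="session")
def fixtures():
    return fixture_set()


@pytest.fixture(scope="session")
def grammar_pool():
    return grammar_smiles()
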