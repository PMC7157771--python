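import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from tnta.reference import load_reference_library


@pytest.fixture(scope="session")
def library():
    return load_reference_library()
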