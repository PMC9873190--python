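import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the test-only oracles


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def uneven_zt():
    """46 uneven ZT values spanning the full [-6, 18) window."""
    r = np.random.default_rng(7)
    return np.sort(r.uniform(-6.0, 18.0, size=46))
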