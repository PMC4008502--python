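import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from smirna import simulate  # noqa: E402


@pytest.fixture(scope="session")
def small_bundle() -> simulate.ReferenceBundle:
    """5 known miRNAs, 4 decoys, 2 planted novel precursors."""
    return simulate.generate_reference_bundle(5, 4, 2, seed=7)


@pytest.fixture(scope="session")
def default_bundle() -> simulate.ReferenceBundle:
    """The default-fixture bundle used by the end-to-end checks."""
    return simulate.generate_reference_bundle(10, 8, 2, seed=42)
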