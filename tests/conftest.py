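import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from nr2dbd import Config, synth


@pytest.fixture(scope="session")
def config() -> Config:
    return Config()


@pytest.fixture(scope="session")
def small_panel():
    """One copy of every template and decoy, with ground truth."""
    return synth.make_panel(1, seed=42)


@pytest.fixture(scope="session")
def recovery_panel():
    """100 positives (20 copies of each of the five P-P templates)."""
    records, truths = synth.make_panel(20, seed=20260925)
    keep = [(r, t) for r, t in zip(records, truths)
            if t.pp_module is not None]
    assert len(keep) == 100
    return keep
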