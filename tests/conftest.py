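import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/util.py

from lucfam import synthdata as sd


@pytest.fixture(scope="session")
def two_family_truth():
    """A small two-family simulation shared across read-only tests."""
    cfg = sd.SimConfig(
        seed=11,
        families=[
            sd.FamilyConfig(name="F1", n_copies=3, target_ks_within=0.15, omega=0.05),
            sd.FamilyConfig(name="F2", parent="F1", target_ks_between=0.5,
                            n_copies=3, target_ks_within=0.15, omega=0.05),
        ],
        samples=2,
    )
    return sd.simulate_family_set(cfg)
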