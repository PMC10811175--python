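import numpy as np
import pytest

from tricot import TrialTruth, simulate_trial


@pytest.fixture(scope="session")
def five_item_trial():
    """300-farm trial from a known 5-item worth vector (single regime)."""
    truth = TrialTruth(
        ("V1", "V2", "V3", "V4", "V5"), (0.8, 0.4, 0.0, -0.4, -0.8)
    )
    return simulate_trial(truth, 300, seed=20240101)


@pytest.fixture(scope="session")
def symmetric_rankings():
    """Every permutation of {A, B, C} exactly once: perfectly symmetric."""
    import itertools

    return [tuple(p) for p in itertools.permutations(("A", "B", "C"))]
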