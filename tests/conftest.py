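import numpy as np
import pytest

import stenovoice as sv
from stenovoice.sweep import SweepConfig, run_sweep


@pytest.fixture(scope="session")
def baseline_series():
    """One baseline (no stenosis) simulation shared across tests."""
    return sv.simulate(duration=0.08)


@pytest.fixture(scope="session")
def baseline_report(baseline_series):
    return sv.analyze_series(baseline_series)


@pytest.fixture(scope="session")
def default_sweep():
    """The full default severity × location sweep (14 runs)."""
    return run_sweep(SweepConfig())


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
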