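"""Shared fixtures: one desk-scale synthetic cohort reused across modules."""

import pytest

from bchromkit.simulate import TruthSpec, simulate_cohort


@pytest.fixture(scope="session")
def spec1() -> TruthSpec:
    """Default study conditions with a fixed seed."""
    return TruthSpec(seed=1)


@pytest.fixture(scope="session")
def cohort1(spec1):
    """One fully simulated cohort shared by read-only tests."""
    return simulate_cohort(spec1)
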