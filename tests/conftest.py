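import numpy as np
import pytest

from gmsubtype import SimulationSpec, default_schema, simulate_cohort


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (n=165, planted 49/76/40 design)."""
    return simulate_cohort(SimulationSpec(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort for fast I/O and plumbing tests."""
    spec = SimulationSpec(n_per_cluster=(8, 10, 6),
                          center_mix=((3, 1, 1, 1),) * 3, seed=5)
    return simulate_cohort(spec), spec
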