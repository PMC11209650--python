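import numpy as np
import pytest

import reachadapt as ra


@pytest.fixture(scope="session")
def schedule():
    return ra.build_schedule()


@pytest.fixture(scope="session")
def small_cohort():
    """Four synthetic participants on the default schedule."""
    return ra.recovery_dataset(4, seed=11)


@pytest.fixture(scope="session")
def reduced_fit(small_cohort):
    """Reduced-profile hierarchical fit of the small cohort (shared across
    tests to keep the suite fast)."""
    model = ra.HierarchicalDualRate.from_cohort(small_cohort)
    return model.fit(profile="reduced", seed=0)


@pytest.fixture(scope="session")
def fig6_sims(schedule):
    """Noise-free simulations with the published deterministic parameter sets."""
    return {
        g: ra.simulate(ra.DualRateParams.fig6(g), schedule) for g in ("control", "patient")
    }
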