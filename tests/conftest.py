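import numpy as np
import pytest

from circamasld import actigraphy, synth


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort with strong planted mediation structure."""
    cfg = synth.SynthConfig(n_participants=2500, n_proteins=120, n_mediators=8,
                            seed=42)
    return synth.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort_ra(small_cohort):
    """RA metrics table for the session cohort."""
    return actigraphy.metrics_table(small_cohort.profiles)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
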