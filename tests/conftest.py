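import numpy as np
import pytest

from embryodyn.simulate import SimConfig, simulate_all

BALANCED_ONLY = {
    "balanced": 1.0,
    "A-dominant": 0.0, "B-dominant": 0.0, "D-dominant": 0.0,
    "A-suppressed": 0.0, "B-suppressed": 0.0, "D-suppressed": 0.0,
}


def small_config(seed: int = 7, **overrides) -> SimConfig:
    """A reduced genome that keeps unit tests fast but structurally complete."""
    cfg = SimConfig(
        seed=seed,
        chrom_length_bp=700_000,
        n_triads=80,
        n_singletons=30,
        transient_dacr_count=60,
        constant_dacr_count=80,
        background_dacr_count=15,
        targets_per_tf=2,
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    cfg.validate()
    return cfg


@pytest.fixture(scope="session")
def small_ds():
    return simulate_all(small_config())


@pytest.fixture(scope="session")
def default_ds():
    """One full-size dataset at the default study conditions."""
    return simulate_all(SimConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
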