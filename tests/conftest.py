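import numpy as np
import pytest

from bullseye import make_phantom_brain, parcellate, simulate_cohort
from bullseye.quantify import adjust_etiv, log_transform, table_from_cohort


@pytest.fixture(scope="session")
def small_brain():
    """48^3 phantom — fast, still populates all 36 parcels."""
    return make_phantom_brain(shape=(48, 48, 48), seed=7)


@pytest.fixture(scope="session")
def small_bullseye(small_brain):
    return parcellate(
        small_brain.ventricle_mask,
        small_brain.cortex_mask,
        small_brain.wm_mask,
        small_brain.lobar_labels,
    )


@pytest.fixture(scope="session")
def default_brain():
    """Default 96^3 phantom (the acceptance-target configuration)."""
    return make_phantom_brain(seed=0)


@pytest.fixture(scope="session")
def default_bullseye(default_brain):
    return parcellate(
        default_brain.ventricle_mask,
        default_brain.cortex_mask,
        default_brain.wm_mask,
        default_brain.lobar_labels,
    )


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(n=108, seed=11)


@pytest.fixture(scope="session")
def default_log_table(default_cohort):
    return log_transform(adjust_etiv(table_from_cohort(default_cohort.table)))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
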