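import pytest

from mammosim import (
    SCREENED,
    UNSCREENED,
    build_schedule,
    default_demography,
    sweep_ages,
)


@pytest.fixture(scope="session")
def demog():
    """Calibrated synthetic demography shared across the suite."""
    return default_demography()


@pytest.fixture(scope="session")
def schedules():
    return {
        "screened": build_schedule(SCREENED),
        "unscreened": build_schedule(UNSCREENED),
    }


@pytest.fixture(scope="session")
def sweep_full(demog):
    """The full 21-cohort, 50-replicate age sweep (one computation per session)."""
    return sweep_ages(demog, master_seed=1, replicates=50)
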