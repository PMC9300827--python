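import pytest

from dexdyn.synthlib import (
    SimParams,
    make_library,
    simulate_cohort,
    simulate_counts,
)


@pytest.fixture(scope="session")
def small_params() -> SimParams:
    return SimParams(n_patients=5, library_size=24, depth=3e4, seed=11)


@pytest.fixture(scope="session")
def small_library(small_params):
    return make_library(small_params)


@pytest.fixture(scope="session")
def small_truth(small_params):
    return simulate_cohort(small_params)


@pytest.fixture(scope="session")
def small_screen(small_truth, small_library, small_params):
    """(CountMatrix, SampleSheet) for the small planted cohort."""
    return simulate_counts(small_truth, small_library, small_params)


def truth_pairs(truth) -> set[tuple[str, str]]:
    """Planted (sample_id, pmhc_id) response pairs of a cohort truth."""
    pairs = set()
    for p in truth.patients:
        pairs |= {(f"{p.patient_id}_BL", pm) for pm in p.present_bl}
        pairs |= {(f"{p.patient_id}_FU", pm) for pm in p.present_fu}
    return pairs
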