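import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from neonet.cohort import CohortConfig, generate_cohort, records_frame


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size synthetic cohort: 65 subjects, 8 scanned twice, seed 1."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def default_metadata(default_cohort):
    return records_frame(default_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """Small cohort for fast pipeline tests: 12 subjects, 3 repeats, 40 nodes."""
    return generate_cohort(
        CohortConfig(n_subjects=12, n_repeat_scans=3, node_count=40, seed=5)
    )
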