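"""Shared fixtures: small deterministic synthetic cohorts."""

from pathlib import Path

import pytest

from sarcnet.simulate import SimConfig, generate_frame

DATA_DIR = Path(__file__).parent / "data"

TIMEPOINTS = ("preop", "h48", "d7", "w13")

#: Config of the checked-in synthetic fixture tests/data/tiny_cohort.csv
#: (regenerate with sarcnet.cohort.write_cohort_csv(generate_frame(TINY_CONFIG), path)).
TINY_CONFIG = SimConfig(seed=12, group_sizes={"elective": 4, "emergency": 3,
                                              "medical": 5})


def complete_config(**overrides) -> SimConfig:
    """A config with no missingness, full retention and no visit schedule."""
    defaults = dict(
        missing_rates={tp: 0.0 for tp in TIMEPOINTS},
        retention={tp: 1.0 for tp in TIMEPOINTS},
        assessment_schedule=False,
        bio_coverage_h48=1.0,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_frame():
    return generate_frame(TINY_CONFIG)


@pytest.fixture(scope="session")
def study_frame():
    """A default-condition cohort (sizes 24/14/41, study-like missingness)."""
    return generate_frame(SimConfig(seed=11))


@pytest.fixture(scope="session")
def complete_frame():
    return generate_frame(complete_config(seed=5))
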