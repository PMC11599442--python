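"""Shared fixtures: small synthetic registers and pipeline runs."""
from __future__ import annotations

import pytest

from coexpose import StudyConfig, generate_register
from coexpose.pipeline import run_pipeline

VALIDATION_SEED = 20240101


@pytest.fixture(scope="session")
def register600():
    """The validation register: mixed 1-4-drug regimens, one FDC, gaps, decoys."""
    return generate_register(600, seed=VALIDATION_SEED)


@pytest.fixture(scope="session")
def pipeline600(register600):
    return run_pipeline(
        register600.records,
        StudyConfig(),
        fdc_map=register600.fdc_map,
        censoring=register600.censoring,
    )
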