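import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from fishlabel import (
    load_default_designations,
    load_default_taxa,
    load_paper_fixture,
    run_fixture_audit,
)


@pytest.fixture(scope="session")
def registry():
    return load_default_taxa()


@pytest.fixture(scope="session")
def designations():
    return load_default_designations()


@pytest.fixture(scope="session")
def audit_fixture():
    return load_paper_fixture()


@pytest.fixture(scope="session")
def fixture_audit_results():
    """Verdicts and report for the packaged 115-sample audit."""
    return run_fixture_audit()
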