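import pytest

from clonetrack.fixtures import (
    AMPLICON_ROWS,
    PANEL_CALLS,
    index_repertoire,
    panel_pileups,
)


@pytest.fixture(scope="session")
def panel_maps():
    """(normal, tumor, genes) pileup maps for the 14-site panel fixture."""
    return panel_pileups()


@pytest.fixture(scope="session")
def amplicon_rows():
    return AMPLICON_ROWS


@pytest.fixture(scope="session")
def panel_rows():
    return PANEL_CALLS


@pytest.fixture()
def two_part_repertoire():
    """Dominant paired clone + matching beta-only orphan over background."""
    return index_repertoire()
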