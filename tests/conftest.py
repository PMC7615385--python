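import pytest

from lapkit.labware import load_labware_catalog, make_pipette


@pytest.fixture(scope="session")
def catalog():
    return load_labware_catalog()


@pytest.fixture(scope="session")
def pipette_pair():
    """The standard two-pipette setup: small on the left, large on the
    right."""
    return [make_pipette("left", "p20_single"),
            make_pipette("right", "p300_single")]
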