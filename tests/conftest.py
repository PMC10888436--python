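import pytest

from circbact.mining import ReferencePanel


@pytest.fixture(scope="session")
def panel() -> ReferencePanel:
    return ReferencePanel.bundled()


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Synthetic genome + peak lists written once per session (seed 7)."""
    from circbact.synthdata import NoiseParams, write_fixture

    out = tmp_path_factory.mktemp("fixture")
    return write_fixture(7, out, noise=NoiseParams())
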