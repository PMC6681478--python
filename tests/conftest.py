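import hypothesis
import pytest

from protpi.tables import get_pka_set, load_mass_table

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=25, deadline=None
)
hypothesis.settings.load_profile("default")


@pytest.fixture(scope="session")
def pka():
    return get_pka_set()


@pytest.fixture(scope="session")
def masses():
    return load_mass_table()


@pytest.fixture()
def fasta_file(tmp_path):
    """Write FASTA text to a temp file and return its path."""

    def write(text, name="test.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return write
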