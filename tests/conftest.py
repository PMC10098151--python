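import numpy as np
import pytest


@pytest.fixture
def rng():
    """Deterministic generator shared by randomized tests."""
    return np.random.default_rng(20231)


@pytest.fixture
def fasta_file(tmp_path):
    """Factory writing FASTA text to a temp file."""

    def _write(text: str, name: str = "input.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write
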