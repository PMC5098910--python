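import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from idrscape.physchem import EMBOSS_PKS


@pytest.fixture
def pks_dict() -> dict[str, float]:
    """The default pK set as a plain dict, for oracle use."""
    return dict(EMBOSS_PKS.values)


@pytest.fixture
def fasta_file(tmp_path):
    """Write FASTA text to a temp file and return its path."""

    def _write(text: str, name: str = "toy.fa") -> Path:
        p = tmp_path / name
        p.write_text(text)
        return p

    return _write
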