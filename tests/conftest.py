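import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from matchvar.fixtures import evolve, random_protein


@pytest.fixture
def toy_pair():
    """A length-200 synthetic ortholog pair with mild divergence."""
    parent = random_protein(200, seed=11, accession="SYN_HUM")
    return evolve(parent, sub_rate=0.05, indel_rate=0.01, seed=12,
                  child_accession="SYN_WRM")


@pytest.fixture
def tmp_fasta(tmp_path):
    def _write(name, entries):
        path = tmp_path / name
        path.write_text("".join(f">{acc}\n{seq}\n" for acc, seq in entries))
        return path

    return _write
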