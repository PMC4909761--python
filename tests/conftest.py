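import pytest

from aoxaudit.fingerprints import default_motifs
from aoxaudit.seqio import SequenceRecord


def protein(id: str, residues: str, **kw) -> SequenceRecord:
    return SequenceRecord(id=id, residues=residues, alphabet="protein", **kw)


def nucleotide(id: str, residues: str, **kw) -> SequenceRecord:
    return SequenceRecord(id=id, residues=residues, alphabet="nucleotide", **kw)


@pytest.fixture(scope="session")
def motifs():
    return default_motifs()
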