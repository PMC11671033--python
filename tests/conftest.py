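import pytest

from seqlensplit import SequenceRecord, write_fasta


@pytest.fixture
def make_fasta(tmp_path):
    """Write records (or raw (id, desc, residues) tuples) to a temp FASTA."""

    def _make(records, name="input.fasta", wrap_width=60):
        recs = [
            r if isinstance(r, SequenceRecord) else SequenceRecord(*r)
            for r in records
        ]
        path = tmp_path / name
        write_fasta(recs, path, wrap_width=wrap_width)
        return path

    return _make
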