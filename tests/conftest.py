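import pytest

from serpinkit.seq_io import load_rice_fixture


@pytest.fixture(scope="session")
def rice_fixture():
    return load_rice_fixture()


@pytest.fixture(scope="session")
def rice_loci(rice_fixture):
    return rice_fixture.loci


@pytest.fixture
def write_fasta_file(tmp_path):
    def _write(entries, name="seqs.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in entries:
                fh.write(f">{rid}\n{seq}\n")
        return path

    return _write
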