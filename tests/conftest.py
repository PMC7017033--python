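import pytest

from idpsol import (
    PUBLISHED_PARAMS,
    ProteinSequence,
    load_ionization_table,
    load_lipophilicity_scale,
)


@pytest.fixture(scope="session")
def table():
    return load_ionization_table()


@pytest.fixture(scope="session")
def scale():
    return load_lipophilicity_scale()


@pytest.fixture(scope="session")
def params():
    return PUBLISHED_PARAMS


@pytest.fixture
def poly_ala_blocked():
    return ProteinSequence(
        id="polyA", residues="A" * 20, n_term_blocked=True, c_term_blocked=True
    )


@pytest.fixture
def fasta_file(tmp_path):
    """Factory writing a FASTA file from (header, sequence) pairs."""

    def _write(records, name="input.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for header, seq in records:
                fh.write(f">{header}\n{seq}\n")
        return path

    return _write
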