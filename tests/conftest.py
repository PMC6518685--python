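import pytest

from ltpscan.ecm_classifier import load_templates


@pytest.fixture(scope="session")
def templates():
    return load_templates()


@pytest.fixture
def write_fasta_file(tmp_path):
    def _write(records, name="seqs.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rec_id, seq in records:
                fh.write(f">{rec_id}\n{seq}\n")
        return path

    return _write


def build_ecm(spacers, filler="A"):
    """Assemble an ECM core sequence from five spacer lengths."""
    s1, s2, s3, s4, s5 = spacers
    return ("C" + filler * s1 + "C" + filler * s2 + "CC" + filler * s3
            + "C" + filler + "C" + filler * s4 + "C" + filler * s5 + "C")
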