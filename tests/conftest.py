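import pytest


@pytest.fixture
def write_text(tmp_path):
    """Write a named text file into tmp_path and return its path."""

    def _write(name: str, content: str):
        p = tmp_path / name
        p.write_text(content)
        return p

    return _write


@pytest.fixture
def two_record_fasta(write_text):
    return write_text(
        "two.fasta",
        ">p1 first protein\nMKKA\n>p2\nggcdef\n",
    )
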