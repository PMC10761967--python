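import pytest
from hypothesis import settings

from irscreen import ProteinRecord, write_fasta

settings.register_profile("stable", deadline=None, derandomize=True)
settings.load_profile("stable")

PANEL = ("human", "house_mouse", "bovine", "rabbit")


@pytest.fixture
def panel():
    return PANEL


@pytest.fixture
def toy_records():
    """A two-gene, four-species panel with isoform variants for one gene."""
    return [
        ProteinRecord("ACC1", "GENEA", "human", "MKTAYIAKQR"),
        ProteinRecord("ACC2", "GENEA", "human", "MKTAYIAKQRQISFVK"),  # longest
        ProteinRecord("ACC3", "GENEA", "house_mouse", "MKTAYLAKQRQISFVK"),
        ProteinRecord("ACC4", "GENEA", "bovine", "MKTAYIAKQRQISFVR"),
        ProteinRecord("ACC5", "GENEA", "rabbit", "MKTAYIAKQRQISYVK"),
        ProteinRecord("ACC6", "GENEB", "human", "MSGRGKQGGKARAKAK"),
        ProteinRecord("ACC7", "GENEB", "house_mouse", "MSGRGKQGGKARAKAK"),
    ]


@pytest.fixture
def toy_fasta(tmp_path, toy_records):
    path = tmp_path / "toy.fasta"
    write_fasta(toy_records, path)
    return path
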