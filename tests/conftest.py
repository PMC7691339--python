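import numpy as np
import pytest

from cysmotif.records import SequenceRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20231115)


def random_protein(rng, length, alphabet="ACDEFGHIKLMNPQRSTVWY", p=None):
    letters = np.array(list(alphabet))
    if p is not None:
        return "".join(letters[rng.choice(len(letters), size=length, p=p)])
    return "".join(letters[rng.integers(0, len(letters), size=length)])


def random_dna(rng, length):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def protein_record(rng, rec_id, length, **kw):
    return SequenceRecord(rec_id, random_protein(rng, length, **kw))
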