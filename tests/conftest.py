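import numpy as np
import pytest

from ampliqc.model import MarkerSpec, PreparedSequence, ReadPair, ReadRecord, Stream


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_seq(rng, length: int) -> str:
    return "".join(rng.choice(["A", "C", "G", "T"], size=length))


def mutate(rng, seq: str, n_changes: int) -> str:
    """Substitute exactly n distinct positions."""
    s = list(seq)
    for i in rng.choice(len(s), size=n_changes, replace=False):
        s[i] = rng.choice([b for b in "ACGT" if b != s[i]])
    return "".join(s)


def read(bases: str, q: int = 38, read_id: str = "r") -> ReadRecord:
    return ReadRecord(read_id, bases, np.full(len(bases), q, dtype=np.int16))


def pair_from_template(template: str, read_len: int, read_id: str = "p") -> ReadPair:
    from ampliqc.seq import revcomp

    r1 = read(template[:read_len], read_id=read_id)
    r2 = read(revcomp(template)[:read_len], read_id=read_id)
    return ReadPair(r1, r2)


def prepared(bases: str, abundance: int = 1, sid: str = "s1", marker: str = "M") -> PreparedSequence:
    return PreparedSequence(sid, marker, bases, abundance, Stream.MERGED)
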