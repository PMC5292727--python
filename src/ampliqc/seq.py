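"""Small sequence utilities: complements, IUPAC matching, translation."""

from __future__ import annotations

from Bio.Seq import Seq

_COMP = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                      "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

# IUPAC degeneracy expansion
IUPAC_BASES: dict[str, frozenset] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def iupac_match(pattern_base: str, read_base: str) -> bool:
    """Does a read base satisfy a (possibly degenerate) primer base?

    An N in the read matches anything; unknown characters match nothing.
    """
    if read_base == "N":
        return True
    allowed = IUPAC_BASES.get(pattern_base.upper())
    return allowed is not None and read_base.upper() in allowed


def hamming_iupac(pattern: str, window: str) -> int:
    """IUPAC-aware mismatch count between a primer and an equal-length window."""
    if len(pattern) != len(window):
        raise ValueError("hamming_iupac requires equal lengths")
    return sum(0 if iupac_match(p, w) else 1 for p, w in zip(pattern, window))


def translate(seq: str, frame: int, table_id: int) -> str:
    """Translate from ``frame`` (0..2), dropping the terminal partial codon."""
    s = seq[frame:]
    s = s[: len(s) - len(s) % 3]
    if not s:
        return ""
    return str(Seq(s).translate(table=table_id))


def has_internal_stop(aa: str) -> bool:
    """A stop anywhere in the translated fragment of a mid-gene amplicon."""
    return "*" in aa
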