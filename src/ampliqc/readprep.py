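"""Front end of the pipeline: pair merging, marker assignment and primer
removal, quality truncation, length filtering, dereplication.

Every read pair first gets a merge attempt (end-overlap of R1 against the
reverse complement of R2). Merged reads flow as one plus-strand sequence;
unmerged pairs are processed as separate read-1 / read-2 streams, with the
read-2 stream reverse-complemented right after primer removal so that all
downstream sequences are plus-strand.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .model import MarkerSpec, PreparedSequence, ReadPair, ReadRecord, Stream
from .seq import hamming_iupac, revcomp


# ------------------------------------------------------------------ merge

@dataclass
class MergeResult:
    merged: Optional[ReadRecord]  # None -> no_overlap
    overlap: int = 0
    mismatches: int = 0

    @property
    def tag(self) -> str:
        return "merged" if self.merged is not None else "no_overlap"


def merge_pair(
    pair: ReadPair, min_overlap: int = 25, max_mismatch_rate: float = 0.25
) -> MergeResult:
    """Merge R1 with the reverse complement of R2 by best end overlap.

    Every candidate overlap length is scored by its mismatch rate over the
    overlap (positions where either base is N are not counted as
    mismatches); the lowest rate wins, longer overlap breaking ties. If the
    best candidate has rate <= ``max_mismatch_rate`` the pair is merged:
    disagreeing positions take the higher-quality base (ties -> R1) and the
    merged quality is the max of the two.
    """
    r1, r2rc = pair.r1, pair.r2.reverse_complement()
    b1 = np.frombuffer(r1.bases.encode(), dtype="S1")
    b2 = np.frombuffer(r2rc.bases.encode(), dtype="S1")
    L1, L2 = len(b1), len(b2)
    if L1 == 0 or L2 == 0:
        return MergeResult(None)
    best = None  # (rate, overlap, mismatches)
    for ov in range(min(L1, L2), min_overlap - 1, -1):
        s1 = b1[L1 - ov :]
        s2 = b2[:ov]
        neq = s1 != s2
        informative = (s1 != b"N") & (s2 != b"N")
        mism = int(np.count_nonzero(neq & informative))
        rate = mism / ov
        if best is None or rate < best[0]:
            best = (rate, ov, mism)
    if best is None or best[0] > max_mismatch_rate:
        return MergeResult(None)
    rate, ov, mism = best
    q1 = r1.quals[L1 - ov :]
    q2 = r2rc.quals[:ov]
    take2 = q2 > q1  # ties -> R1 base
    over_b1 = b1[L1 - ov :].copy()
    over_b1[take2] = b2[:ov][take2]
    merged_bases = (
        b1[: L1 - ov].tobytes() + over_b1.tobytes() + b2[ov:].tobytes()
    ).decode()
    merged_quals = np.concatenate(
        [r1.quals[: L1 - ov], np.maximum(q1, q2), r2rc.quals[ov:]]
    )
    rec = ReadRecord(r1.read_id, merged_bases, merged_quals)
    return MergeResult(rec, overlap=ov, mismatches=mism)


# -------------------------------------------------------- marker assignment

@dataclass
class Assignment:
    marker: MarkerSpec
    trimmed: "ReadRecord | ReadPair"
    mismatches: int
    offset: int
    ambiguous: bool = False


def _find_primer(
    bases: str, primer: str, max_mismatches: int, max_spacer: int
) -> Optional[tuple[int, int]]:
    """Best (offset, mismatches) of a primer at 5' offsets 0..max_spacer."""
    lp = len(primer)
    best = None
    for off in range(0, max_spacer + 1):
        window = bases[off : off + lp]
        if len(window) < lp:
            break
        m = hamming_iupac(primer, window)
        if m <= max_mismatches and (best is None or m < best[1]):
            best = (off, m)
    return best


def assign_marker(
    item: "ReadRecord | ReadPair",
    markers: Sequence[MarkerSpec],
    max_primer_mismatches: int = 1,
    max_spacer: int = 3,
) -> Optional[Assignment]:
    """Assign a merged read or an unmerged pair to a marker and strip
    spacer + primer bases.

    Merged reads must show the forward primer near the 5' end and the
    reverse-complemented reverse primer near the 3' end; unmerged pairs
    must show the forward primer on R1 and the reverse primer on R2 (each
    at its own 5' end). Ties are broken by fewest total mismatches, then by
    marker order in the configuration (the tie is recorded as ambiguous).
    """
    candidates = []  # (total_mism, config_index, assignment pieces)
    for idx, mk in enumerate(markers):
        if isinstance(item, ReadRecord):
            hit_f = _find_primer(item.bases, mk.fwd_primer, max_primer_mismatches, max_spacer)
            if hit_f is None:
                continue
            # the reverse primer sits reverse-complemented at the 3' end
            # (possibly followed by a spacer); search it on the revcomp
            hit_r = _find_primer(
                revcomp(item.bases), mk.rev_primer, max_primer_mismatches, max_spacer
            )
            if hit_r is None:
                continue
            off_f, m_f = hit_f
            off_r, m_r = hit_r
            start = off_f + len(mk.fwd_primer)
            end = len(item.bases) - off_r - len(mk.rev_primer)
            if end <= start:
                continue
            trimmed = ReadRecord(item.read_id, item.bases[start:end], item.quals[start:end])
            candidates.append((m_f + m_r, idx, Assignment(mk, trimmed, m_f + m_r, off_f)))
        else:
            hit_f = _find_primer(item.r1.bases, mk.fwd_primer, max_primer_mismatches, max_spacer)
            hit_r = _find_primer(item.r2.bases, mk.rev_primer, max_primer_mismatches, max_spacer)
            if hit_f is None or hit_r is None:
                continue
            off_f, m_f = hit_f
            off_r, m_r = hit_r
            s1 = off_f + len(mk.fwd_primer)
            s2 = off_r + len(mk.rev_primer)
            trimmed = ReadPair(
                ReadRecord(item.r1.read_id, item.r1.bases[s1:], item.r1.quals[s1:]),
                ReadRecord(item.r2.read_id, item.r2.bases[s2:], item.r2.quals[s2:]),
            )
            candidates.append((m_f + m_r, idx, Assignment(mk, trimmed, m_f + m_r, off_f)))
    if not candidates:
        return None
    candidates.sort(key=lambda c: (c[0], c[1]))
    best = candidates[0][2]
    if len(candidates) > 1 and candidates[1][0] == candidates[0][0]:
        best.ambiguous = True
    return best


# -------------------------------------------------------------- filtering

def quality_truncate(read: ReadRecord, q_min: int = 21) -> ReadRecord:
    """Keep the prefix ending just before the first base with Q < q_min.

    Idempotent; may return an empty read (removed by the length filter)."""
    bad = np.nonzero(read.quals < q_min)[0]
    if bad.size == 0:
        return read
    cut = int(bad[0])
    return ReadRecord(read.read_id, read.bases[:cut], read.quals[:cut])


def length_filter(
    seqs: Iterable, min_len: int, max_len: Optional[int] = None
) -> list:
    """Inclusive length bounds on strings or records with ``bases``."""
    out = []
    for s in seqs:
        n = len(s.bases) if hasattr(s, "bases") else len(s)
        if n >= min_len and (max_len is None or n <= max_len):
            out.append(s)
    return out


def dereplicate(
    seqs: Iterable[str], specimen_id: str, marker: str, origin: Stream
) -> list[PreparedSequence]:
    """Collapse exact duplicates (case-folded) into abundance-sorted uniques.

    Sorted by abundance descending, lexicographic sequence as tiebreak, so
    downstream clustering is deterministic."""
    counts = Counter(s.upper() for s in seqs)
    uniq = [
        PreparedSequence(specimen_id, marker, s, n, origin)
        for s, n in counts.items()
    ]
    uniq.sort(key=lambda u: (-u.abundance, u.bases))
    return uniq


def quality_profile(reads: Sequence[ReadRecord]) -> dict:
    """Per-read mean quality distribution, fraction reaching Q30, and the
    per-position mean quality series."""
    means = np.array([r.quals.mean() for r in reads if len(r)])
    maxlen = max((len(r) for r in reads), default=0)
    sums = np.zeros(maxlen)
    counts = np.zeros(maxlen)
    for r in reads:
        n = len(r)
        sums[:n] += r.quals
        counts[:n] += 1
    with np.errstate(invalid="ignore"):
        per_position = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return {
        "mean_q": means,
        "fraction_q30": float((means >= 30).mean()) if means.size else 0.0,
        "per_position_mean": per_position,
    }
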