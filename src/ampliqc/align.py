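"""Pairwise alignment helpers built on edlib.

All pipeline sequences are plus-strand and 5'-anchored at the primer cut,
so three alignment shapes cover every need:

* ``NW``  — global, for same-locus sequences of similar extent
  (consensus projection, p-distances, chimera parent scans);
* ``SHW`` — prefix, shorter sequence against a longer one whose 3' tail is
  free (overlap identity between quality-truncated reads / consensuses);
* ``HW``  — infix, a consensus against a full-length reference with free
  end gaps on the reference.

edlib cigar convention: ``=`` match, ``X`` mismatch, ``I`` consumes query
only (insertion in query), ``D`` consumes target only (gap in query).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Optional

import edlib

from .seq import revcomp

_CIG = re.compile(r"(\d+)([=XID])")


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIG.findall(cigar)]


def _clean(s: str) -> str:
    return s.upper()


@dataclass
class Alignment:
    """A parsed pairwise alignment of query against target."""

    query: str
    target: str
    mode: str
    edit_distance: int
    target_start: int  # start of the aligned span in the target
    target_end: int    # exclusive
    cigar: str

    @property
    def ops(self) -> list[tuple[int, str]]:
        return parse_cigar(self.cigar)

    @property
    def n_columns(self) -> int:
        return sum(n for n, _ in self.ops)

    @property
    def matches(self) -> int:
        return sum(n for n, op in self.ops if op == "=")

    @property
    def identity(self) -> float:
        cols = self.n_columns
        return self.matches / cols if cols else 0.0

    def internal_indels(self) -> list[int]:
        """Lengths of indel runs, excluding runs at either alignment end."""
        ops = self.ops
        out = []
        for i, (n, op) in enumerate(ops):
            if op in "ID" and 0 < i < len(ops) - 1:
                out.append(n)
        return out

    def columns(self) -> Iterator[tuple[Optional[int], Optional[int]]]:
        """Yield (query_pos, target_pos) per column; None marks a gap."""
        q, t = 0, self.target_start
        for n, op in self.ops:
            for _ in range(n):
                if op in "=X":
                    yield q, t
                    q += 1
                    t += 1
                elif op == "I":
                    yield q, None
                    q += 1
                else:  # D
                    yield None, t
                    t += 1


def align(query: str, target: str, mode: str = "NW") -> Alignment:
    """Full-DP edlib alignment with path; raises on empty input."""
    query, target = _clean(query), _clean(target)
    if not query or not target:
        raise ValueError("cannot align empty sequences")
    r = edlib.align(query, target, mode=mode, task="path")
    start, end = r["locations"][0]
    return Alignment(
        query=query,
        target=target,
        mode=mode,
        edit_distance=r["editDistance"],
        target_start=start if start is not None else 0,
        target_end=(end + 1) if end is not None else len(target),
        cigar=r["cigar"],
    )


def overlap_identity(a: str, b: str) -> tuple[float, int]:
    """Identity over the full shared extent of two same-locus sequences.

    The shorter sequence is aligned within the longer with free end gaps on
    the longer (infix mode), which covers both 3'-truncated (prefix) and
    5'-truncated (suffix, e.g. reverse-read) geometries. Returns
    (identity, overlap_length) where overlap length is the number of
    alignment columns.
    """
    a, b = _clean(a), _clean(b)
    if not a or not b:
        return 0.0, 0
    shorter, longer = (a, b) if len(a) <= len(b) else (b, a)
    aln = align(shorter, longer, mode="HW")
    return aln.identity, aln.n_columns


def shared_extent_identical(a: str, b: str) -> bool:
    """True if two sequences are 100% identical over their shared extent

    (the shorter aligns within the longer with no mismatches and no
    indels)."""
    a, b = _clean(a), _clean(b)
    if not a or not b:
        return False
    shorter, longer = (a, b) if len(a) <= len(b) else (b, a)
    r = edlib.align(shorter, longer, mode="HW", task="distance")
    return r["editDistance"] == 0


def best_strand_ref_align(seq: str, ref: str) -> tuple[Alignment, int]:
    """Align a consensus to a reference, trying both strands.

    Uses infix mode with the shorter of the two as query so end gaps on the
    longer sequence are free. Returns (alignment, strand); strand is -1 when
    the reverse complement of ``seq`` aligned better. The returned alignment
    always has the (possibly reverse-complemented) consensus as query and
    the reference as target; if the consensus is longer than the reference
    the roles are swapped internally and coordinates re-expressed on the
    reference (query overhangs clipped by NW in that rare case).
    """
    seq, ref = _clean(seq), _clean(ref)
    best = None
    for strand, s in ((1, seq), (-1, revcomp(seq))):
        mode = "HW" if len(s) <= len(ref) else "NW"
        aln = align(s, ref, mode=mode)
        if best is None or aln.identity > best[0].identity:
            best = (aln, strand)
    return best


def prefix_cost_profile(query: str, target: str) -> list[int]:
    """Cumulative edit cost of explaining ``query[:i]`` by the target,
    for i = 0..len(query).

    The query is aligned within the target with free target end gaps
    (infix mode), so a parent's overhang beyond the query costs nothing —
    essential for the chimera scan, where ``cost[i]`` must count only the
    non-match columns up to query position i, not length differences.
    """
    aln = align(query, target, mode="HW")
    cost = [0] * (len(query) + 1)
    c = 0
    q = 0
    for n, op in aln.ops:
        if op == "=":
            for _ in range(n):
                q += 1
                cost[q] = c
        elif op in ("X", "I"):
            for _ in range(n):
                c += 1
                q += 1
                cost[q] = c
        else:  # D: gap in query; attribute to the current query boundary
            c += n
            cost[q] = c
    return cost
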