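"""Final barcode construction.

Two joining operations run after QC: (1) the read-1 and read-2 half
consensuses of a non-overlapping marker are placed at their reference
coordinates and joined, padding any uncovered span with N (recorded as an
explicit gap interval); (2) a long and a short amplicon of the same locus
(e.g. COI-long + COI-short) are merged into the longest possible sequence
when their doubly-called positions agree exactly — any disagreement keeps
both sequences in the final set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .model import ConsensusRecord, SpecimenBarcode
from .qc import RefAlignment


class PlacementError(ValueError):
    """Halves or fragments could not be placed on a common reference."""


def _project_to_ref(ra: RefAlignment) -> dict[int, str]:
    """Map consensus bases onto reference coordinates (insertions relative
    to the reference are dropped; reference positions deleted in the
    consensus are absent from the map)."""
    out = {}
    seq = ra.oriented_sequence
    for qpos, tpos in ra.alignment.columns():
        if qpos is not None and tpos is not None:
            out[tpos] = seq[qpos]
    return out


def join_read_halves(
    rec1: Optional[ConsensusRecord],
    rec2: Optional[ConsensusRecord],
    ra1: Optional[RefAlignment],
    ra2: Optional[RefAlignment],
    marker: Optional[str] = None,
) -> SpecimenBarcode:
    """Join forward- and reverse-read half consensuses on their shared
    reference.

    If the halves abut or overlap with identical calls they are fused;
    a non-covered span between them becomes an N run recorded in
    ``gap_intervals``; conflicting overlap keeps both halves in one record
    flagged as a conflict. Either half may be absent.
    """
    present = [
        (r, a) for r, a in ((rec1, ra1), (rec2, ra2)) if r is not None
    ]
    if not present:
        raise ValueError("join_read_halves needs at least one half")
    name = marker or present[0][0].marker
    if len(present) == 1:
        rec, _ = present[0]
        return SpecimenBarcode(
            specimen_id=rec.specimen_id,
            marker=name,
            sequence=rec.sequence,
            gap_intervals=[],
            sources=[rec],
        )
    (ra, aa), (rb, ab) = present
    if aa is None or ab is None or aa.entry.ref_id != ab.entry.ref_id:
        raise PlacementError(
            f"{ra.specimen_id}/{name}: halves align to inconsistent references"
        )
    pa = _project_to_ref(aa)
    pb = _project_to_ref(ab)
    overlap_positions = set(pa) & set(pb)
    conflict = any(pa[t] != pb[t] for t in overlap_positions)
    lo = min(min(pa), min(pb))
    hi = max(max(pa), max(pb)) + 1
    seq_chars = []
    padding = []  # reference positions padded with N
    for t in range(lo, hi):
        if t in pa:
            seq_chars.append(pa[t])
        elif t in pb:
            seq_chars.append(pb[t])
        else:
            seq_chars.append("N")
            padding.append(t - lo)
    return SpecimenBarcode(
        specimen_id=ra.specimen_id,
        marker=name,
        sequence="".join(seq_chars),
        gap_intervals=_runs(padding),
        sources=[ra, rb],
        conflict=conflict,
    )


def _runs(positions: list[int]) -> list[tuple[int, int]]:
    """Collapse sorted positions into half-open [start, end) intervals."""
    if not positions:
        return []
    runs = []
    start = prev = positions[0]
    for p in positions[1:]:
        if p == prev + 1:
            prev = p
            continue
        runs.append((start, prev + 1))
        start = prev = p
    runs.append((start, prev + 1))
    return runs


@dataclass
class MarkerMergeResult:
    merged: Optional[SpecimenBarcode]
    kept_separate: Optional[tuple[SpecimenBarcode, SpecimenBarcode]]

    @property
    def is_merged(self) -> bool:
        return self.merged is not None


def merge_markers(
    long_bar: SpecimenBarcode,
    short_bar: SpecimenBarcode,
    ra_long: RefAlignment,
    ra_short: RefAlignment,
    output_marker: str = "COI",
) -> MarkerMergeResult:
    """Merge overlapping amplicons of the same locus via their shared
    reference frame.

    Positions called (non-N) in both must be exactly identical; then the
    union is emitted — each position takes the non-N call, N only where
    neither covers or both are N. Any disagreement keeps both barcodes
    (the specimen counts in the "two valid sequences" report row). The
    operation is commutative and idempotent, and joined-gap Ns shrink when
    the other fragment covers them.
    """
    if ra_long.entry.ref_id != ra_short.entry.ref_id:
        return MarkerMergeResult(None, (long_bar, short_bar))

    pl = _project_to_ref(ra_long)
    ps = _project_to_ref(ra_short)
    for t in set(pl) & set(ps):
        if pl[t] != "N" and ps[t] != "N" and pl[t] != ps[t]:
            return MarkerMergeResult(None, (long_bar, short_bar))
    lo = min(min(pl), min(ps))
    hi = max(max(pl), max(ps)) + 1
    chars = []
    padding = []
    for t in range(lo, hi):
        a = pl.get(t, "N")
        b = ps.get(t, "N")
        base = a if a != "N" else b
        chars.append(base)
        if base == "N":
            padding.append(t - lo)
    merged = SpecimenBarcode(
        specimen_id=long_bar.specimen_id,
        marker=output_marker,
        sequence="".join(chars),
        gap_intervals=_runs(padding),
        sources=long_bar.sources + short_bar.sources,
        dual_copy=long_bar.dual_copy or short_bar.dual_copy,
    )
    return MarkerMergeResult(merged, None)
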