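"""Step-2 screens on cluster consensuses.

Screen order is fixed: reference alignment and frame assignment ->
translation (coding) screen -> taxon screen -> cross-contamination flag ->
major-cluster selection with dual-copy retention. A record failing an
earlier screen never reaches a later one, which keeps per-stage report
counts additive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .align import Alignment, best_strand_ref_align, shared_extent_identical
from .model import (
    ConsensusRecord,
    GeneticCode,
    QCFlag,
    ReferenceEntry,
    ReferenceSet,
    TaxonClass,
)
from .report import p_distance
from .seq import has_internal_stop, revcomp, translate


@dataclass
class RefAlignment:
    """Best-reference placement of a consensus."""

    entry: ReferenceEntry
    alignment: Alignment  # oriented consensus (query) vs reference (target)
    strand: int
    identity: float
    ref_start: int
    ref_end: int
    frame: int
    oriented_sequence: str  # plus-strand consensus


def align_to_reference(
    consensus: str, refset: ReferenceSet, floor_identity: float = 0.60
) -> Optional[RefAlignment]:
    """Align a consensus against every reference (both strands), keep the
    best identity; below ``floor_identity`` the record is unalignable
    (returns None) and is routed straight to the taxon screen.

    The reading frame is inherited from the best reference: a consensus
    starting at reference position p carries its first codon start at
    consensus offset (frame_offset - p) mod 3.
    """
    if not refset.entries:
        raise ValueError(f"empty reference set for marker {refset.marker!r}")
    best: Optional[RefAlignment] = None
    for entry in refset.entries:
        aln, strand = best_strand_ref_align(consensus, entry.sequence)
        if best is None or aln.identity > best.identity:
            oriented = consensus if strand == 1 else revcomp(consensus)
            frame = (entry.frame_offset - aln.target_start) % 3
            best = RefAlignment(
                entry=entry,
                alignment=aln,
                strand=strand,
                identity=aln.identity,
                ref_start=aln.target_start,
                ref_end=aln.target_end,
                frame=frame,
                oriented_sequence=oriented,
            )
    if best is None or best.identity < floor_identity:
        return None
    return best


def screen_coding(
    sequence: str,
    frame: int,
    genetic_code: GeneticCode,
    alignment: Optional[Alignment] = None,
) -> tuple[bool, list[str]]:
    """Pass iff the in-frame translation is stop-free and the reference
    alignment carries no frameshift indel (length not a multiple of 3).

    Terminal partial codons are ignored by translation; indel runs at the
    alignment ends are terminal overhangs, not frameshifts.
    """
    reasons = []
    if alignment is not None:
        # net frame disruption across internal indel runs; balanced
        # insertion/deletion pairs (including alignment cost ties that
        # trade two mismatches for a 1-nt I/D pair) preserve frame and
        # are left for the stop-codon check to adjudicate
        ops = alignment.ops
        net = 0
        for i, (n, op) in enumerate(ops):
            if op in "ID" and 0 < i < len(ops) - 1:
                net += n if op == "I" else -n
        if net % 3 != 0:
            reasons.append(f"frameshift: net indel offset {net}")
    aa = translate(sequence, frame, genetic_code.table_id)
    if has_internal_stop(aa):
        reasons.append("premature stop codon")
    return (not reasons), reasons


def screen_taxon(
    consensus: str,
    refset: ReferenceSet,
    min_target_identity: float = 0.75,
) -> tuple[str, Optional[str]]:
    """Nearest-reference taxon classification.

    Returns (verdict, detail): verdict is 'target', 'off_target' or
    'unknown'; detail names the off-target species when applicable. The
    best hit over the whole panel decides; a best target hit below
    ``min_target_identity`` is 'unknown'. A configured external
    similarity-search hook replaces this local screen when present.
    """
    if not refset.entries:
        return "unknown", None
    best_entry, best_ident = None, -1.0
    for entry in refset.entries:
        aln, _ = best_strand_ref_align(consensus, entry.sequence)
        if aln.identity > best_ident:
            best_entry, best_ident = entry, aln.identity
    if best_entry.taxon_class is TaxonClass.OFF_TARGET:
        return "off_target", best_entry.species_label
    if best_ident >= min_target_identity:
        return "target", None
    return "unknown", None


@dataclass
class ContaminantPair:
    record_a: ConsensusRecord
    record_b: ConsensusRecord
    dropped: list[ConsensusRecord]
    tie: bool


def flag_contaminants(
    records: Sequence[ConsensusRecord],
    species_of: dict[str, str],
    allowed_pairs: Optional[set[frozenset]] = None,
) -> list[ContaminantPair]:
    """Flag cross-species records with sequences 100% identical over their
    full shared extent.

    Symmetric and order-invariant: every qualifying unordered pair is
    examined. Default resolution drops (flags CONTAMINANT on) the record
    with fewer reads; on a tie both are flagged for manual review. The
    returned pair list is the audit trail for the curation report.
    """
    allowed_pairs = allowed_pairs or set()
    out: list[ContaminantPair] = []
    recs = list(records)
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            a, b = recs[i], recs[j]
            sp_a = species_of[a.specimen_id]
            sp_b = species_of[b.specimen_id]
            if sp_a == sp_b:
                continue
            if frozenset((sp_a, sp_b)) in allowed_pairs:
                continue
            if not shared_extent_identical(a.sequence, b.sequence):
                continue
            if a.total_reads == b.total_reads:
                dropped = [a, b]
                tie = True
            elif a.total_reads < b.total_reads:
                dropped, tie = [a], False
            else:
                dropped, tie = [b], False
            for rec in dropped:
                rec.qc_flags.add(QCFlag.CONTAMINANT)
                rec.fail_reasons.append(
                    f"identical to {(b if rec is a else a).specimen_id} "
                    f"({sp_b if rec is a else sp_a})"
                )
            out.append(ContaminantPair(a, b, dropped, tie))
    return out


def select_major(
    records: Sequence[ConsensusRecord],
    min_copy_divergence: float = 0.03,
) -> tuple[Optional[ConsensusRecord], Optional[ConsensusRecord]]:
    """Pick the major cluster among records that passed every screen.

    Primary = most reads (ties: longer consensus, then lexicographic).
    The second-ranked passing record is retained with DUAL_COPY iff its
    p-distance to the primary exceeds ``min_copy_divergence`` — the
    irreducible two-sequence case; all lower ranks are discarded.
    Returns (None, None) when nothing passes ("PCR+ but no sequence").
    """
    passing = [r for r in records if not r.excluded and r.taxon != "unknown"]
    if not passing:
        return None, None
    passing.sort(key=lambda r: (-r.total_reads, -len(r.sequence), r.sequence))
    primary = passing[0]
    if len(passing) > 1:
        second = passing[1]
        if p_distance(primary.sequence, second.sequence) > min_copy_divergence:
            second.qc_flags.add(QCFlag.DUAL_COPY)
            return primary, second
    return primary, None
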