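"""Scoring a pipeline result against a simulation truth table.

These metrics quantify what the QC workflow is for: does the reported
primary barcode equal the true template, are stop-codon pseudogene
co-amplicons removed, do coding dual copies surface as DUAL_COPY records,
and are cross-specimen contaminant clusters caught.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from .model import QCFlag, Stream
from .pipeline import PipelineResult
from .simulate import TruthTable


def _subsequence_exact(sub: str, full: str) -> bool:
    """Is ``sub`` an exact (edit-distance 0) infix of ``full``?"""
    if not sub or not full or len(sub) > len(full):
        return False
    return edlib.align(sub.upper(), full.upper(), mode="HW", task="distance")[
        "editDistance"
    ] == 0


def _infix_span(sub: str, full: str) -> tuple[int, int] | None:
    """Target span [start, end) of an exact infix placement, else None."""
    if not sub or not full or len(sub) > len(full):
        return None
    r = edlib.align(sub.upper(), full.upper(), mode="HW", task="locations")
    if r["editDistance"] != 0:
        return None
    s, e = r["locations"][0]
    return s, e + 1


def barcode_matches_truth(sequence: str, truth_amplicon: str) -> bool:
    """True iff every called (non-N) position of ``sequence`` agrees with
    the truth template at its aligned position, with no internal indels.

    N runs (join padding) are not held against the barcode; the barcode
    may cover only part of the template (e.g. a single read half)."""
    from .align import align

    if not sequence or not truth_amplicon:
        return False
    mode = "HW" if len(sequence) <= len(truth_amplicon) else "NW"
    aln = align(sequence, truth_amplicon, mode=mode)
    if aln.internal_indels():
        return False
    for qpos, tpos in aln.columns():
        if qpos is None or tpos is None:
            continue
        a, b = aln.query[qpos], aln.target[tpos]
        if a != "N" and b != "N" and a != b:
            return False
    return True


@dataclass
class TruthEvaluation:
    n_primaries: int
    n_primaries_correct: int
    n_stop_numt_units: int
    n_stop_numt_escaped: int
    n_coding_numt_expected: int      # coding NUMT with a cluster-sized read share
    n_dual_copy_detected: int
    n_contaminant_events: int        # hop bursts large enough to form a cluster
    n_contaminant_flagged: int
    n_offtarget_units: int
    n_offtarget_flagged: int

    @property
    def primary_recovery(self) -> float:
        return (
            self.n_primaries_correct / self.n_primaries if self.n_primaries else 0.0
        )

    @property
    def stop_numt_removal(self) -> float:
        if not self.n_stop_numt_units:
            return 1.0
        return 1.0 - self.n_stop_numt_escaped / self.n_stop_numt_units

    @property
    def contaminant_recall(self) -> float:
        if not self.n_contaminant_events:
            return 1.0
        return self.n_contaminant_flagged / self.n_contaminant_events


def evaluate_against_truth(
    result: PipelineResult,
    truth: TruthTable,
    min_cluster_reads: int = 10,
) -> TruthEvaluation:
    """Score the run. Markers are evaluated at the pre-merge level (the
    truth table is keyed by the amplified marker), barcodes at the final
    level via their source records."""
    # group records by (specimen, marker)
    recs_by_unit: dict[tuple[str, str], list] = {}
    for r in result.records:
        recs_by_unit.setdefault((r.specimen_id, r.marker), []).append(r)

    n_primaries = n_correct = 0
    for key, (primary, _secondary) in result.primaries.items():
        sid, marker, _stream = key
        if primary is None:
            continue
        unit = truth.units.get((sid, marker))
        if unit is None:
            continue
        n_primaries += 1
        if barcode_matches_truth(primary.sequence, unit.true_barcode):
            n_correct += 1

    n_stop_units = n_escaped = 0
    n_coding_expected = n_dual = 0
    n_contam_events = n_contam_flagged = 0
    n_off_units = n_off_flagged = 0
    for (sid, marker), unit in truth.units.items():
        recs = recs_by_unit.get((sid, marker), [])
        if unit.numt_sequence is not None and unit.numt_coding is False:
            n_stop_units += 1
            stop = unit.numt_stop_pos
            for r in recs:
                if r.excluded or _subsequence_exact(r.sequence, unit.true_barcode):
                    continue
                span = _infix_span(r.sequence, unit.numt_sequence)
                if span is None:
                    continue
                # an escape means a passing record whose extent actually
                # contains the premature stop codon; read halves that never
                # covered it cannot be caught by translation
                if stop is None or (span[0] <= stop and stop + 3 <= span[1]):
                    n_escaped += 1
                    break
        if (
            unit.numt_sequence is not None
            and unit.numt_coding
            and unit.n_numt_reads >= min_cluster_reads
        ):
            n_coding_expected += 1
            for r in recs:
                if QCFlag.DUAL_COPY in r.qc_flags and _subsequence_exact(
                    r.sequence, unit.numt_sequence
                ):
                    n_dual += 1
                    break
        for hop in unit.hops_in:
            if hop.count < min_cluster_reads:
                continue
            n_contam_events += 1
            src_unit = truth.units.get((hop.source_specimen, marker))
            src_seq = src_unit.true_barcode if src_unit else None
            # the event is caught when its cluster is CONTAMINANT-flagged;
            # an event whose reads fell below the cluster floor before
            # clustering never reaches the final set and is equally
            # harmless — only an unflagged surviving copy of the source
            # sequence counts as a miss
            escaped = False
            flagged = False
            for r in recs:
                matches_src = src_seq is not None and _subsequence_exact(
                    r.sequence, src_seq
                ) and not _subsequence_exact(r.sequence, unit.true_barcode)
                if not matches_src:
                    continue
                if QCFlag.CONTAMINANT in r.qc_flags:
                    flagged = True
                elif not r.excluded:
                    escaped = True
            if flagged or not escaped:
                n_contam_flagged += 1
        if unit.n_offtarget_reads >= min_cluster_reads:
            n_off_units += 1
            if any(QCFlag.OFF_TARGET in r.qc_flags for r in recs):
                n_off_flagged += 1

    return TruthEvaluation(
        n_primaries=n_primaries,
        n_primaries_correct=n_correct,
        n_stop_numt_units=n_stop_units,
        n_stop_numt_escaped=n_escaped,
        n_coding_numt_expected=n_coding_expected,
        n_dual_copy_detected=n_dual,
        n_contaminant_events=n_contam_events,
        n_contaminant_flagged=n_contam_flagged,
        n_offtarget_units=n_off_units,
        n_offtarget_flagged=n_off_flagged,
    )
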