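"""Reference alignment and frame, coding screen, taxon screen,
contamination flags, major-cluster selection."""

import pytest

from ampliqc.model import (
    ConsensusRecord,
    GeneticCode,
    QCFlag,
    ReferenceEntry,
    ReferenceSet,
    Stream,
    TaxonClass,
)
from ampliqc.qc import (
    align_to_reference,
    flag_contaminants,
    screen_coding,
    screen_taxon,
    select_major,
)
from ampliqc.seq import revcomp, translate

from conftest import mutate, random_seq


def coding_seq(rng, length, table_id=5):
    from ampliqc.simulate import _random_coding

    return _random_coding(rng, length, table_id)


def refset(marker, entries):
    rs = ReferenceSet(marker)
    for i, (seq, sp, frame, cls) in enumerate(entries):
        rs.entries.append(
            ReferenceEntry(f"ref{i}", marker, seq, sp, frame, cls)
        )
    return rs


def record(sid, seq, reads, rank=1, marker="M", stream=Stream.MERGED, taxon="target"):
    return ConsensusRecord(
        specimen_id=sid, marker=marker, stream=stream, sequence=seq,
        rank=rank, total_reads=reads, taxon=taxon,
    )


class TestAlignToReference:
    def test_identical_consensus(self, rng):
        ref = coding_seq(rng, 300)
        rs = refset("M", [(ref, "sp1", 0, TaxonClass.TARGET)])
        ra = align_to_reference(ref, rs)
        assert ra.identity == 1.0
        assert ra.frame == 0
        assert ra.ref_start == 0

    def test_leading_truncation_shifts_frame(self, rng):
        # dropping p leading bases moves the first codon start to
        # (frame_offset - p) mod 3; verified by translating both
        ref = coding_seq(rng, 300)
        rs = refset("M", [(ref, "sp1", 0, TaxonClass.TARGET)])
        ra = align_to_reference(ref[2:], rs)
        assert ra.ref_start == 2
        assert ra.frame == (0 - 2) % 3 == 1
        assert translate(ref[2:], ra.frame, 5) == translate(ref, 0, 5)[1:]

    def test_reverse_complement_strand_symmetry(self, rng):
        ref = coding_seq(rng, 300)
        rs = refset("M", [(ref, "sp1", 0, TaxonClass.TARGET)])
        fwd = align_to_reference(ref, rs)
        rev = align_to_reference(revcomp(ref), rs)
        assert rev.identity == fwd.identity == 1.0
        assert rev.strand == -1
        assert rev.oriented_sequence == ref

    def test_floor_identity_routes_to_unalignable(self, rng):
        ref = coding_seq(rng, 300)
        rs = refset("M", [(ref, "sp1", 0, TaxonClass.TARGET)])
        assert align_to_reference(random_seq(rng, 300), rs, 0.60) is None


class TestScreenCoding:
    def test_tga_passes_under_invertebrate_mito(self):
        # TGA is Trp in the invertebrate mitochondrial code
        seq = "ATT" + "TGA" + "GCT" * 5
        ok, reasons = screen_coding(seq, 0, GeneticCode.INVERTEBRATE_MITO)
        assert ok, reasons

    def test_internal_taa_fails(self):
        seq = "ATT" + "TAA" + "GCT" * 5
        ok, reasons = screen_coding(seq, 0, GeneticCode.INVERTEBRATE_MITO)
        assert not ok and any("stop" in r for r in reasons)

    def test_one_nt_deletion_is_frameshift(self, rng):
        # deleting one base relative to the reference shifts the frame;
        # translation downstream of the indel hits stops sooner or later,
        # and the alignment itself carries a net 1-nt indel
        from ampliqc.align import align

        ref = coding_seq(rng, 300)
        broken = ref[:150] + ref[151:]
        aln = align(broken, ref, mode="NW")
        ok, reasons = screen_coding(broken, 0, GeneticCode.INVERTEBRATE_MITO, aln)
        assert not ok and any("frameshift" in r for r in reasons)

    def test_in_frame_codon_deletion_passes(self, rng):
        from ampliqc.align import align

        ref = coding_seq(rng, 300)
        cut = ref[:150] + ref[153:]  # whole codon out
        aln = align(cut, ref, mode="NW")
        ok, reasons = screen_coding(cut, 0, GeneticCode.INVERTEBRATE_MITO, aln)
        assert ok, reasons

    def test_terminal_partial_codon_ignored(self):
        seq = "ATTGCT" + "TA"  # dangling partial codon, not a stop
        ok, _ = screen_coding(seq, 0, GeneticCode.INVERTEBRATE_MITO)
        assert ok


class TestScreenTaxon:
    def test_identical_to_target(self, rng):
        t = coding_seq(rng, 300)
        rs = refset("M", [(t, "sp1", 0, TaxonClass.TARGET)])
        assert screen_taxon(t, rs)[0] == "target"

    def test_identical_to_off_target_panel_entry(self, rng):
        t = coding_seq(rng, 300)
        w = coding_seq(rng, 300)
        rs = refset(
            "M",
            [(t, "sp1", 0, TaxonClass.TARGET), (w, "Wolbachia_sp", 0, TaxonClass.OFF_TARGET)],
        )
        verdict, label = screen_taxon(w, rs)
        assert verdict == "off_target" and label == "Wolbachia_sp"

    def test_distant_sequence_is_unknown(self, rng):
        t = coding_seq(rng, 300)
        rs = refset("M", [(t, "sp1", 0, TaxonClass.TARGET)])
        assert screen_taxon(random_seq(rng, 300), rs, 0.75)[0] == "unknown"


class TestFlagContaminants:
    def test_same_species_identical_not_flagged(self, rng):
        seq = random_seq(rng, 300)
        a, b = record("s1", seq, 100), record("s2", seq, 50)
        pairs = flag_contaminants([a, b], {"s1": "spX", "s2": "spX"})
        assert pairs == []
        assert not a.qc_flags and not b.qc_flags

    def test_cross_species_identical_smaller_dropped(self, rng):
        seq = random_seq(rng, 300)
        a, b = record("s1", seq, 100), record("s2", seq, 50)
        pairs = flag_contaminants([a, b], {"s1": "spX", "s2": "spY"})
        assert len(pairs) == 1 and not pairs[0].tie
        assert QCFlag.CONTAMINANT in b.qc_flags
        assert QCFlag.CONTAMINANT not in a.qc_flags

    def test_tie_flags_both_for_review(self, rng):
        seq = random_seq(rng, 300)
        a, b = record("s1", seq, 50), record("s2", seq, 50)
        pairs = flag_contaminants([a, b], {"s1": "spX", "s2": "spY"})
        assert pairs[0].tie
        assert QCFlag.CONTAMINANT in a.qc_flags and QCFlag.CONTAMINANT in b.qc_flags

    def test_hybridizing_pair_exempt(self, rng):
        seq = random_seq(rng, 300)
        a, b = record("s1", seq, 100), record("s2", seq, 50)
        pairs = flag_contaminants(
            [a, b], {"s1": "spX", "s2": "spY"}, {frozenset(("spX", "spY"))}
        )
        assert pairs == [] and not a.qc_flags and not b.qc_flags

    def test_truncated_copy_counts_as_identical(self, rng):
        seq = random_seq(rng, 300)
        a, b = record("s1", seq, 100), record("s2", seq[:220], 40)
        flag_contaminants([a, b], {"s1": "spX", "s2": "spY"})
        assert QCFlag.CONTAMINANT in b.qc_flags

    def test_order_invariance(self, rng):
        seq = random_seq(rng, 300)
        other = mutate(rng, seq, 30)
        species = {"s1": "spX", "s2": "spY", "s3": "spZ"}
        recs1 = [record("s1", seq, 100), record("s2", seq, 50), record("s3", other, 70)]
        recs2 = [record("s3", other, 70), record("s2", seq, 50), record("s1", seq, 100)]
        flag_contaminants(recs1, species)
        flag_contaminants(recs2, species)
        flags1 = {r.specimen_id: QCFlag.CONTAMINANT in r.qc_flags for r in recs1}
        flags2 = {r.specimen_id: QCFlag.CONTAMINANT in r.qc_flags for r in recs2}
        assert flags1 == flags2 == {"s1": False, "s2": True, "s3": False}


class TestSelectMajor:
    def test_identical_consensuses_primary_only(self, rng):
        seq = random_seq(rng, 300)
        primary, secondary = select_major(
            [record("s1", seq, 500), record("s1", seq, 30, rank=2)], 0.03
        )
        assert primary.total_reads == 500 and secondary is None

    def test_divergent_second_cluster_kept_as_dual_copy(self, rng):
        seq = random_seq(rng, 300)
        other = mutate(rng, seq, 24)  # 8% divergent second copy
        primary, secondary = select_major(
            [record("s1", seq, 500), record("s1", other, 200, rank=2)], 0.03
        )
        assert primary.total_reads == 500
        assert secondary is not None
        assert QCFlag.DUAL_COPY in secondary.qc_flags

    def test_single_record(self, rng):
        primary, secondary = select_major([record("s1", random_seq(rng, 300), 42)], 0.03)
        assert primary is not None and secondary is None

    def test_no_passing_record(self, rng):
        r = record("s1", random_seq(rng, 300), 42)
        r.qc_flags.add(QCFlag.NON_CODING)
        assert select_major([r], 0.03) == (None, None)

    def test_excluded_records_never_selected(self, rng):
        good = record("s1", random_seq(rng, 300), 10, rank=2)
        bad = record("s1", random_seq(rng, 300), 400)
        bad.qc_flags.add(QCFlag.OFF_TARGET)
        primary, _ = select_major([bad, good], 0.03)
        assert primary is good
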