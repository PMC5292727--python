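"""Core data model: markers, samples, reads, clusters, barcodes.

The flowing units of the pipeline are :class:`ReadRecord` / :class:`ReadPair`
(raw reads), :class:`PreparedSequence` (dereplicated uniques with abundance),
:class:`Cluster` / :class:`ConsensusRecord` (clustered uniques and their
called consensus with QC flags) and :class:`SpecimenBarcode` (final curated
per-specimen, per-marker sequence).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .seq import revcomp, translate, has_internal_stop


class ValidationError(ValueError):
    """A record violates a model invariant; the message names the record."""


class GeneticCode(str, enum.Enum):
    """Translation table for a marker (NCBI table ids 5 and 1)."""

    INVERTEBRATE_MITO = "invertebrate_mito"
    STANDARD = "standard"

    @property
    def table_id(self) -> int:
        return 5 if self is GeneticCode.INVERTEBRATE_MITO else 1


class Stream(str, enum.Enum):
    """Which read stream a sequence came from.

    Non-overlapping markers are analysed as separate forward (read1) and
    reverse (read2) streams; overlapping markers as a single merged stream.
    """

    MERGED = "merged"
    READ1 = "read1"
    READ2 = "read2"


class QCFlag(str, enum.Enum):
    NON_CODING = "NON_CODING"
    OFF_TARGET = "OFF_TARGET"
    CONTAMINANT = "CONTAMINANT"
    DUAL_COPY = "DUAL_COPY"


class TaxonClass(str, enum.Enum):
    TARGET = "target"
    OFF_TARGET = "off_target"


_IUPAC = set("ACGTRYSWKMBDHVN")


@dataclass(frozen=True)
class MarkerSpec:
    """A target gene region: primers, length bounds and genetic code.

    ``sequenced_product_len`` is derived: forward primer + amplicon +
    reverse primer — the fragment the instrument actually reads into.
    """

    name: str
    fwd_primer: str
    rev_primer: str
    expected_amplicon_len: int
    min_len: Optional[int] = None
    max_len: Optional[int] = None
    genetic_code: GeneticCode = GeneticCode.INVERTEBRATE_MITO
    read_overlap_expected: bool = True

    def __post_init__(self):
        if not self.name:
            raise ValidationError("marker with empty name")
        for label, p in (("fwd", self.fwd_primer), ("rev", self.rev_primer)):
            if not p:
                raise ValidationError(f"marker {self.name!r}: missing {label} primer")
            bad = set(p.upper()) - _IUPAC
            if bad:
                raise ValidationError(
                    f"marker {self.name!r}: non-IUPAC characters {sorted(bad)} in {label} primer"
                )
        if self.expected_amplicon_len <= 0:
            raise ValidationError(f"marker {self.name!r}: non-positive amplicon length")
        if (
            self.min_len is not None
            and self.max_len is not None
            and self.min_len > self.max_len
        ):
            raise ValidationError(
                f"marker {self.name!r}: min_len {self.min_len} > max_len {self.max_len}"
            )

    @property
    def sequenced_product_len(self) -> int:
        return self.expected_amplicon_len + len(self.fwd_primer) + len(self.rev_primer)


@dataclass(frozen=True)
class SampleRecord:
    """One specimen: id, morphological species label, optional metadata."""

    specimen_id: str
    species_label: str
    collection_year: Optional[int] = None
    r1_path: Optional[str] = None
    r2_path: Optional[str] = None

    def __post_init__(self):
        if not self.specimen_id:
            raise ValidationError("sample with empty specimen_id")
        if not self.species_label:
            raise ValidationError(f"sample {self.specimen_id!r}: empty species label")


@dataclass
class ReadRecord:
    """A sequence with per-base Phred quality scores."""

    read_id: str
    bases: str
    quals: np.ndarray  # int array, same length as bases

    def __post_init__(self):
        self.quals = np.asarray(self.quals, dtype=np.int16)
        if len(self.bases) != len(self.quals):
            raise ValidationError(
                f"read {self.read_id!r}: {len(self.bases)} bases vs {len(self.quals)} quals"
            )
        if len(self.quals) and (self.quals.min() < 0 or self.quals.max() > 60):
            raise ValidationError(f"read {self.read_id!r}: Phred scores outside [0, 60]")

    def __len__(self) -> int:
        return len(self.bases)

    def reverse_complement(self) -> "ReadRecord":
        return ReadRecord(self.read_id, revcomp(self.bases), self.quals[::-1].copy())


@dataclass
class ReadPair:
    r1: ReadRecord
    r2: ReadRecord


@dataclass(frozen=True)
class ReferenceEntry:
    """A curated reference sequence (e.g. from Sanger) for one marker."""

    ref_id: str
    marker: str
    sequence: str
    species_label: str
    frame_offset: int = 0
    taxon_class: TaxonClass = TaxonClass.TARGET

    def __post_init__(self):
        if self.frame_offset not in (0, 1, 2):
            raise ValidationError(f"reference {self.ref_id!r}: frame_offset not in 0..2")


@dataclass
class ReferenceSet:
    """All references for one marker, target and off-target entries together."""

    marker: str
    entries: list[ReferenceEntry] = field(default_factory=list)

    @property
    def targets(self) -> list[ReferenceEntry]:
        return [e for e in self.entries if e.taxon_class is TaxonClass.TARGET]

    @property
    def off_targets(self) -> list[ReferenceEntry]:
        return [e for e in self.entries if e.taxon_class is TaxonClass.OFF_TARGET]

    def validate_coding(self, code: GeneticCode) -> None:
        """Target entries must be in-frame coding (no internal stops)."""
        for e in self.targets:
            aa = translate(e.sequence, e.frame_offset, code.table_id)
            if has_internal_stop(aa):
                raise ValidationError(
                    f"reference {e.ref_id!r} ({self.marker}): internal stop codon in target entry"
                )


@dataclass
class PreparedSequence:
    """A dereplicated unique sequence with its read abundance."""

    specimen_id: str
    marker: str
    bases: str
    abundance: int
    origin: Stream

    def __post_init__(self):
        if self.abundance < 1:
            raise ValidationError("PreparedSequence abundance must be >= 1")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class Cluster:
    """A group of uniques sharing one consensus; rank 1 = most reads."""

    members: list[PreparedSequence]
    consensus: str = ""
    rank: int = 0

    @property
    def total_reads(self) -> int:
        return sum(m.abundance for m in self.members)

    @property
    def seed(self) -> PreparedSequence:
        return self.members[0]


@dataclass
class ConsensusRecord:
    """A cluster consensus annotated through the QC screens."""

    specimen_id: str
    marker: str
    stream: Stream
    sequence: str
    rank: int
    total_reads: int
    qc_flags: set[QCFlag] = field(default_factory=set)
    best_reference: Optional[tuple[str, float]] = None  # (ref id, identity)
    frame: Optional[int] = None
    strand: int = 1  # +1 if sequence already plus-strand w.r.t. best reference
    unalignable: bool = False
    taxon: Optional[str] = None  # 'target' | off-target label | 'unknown'
    fail_reasons: list[str] = field(default_factory=list)

    @property
    def excluded(self) -> bool:
        """True if any hard-fail flag is set (record leaves the final set)."""
        return bool(
            self.qc_flags
            & {QCFlag.NON_CODING, QCFlag.OFF_TARGET, QCFlag.CONTAMINANT}
        )


@dataclass
class SpecimenBarcode:
    """Final curated barcode for one specimen and one (post-merge) marker.

    ``gap_intervals`` are the half-open [start, end) runs of N padding
    introduced by joining non-overlapping read halves — not base-call Ns.
    """

    specimen_id: str
    marker: str
    sequence: str
    gap_intervals: list[tuple[int, int]] = field(default_factory=list)
    sources: list[ConsensusRecord] = field(default_factory=list)
    dual_copy: bool = False
    conflict: bool = False

    def __post_init__(self):
        if not self.sequence:
            raise ValidationError(
                f"barcode {self.specimen_id}/{self.marker}: empty sequence"
            )

    @property
    def n_padding(self) -> int:
        return sum(e - s for s, e in self.gap_intervals)


@dataclass
class DistanceMatrix:
    """Symmetric p-distance matrix with labels."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValidationError("distance matrix diagonal is not zero")
        self.matrix = m


@dataclass
class Thresholds:
    """All tunable cutoffs of the pipeline, with package defaults."""

    quality_min: int = 21          # truncate read at first base with Q below this
    min_len: int = 150             # global post-trim length floor (nt)
    min_cluster_reads: int = 10    # clusters with fewer reads are dropped
    merge_min_overlap: int = 25    # minimum end overlap to merge a read pair (nt)
    merge_max_mismatch_rate: float = 0.25
    max_primer_mismatches: int = 1
    max_spacer: int = 3            # heterogeneity spacer length range 0..max
    cluster_min_overlap: int = 100  # overlap needed to join a cluster (nt)
    cluster_min_identity: float = 0.97
    chimera_min_parent_ratio: float = 2.0
    chimera_min_score: int = 3     # diagnostic-site margin of two-parent model
    ref_floor_identity: float = 0.60  # below this a consensus is 'unalignable'
    min_target_identity: float = 0.75
    min_copy_divergence: float = 0.03  # p-distance to retain a DUAL_COPY second
    problem_divergence: float = 0.07   # strict > threshold for problem species

    def __post_init__(self):
        for name in (
            "merge_max_mismatch_rate",
            "cluster_min_identity",
            "ref_floor_identity",
            "min_target_identity",
            "min_copy_divergence",
            "problem_divergence",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"threshold {name}={v} outside [0, 1]")


@dataclass
class RunConfig:
    """A full run: markers, samples, thresholds, references and merge plan."""

    markers: list[MarkerSpec]
    samples: list[SampleRecord]
    thresholds: Thresholds = field(default_factory=Thresholds)
    reference_path: Optional[str] = None
    pcr_results_path: Optional[str] = None
    tree_paths: dict[str, str] = field(default_factory=dict)  # marker -> newick
    # merge plan: each entry joins a long and a short marker into one output
    merge_plan: list[dict] = field(default_factory=list)
    allowed_hybrid_pairs: set[frozenset] = field(default_factory=set)

    def __post_init__(self):
        if not self.markers:
            raise ValidationError("no markers configured")
        if not self.samples:
            raise ValidationError("no samples")
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate marker names")
        ids = [s.specimen_id for s in self.samples]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate specimen_id: {sorted(dupes)}")

    def marker(self, name: str) -> MarkerSpec:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(name)
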