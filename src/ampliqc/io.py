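"""Reading and writing the run's external formats.

FASTQ is 4-line Phred+33; FASTA is wrapped at a fixed width; references
carry their marker / species / frame / taxon class as ``key=value`` tokens
on the description line; sample sheets and reports are TSV; trees are
newick; the run configuration is a single YAML file referencing the rest.
"""

from __future__ import annotations

import io as _io
import os
from typing import Iterator, Optional

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    GeneticCode,
    MarkerSpec,
    ReadPair,
    ReadRecord,
    ReferenceEntry,
    ReferenceSet,
    RunConfig,
    SampleRecord,
    TaxonClass,
    Thresholds,
    ValidationError,
)

FASTA_WIDTH = 70


class ParseError(ValueError):
    """Malformed input file; the message carries file and line context."""


# ---------------------------------------------------------------- FASTQ

def read_fastq(path: str) -> list[ReadRecord]:
    """Read a 4-line FASTQ (Phred+33) into ReadRecords."""
    records = []
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                break
            lineno += 1
            if not header.startswith("@"):
                raise ParseError(f"{path}:{lineno}: expected '@' header")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not qual and not plus:
                raise ParseError(f"{path}:{lineno}: truncated FASTQ record")
            lineno += 3
            if not plus.startswith("+"):
                raise ParseError(f"{path}:{lineno - 1}: expected '+' separator")
            if len(seq) != len(qual):
                raise ParseError(
                    f"{path}:{lineno}: sequence/quality length mismatch"
                )
            quals = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(
                np.int16
            ) - 33
            records.append(
                ReadRecord(header[1:].split()[0], seq.upper(), quals)
            )
    return records


def write_fastq(path: str, records: list[ReadRecord]) -> None:
    with open(path, "w") as fh:
        for r in records:
            qual = "".join(chr(int(q) + 33) for q in r.quals)
            fh.write(f"@{r.read_id}\n{r.bases}\n+\n{qual}\n")


def read_fastq_pairs(r1_path: str, r2_path: str) -> list[ReadPair]:
    """Read mate files and pair records by order, checking id agreement."""
    r1 = read_fastq(r1_path)
    r2 = read_fastq(r2_path)
    if len(r1) != len(r2):
        raise ParseError(
            f"{r1_path} has {len(r1)} reads but {r2_path} has {len(r2)}"
        )
    pairs = []
    for i, (a, b) in enumerate(zip(r1, r2)):
        ida, idb = a.read_id.removesuffix("/1"), b.read_id.removesuffix("/2")
        if ida != idb:
            raise ParseError(
                f"read pair {i + 1}: mismatched ids {a.read_id!r} vs {b.read_id!r}"
            )
        pairs.append(ReadPair(a, b))
    return pairs


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str) -> list[tuple[str, str, str]]:
    """Return (id, description, sequence) tuples."""
    out = []
    for rec in SeqIO.parse(path, "fasta"):
        out.append((rec.id, rec.description, str(rec.seq).upper()))
    return out


def write_fasta(path: str, records: list[tuple[str, str]], width: int = FASTA_WIDTH) -> None:
    """Write (header, sequence) pairs wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ------------------------------------------------------------ references

def _kv_tokens(description: str) -> dict[str, str]:
    return dict(
        tok.split("=", 1) for tok in description.split() if "=" in tok
    )


def read_reference_sets(path: str) -> dict[str, ReferenceSet]:
    """Parse a reference FASTA whose descriptions carry
    ``marker= species= frame= class=`` tokens; returns one set per marker."""
    sets: dict[str, ReferenceSet] = {}
    for rid, desc, seq in read_fasta(path):
        kv = _kv_tokens(desc)
        try:
            marker = kv["marker"]
        except KeyError:
            raise ParseError(f"{path}: reference {rid!r} lacks a marker= token")
        entry = ReferenceEntry(
            ref_id=rid,
            marker=marker,
            sequence=seq,
            species_label=kv.get("species", "unknown"),
            frame_offset=int(kv.get("frame", 0)),
            taxon_class=TaxonClass(kv.get("class", "target")),
        )
        sets.setdefault(marker, ReferenceSet(marker)).entries.append(entry)
    return sets


def write_reference_sets(path: str, sets: dict[str, ReferenceSet]) -> None:
    recs = []
    for marker in sorted(sets):
        for e in sets[marker].entries:
            header = (
                f"{e.ref_id} marker={e.marker} species={e.species_label} "
                f"frame={e.frame_offset} class={e.taxon_class.value}"
            )
            recs.append((header, e.sequence))
    write_fasta(path, recs)


# ---------------------------------------------------------------- newick

def read_newick(path: str):
    """Parse a newick tree into an skbio TreeNode."""
    from skbio import TreeNode

    with open(path) as fh:
        return TreeNode.read(fh, format="newick")


def write_newick(path: str, tree) -> None:
    with open(path, "w") as fh:
        tree.write(fh, format="newick")


# ------------------------------------------------------------------ TSV

def read_sample_sheet(path: str, base_dir: Optional[str] = None) -> list[SampleRecord]:
    """TSV with header: specimen_id, species_label, collection_year, r1, r2."""
    import csv

    samples = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"specimen_id", "species_label"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ParseError(f"{path}: sample sheet must have columns {sorted(required)}")
        for i, row in enumerate(reader, start=2):
            year = row.get("collection_year") or None
            r1 = row.get("r1") or None
            r2 = row.get("r2") or None
            if base_dir is not None:
                r1 = os.path.join(base_dir, r1) if r1 else None
                r2 = os.path.join(base_dir, r2) if r2 else None
            try:
                samples.append(
                    SampleRecord(
                        specimen_id=row["specimen_id"],
                        species_label=row["species_label"],
                        collection_year=int(year) if year else None,
                        r1_path=r1,
                        r2_path=r2,
                    )
                )
            except (ValueError, ValidationError) as e:
                raise ParseError(f"{path}:{i}: {e}") from e
    if not samples:
        raise ParseError(f"{path}: no samples")
    return samples


def write_sample_sheet(path: str, samples: list[SampleRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("specimen_id\tspecies_label\tcollection_year\tr1\tr2\n")
        for s in samples:
            year = "" if s.collection_year is None else s.collection_year
            fh.write(
                f"{s.specimen_id}\t{s.species_label}\t{year}\t"
                f"{s.r1_path or ''}\t{s.r2_path or ''}\n"
            )


def read_pcr_results(path: str) -> dict[tuple[str, str], bool]:
    """TSV: specimen_id, marker, pcr_positive (0/1) -> gel-band observations."""
    import csv

    out = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out[(row["specimen_id"], row["marker"])] = row["pcr_positive"] in (
                "1",
                "True",
                "true",
            )
    return out


def write_pcr_results(path: str, results: dict[tuple[str, str], bool]) -> None:
    with open(path, "w") as fh:
        fh.write("specimen_id\tmarker\tpcr_positive\n")
        for (sp, mk), pos in results.items():
            fh.write(f"{sp}\t{mk}\t{1 if pos else 0}\n")


# ------------------------------------------------------------ run config

def load_run_config(path: str) -> RunConfig:
    """Load the YAML run configuration and validate every record.

    The YAML holds the marker table and thresholds inline and references
    the sample sheet / reference FASTA / PCR table by relative path.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ParseError(f"{path}: not a YAML mapping")
    base = os.path.dirname(os.path.abspath(path))

    markers = []
    for m in doc.get("markers", []):
        try:
            markers.append(
                MarkerSpec(
                    name=m["name"],
                    fwd_primer=m["fwd_primer"],
                    rev_primer=m["rev_primer"],
                    expected_amplicon_len=int(m["expected_amplicon_len"]),
                    min_len=m.get("min_len"),
                    max_len=m.get("max_len"),
                    genetic_code=GeneticCode(m.get("genetic_code", "invertebrate_mito")),
                    read_overlap_expected=bool(m.get("read_overlap_expected", True)),
                )
            )
        except KeyError as e:
            raise ValidationError(
                f"marker entry {m.get('name', '?')!r}: missing field {e}"
            ) from e
        if "sequenced_product_len" in m:
            expected = int(m["sequenced_product_len"])
            if markers[-1].sequenced_product_len != expected:
                raise ValidationError(
                    f"marker {markers[-1].name!r}: declared sequenced_product_len "
                    f"{expected} != primers+amplicon {markers[-1].sequenced_product_len}"
                )

    sheet = doc.get("samples")
    if not sheet:
        raise ValidationError("no samples: config lacks a 'samples' sheet path")
    samples = read_sample_sheet(os.path.join(base, sheet), base_dir=base)

    thr_doc = doc.get("thresholds", {}) or {}
    valid = set(Thresholds.__dataclass_fields__)
    unknown = set(thr_doc) - valid
    if unknown:
        raise ValidationError(f"unknown threshold keys: {sorted(unknown)}")
    thresholds = Thresholds(**thr_doc)

    ref = doc.get("references")
    pcr = doc.get("pcr_results")
    trees = {
        k: os.path.join(base, v) for k, v in (doc.get("trees") or {}).items()
    }
    allowed = {
        frozenset(pair) for pair in doc.get("allowed_hybrid_pairs", [])
    }
    return RunConfig(
        markers=markers,
        samples=samples,
        thresholds=thresholds,
        reference_path=os.path.join(base, ref) if ref else None,
        pcr_results_path=os.path.join(base, pcr) if pcr else None,
        tree_paths=trees,
        merge_plan=doc.get("merge_plan", []) or [],
        allowed_hybrid_pairs=allowed,
    )
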