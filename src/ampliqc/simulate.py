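"""Deterministic simulator of multi-marker amplicon runs with ground truth.

The generator emulates a multi-specimen, multi-marker two-step PCR MiSeq
design and every artefact class the pipeline screens for:

* per-species coding barcode sequences evolved from random roots;
* paired 300-nt reads of the primer+spacer-flanked product, with
  substitution errors concentrated where the emitted Phred quality decays;
* NUMT co-amplification (coding, or carrying premature stop codons) at a
  configured divergence from the true barcode;
* off-target (symbiont / parasite) co-amplification;
* PCR chimeras spliced from two templates of the same reaction;
* index hopping: bursts of reads relabelled to one other specimen;
* age-dependent PCR failure (success declines with years in ethanol),
  with low-depth read leakage from "negative" reactions.

A fixed seed yields byte-identical output; every emitted read id appears
exactly once in the truth table.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import default_markers
from .model import (
    GeneticCode,
    MarkerSpec,
    ReadRecord,
    ReferenceEntry,
    ReferenceSet,
    SampleRecord,
    TaxonClass,
    ValidationError,
)
from .seq import IUPAC_BASES, revcomp
from . import io as aio

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = {1: {"TAA", "TAG", "TGA"}, 5: {"TAA", "TAG"}}


@dataclass
class SimulationConfig:
    """Study conditions for one simulated run (rates are probabilities)."""

    seed: int = 0
    n_species: int = 6
    specimens_per_species: int = 3
    markers: list[MarkerSpec] = field(default_factory=default_markers)
    species_divergence: float = 0.10   # pairwise divergence between species
    numt_rate: float = 0.10            # per specimen x mito-marker
    numt_divergence: float = 0.08      # NUMT vs true barcode
    numt_coding_fraction: float = 0.5  # NUMTs without stops
    numt_read_fraction: float = 0.10   # share of the unit's reads
    offtarget_rate: float = 0.05       # per specimen x marker co-amplification
    offtarget_read_fraction: float = 0.35
    index_hop_rate: float = 0.05       # per-read; bursts to one destination
    chimera_rate: float = 0.01         # per-read
    reads_per_amplicon: int = 150
    read_len: int = 300
    error_rate: float = 0.01           # mean per-base substitution rate
    quality_decay: float = 0.03        # mean-Q slope per nt on R1 (R2: 2x)
    q_start: float = 38.0
    q_noise_sd: float = 2.0
    pcr_fail_base: float = 0.05
    pcr_fail_age_slope: float = 0.012  # extra failure probability per year
    pcr_neg_read_factor: float = 0.07  # depth of reads from PCR- reactions
    sanger_divergence: float = 0.002   # reference drift from the truth
    year_range: tuple = (1996, 2015)
    current_year: int = 2016
    # marker pairs sharing one locus: (long marker, short marker, locus name)
    nested_markers: tuple = (("COI-long", "COI-short", "COI"),)

    def __post_init__(self):
        for name in (
            "species_divergence", "numt_rate", "numt_divergence",
            "numt_coding_fraction", "numt_read_fraction", "offtarget_rate",
            "offtarget_read_fraction", "index_hop_rate", "chimera_rate",
            "error_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"simulation rate {name}={v} outside [0, 1]")
        for mk in self.markers:
            if mk.expected_amplicon_len <= len(mk.fwd_primer) + len(mk.rev_primer):
                raise ValidationError(
                    f"marker {mk.name!r}: amplicon shorter than its primers"
                )


@dataclass
class HopEvent:
    source_specimen: str
    source_species: str
    dest_specimen: str
    count: int


@dataclass
class UnitTruth:
    """Ground truth for one specimen x marker amplification."""

    specimen_id: str
    species: str
    marker: str
    true_barcode: str
    pcr_positive: bool
    n_reads: int
    numt_sequence: Optional[str] = None
    numt_coding: Optional[bool] = None
    numt_stop_pos: Optional[int] = None  # stop codon start, non-coding NUMTs
    offtarget_label: Optional[str] = None
    chimeric_read_ids: list[str] = field(default_factory=list)
    hops_in: list[HopEvent] = field(default_factory=list)
    # per-origin read tallies for this unit's own well
    n_true_reads: int = 0
    n_numt_reads: int = 0
    n_offtarget_reads: int = 0
    n_chimera_reads: int = 0
    n_hopped_out: int = 0


@dataclass
class TruthTable:
    units: dict = field(default_factory=dict)  # (specimen, marker) -> UnitTruth
    read_origins: dict = field(default_factory=dict)  # read_id -> origin label

    def to_json(self, path: str) -> None:
        doc = {
            "units": {
                f"{k[0]}|{k[1]}": {
                    "specimen_id": u.specimen_id,
                    "species": u.species,
                    "marker": u.marker,
                    "true_barcode": u.true_barcode,
                    "pcr_positive": u.pcr_positive,
                    "n_reads": u.n_reads,
                    "numt_sequence": u.numt_sequence,
                    "numt_coding": u.numt_coding,
                    "numt_stop_pos": u.numt_stop_pos,
                    "offtarget_label": u.offtarget_label,
                    "chimeric_read_ids": u.chimeric_read_ids,
                    "n_true_reads": u.n_true_reads,
                    "n_numt_reads": u.n_numt_reads,
                    "n_offtarget_reads": u.n_offtarget_reads,
                    "n_chimera_reads": u.n_chimera_reads,
                    "n_hopped_out": u.n_hopped_out,
                    "hops_in": [
                        [h.source_specimen, h.source_species, h.dest_specimen, h.count]
                        for h in u.hops_in
                    ],
                }
                for k, u in self.units.items()
            },
            "read_origins": self.read_origins,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)


# ------------------------------------------------------- sequence evolution

def _random_coding(rng: np.random.Generator, length: int, table_id: int) -> str:
    """Random in-frame coding sequence (no stops) of exactly ``length`` nt;
    the terminal partial codon, if any, is random."""
    stops = _STOPS[table_id]
    n_codons = length // 3
    codons = []
    while len(codons) < n_codons:
        c = "".join(rng.choice(["A", "C", "G", "T"], size=3))
        if c not in stops:
            codons.append(c)
    tail = "".join(rng.choice(["A", "C", "G", "T"], size=length % 3))
    return "".join(codons) + tail


def _mutate_coding(
    rng: np.random.Generator, seq: str, rate: float, table_id: int, frame: int = 0
) -> str:
    """Substitute each site with probability ``rate``, re-drawing any
    substitution that would create an in-frame stop codon."""
    stops = _STOPS[table_id]
    s = list(seq)
    hits = np.nonzero(rng.random(len(s)) < rate)[0]
    for i in hits:
        original = s[i]
        for b in rng.permutation(["A", "C", "G", "T"]):
            if b == original:
                continue
            s[i] = b
            cstart = i - ((i - frame) % 3)
            if cstart < frame or cstart + 3 > len(s):
                break  # partial codon, anything goes
            if "".join(s[cstart : cstart + 3]) not in stops:
                break
            s[i] = original
    return "".join(s)


def _inject_stop(
    rng: np.random.Generator, seq: str, table_id: int, frame: int = 0
) -> tuple[str, int]:
    """Replace one internal codon with a stop codon of the table; returns
    the mutated sequence and the stop codon's start position."""
    stops = sorted(_STOPS[table_id])
    n_codons = (len(seq) - frame) // 3
    ci = int(rng.integers(n_codons // 4, 3 * n_codons // 4))
    pos = frame + 3 * ci
    stop = stops[int(rng.integers(len(stops)))]
    return seq[:pos] + stop + seq[pos + 3 :], pos


def _resolve_iupac(rng: np.random.Generator, primer: str) -> str:
    """Pick one concrete base per degenerate primer position."""
    out = []
    for ch in primer.upper():
        allowed = sorted(IUPAC_BASES[ch])
        out.append(allowed[int(rng.integers(len(allowed)))] if len(allowed) > 1 else ch)
    return "".join(out)


# --------------------------------------------------------------- the run

def simulate_dataset(cfg: SimulationConfig, out_dir: str) -> tuple[dict, TruthTable]:
    """Generate a full dataset under ``out_dir``.

    Writes per-specimen paired FASTQ, the sample sheet, the reference FASTA
    (targets + off-target panel), the per-marker PCR gel table, a ready
    run.yaml, and truth.json. Returns ({'run_config': path, ...}, truth).
    """
    rng = np.random.default_rng(cfg.seed)
    os.makedirs(out_dir, exist_ok=True)
    fastq_dir = os.path.join(out_dir, "fastq")
    os.makedirs(fastq_dir, exist_ok=True)

    species = [f"species_{i + 1:02d}" for i in range(cfg.n_species)]
    samples: list[SampleRecord] = []
    for si, sp in enumerate(species):
        for k in range(cfg.specimens_per_species):
            year = int(rng.integers(cfg.year_range[0], cfg.year_range[1] + 1))
            sid = f"SP{si + 1:02d}_{k + 1:02d}"
            samples.append(
                SampleRecord(
                    specimen_id=sid,
                    species_label=sp,
                    collection_year=year,
                    r1_path=f"fastq/{sid}_R1.fastq",
                    r2_path=f"fastq/{sid}_R2.fastq",
                )
            )

    # --- per-locus species sequences (nested markers share one locus) ---
    locus_of: dict[str, tuple[str, int]] = {}  # marker -> (locus, offset)
    locus_len: dict[str, int] = {}
    nested_long = {long: (short, locus) for long, short, locus in cfg.nested_markers}
    nested_short = {short: (long, locus) for long, short, locus in cfg.nested_markers}
    for mk in cfg.markers:
        if mk.name in nested_short:
            long_name, locus = nested_short[mk.name]
            long_mk = next(m for m in cfg.markers if m.name == long_name)
            offset = long_mk.expected_amplicon_len - mk.expected_amplicon_len
            locus_of[mk.name] = (locus, offset)
            locus_len[locus] = long_mk.expected_amplicon_len
        elif mk.name in nested_long:
            locus = nested_long[mk.name][1]
            locus_of[mk.name] = (locus, 0)
            locus_len[locus] = mk.expected_amplicon_len
        else:
            locus_of[mk.name] = (mk.name, 0)
            locus_len[mk.name] = mk.expected_amplicon_len

    code_of_locus = {
        locus_of[mk.name][0]: mk.genetic_code.table_id for mk in cfg.markers
    }
    species_seq: dict[tuple[str, str], str] = {}  # (locus, species) -> sequence
    for locus in sorted(locus_len):
        root = _random_coding(rng, locus_len[locus], code_of_locus[locus])
        for sp in species:
            species_seq[(locus, sp)] = _mutate_coding(
                rng, root, cfg.species_divergence / 2, code_of_locus[locus]
            )

    def marker_truth(mk: MarkerSpec, sp: str) -> tuple[str, int]:
        """(amplicon sequence, frame offset) of a species on a marker."""
        locus, offset = locus_of[mk.name]
        seq = species_seq[(locus, sp)][offset : offset + mk.expected_amplicon_len]
        return seq, (-offset) % 3

    # --- references: slightly drifted targets + coding off-target panel ---
    ref_sets: dict[str, ReferenceSet] = {}
    offtarget_templates: dict[str, list[tuple[str, str]]] = {}
    for mk in cfg.markers:
        rs = ReferenceSet(mk.name)
        for sp in species:
            seq, frame = marker_truth(mk, sp)
            drifted = _mutate_coding(
                rng, seq, cfg.sanger_divergence, mk.genetic_code.table_id, frame
            )
            rs.entries.append(
                ReferenceEntry(
                    ref_id=f"ref_{mk.name}_{sp}",
                    marker=mk.name,
                    sequence=drifted,
                    species_label=sp,
                    frame_offset=frame,
                    taxon_class=TaxonClass.TARGET,
                )
            )
        templates = []
        for label in ("Wolbachia_sp", "Nematoda_sp"):
            t = _random_coding(
                rng, mk.expected_amplicon_len, mk.genetic_code.table_id
            )
            templates.append((label, t))
            rs.entries.append(
                ReferenceEntry(
                    ref_id=f"off_{mk.name}_{label}",
                    marker=mk.name,
                    sequence=t,
                    species_label=label,
                    frame_offset=0,
                    taxon_class=TaxonClass.OFF_TARGET,
                )
            )
        offtarget_templates[mk.name] = templates
        ref_sets[mk.name] = rs

    # --- per-unit truth: PCR outcome, NUMT, off-target, depths ---
    truth = TruthTable()
    resolved_primers = {}
    spacers = {}
    for s in samples:
        age = cfg.current_year - (s.collection_year or cfg.current_year)
        for mk in cfg.markers:
            p_fail = min(0.95, cfg.pcr_fail_base + cfg.pcr_fail_age_slope * age)
            pcr_pos = bool(rng.random() >= p_fail)
            n_reads = (
                cfg.reads_per_amplicon
                if pcr_pos
                else int(rng.poisson(cfg.reads_per_amplicon * cfg.pcr_neg_read_factor))
            )
            barcode, frame = marker_truth(mk, s.species_label)
            unit = UnitTruth(
                specimen_id=s.specimen_id,
                species=s.species_label,
                marker=mk.name,
                true_barcode=barcode,
                pcr_positive=pcr_pos,
                n_reads=n_reads,
            )
            is_mito = mk.genetic_code is GeneticCode.INVERTEBRATE_MITO
            if is_mito and rng.random() < cfg.numt_rate:
                numt = _mutate_coding(
                    rng, barcode, cfg.numt_divergence, mk.genetic_code.table_id, frame
                )
                coding = bool(rng.random() < cfg.numt_coding_fraction)
                if not coding:
                    numt, stop_pos = _inject_stop(
                        rng, numt, mk.genetic_code.table_id, frame
                    )
                    unit.numt_stop_pos = stop_pos
                unit.numt_sequence = numt
                unit.numt_coding = coding
            if rng.random() < cfg.offtarget_rate:
                idx = int(rng.integers(len(offtarget_templates[mk.name])))
                unit.offtarget_label = offtarget_templates[mk.name][idx][0]
            truth.units[(s.specimen_id, mk.name)] = unit
            resolved_primers[(s.specimen_id, mk.name)] = (
                _resolve_iupac(rng, mk.fwd_primer),
                _resolve_iupac(rng, mk.rev_primer),
            )
            spacers[(s.specimen_id, mk.name)] = (
                "".join(rng.choice(["A", "C", "G", "T"], size=rng.integers(0, 4))),
                "".join(rng.choice(["A", "C", "G", "T"], size=rng.integers(0, 4))),
            )

    # --- emit reads ---
    reads_r1: dict[str, list[ReadRecord]] = {s.specimen_id: [] for s in samples}
    reads_r2: dict[str, list[ReadRecord]] = {s.specimen_id: [] for s in samples}
    counters: dict[str, int] = {s.specimen_id: 0 for s in samples}
    species_of = {s.specimen_id: s.species_label for s in samples}
    specimen_ids = [s.specimen_id for s in samples]

    def emit_pair(dest: str, mk: MarkerSpec, template: str, origin: str,
                  source_unit: UnitTruth) -> str:
        counters[dest] += 1
        rid = f"{dest}.{counters[dest]:06d}"
        fwd, rev = resolved_primers[(source_unit.specimen_id, mk.name)]
        sp_f, sp_r = spacers[(source_unit.specimen_id, mk.name)]
        product = sp_f + fwd + template + revcomp(rev) + revcomp(sp_r)
        r1 = _sequence_read(rng, product, cfg, cfg.quality_decay)
        r2 = _sequence_read(rng, revcomp(product), cfg, 2 * cfg.quality_decay)
        reads_r1[dest].append(ReadRecord(rid, r1[0], r1[1]))
        reads_r2[dest].append(ReadRecord(rid, r2[0], r2[1]))
        truth.read_origins[rid] = origin
        return rid

    for s in samples:
        for mk in cfg.markers:
            unit = truth.units[(s.specimen_id, mk.name)]
            n = unit.n_reads
            if n == 0:
                continue
            offtarget_seq = None
            if unit.offtarget_label is not None:
                offtarget_seq = dict(offtarget_templates[mk.name])[unit.offtarget_label]
            # per-read template assignment
            draws = rng.random(n)
            hop_mask = rng.random(n) < cfg.index_hop_rate
            hop_dest = None
            if hop_mask.any():
                others = [
                    x for x in specimen_ids
                    if species_of[x] != s.species_label
                ]
                hop_dest = others[int(rng.integers(len(others)))]
            hop_count = 0
            for i in range(n):
                r = draws[i]
                template, origin = unit.true_barcode, "true"
                if unit.numt_sequence is not None and r < cfg.numt_read_fraction:
                    template, origin = unit.numt_sequence, "numt"
                elif offtarget_seq is not None and r < cfg.numt_read_fraction + cfg.offtarget_read_fraction:
                    template, origin = offtarget_seq, f"offtarget:{unit.offtarget_label}"
                is_chimera = rng.random() < cfg.chimera_rate
                if is_chimera and unit.numt_sequence is not None and origin == "true":
                    cut = int(
                        rng.integers(len(template) // 3, 2 * len(template) // 3)
                    )
                    template = unit.true_barcode[:cut] + unit.numt_sequence[cut:]
                    origin = "chimera"
                if hop_mask[i] and origin == "true":
                    emit_pair(hop_dest, mk, template,
                              f"hopped:{s.specimen_id}", unit)
                    hop_count += 1
                    unit.n_hopped_out += 1
                else:
                    rid = emit_pair(s.specimen_id, mk, template, origin, unit)
                    if origin == "chimera":
                        unit.chimeric_read_ids.append(rid)
                        unit.n_chimera_reads += 1
                    elif origin == "true":
                        unit.n_true_reads += 1
                    elif origin == "numt":
                        unit.n_numt_reads += 1
                    else:
                        unit.n_offtarget_reads += 1
            if hop_count:
                truth.units[(hop_dest, mk.name)].hops_in.append(
                    HopEvent(s.specimen_id, s.species_label, hop_dest, hop_count)
                )

    # --- write files ---
    for s in samples:
        aio.write_fastq(os.path.join(out_dir, s.r1_path), reads_r1[s.specimen_id])
        aio.write_fastq(os.path.join(out_dir, s.r2_path), reads_r2[s.specimen_id])
    aio.write_sample_sheet(os.path.join(out_dir, "samples.tsv"), samples)
    aio.write_reference_sets(os.path.join(out_dir, "references.fasta"), ref_sets)
    aio.write_pcr_results(
        os.path.join(out_dir, "pcr_results.tsv"),
        {
            (u.specimen_id, u.marker): u.pcr_positive
            for u in truth.units.values()
        },
    )
    truth.to_json(os.path.join(out_dir, "truth.json"))

    run_yaml = os.path.join(out_dir, "run.yaml")
    _write_run_yaml(run_yaml, cfg)
    paths = {
        "run_config": run_yaml,
        "samples": os.path.join(out_dir, "samples.tsv"),
        "references": os.path.join(out_dir, "references.fasta"),
        "pcr_results": os.path.join(out_dir, "pcr_results.tsv"),
        "truth": os.path.join(out_dir, "truth.json"),
        "fastq_dir": fastq_dir,
    }
    return paths, truth


def _sequence_read(
    rng: np.random.Generator, strand: str, cfg: SimulationConfig, decay: float
) -> tuple[str, np.ndarray]:
    """One read of the product: clip to read length, emit decaying Phred
    qualities, and draw substitution errors with per-position probability
    proportional to 10^(-Q/10), normalised so the read-mean equals the
    configured error rate."""
    bases = np.frombuffer(strand[: cfg.read_len].encode(), dtype="S1").copy()
    L = len(bases)
    mean_q = cfg.q_start - decay * np.arange(L)
    quals = np.clip(
        np.rint(rng.normal(mean_q, cfg.q_noise_sd)), 2, 40
    ).astype(np.int16)
    w = np.power(10.0, -quals / 10.0)
    w = w / w.mean()
    p = np.minimum(cfg.error_rate * w, 0.75)
    err = rng.random(L) < p
    if err.any():
        idx = np.nonzero(err)[0]
        for i in idx:
            choices = _BASES[_BASES != bases[i]]
            bases[i] = choices[int(rng.integers(len(choices)))]
    return bases.tobytes().decode(), quals


def _write_run_yaml(path: str, cfg: SimulationConfig) -> None:
    import yaml

    doc = {
        "markers": [
            {
                "name": mk.name,
                "fwd_primer": mk.fwd_primer,
                "rev_primer": mk.rev_primer,
                "expected_amplicon_len": mk.expected_amplicon_len,
                "sequenced_product_len": mk.sequenced_product_len,
                "min_len": mk.min_len,
                "max_len": mk.max_len,
                "genetic_code": mk.genetic_code.value,
                "read_overlap_expected": mk.read_overlap_expected,
            }
            for mk in cfg.markers
        ],
        "samples": "samples.tsv",
        "references": "references.fasta",
        "pcr_results": "pcr_results.tsv",
        "thresholds": {},
        "merge_plan": [
            {"long": long, "short": short, "output": locus, "reference_marker": long}
            for long, short, locus in cfg.nested_markers
            if any(m.name == long for m in cfg.markers)
            and any(m.name == short for m in cfg.markers)
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
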