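"""End-to-end orchestration: raw paired FASTQ per specimen to curated
per-specimen, per-marker barcodes plus the curation report.

Step 1 (per specimen): merge attempt per pair, marker assignment and
primer/spacer removal, quality truncation of unmerged streams, length
filters, dereplication, chimera removal, clustering, small-cluster
removal. Step 2 (per cluster consensus): reference alignment and frame,
translation screen, taxon screen, cross-contamination flag, major-cluster
selection, read-half joining and long+short marker merging, reporting.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import io as aio
from .assembly import join_read_halves, merge_markers
from .cluster import (
    cluster_sequences,
    filter_small_clusters,
    remove_chimeras,
)
from .model import (
    ConsensusRecord,
    MarkerSpec,
    QCFlag,
    ReferenceSet,
    RunConfig,
    SpecimenBarcode,
    Stream,
)
from .qc import (
    RefAlignment,
    align_to_reference,
    flag_contaminants,
    screen_coding,
    screen_taxon,
    select_major,
)
from .readprep import (
    assign_marker,
    dereplicate,
    length_filter,
    merge_pair,
    quality_truncate,
)
from .report import (
    CurationReport,
    FinalMarkerCounts,
    MarkerStageCounts,
    build_nj_tree,
    distance_matrix,
    flag_problem_species,
    success_by_year_series,
)
from .seq import revcomp


@dataclass
class PipelineResult:
    config: RunConfig
    records: list[ConsensusRecord] = field(default_factory=list)
    ref_alignments: dict = field(default_factory=dict)  # id(record) -> RefAlignment
    primaries: dict = field(default_factory=dict)
    # (specimen, marker, stream) -> (primary, secondary)
    barcodes: list[SpecimenBarcode] = field(default_factory=list)
    report: Optional[CurationReport] = None
    trees: dict = field(default_factory=dict)  # final marker -> PhyloTree
    unassigned_reads: int = 0
    assigned_reads: int = 0

    def barcode_for(self, specimen_id: str, marker: str) -> list[SpecimenBarcode]:
        return [
            b
            for b in self.barcodes
            if b.specimen_id == specimen_id and b.marker == marker
        ]


def _prepare_streams(config: RunConfig):
    """Step-1 front end: returns ({(specimen, marker, stream): [bases]},
    assigned count, unassigned count)."""
    thr = config.thresholds
    buckets: dict[tuple[str, str, Stream], list[str]] = {}
    assigned = unassigned = 0
    for sample in config.samples:
        pairs = aio.read_fastq_pairs(sample.r1_path, sample.r2_path)
        for pair in pairs:
            mr = merge_pair(pair, thr.merge_min_overlap, thr.merge_max_mismatch_rate)
            if mr.merged is not None:
                hit = assign_marker(
                    mr.merged, config.markers, thr.max_primer_mismatches, thr.max_spacer
                )
                if hit is None:
                    unassigned += 1
                    continue
                assigned += 1
                buckets.setdefault(
                    (sample.specimen_id, hit.marker.name, Stream.MERGED), []
                ).append(hit.trimmed.bases)
            else:
                hit = assign_marker(
                    pair, config.markers, thr.max_primer_mismatches, thr.max_spacer
                )
                if hit is None:
                    unassigned += 1
                    continue
                assigned += 1
                r1 = quality_truncate(hit.trimmed.r1, thr.quality_min)
                r2 = quality_truncate(hit.trimmed.r2, thr.quality_min)
                key1 = (sample.specimen_id, hit.marker.name, Stream.READ1)
                key2 = (sample.specimen_id, hit.marker.name, Stream.READ2)
                buckets.setdefault(key1, []).append(r1.bases)
                # read-2 stream is reverse-complemented right after primer
                # removal so every downstream sequence is plus-strand
                buckets.setdefault(key2, []).append(revcomp(r2.bases))
    # length filters: the marker's own [min, max] window applies to the
    # merged stream; unmerged half-streams only get the global floor
    filtered: dict[tuple[str, str, Stream], list[str]] = {}
    for (sid, marker, stream), seqs in buckets.items():
        mk = config.marker(marker)
        if stream is Stream.MERGED and mk.min_len is not None:
            kept = length_filter(seqs, max(mk.min_len, thr.min_len), mk.max_len)
        else:
            kept = length_filter(seqs, thr.min_len, None)
        if kept:
            filtered[(sid, marker, stream)] = kept
    return filtered, assigned, unassigned


def run(config: RunConfig, output_dir: Optional[str] = None) -> PipelineResult:
    """Run the full two-step workflow on a loaded configuration."""
    thr = config.thresholds
    result = PipelineResult(config=config)
    species_of = {s.specimen_id: s.species_label for s in config.samples}

    ref_sets: dict[str, ReferenceSet] = {}
    if config.reference_path:
        ref_sets = aio.read_reference_sets(config.reference_path)
    pcr = (
        aio.read_pcr_results(config.pcr_results_path)
        if config.pcr_results_path
        else {}
    )

    buckets, assigned, unassigned = _prepare_streams(config)
    result.assigned_reads, result.unassigned_reads = assigned, unassigned

    # ---- dereplicate, de-chimera, cluster per specimen x marker x stream
    clusters_by_key = {}
    for key in sorted(buckets, key=lambda k: (k[0], k[1], k[2].value)):
        sid, marker, stream = key
        uniques = dereplicate(buckets[key], sid, marker, stream)
        kept, _ = remove_chimeras(
            uniques, thr.chimera_min_parent_ratio, thr.chimera_min_score
        )
        clusters = cluster_sequences(
            kept, thr.cluster_min_overlap, thr.cluster_min_identity
        )
        clusters = filter_small_clusters(clusters, thr.min_cluster_reads)
        if clusters:
            clusters_by_key[key] = clusters

    # ---- step 2 screens
    for key, clusters in clusters_by_key.items():
        sid, marker, stream = key
        mk = config.marker(marker)
        refset = ref_sets.get(marker)
        for cl in clusters:
            rec = ConsensusRecord(
                specimen_id=sid,
                marker=marker,
                stream=stream,
                sequence=cl.consensus,
                rank=cl.rank,
                total_reads=cl.total_reads,
            )
            if refset is not None and refset.entries:
                ra = align_to_reference(cl.consensus, refset, thr.ref_floor_identity)
            else:
                ra = None
            if ra is None:
                rec.unalignable = True
                # unalignable records go straight to the taxon screen
                if refset is not None and refset.entries:
                    verdict, label = screen_taxon(
                        cl.consensus, refset, thr.min_target_identity
                    )
                else:
                    verdict, label = "unknown", None
                rec.taxon = verdict if verdict != "off_target" else label
                if verdict == "off_target":
                    rec.qc_flags.add(QCFlag.OFF_TARGET)
                    rec.taxon = label
                else:
                    rec.taxon = "unknown"
            else:
                rec.best_reference = (ra.entry.ref_id, ra.identity)
                rec.frame = ra.frame
                rec.strand = ra.strand
                rec.sequence = ra.oriented_sequence
                result.ref_alignments[id(rec)] = ra
                ok, reasons = screen_coding(
                    rec.sequence, ra.frame, mk.genetic_code, ra.alignment
                )
                if not ok:
                    rec.qc_flags.add(QCFlag.NON_CODING)
                    rec.fail_reasons.extend(reasons)
                else:
                    verdict, label = screen_taxon(
                        rec.sequence, refset, thr.min_target_identity
                    )
                    if verdict == "off_target":
                        rec.qc_flags.add(QCFlag.OFF_TARGET)
                        rec.taxon = label
                    else:
                        rec.taxon = verdict
            result.records.append(rec)

    # ---- cross-contamination screen (records that survived the earlier
    # screens, compared across specimens within each marker)
    contaminant_pairs = []
    for marker in sorted({m.name for m in config.markers}):
        eligible = [
            r
            for r in result.records
            if r.marker == marker and not r.excluded and r.taxon == "target"
        ]
        contaminant_pairs.extend(
            flag_contaminants(eligible, species_of, config.allowed_hybrid_pairs)
        )

    # ---- major-cluster selection and barcode assembly
    barcodes: list[SpecimenBarcode] = []
    for sample in config.samples:
        sid = sample.specimen_id
        for mk in config.markers:
            recs = [
                r for r in result.records if r.specimen_id == sid and r.marker == mk.name
            ]
            merged_recs = [r for r in recs if r.stream is Stream.MERGED]
            if merged_recs:
                primary, secondary = select_major(merged_recs, thr.min_copy_divergence)
                result.primaries[(sid, mk.name, Stream.MERGED)] = (primary, secondary)
                if primary is not None:
                    barcodes.append(
                        SpecimenBarcode(
                            specimen_id=sid,
                            marker=mk.name,
                            sequence=primary.sequence,
                            sources=[primary],
                            dual_copy=secondary is not None,
                        )
                    )
                    if secondary is not None:
                        barcodes.append(
                            SpecimenBarcode(
                                specimen_id=sid,
                                marker=mk.name,
                                sequence=secondary.sequence,
                                sources=[secondary],
                                dual_copy=True,
                            )
                        )
                    continue
            half_primary = {}
            for stream in (Stream.READ1, Stream.READ2):
                stream_recs = [r for r in recs if r.stream is stream]
                if not stream_recs:
                    continue
                primary, secondary = select_major(stream_recs, thr.min_copy_divergence)
                result.primaries[(sid, mk.name, stream)] = (primary, secondary)
                if primary is not None:
                    half_primary[stream] = primary
            if half_primary:
                rec1 = half_primary.get(Stream.READ1)
                rec2 = half_primary.get(Stream.READ2)
                ra1 = result.ref_alignments.get(id(rec1)) if rec1 else None
                ra2 = result.ref_alignments.get(id(rec2)) if rec2 else None
                if rec1 is not None and rec2 is not None and (
                    ra1 is None or ra2 is None or ra1.entry.ref_id != ra2.entry.ref_id
                ):
                    # inconsistent placement: keep the better-supported half
                    rec1, rec2 = (
                        (rec1, None)
                        if rec1.total_reads >= rec2.total_reads
                        else (None, rec2)
                    )
                    ra1 = result.ref_alignments.get(id(rec1)) if rec1 else None
                    ra2 = result.ref_alignments.get(id(rec2)) if rec2 else None
                barcodes.append(join_read_halves(rec1, rec2, ra1, ra2, mk.name))

    # ---- long + short marker merging
    final_barcodes: list[SpecimenBarcode] = []
    merged_away: set[int] = set()
    final_name_of_marker = {m.name: m.name for m in config.markers}
    for plan in config.merge_plan:
        long_m, short_m = plan["long"], plan["short"]
        out_m = plan.get("output", long_m)
        ref_marker = plan.get("reference_marker", long_m)
        final_name_of_marker[long_m] = out_m
        final_name_of_marker[short_m] = out_m
        refset = ref_sets.get(ref_marker)
        for sample in config.samples:
            sid = sample.specimen_id
            longs = [
                b for b in barcodes
                if b.specimen_id == sid and b.marker == long_m and not b.dual_copy
            ]
            shorts = [
                b for b in barcodes
                if b.specimen_id == sid and b.marker == short_m and not b.dual_copy
            ]
            if not (longs and shorts) or refset is None or not refset.entries:
                continue
            lb, sb = longs[0], shorts[0]
            ra_l = align_to_reference(lb.sequence, refset, thr.ref_floor_identity)
            ra_s = align_to_reference(sb.sequence, refset, thr.ref_floor_identity)
            if ra_l is None or ra_s is None:
                continue
            mm = merge_markers(lb, sb, ra_l, ra_s, out_m)
            if mm.is_merged:
                final_barcodes.append(mm.merged)
                merged_away.add(id(lb))
                merged_away.add(id(sb))
    for b in barcodes:
        if id(b) in merged_away:
            continue
        out = final_name_of_marker.get(b.marker, b.marker)
        if out != b.marker:
            b = SpecimenBarcode(
                specimen_id=b.specimen_id,
                marker=out,
                sequence=b.sequence,
                gap_intervals=b.gap_intervals,
                sources=b.sources,
                dual_copy=b.dual_copy,
                conflict=b.conflict,
            )
        final_barcodes.append(b)
    result.barcodes = final_barcodes

    # ---- trees and problem species per final marker
    ref_marker_of_final = {}
    for m in config.markers:
        ref_marker_of_final[final_name_of_marker[m.name]] = m.name
    for plan in config.merge_plan:
        ref_marker_of_final[plan.get("output", plan["long"])] = plan.get(
            "reference_marker", plan["long"]
        )
    problem_by_marker = {}
    for final_marker in sorted({final_name_of_marker[m.name] for m in config.markers}):
        seqs: dict[str, str] = {}
        spmap: dict[str, str] = {}
        for b in result.barcodes:
            if b.marker != final_marker:
                continue
            bid = f"{b.specimen_id}.{b.marker}"
            if bid in seqs:
                bid = f"{bid}.copy2"
            seqs[bid] = b.sequence
            spmap[bid] = species_of[b.specimen_id]
        refset = ref_sets.get(ref_marker_of_final.get(final_marker, final_marker))
        if refset is not None:
            for e in refset.targets:
                seqs[e.ref_id] = e.sequence
                spmap[e.ref_id] = e.species_label
        if len(seqs) < 3:
            continue
        tree_path = config.tree_paths.get(final_marker)
        if tree_path:
            from .report import PhyloTree

            with open(tree_path) as fh:
                tree = PhyloTree.from_newick(fh.read())
        else:
            dm = distance_matrix(list(seqs), [seqs[k] for k in seqs])
            tree = build_nj_tree(dm)
        result.trees[final_marker] = tree
        problem_by_marker[final_marker] = flag_problem_species(
            seqs, spmap, tree, thr.problem_divergence
        )

    # ---- curation report
    result.report = _summarize(
        config, result, clusters_by_key, pcr, problem_by_marker, contaminant_pairs,
        final_name_of_marker,
    )
    if output_dir:
        os.makedirs(output_dir, exist_ok=True)
        aio.write_fasta(
            os.path.join(output_dir, "barcodes.fasta"),
            [
                (
                    f"{b.specimen_id}.{b.marker}"
                    + (" dual_copy" if b.dual_copy else ""),
                    b.sequence,
                )
                for b in result.barcodes
            ],
        )
        result.report.write(output_dir)
        for marker, tree in result.trees.items():
            with open(os.path.join(output_dir, f"tree_{marker}.nwk"), "w") as fh:
                fh.write(tree.to_newick() + "\n")
    return result


def run_from_config(path: str, output_dir: Optional[str] = None) -> PipelineResult:
    return run(aio.load_run_config(path), output_dir)


# ------------------------------------------------------------- summarize

def _summarize(
    config: RunConfig,
    result: PipelineResult,
    clusters_by_key: dict,
    pcr: dict,
    problem_by_marker: dict,
    contaminant_pairs: list,
    final_name_of_marker: dict,
) -> CurationReport:
    report = CurationReport()
    n_specimens = len(config.samples)
    species = sorted({s.species_label for s in config.samples})
    species_of = {s.specimen_id: s.species_label for s in config.samples}

    # --- per marker x stream stage counts (step-1/step-2 funnel)
    for mk in config.markers:
        streams = sorted(
            {k[2] for k in clusters_by_key if k[1] == mk.name}, key=lambda s: s.value
        )
        for stream in streams:
            sc = MarkerStageCounts(
                marker=mk.name, stream=stream.value, n_specimens=n_specimens
            )
            cluster_counts = []
            for sample in config.samples:
                sid = sample.specimen_id
                pcr_pos = pcr.get((sid, mk.name), True)
                if pcr_pos:
                    sc.pcr_positive += 1
                clusters = clusters_by_key.get((sid, mk.name, stream), [])
                recs = [
                    r
                    for r in result.records
                    if r.specimen_id == sid and r.marker == mk.name and r.stream is stream
                ]
                if clusters:
                    sc.with_cluster += 1
                    cluster_counts.append(len(clusters))
                    if not pcr_pos:
                        sc.with_cluster_pcr_neg += 1
                elif pcr_pos:
                    sc.pcr_pos_no_cluster += 1
                if not recs:
                    sc.no_cluster_specimens += 1
                    continue
                coding = [r for r in recs if QCFlag.NON_CODING not in r.qc_flags]
                if coding:
                    sc.passed_translation += 1
                major = min(recs, key=lambda r: r.rank)
                if QCFlag.NON_CODING in major.qc_flags:
                    sc.major_failed_translation += 1
                coding_majors = [r for r in coding]
                if coding_majors:
                    cm = min(coding_majors, key=lambda r: r.rank)
                    if QCFlag.OFF_TARGET in cm.qc_flags:
                        sc.major_off_target += 1
                    elif QCFlag.CONTAMINANT in cm.qc_flags:
                        sc.major_contaminant += 1
                # exclusive specimen-level funnel categories
                if not coding:
                    sc.removed_translation_specimens += 1
                else:
                    targets = [
                        r
                        for r in coding
                        if QCFlag.OFF_TARGET not in r.qc_flags and r.taxon == "target"
                    ]
                    if not targets:
                        sc.removed_taxon_specimens += 1
                    elif all(QCFlag.CONTAMINANT in r.qc_flags for r in targets):
                        sc.removed_contaminant_specimens += 1
                    else:
                        sc.valid_specimens += 1
            if cluster_counts:
                sc.mean_clusters = float(np.mean(cluster_counts))
                sc.max_clusters = int(np.max(cluster_counts))
            report.stage_counts.append(sc)

    # --- per final marker counts
    finals = sorted({final_name_of_marker[m.name] for m in config.markers})
    source_markers = {
        f: [m.name for m in config.markers if final_name_of_marker[m.name] == f]
        for f in finals
    }
    for final_marker in finals:
        fc = FinalMarkerCounts(
            marker=final_marker,
            n_specimens=n_specimens,
            n_species=len(species),
        )
        seq_species = set()
        for sample in config.samples:
            sid = sample.specimen_id
            bars = [
                b
                for b in result.barcodes
                if b.specimen_id == sid and b.marker == final_marker
            ]
            pcr_any = any(
                pcr.get((sid, m), True) for m in source_markers[final_marker]
            )
            if bars:
                fc.with_sequence += 1
                seq_species.add(species_of[sid])
                if not pcr_any:
                    fc.with_sequence_pcr_neg += 1
                if len(bars) > 1 or any(b.dual_copy for b in bars):
                    fc.two_valid_sequences += 1
                if any(b.gap_intervals for b in bars):
                    fc.internal_gap_sequences += 1
            elif pcr_any:
                fc.pcr_pos_no_sequence += 1
        fc.species_with_sequence = len(seq_species)
        fc.problem_species = len(problem_by_marker.get(final_marker, []))
        report.final_counts.append(fc)
    report.problem_species = problem_by_marker
    report.contaminant_pairs = contaminant_pairs

    # --- amplification success vs storage time
    years, successes = [], []
    for sample in config.samples:
        for mk in config.markers:
            if (sample.specimen_id, mk.name) in pcr:
                years.append(sample.collection_year)
                successes.append(pcr[(sample.specimen_id, mk.name)])
    series, corr = success_by_year_series(years, successes)
    report.success_by_year = series
    report.year_rank_correlation = corr
    return report
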