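# ampliqc

Clustering, consensus calling and quality control for **multi-amplicon DNA
barcoding**: from multiplexed paired-end reads of several markers per
specimen (e.g. two overlapping COI fragments, Cytb, EF1a) to curated
per-specimen, per-marker consensus barcode sequences with explicit QC
flags.

High-throughput amplicon sequencing makes it cheap to barcode hundreds of
specimens on several markers at once, but the deep read piles also surface
everything Sanger chromatograms used to hide: nuclear mitochondrial
pseudogenes (NUMTs) and heteroplasmies, symbiont and parasite
co-amplification (*Wolbachia*, nematodes), PCR chimeras, and
cross-specimen contamination via index hopping. The cluster with the most
reads is **not** always the barcode. `ampliqc` implements a two-step
workflow for this problem, aimed at people building barcode reference
libraries or doing integrative taxonomy.

## The method

**Step 1 — reads to clusters**, per specimen:

1. attempt to merge each read pair by its best end overlap (lowest
   mismatch rate, longer overlap on ties; disagreements resolved to the
   higher-quality base);
2. assign merged reads / unmerged pairs to a marker by IUPAC-aware primer
   matching at 0–3 nt heterogeneity-spacer offsets, and strip
   spacer+primer; unmerged pairs continue as separate read-1/read-2
   streams (read 2 reverse-complemented to plus strand);
3. truncate unmerged reads at the first base with quality < Q21; drop
   sequences < 150 nt (plus a per-marker length window, e.g. 400–550 nt,
   for fully merged fragments);
4. dereplicate, remove de-novo chimeras (a query is chimeric when a
   two-parent single-crossover model beats every single parent by ≥ 3
   diagnostic sites, with parents ≥ 2× its abundance);
5. cluster by greedy abundance-seeded agglomeration under an end-free
   overlap alignment (overlap ≥ 100 nt, identity ≥ 97%), so
   quality-truncated reads of different lengths still co-cluster, and call
   an abundance-weighted majority consensus; drop clusters with < 10
   reads.

**Step 2 — clusters to curated barcodes**, per cluster consensus:

1. align to a curated reference set (both strands, free end gaps) and
   inherit the reading frame: a consensus starting at reference position
   *p* has frame `(ref_frame − p) mod 3`;
2. **coding screen**: reject consensuses with an in-frame premature stop
   codon (invertebrate mitochondrial code for mito markers) or a
   frame-shifting net indel vs. the reference;
3. **taxon screen**: nearest-reference classification against targets
   plus an off-target panel (symbionts/parasites);
4. **contamination screen**: sequences 100% identical over their full
   shared extent between specimens of different, non-hybridizing species
   are flagged; the smaller cluster is dropped, ties go to manual review;
5. **major-cluster selection**: the passing cluster with most reads wins;
   a second passing cluster > 3% p-distance away is retained with a
   `DUAL_COPY` flag (coding NUMT / heteroplasmy — no objective criterion
   can pick one);
6. **assembly**: read-1/read-2 half consensuses of non-overlapping
   markers are joined at their reference coordinates (uncovered span
   padded with N and recorded as a gap interval); a long and a short
   fragment of the same locus merge into the longest possible sequence iff
   their doubly-called positions agree exactly;
7. **reporting**: per-marker funnel counts with printed-style percentages,
   per-collection-year amplification success, and problem-species flags —
   species that are paraphyletic on a (supplied or neighbor-joining) tree
   or whose sequences split into single-linkage groups > 7% p-distance
   apart.

A deterministic simulator (`ampliqc.simulate`) generates full synthetic
runs — species sequences, paired FASTQ with a decaying quality model,
NUMTs, off-target reads, chimeras, index hopping, age-dependent PCR
failure — together with a ground-truth table, so the entire pipeline is
testable offline.

## Worked example

```bash
python examples/01_simulate_and_run.py
```

```
reads assigned: 1100, unassigned: 4
   marker stream  with_cluster  passed_translation  valid_specimens
 COI-long  read1             6                   6                6
 COI-long  read2             6                   6                6
COI-short merged             4                   4                4
     Cytb merged             4                   4                4
       EF merged             4                   3                3

marker  with_sequence  with_sequence_pct  two_valid_sequences  internal_gap_sequences
   COI              6              100.0                    0                       2
  Cytb              4               66.7                    0                       0
    EF              3               50.0                    0                       0

primaries equal to truth: 23/23
```

Six specimens, four markers. COI-long pairs cannot overlap (709-nt product
vs 2 × 300 nt reads) and run as separate read-1/read-2 streams; all six
specimens get a final COI, two of them with an annotated internal N gap
where neither half nor the short fragment covered the middle. Cytb/EF
columns are lower because some reactions failed PCR in the simulation.
Every reported primary consensus equals the true template.

The other examples show overlap geometry prediction
(`02_overlap_prediction.py`), chimera detection and clustering on a toy
set (`03_chimera_and_clustering.py`), and distance/tree-based
problem-species flagging (`04_species_flags.py`). A thin CLI mirrors the
library: `ampliqc simulate`, `ampliqc validate-config`, `ampliqc run`.

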