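# Methods

## Scope and data model

`ampliqc` curates per-specimen, per-marker barcode sequences from
demultiplexed paired-end amplicon reads. The unit of accounting is the
*specimen × marker* amplification; within it, sequences flow as one
*merged* stream (pairs whose mates overlap) and/or separate *read-1* /
*read-2* streams. Streams are never co-clustered: half-reads and merged
full-length sequences measure different extents of the amplicon and mixing
them would blur cluster abundances.

A marker is described by its primers, expected amplicon length and genetic
code; the *sequenced product* (forward primer + amplicon + reverse primer)
is derived, never stored, so the length invariant holds by construction.
With 2 × 300 nt chemistry the shipped four-marker design gives products of
709 / 460 / 485 / 563 nt, hence geometric overlap predictions no / yes /
yes / yes. The prediction is advisory only: the pipeline attempts a merge
on every pair and routes by the outcome, because quality truncation can
defeat a nominally positive overlap (the 563-nt fragment is the classic
case).

The shipped primer *sequences* are defaults to be replaced with the user's
own oligos. Published primer sequences are used where their lengths match
the product arithmetic (the 25/26-nt COI pair, the 26/26-nt Cytb pair);
the remaining two are synthetic placeholders of the documented lengths.
All product-length behaviour depends only on primer lengths.

## Read preparation

**Merging.** R1 is aligned against the reverse complement of R2 at every
end-overlap length ≥ `merge_min_overlap`; the candidate with the lowest
mismatch rate wins (longer overlap on ties) and is accepted at rate ≤ 0.25.
Disagreements take the higher-quality base (ties → R1), merged quality is
the per-position maximum. The default `merge_min_overlap` is 25 nt rather
than the 10 nt a typical merger uses: with hundreds of candidate offsets
per pair, a 10-nt window passes the 0.25 mismatch gate by chance often
enough that non-overlapping fragments acquire systematic false junctions
(the same spurious junction for every read of a template, which then
survives clustering). At 25 nt the chance acceptance rate is negligible
while the smallest true overlap in the shipped design (37 nt) still
merges. Both parameters are config-exposed.

**Marker assignment.** The forward primer is searched at 5' offsets 0–3
(the heterogeneity spacer range) with IUPAC-aware Hamming distance ≤ 1 per
primer; merged reads must also show the reverse-complemented reverse
primer at the 3' end, unmerged pairs show the reverse primer at the R2 5'
end. Ties go to fewest mismatches, then configuration order, and are
logged as ambiguous. Spacer and primer bases are removed; the read-2
stream is reverse-complemented immediately after primer removal so all
downstream sequences are plus-strand.

**Truncation and length filters.** Unmerged reads are truncated before the
first base with Q < 21 (idempotent by construction; merged sequences are
not truncated — their overlap was already error-corrected). Everything
shorter than 150 nt is dropped. A marker's own [min, max] window (400–550
for the two fully merged mitochondrial fragments) applies to the merged
stream only: applying it to ~275-nt half-reads would empty those streams.

## Denoising and clustering

**Chimeras.** Uniques are scanned from least to most abundant. Candidate
parents are unflagged uniques with ≥ 2× the query's abundance. For each
parent, the query's cumulative mismatch profile is computed from an
*infix* alignment (free parent overhangs — a global alignment would charge
parent/query length differences to the model and, because those end-gap
costs land differently per parent, invent crossover gains). A query is
chimeric when the best left-parent/right-parent single-crossover model
beats the best single parent by ≥ 3 sites and each parent contributes at
least one diagnostic site. The pair × crossover search is exhaustive
(vectorised over a parents × parents × positions cost tensor).

**Clustering.** Greedy abundance-seeded agglomeration in canonical order
(abundance desc, lexicographic tiebreak — this makes the whole pipeline
deterministic). A unique joins the first cluster whose consensus it
matches at ≥ 97% identity over ≥ 100 alignment columns under an end-free
overlap alignment; otherwise it seeds a new cluster. The alignment is
infix (shorter sequence within the longer, free ends on the longer), which
handles both 3'-truncated forward reads and 5'-truncated (plus-strand)
reverse reads; fixed-length clustering fragments such data into spurious
clusters. Consensus is refreshed incrementally from a per-seed-column
weight profile, so clustering stays linear in alignments.

**Consensus.** Abundance-weighted per-column majority over members aligned
to the seed. Ties resolve toward the base carried by the most abundant
member; columns with a strict gap majority (> 50% of weight, end gaps
included) are omitted, so a truncated majority shortens the consensus.
Member insertions relative to the seed are dropped — at the error rates
this tool targets, a majority-supported insertion does not occur.
Clusters with < 10 reads are removed.

## Quality-control screens

Screens run in a fixed order — reference alignment → translation → taxon →
contamination → major-cluster selection — and a record failing an earlier
screen never reaches a later one, keeping per-stage report counts
additive.

**Reference alignment and frame.** Each consensus is aligned to every
reference for its marker on both strands with free end gaps; the best
identity wins. Identity < 0.60 routes the record to the taxon screen as
"unalignable". The frame is inherited from the reference:
`(frame_offset − ref_start) mod 3` (removing *p* leading bases advances
the first codon start to `(f − p) mod 3`; verified by translation).

**Coding screen.** Fail on an in-frame stop codon anywhere in the
translated fragment (these are mid-gene amplicons — any stop is
premature; terminal partial codons are not translated), or on a
frame-shifting indel vs. the reference. Frameshift is judged by the *net*
internal indel offset mod 3, not per indel run: optimal-alignment cost
ties can trade two mismatches for a balanced 1-nt insertion/deletion pair,
which preserves frame and must not fail the screen; genuinely unbalanced
indels shift the frame and (in divergent copies) also produce downstream
stops that the first rule catches.

**Taxon screen.** Nearest-reference classification over targets plus an
off-target panel. Best hit in the panel → `OFF_TARGET`; best target hit
below 0.75 identity → unknown (excluded, logged). The local panel replaces
a live remote similarity search so tests are hermetic; an external hook
can be configured instead.

**Contamination.** All passing records of a marker are compared across
specimens; two records from different species (and not a configured
hybridizing pair) that are 100% identical over their full shared extent
are contaminant candidates. Resolution is automated for reproducibility —
drop the smaller cluster, flag both on ties — and every candidate pair is
written to the report as an audit trail for manual review.

**Major cluster and dual copies.** Among fully passing records the one
with most reads is the primary (ties: longer consensus, then
lexicographic). The second-ranked record is retained with `DUAL_COPY` iff
its p-distance to the primary exceeds 0.03 — far above residual sequencing
error at the default error rates, below the 7–10% where divergent coding
copies (NUMTs, heteroplasmies) live. For non-overlapping markers,
selection runs per read-1/read-2 stream and the selected halves are then
joined; when a marker has both merged and unmerged records, merged wins.

## Assembly and final reporting

Read halves are placed at their best-reference coordinates; an uncovered
span between them becomes an explicit N run in `gap_intervals`
(half-open, 0-based; join padding only — never base-call Ns). Conflicting
overlap keeps both calls and flags the barcode. A long and a short
fragment of the same locus merge into their position-wise union iff every
doubly-called position agrees exactly; one disagreement keeps both
sequences in the final set (counted as "two valid sequences"). Merging is
commutative and idempotent, and N padding never increases.

**p-distance** is differing sites over sites where both sequences have
A/C/G/T, after a global alignment (equal lengths) or a shared-extent infix
alignment (unequal). The argument pair is canonically ordered internally
because optimal alignment paths can tie, which would otherwise break
symmetry. **Trees**: a user-supplied newick takes precedence; otherwise a
neighbor-joining tree is built (via scikit-bio) from the p-distance matrix
of final barcodes plus target references. **Problem species** are flagged
if paraphyletic (some edge bipartition must isolate exactly the species'
leaves; singletons are monophyletic) or if their sequences split into ≥ 2
single-linkage groups at p-distance strictly > 0.07 — single linkage
because it is the reproducible operationalisation of "clusters into
divergent groups", parameter-free beyond the stated threshold, and the
boundary is strict.

Report percentages are rounded half-up to one decimal, matching how such
tables are conventionally printed. Amplification success is summarised per
collection year with its Spearman rank correlation (success declines with
specimen age in ethanol).

## The simulator

`ampliqc.simulate` emulates the study design end to end. Default
conditions: 6 species × 3 specimens, four markers, 150 read pairs per
amplification, 2 × 300 nt reads.

* **Species sequences** are stop-free codon sequences evolved from a
  random root at 10% pairwise divergence (codon-aware substitutions). The
  two COI fragments are nested views of one locus, so fragment merging has
  a real shared template. References are the species sequences drifted by
  0.2% (a "Sanger" set), plus two coding off-target templates per marker.
* **Reads** carry spacer (0–3 nt) + primer + template; qualities follow a
  linearly decaying mean (slope 0.03 Q/nt on R1, 2× on R2, Gaussian noise,
  clipped to [2, 40]); substitution errors are drawn per position with
  probability proportional to 10^(−Q/10), normalised so the read-mean
  equals the configured 1% — errors concentrate in the low-quality tail,
  which is what drives truncation-length variation in the half streams.
* **Artefacts**: NUMTs in 10% of mitochondrial units at 8% divergence,
  half of them coding, half carrying a premature stop (position recorded);
  NUMT reads take a 10% share. Off-target co-amplification in 5% of units
  (35% read share). Chimeras at 1% per read (true × NUMT crossover).
  Index hopping at 5% per read, concentrated into one destination
  specimen per unit — per-read independent hops at realistic rates almost
  never reach the 10-read cluster floor, whereas real index conversion
  arrives in bursts; the burst model is what makes the contamination
  screen testable end to end. PCR failure probability grows with specimen
  age (5% base + 1.2%/year); failed reactions still leak ~7% read depth,
  reproducing the "negative PCR that still yields a sequence" phenomenon.

Every read id appears exactly once in the truth table with its origin; a
fixed seed gives byte-identical output.

**What the simulator does not model** — and hence what passing tests do
not show about real data: PCR amplification bias and depth variation
between markers, indel sequencing errors (substitutions only), degraded
or co-extracted DNA, within-species haplotype variation (specimens of a
species share one haplotype, so contaminant detection sees exact
identity), primer-template mismatch dropout, and multi-way chimeras.

## Evaluation metrics

`ampliqc.evaluate` scores a run against the truth table. A primary is
*correct* when every called (non-N) position equals the true template at
its aligned position with no internal indels — full-length equality for
merged markers, called-extent equality for joined halves. Stop-NUMT
removal counts an escape only when a passing record's extent actually
contains the injected stop codon (a read half that never covered the stop
is a biological blind spot of translation screening, not a screen
failure). A contamination event (hop burst ≥ 10 reads) is caught when its
cluster is flagged, or when attrition kept it below the cluster floor so
nothing contaminated the final set; only an unflagged surviving copy of
the source sequence counts as a miss.

## Problem sizes

The test suite and acceptance script run the simulator at its default
conditions (18 specimens × 4 markers, ~9,500 read pairs, ≈25 s) — chosen
as the smallest design in which every artefact class occurs several times
per run. Oracle-equivalence tests use up to 200 uniques (clustering vs.
brute-force single linkage), 50 uniques (chimera scan vs. exhaustive
crossover enumeration), 12-leaf trees (monophyly vs. edge-cut
enumeration) and 4-taxon additive matrices (exact NJ recovery).

## Known limitations

* Consensus columns are capped at the seed's extent; a cluster whose seed
  is shorter than most members yields a seed-length consensus.
* The contamination rule requires exact shared-extent identity; hopped
  reads that acquired a consensus-level error (not observed at default
  depths) would evade it.
* Frame assignment depends on a reference; markers without references
  skip the coding and taxon screens (records pass through unflagged).
* Paraphyly flags inherit whatever tree is supplied; the built-in NJ
  fallback is distance-based and can differ from a likelihood tree near
  short internal branches.
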