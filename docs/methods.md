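# Methods

## Problem setting and assumptions

`mitoloop` targets the regime where an organism has been whole-genome
sequenced with long, highly accurate reads (circular-consensus long reads:
roughly 5–20 kb, per-base error well under 1 %), and the mitochondrial
genome — a circular molecule of ~13–150 kb present at high copy number —
must be extracted, assembled, circularized, annotated and reported. The
pipeline assumes:

- a closely-related reference mitogenome with GenBank annotation is
  available; recruitment and annotation are homology-based throughout;
- reads are accurate enough that true overlaps align at ≥99 % identity,
  so overlap detection can demand near-exact agreement and treat anything
  below it as a different locus (NUMT) or a different haplotype;
- the genome contains no repeat longer than a read (the classical
  overlap-layout-consensus assumption; see Limitations).

All internal coordinates are 0-based half-open; GenBank and GFF3 emission
converts to 1-based inclusive at the boundary, and converting out and back
is the identity. FASTQ is accepted anywhere FASTA is; qualities are
discarded because no stage uses base quality.

## Read recruitment and the NUMT length rule

Reads are mapped to the reference concatenated to itself, so a read
spanning the origin of the circular reference maps contiguously; mapping
positions at or beyond the reference length L are renormalized modulo L
(an end beyond L encodes the wrap). The mapper is a k-mer
seed/chain/extend design: exact 15-mers are indexed (k-mers occurring more
than 64 times are dropped), hits are clustered by diagonal, and the best
cluster with at least 3 seeds is verified by banded edit-distance alignment
(edlib) of the whole read against the implied window. Identity is defined
as matches / alignment columns, computed from the extended CIGAR. At most
one primary mapping is kept per read; mapping quality is 60 for a unique
candidate and shrinks with the score ratio of the runner-up.

A read is recruited iff it has a primary mapping at identity
≥ `recruit_min_identity` (default 0.7 — deliberately permissive, the
reference is a different species) **and** its length does not exceed
`max_read_len`, which defaults to the exact reference length. The length
rule is strictly "more than": a read exactly as long as the reference is
kept. The rationale: genuine organellar reads cannot be longer than the
circle, while reads carrying a mitochondrial insertion plus nuclear flank
can be. NUMT-carrying reads *shorter* than the reference may still be
recruited; they are eliminated later because their nuclear flanks prevent
high-identity overlaps with true mitochondrial reads, and the NUMT contig
they form fails the contig filters.

## Assembly

A greedy overlap-layout-consensus assembler, adequate for small circular
genomes at ≥20× coverage from accurate reads:

- **Overlaps.** All suffix–prefix overlaps ≥ `min_overlap` (default
  1000 bp) at identity ≥ `min_overlap_identity` (default 0.99) are found
  by shared-k-mer seeding and verified by prefix-anchored edlib alignment.
  Both orientations are handled; one record per pair and orientation covers
  all four dovetail classes via a signed hang (negative hang = the oriented
  second read precedes the first). Reads fully contained in another read
  are flagged and set aside: they vote in the consensus but never extend a
  layout. Near-flush placements (stagger within a small length-scaled
  slop) are tried as containment first, then as dovetail.
- **Layout.** Edges are processed best-overlap-first (longer overlap, then
  higher identity, then lexicographic read ids — a total order, so assembly
  is deterministic). Each read joins at most one path, in one orientation;
  when the best usable edge connects a path's tail to its own head the path
  closes into a cycle. Closed cycles accept no further extension.
- **Consensus.** The layout is spliced into a backbone (each junction drops
  the overlap-consumed prefix of the next read); cyclic layouts keep the
  closing overlap duplicated at the ends so the circularization stage can
  detect it. Every layout and contained read is then realigned to the
  backbone within a window around its expected offset and a per-column
  vote is taken: substitutions and deletions by column majority, insertions
  applied when supported by more than half the covering reads; ties break
  toward the vote first cast by the earliest read in the layout, then
  lexicographically — again a total order.
- **Haplotype deferral.** During polishing, a read is *deferred* if its
  identity to the backbone falls below `min_read_identity` (default 0.97)
  or it shows a single indel run ≥ `min_structural_indel` (default 50 bp).
  The structural rule exists because a typical heteroplasmic event (e.g. a
  100 bp insertion in a ~10 kb read) barely dents identity (~0.99) yet is
  unambiguous structural disagreement. Deferred reads are excluded from
  the vote and, if at least `min_deferred_reads` (3) accumulate, assembled
  in one second round, which is how a heteroplasmic mixture yields one
  candidate contig per haplotype. Cross-haplotype overlaps spanning the
  event are already rejected by the 0.99 overlap-identity floor.

Pre-assembled contigs can be supplied instead of reads; they enter the
stage chain unchanged after the assembly step.

## Contig filtering

Each candidate is compared to the reference by seeding, diagonal-chaining
into local blocks (chain gap ≤ 500 bp, block identity ≥ 0.7, both strands),
merging block intervals on contig coordinates (avoids double-counting
overlapping matches) and computing the covered fraction of the *contig*
length. A contig is retained iff, all bounds strict:

- covered fraction > `p_coverage`/100 (default 50 %),
- length < 5 × reference length (dropped entirely in plant mode, where
  genuine mitogenomes vary hugely in size — only this upper rule is
  relaxed),
- length > 0.8 × reference length.

Every contig receives a verdict row (`parsed_blast_all.txt`); retained ones
are repeated in `parsed_blast.txt`.

## Circularization

Terminal redundancy is sought between a prefix window and a suffix window
(window = min(contig/2, 30 kb)); matching k-mer diagonals give candidate
redundancy lengths r, each verified by global alignment of the first and
last r bases. The contig is circular iff r > `circular_size` (default
220 bp, strict) and identity ≥ 0.99 (the conventional criterion is a
length threshold only; the identity floor is this package's addition —
consensus ends of accurate-read assemblies should agree nearly exactly). Trimming
removes the suffix copy (keeping the contig start stable for rotation) and
re-detects iteratively, at most 3 rounds, so tandem double redundancy
converges; trimmed length + overlap length = original length always.
Contigs of length ≤ 2× `circular_size` are reported "too short".

## Annotation transfer and frameshifts

Each reference CDS/rRNA/tRNA is extracted in reading orientation and
aligned to the candidate on both strands (candidate doubled when circular,
so origin-spanning genes are found intact). A placement becomes a gene call
iff identity ≥ 0.6 and reference coverage ≥ 0.7; features shorter than
100 bp (tRNAs) instead require identity ≥ 0.8 *and* at least one exact
12-mer inside the placement, because a 65–75 bp query reaches deceptively
high best-infix identity against random sequence. When one gene places
multiply, the highest-identity call wins. Unplaced genes are listed as
missing. Gene names are normalized to a common namespace on input
(COI/CO1/COX1 → COX1, tRNA-Phe → trnF, …) so gene sets are comparable
across annotations.

A CDS call is flagged frameshifted when its span length modulo 3 differs
from the reference CDS, or when translation under the configured NCBI code
(tables 1, 2, 4, 5 and the other standard tables) hits a stop before 90 %
of the expected protein length. Minus-strand genes are translated from the
reverse complement, so detection is strand-invariant. This operational
definition is this package's own: upstream annotators report a frameshift
flag without defining it precisely.

## Rotation and selection

The rotation anchor is trnF if any candidate annotates it, else the tRNA
present on the most candidates (ties lexicographic); with no tRNAs at all,
rotation is skipped with a warning. A minus-strand anchor triggers
reverse-complementation first, so the final genome always begins at the
anchor's first base on the plus strand; the cyclic sequence content is
unchanged.

Candidates are ranked by genes annotated relative to the reference
(descending), then by |length − reference length|, then id. The first
candidate that is (A) circular with redundancy removed, (B) size-similar
(within [0.8, 1.2] × reference — the lower bound mirrors the retention
filter; the convention is qualitative, this range is the package's
operationalization) and (C) frameshift-free is selected. Failing that, the
best circular candidate also satisfying B, then one satisfying C, then any
circular candidate; with nothing circular, the top-ranked contig is emitted
under a prominent warning rather than failing — a draft is more useful than
an error. Circularity is read as mandatory in the fallback ("the circular
contig that follows at least two of the criteria, in order A>B>C").

Coverage tables (reads mode only) map the recruited reads back to the final
genome and to the concatenation of all candidates, discarding alignments
with mapq below `cov_mapq_min`; depth conservation (sum of depths = sum of
aligned bases) is a tested invariant. Plot rendering is an optional
presentation layer; the TSVs are the artifact.

## Synthetic data

The generator emulates the target data regime, and its defaults are the
conditions the test suite measures under:

- **Genome**: random circular sequence, default 16.5 kb, with 13 planted
  ATG-initiated stop-free CDS (length scaled to the genome's spare space),
  2 rRNA blocks (~0.8/1.2 kb), 22 tRNAs of 65–75 bp including exactly one
  trnF, on mixed strands, never overlapping. Real mitogenomes overlap some
  genes and carry control regions; planted genes do not overlap and
  intergenic sequence is random — annotation transfer is therefore easier
  on fixtures than on diverged real references.
- **Reads**: starts uniform on the circle (wrapping the origin), lengths
  truncated-normal (mean 10 kb, sd 2 kb, min 5 kb, capped at the genome
  length), i.i.d. errors at 0.2 % substitutions and 0.05 % indels. No
  quality strings, no chimeras, no adapter artifacts.
- **NUMT**: a random nuclear background (default 100 kb) with a recorded
  mitochondrial fragment inserted, optionally mutated to a stated
  divergence.
- **Heteroplasmy**: a second haplotype built by a described edit (insertion
  or k substitutions), reads drawn per-haplotype at stated frequencies.

Everything flows through one numpy Generator per call, seeded explicitly:
identical seeds reproduce fixtures bit-for-bit, and every read carries a
provenance record (source, start, strand, haplotype, error count) against
which end-to-end accuracy is measured. Passing tests on these fixtures
demonstrates the pipeline's logic and numerical behavior, not performance
on diverged cross-species references or repeat-rich organelles.

## Numerical and engineering choices

- edlib supplies all pairwise alignment (global, prefix-anchored, infix);
  identity is always matches/columns from the extended CIGAR.
- Seeding uses exact 15-mers (overlap seeding adapts k and sampling stride
  for short inputs); diagonal clustering buckets hits at ±100 bp and takes
  the median diagonal, which absorbs indel drift.
- Every tie-break in layout, consensus, ranking and anchor choice is total
  (score, then lexicographic), so byte-identical inputs give byte-identical
  outputs; the run manifest records config and input digests but no
  timings in its file form.
- Degenerate inputs have defined behavior: empty FASTA → "no sequences"
  error; a single read → one linear contig equal to it; zero recruited
  reads and zero retained contigs abort with distinct exit codes (3, 4);
  empty report tables are emitted header-only.
- Problem sizes in the test suite: the end-to-end fixtures use a 16.5 kb
  genome at 30× (~50 reads) — ample for the statistical behavior being
  checked while keeping whole-suite turnaround interactive; oracle
  comparisons run on reads of a few hundred bp where the full DP matrix is
  cheap.

## Limitations

- Greedy OLC cannot resolve repeats longer than a read; plastid-scale
  inverted repeats and plant mitochondrial isomer structure need a graph
  representation and are out of scope.
- tRNAs are transferred by homology like every other feature; there is no
  covariance-model scan, so tRNA discovery de novo (or after substantial
  divergence) is absent. External annotations in GenBank format can be
  supplied through the contig entry point's file conventions.
- Intron-containing gene models (common in fungal and plant organelles)
  are not modeled; a split gene transfers as its best single block and may
  be flagged frameshifted.
- Heteroplasmy handling emits alternative candidate contigs; it does not
  estimate haplotype frequencies or phase more than two haplotypes.
- The `-t/--threads` option is accepted for interface compatibility;
  annotation is computed sequentially in sorted order, which already
  satisfies the order-independence contract.
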