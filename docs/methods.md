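# Methods

This note records the models behind each stage of the pipeline, the
defaults that matter, the numerical choices, and what the synthetic
data does and does not emulate.

## Coordinates and sequence conventions

All intervals are 0-based half-open internally; GFF3's 1-based
inclusive convention exists only at file boundaries, and the round trip
composes to identity. Genome sequences are uppercase ACGTN. `N` never
matches anything in any aligner or exact-match rule in this package —
a conservative choice for TIR/TSD calls, where an accidental `N`
"match" would fabricate structure.

## Alignment kernels

Three dynamic programs (numba-compiled) back the pipeline:

- **Local affine-gap Smith–Waterman** for translated homology and
  nucleotide fragment searches. A gap of length k costs
  `open + k·extend` (protein defaults 11/1, matching the usual gapped
  BLOSUM62 setting; DNA defaults 2/1 with match +1 / mismatch −1).
  Unknown residues (`X`, `*`, anything unrecognized) score −4 against
  everything. Traceback ties break diagonal → up → left, so results
  are deterministic.
- **Global Needleman–Wunsch** with a linear gap penalty for center-star
  alignment, identity computation and boundary detection.
- **Anchored extension** (start pinned at the sequence ends, free to
  stop anywhere) for TIR detection.

For TIR and boundary detection the DNA scores are stiffened to
match +1 / mismatch −2 / gap −4. With cheap gaps, an equally-scoring
global alignment can "desynchronize" at a repeat boundary and trade the
last few true columns for stray matches in flanking sequence; the stiff
costs make any such trade strictly worse in all but pathological cases,
and the boundary refinements below absorb the rest.

## Translated DDE-domain search

All six frames of every scaffold are translated (stops as `*`) and
scanned with the peptide query. Hits are harvested iteratively per
frame: best alignment, mask its subject span with `X`, repeat until the
E-value exceeds the cutoff. Significance uses the Karlin–Altschul form
`E = K·m·n·exp(−λS)` with fixed gapped-BLOSUM62 constants λ = 0.267,
K = 0.041, m the query length and n the genome length in bp. This is a
surrogate, not a BLAST replica: any monotone transform of the score
preserves cutoff semantics, and fixed constants keep runs
deterministic. Two cutoffs are exposed because discovery and reporting
legitimately differ: a permissive search cutoff (default 10⁻³) and a
strict post-filter (default 10⁻¹⁵) applied after deduplication.
Deduplication is greedy: hits sorted by score, a later hit is dropped
if it overlaps a kept hit on the same scaffold and strand by ≥50% of
both spans.

## Element annotation

**Boundaries** come from globally aligning two copies of a family with
their flanks. The element is the maximal block of alignment columns
whose 20-column windowed identity stays ≥0.8, refined to the first/last
run of 6 consecutive matching columns, then extended outward over
directly equal bases. The window and identity are config defaults
(this step was done by eye in the original workflow, so the defaults
are ours). Two copies at the same locus — flanks similar too — raise an
error instead of returning a fabricated boundary. Exact edge recovery
is only guaranteed when the flanks genuinely cannot match at the
boundary; with random flanks the adjacent base agrees by chance 1/4 of
the time and the "boundary" is then intrinsically ambiguous at ±a few
bp, which is why the diverged-copy tests assert ±5 bp rather than
exactness.

**TIRs** are found by anchored extension of the 5' prefix against the
reverse complement of the 3' suffix (window `min(len/2, 1000)` bp),
trying all anchor offsets within 5 bp of each terminus. The aligned arm
is trimmed back to the end of its last 6 consecutive matches so stray
flank matches cannot inflate the repeat, then the longest arm with
identity ≥0.8 and length ≥50 bp is reported.

**TSDs** are exact-match only: the longest k ∈ [8, 10] whose k-suffix
of the left flank equals the k-prefix of the right flank. Longest wins
because a 9-bp duplication necessarily contains a nested 8-bp one and
is a single 9-bp TSD. One-mismatch candidates can be reported behind a
flag but are never counted as verified TSDs — a perfect-duplication
census excludes them by definition.

**Subterminal repeats** are found by seeding a unit of each length in
9–15 bp at every phase and greedily chaining further copies separated
by 0–6 bp spacers with ≤1 mismatch per copy. The chain score is
`copies × unit_len − 2 × mismatches`; the mismatch penalty exists
because a unit extended by one spacer base chains with exactly one
mismatch per copy and would otherwise outscore the true unit whenever
spacer boundary bases happen to agree. Ties prefer the shorter unit,
then the earlier start.

**Terminal palindrome**: position i (1..5) of the terminal 10-mer pairs
with 11−i iff the bases are Watson–Crick complements; both members of a
failed pair are reported unpaired, and non-ACGT bases never pair.

**Coding span**: the best translated local alignment of the DDE query
over six frames locates the domain; the longest stop-free segment of
that frame overlapping the domain is reported as the ORF. Multi-exon
structure is deliberately not inferred (single-ORF approximation —
gene prediction is out of scope); a stop codon inside the aligned
domain sets an `interrupted` flag.

## Families and phylogeny

Pairwise identity is computed on a global alignment with gaps counting
against identity; clustering is single linkage at strict
identity > 0.95 — "members share >95% similarity" is transitive under
single linkage, which is why that linkage was chosen. Identity is
computed on nucleotide element sequences by default with a `kind`
switch for translated domains, since the similarity level at which
families were originally delimited is not pinned to either.

The multiple alignment is center-star progressive alignment: the
center is the sequence maximizing summed pairwise score, other rows are
merged in under "once a gap, always a gap". A full progressive aligner
(MUSCLE-class) would give better columns, but downstream consumers here
are distance matrices and topologies, not column-level inferences.

Neighbor joining is the Saitou–Nei agglomeration on p-distances
(pairwise deletion of gapped columns). Ties on the Q criterion break on
the smallest index pair; negative branch lengths are clamped to zero;
the output is an unrooted tree with a trifurcation at the last join.
On additive matrices the reconstruction is exact (verified against
path-length recomputation on simulated trees and against scikit-bio's
implementation). Bootstrap supports resample alignment columns with
replacement; support is the percentage of replicate trees containing
each internal bipartition of the full-data tree, stored canonically so
they are invariant to leaf order and rooting. An alignment whose
distances are all zero has no defined topology and raises rather than
returning an arbitrary tree. An outgroup is just another leaf; rooting
is presentational.

## Derivative discovery

The autonomous element's first 50 bp (and its reverse complement) are
searched genome-wide by 12-mer exact seeding plus mismatch-bounded
verification (default ≤5 mismatches — a deterministic stand-in for a
BLASTN stage). Convergent end pairing processes 5' hits
innermost-first, pairing each with its closest downstream reverse-
oriented hit within 100 bp–20 kb; nested candidates are all emitted
and flagged, never merged. TSD verification applies the exact-match
caller to 100-bp flanks; the census reports both all candidates and
the perfect-TSD subset, because the gap between "putative" and
"TSD-verified" is a real property of such censuses, not noise to be
hidden. Pack content is classified by local nucleotide alignment of
the internal region against host CDS sequences; defaults (≥70%
identity over ≥100 bp) sit far below the one quantified exemplar
(97.5% over 276 bp) and are exposed in config. A host gene whose
annotated span itself contains a planted element will trivially align
to that element's internal region — host CDS sets for closed-loop tests
therefore use genes free of insertions.

## Insertion statistics

Sites are classified gene body / within window / distal. Distance to a
gene `[s, e)` from position p is `s − p` upstream and `p − (e − 1)`
downstream, strand-ignored, and the window (5 kb for the genomic
census, 1 kb for the yeast analysis) is inclusive; ties resolve toward
the more genic category. The randomized null draws positions uniformly
over total genome length (scaffolds weighted by length), classifies
each replicate identically, and reports per-category means and sample
SDs over replicates (default 1,000). Enrichment is a plain z-score;
with SD 0 a matching observation gives z = 0 and a discrepant one is
flagged ±∞. No multiple-testing correction is applied because exactly
one contrast is performed. Position-frequency matrices use a uniform
background: `IC_j = 2 + Σ_b f_bj log₂ f_bj` bits, clipped to [0, 2].

## Yeast-assay analytics

Viable cells per culture are estimated as
`colonies × dilution × (resuspension / plated volume)` per plating
(defaults: 500 µl resuspension, 100 µl plated) and averaged over
dilutions; excision frequency is revertants over viable cells.
Reintegration ratio is the rounded percentage of one frequency (or
colony count) over another. Reported ± spreads on frequencies are
across-culture SDs and are carried as inputs, not recomputed.

Footprint classification reconstructs the empty donor site — left
flank + one TSD copy + right flank when a donor TSD exists, plain
flank + flank otherwise — anchors the revertant junction to it by its
outermost 12-mers (sequence beyond the stored flanks is ignored), and
decomposes the discrepancy. Missing reference bases are a flank
deletion with per-side counts (deletions spanning the TSD split at its
midpoint); extra bases are tested against every equivalent placement of
the inserted block (indel position is ambiguous inside repeated
context) and called a TIR remnant if any placement equals a prefix of
the 5' terminus or suffix of the 3' terminus at ≤13 bp — longer
terminus matches and deletion+insertion mixtures are complex; other
extra bases are an insertion. A junction still containing both full
termini raises "element not excised". "Precise" without a donor TSD
means exact restoration of the original sequence, since there is no
duplication to retain.

Transposon-display reads are trimmed by the longest terminus suffix
(≥12 bp) opening the read; the remaining flank (≥20 bp) is searched
exactly on both strands — unique hit, ambiguous, or unmapped. At a
mapped reinsertion junction the TSD length is the longest perfect
duplication between the two read flanks; because both flanks are also
contiguous genomic substrings, the overlap of their genomic spans
independently implies a length, and a disagreement (a coincidental
extra matching base, e.g. inside a homopolymer) sets an ambiguity flag
while the longest-match value is kept.

## Synthetic data: what it emulates and what it does not

The generator plants elements whose structure mirrors the active
family studied: 3,198 bp total, 145-bp TIRs opening with a 10-bp
imperfect palindrome (5th/6th positions unpaired), nine copies of a
12-bp subterminal repeat with 3–4 bp spacers, a 504-residue transposase
with the DDE triad at residues 214/283/419, two exons, 8/9-bp TSDs
created by duplicating the bases at the insertion point. The
transposase itself is a synthetic fixture drawn once from a fixed
random stream — any D..D..E-bearing ORF serves the search — and is
back-translated with a fixed one-codon-per-residue table. Background
is i.i.d. uniform ACGT; one global seed drives fixed-offset substreams,
so identical seeds give byte-identical output.

Placement uses a slot grid sized so that each site's gene (for genic
sites) fits entirely within its slot and non-genic sites stay more
than one window from every gene; the genic fraction is hit exactly
(rounded count). For planted *elements* the site is the left junction,
so window-proximal genes are placed upstream; a separate point-site
planter serves reinsertion-style analyses where sites have no length.
Derivative TIR truncations are drawn uniformly from 50–100% of the arm
(the observed structures are "often truncated" with no stated
distribution), and derivative internal lengths are a config range for
the same reason.

Several fixture-level disambiguations keep the truth table literally
true: the base following each planted TSD is resampled so the
duplication reads as exactly its planted length; the first internal
base is resampled if it would extend the TIR by a complementary base
(the element would then truly have a longer TIR than declared); spacer
boundary bases are balanced so no unit+phase reading outscores the
planted repeat; footprint insertions are redrawn if any placement
mimics a terminus; reinsertion sites are resampled until the
duplication is unambiguous and the flank maps uniquely. Real loci are
not this clean — passing closed-loop tests demonstrates correctness of
the operations under their stated definitions, not that real-genome
ambiguity (homopolymers, nested repeats, diverged copies) resolves
itself. Base composition, repeat landscapes and sequencing error are
explicitly not modeled.

## Problem sizes and defaults

The shipped defaults — 4 scaffolds × 120 kb, 7 full copies, 8
derivatives, genic fraction 0.643, window 5 kb, 1,000 null replicates,
1,000 bootstrap replicates exposed as a parameter — are the package's
chosen validation scale: large enough that every stage (seeding,
pairing, masking, null sampling) is exercised with non-trivial
multiplicity, small enough that the full suite runs in well under a
minute of alignment work. Tests that need many repetitions (bootstrap,
false-positive sweeps) use reduced replicate counts; the operations are
replicate-count-agnostic.

## Known limitations

- The E-value is a calibrated surrogate; absolute values are not
  comparable to BLAST output, only orderings and cutoffs.
- Center-star alignment is O(n²) pairwise and not column-optimal;
  distance-level results are its supported use.
- Boundary detection assumes the two copies' flanks are unrelated;
  segmental duplications violate that and raise or mislocate.
- Multi-exon transposase structure is not reconstructed; the coding
  annotation is a single-ORF approximation with an interrupted flag.
- The footprint classifier assumes one contiguous discrepancy (or a
  mixture, which it labels complex); multi-block rearrangements are
  all "complex" without further decomposition.
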