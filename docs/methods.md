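# Methods

## The statistic

The homologous coverage ratio (HCR) of two genomes A and B is

    HCR(A, B) = (H_A + H_B) / (S_A + S_B)

with S_X the total length of assembly X and H_X the number of bases of X
covered by homologous sequence. It is an overall genome relatedness index:
1 for identical genomes, ~0 for unrelated ones. Two properties distinguish
it from identity-style indices such as ANI: it is sensitive to genome-size
change (the same amount of shared sequence in smaller genomes gives a
larger ratio), and homologous repeats at distinct loci each contribute
coverage. Plasmids are excluded from S before scoring; exclusion is by the
case-insensitive token "plasmid" in the FASTA header, which matches RefSeq
conventions and needs no external metadata.

hcrkit computes the ratio two ways.

### Alignment route (precise)

H_A and H_B are obtained from local alignment blocks produced by any
external pairwise aligner emitting MAF or 12-column BLAST tabular output
(LAST is the natural choice; the aligner itself is never reimplemented and
E-values are consumed, never computed). Blocks with E-value ≥ 1e-10 are
discarded — the inequality is strict, a block at exactly 1e-10 fails.
Remaining blocks are projected onto each genome, grouped per contig, and
merged as interval unions, so a locus hit by many alignments counts once
and H_X ≤ S_X, hence HCR ≤ 1. (Whether raw block lengths should instead be
summed — allowing ratios above 1 in repeat-rich comparisons — is a
defensible alternative reading; merging was adopted because it keeps the
ratio a true coverage fraction while still crediting each distinct repeat
locus.) All coordinates are handled 0-based half-open internally: MAF
start+length converts directly, reverse-strand MAF coordinates are flipped
to the forward strand, and tabular 1-based inclusive coordinates subtract
one from the start; reversed subject intervals (start > end) are swapped
and marked minus-strand. One alignment run per pair is projected onto both
genomes; no bidirectional reconciliation is attempted. No minimum block
length is imposed.

### k-mer route (screening approximation)

    HCR_kmer(A, B) = (Hit_A + Hit_B) / (HS_A + HS_B)

where HS_X is the number of distinct k-mers of genome X and Hit_X the
number of X's k-mers present in the other genome's set. Membership is
exact (a Python set), not a sketch, and multiplicity is ignored. Hit_A and
Hit_B both equal the intersection cardinality under this cross-containment
definition, which makes the score symmetric, exactly 1 on identical
genomes, and bounded by 1. Windows containing non-ACGT symbols are
skipped; windows never span contig boundaries.

Parameters:

* **k = 12** (configurable, k ≥ 3). 4^12 ≈ 1.7×10^7 possible keys — large
  enough that two unrelated megabase-scale genomes share only a fraction
  of a percent of k-mers by chance (expected collisions ~ S_A·S_B / 4^k),
  small enough to keep per-genome sets in memory.
* **canonical = True**: each k-mer is collapsed with its reverse
  complement (lexicographic minimum) because assembly strand is arbitrary.
  Non-canonical mode is retained for oracle tests against literal window
  enumeration.

## Ambiguity screening

Scores are aggregated per unordered taxon pair at genus or phylum level.
For a pair (X, Y): `max_inter` is the best cross-taxon score; the
**anchored** `max_intra` is the best within-taxon score involving one of
the two genomes achieving `max_inter` (each searched within its own
taxon); `min_intra` is the worst within-taxon score over both taxa
(restrictable to the first taxon). Two criteria:

* `anchored_max` (genus level): flag iff `max_inter > max_intra`,
  strictly — a tie is not ambiguous. Anchoring asks whether a specific
  genome is closer to a foreign genus than to any genome of its own; a
  global (non-anchored) within-taxon maximum is available via
  `anchored=False` but is not the default, since a distant corner of a
  large genus should not mask the anomaly.
* `min_intra_ratio` (phylum level): flag iff `max_inter / min_intra`
  exceeds a threshold (2 and 4 are the conventional survey cutoffs). The
  "difference" between cross- and within-taxon HCR is read as a ratio,
  consistent with how such comparisons are quoted ("15 times", "9 times");
  the ratio is infinite when `min_intra` is 0 and a positive cross score
  exists.

Taxa with a single genome have no within-taxon statistic; their pairs are
skipped with a log note rather than treated as zero (undefined ≠ 0).
`candidate_screen` ranks genus pairs by anchored excess
(`max_inter − max_intra`) and returns the positive-excess top-n for
alignment-stage refinement.

## Ordination

Pairwise scores are converted to distances d = 1 − HCR — the simplest
monotone transform sending identity to distance 0 — and embedded by
classical (Torgerson) MDS: B = −½·J·D²·J with J the centering matrix,
eigendecomposition of B, coordinates from the top non-negative eigenpairs.
Classical MDS was chosen over stress-majorization because it is
deterministic and seed-free; negative eigenvalues (non-Euclidean
distances) are truncated to zero contribution, and each axis's sign is
fixed by making its largest-magnitude coordinate positive, so outputs are
byte-reproducible and invariant to input order. For distance matrices that
are exactly Euclidean the embedding recovers pairwise distances to
machine precision (tested at 1e-6).

## Synthetic data

The generator emulates the single property the statistics measure — the
fraction of two genomes that is shared — with everything planted and
closed-form:

* Backgrounds are i.i.d. uniform A/C/G/T. Real genomes have skewed
  composition, repeats, and rearrangements; none of these affect what the
  tests assert (set containment and interval arithmetic), so they are
  deliberately not modelled. Passing tests therefore demonstrate
  correctness of the computation, not aligner-level performance on real
  genomes.
* `make_pair` copies a planted fraction of genome A into genome B as
  non-overlapping segments (one per equal-width slot, offset randomly),
  optionally with point substitutions but never indels, so planted
  coordinates stay exact and double as a ready-made tabular alignment
  fixture (`emit_alignment_fixture`) whose expected coverage ratio is a
  closed-form sum. The returned planted fractions are exact.
* `make_taxonomy_fixture` gives every genome of a genus a shared genus
  backbone and every genome a shared global backbone, so within-genus
  pairs share `intra_fraction` of their length and cross-genus pairs
  `inter_fraction`; an optional ambiguous genus pair gets one cross-genus
  genome pair with an extra private segment raising their sharing to
  `ambiguous_fraction`. Because the backbone, global, and private segments
  are disjoint stretches of one genome, the fractions must satisfy
  `(intra − inter) + inter + (ambiguous − inter) ≤ 1`; the defaults
  intra = 0.3, inter = 0.05, ambiguous = 0.5 keep comfortable margins on
  a 20 kb genome while preserving the ordering that matters
  (ambiguous > intra > inter), and infeasible combinations are rejected
  rather than silently rescaled.
* All randomness flows through numpy's PCG64 generator; a seed fixes every
  output bit-for-bit across platforms.

Expected k-mer recovery on a planted pair of equal length L and fraction f
is f minus a boundary loss of (k−1) k-mers per segment (~10^-4 at the
default layout) plus a chance-collision gain of order L/4^k; both are well
inside the ±0.05 tolerance the recovery tests use.

## Numerical and interface choices

* HCR values are printed to 9 decimal places in TSV outputs, matching the
  precision at which survey tables of this statistic are reported.
* Sequences are uppercased on input; soft-masking is ignored.
* The CLI (`scan`, `refine`, `screen`, `mds`, `synth`) is a thin layer
  over the library; outputs are deterministic TSV, logs go to stderr, and
  exit codes distinguish usage (2), input (3), and partial failure (4).
  Alignment files for `refine` follow the `<accA>__<accB>.<ext>` naming
  convention, either order accepted.
* Test problem sizes: parameter recovery uses 100 kb genomes at k = 12;
  fuzzed oracle-equivalence suites use sequences up to 10 kb; the planted
  taxonomy uses 9 × 20 kb genomes.

## Known limitations

* The k-mer approximation measures containment of exact k-mers: point
  mutations in real diverged genomes erode it faster than they erode
  alignment coverage, so k-mer and alignment HCR agree best on closely
  related or simulated genomes. The two-stage design treats the k-mer
  score only as a screen.
* E-values depend on the aligner's scoring parameters; alignment-route HCR
  values are therefore reproducible only together with the aligner
  configuration that produced the input files.
* The plasmid rule is textual; assemblies with unlabeled plasmid contigs
  keep them in S.
* The synthetic generator plants substitutions but no indels,
  rearrangements, or horizontal transfer; it validates computation, not
  biology.
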