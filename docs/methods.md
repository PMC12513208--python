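# Methods

## The virtual-marker model

A virtual marker set is defined by a spacing *s* (bp between consecutive
marker starts), a marker length *m*, and a grid anchored at the first
base of each reference chromosome: candidate windows start at 1-based
positions 1, s+1, 2s+1, … and must fit entirely inside the chromosome.
Defaults are s = 1 Mb, m = 2 kb (the genome-wide validation geometry);
s = 100 kb with the same m is the breakpoint-resolution geometry.
Windows with more than `max_ambiguous_frac` (default 0.2) N are skipped
so markers are never cut from assembly gaps; this masking rule is this
package's choice, as is the 1-anchored grid (which makes all reported
breakpoints take the k·s+1 form seen in the call tables).

The comparison model assumes the assembly differs from the reference by
(a) large-scale order/orientation changes — the signal — and (b)
base-level substitution divergence and missing sequence — the noise.
Under these assumptions each marker has at most one true locus, a
marker inside an inverted segment maps on the opposite strand with its
neighbors in reversed subject order, and a marker inside a translocated
segment maps on a scaffold belonging to another chromosome.

## Placement and filtering

The built-in matcher finds candidate loci by exact k-mer seeds
(k = 21, ~8 seeds sampled evenly per marker, both strands), groups seed
hits by (subject, implied offset, strand), and scores each candidate
locus by ungapped comparison over the full marker length:
pident = matches/m × 100, N counting as mismatch.  Candidates at
≥ 80% identity are reported.  The matcher is substitution-only by
design: it is exactly testable and dependency-free, and the simulator
is substitution-only to match.  Indel-bearing alignments should come
from an external aligner (blastn outfmt-6 or PAF are imported
natively); internally both routes produce the same row type and flow
through identical downstream code.

Hit filtering keeps rows with pident ≥ `min_pident` (default 99.0,
operationalizing "near-100% identity" while tolerating individual-level
SNVs over 2 kb) **or** on an exempt scaffold.  The exemption set holds
each chromosome's longest assigned scaffold: sub-threshold hits there
may be genuine inter-individual variation rather than mismapping.
Because the exemption needs assignments and assignments need hits, the
pipeline runs two passes: strict filter → assign → re-admit
sub-threshold hits on primaries → re-place and re-assign.

Best-hit selection ranks by bitscore (imported alignments) or by
pident then alignment length (built-in matcher), breaking ties by
smallest subject start then lexicographic subject id so selection is
deterministic.  A marker whose runner-up scores within 2% (relative) of
the winner is flagged ambiguous — typically a repeat — and is retained
for dot plots but excluded from calling.

## Assignment, orientation, and blocks

Scaffolds are assigned to chromosomes by majority vote of their placed
markers (ties resolved lexicographically and logged), with orientation
equal to the majority strand.  All placements are then mirrored into
each scaffold's dominant orientation before any strand is interpreted:
Hi-C scaffolds carry arbitrary strand, so inversions must be read
relative to the scaffold's own frame.  Consequently a wholly
reverse-complemented scaffold yields plus blocks and zero calls (this
is a tested invariant).

Oriented, unambiguous placements are chained into signed collinear
blocks: a block extends while the next marker (in reference order) is
on the same subject and normalized strand and its subject-side jump is
consistent with the reference-side jump to within
`gap_tol × s` (gap_tol default 3).  The slack exists to bridge isolated
masked or unplaced markers without fragmenting blocks; the operative
rule bounds the *discrepancy* |Δsubject − sign·Δref|, so clean chains
with missing members stay whole while genuine structural jumps break
the chain.

## Calling and detection limits

Every minus block with at least `min_markers` (default 2) members
becomes an inversion call; maximal runs of ≥ min_markers consecutive
markers on a foreign-assigned scaffold become translocation calls.
Intervals are reported 1-based inclusive from the first supporting
marker start to one grid step past the last — so each endpoint is
within one grid step of the true breakpoint whenever the boundary
markers place (also a tested invariant).

The guaranteed-detectable length — the smallest rearrangement that
contains ≥ k full markers for *every* placement offset — is computed by
brute force over all s integer offsets with a binary search over L
(exact, because containment is monotone in L).  The closed form
k·s + m − 1 agrees with the brute force and with a small-scale
enumeration oracle in the tests.  For the default k = 2 this gives
2,001,999 bp at 1-Mb spacing and 201,999 bp at 100-kb spacing: the
1-Mb grid cannot guarantee inversions much under 2 Mb, the 100-kb grid
reaches ~200 kb.  min_markers = 2 is the default because it matches
those operating points; 3 is recommended for noisy imported alignments.

Calls from multiple assemblies are merged into loci by single-linkage
clustering at reciprocal overlap ≥ 0.8 (same chromosome and type), and
reported as a presence/absence genotype matrix.  Raw-read corroboration
of a breakpoint is available as `span_support`: the count of read
alignments covering a breakpoint by ≥ `flank` (default 10 kb, inclusive
boundaries) on both sides — few spanning reads at a putative breakpoint
support the call.

## Contiguity statistics and subsampling

N50/L50 sort scaffold lengths descending; L50 is the smallest rank
whose cumulative length reaches ≥ half the total (the ≥ convention
makes a perfect 23-chromosome human assembly come out at L50 8–9), and
N50 is the length at that rank.  Coverage subsampling keeps each FASTQ
read independently with probability c·G/B (target coverage × genome
size / input bases) from a seeded generator — order-preserving,
streamable in two passes, byte-reproducible per seed, and with expected
output equal to the target; per-read Bernoulli sampling was chosen over
exact base-count targeting to mirror standard seqtk-style titration
practice.  `titration_table` aggregates replicate assemblies per
coverage into mean ± sd of N50/L50/total size (population sd, so a
single replicate reports 0).

## The simulator

`random_genome` draws i.i.d. bases at GC 0.41 (the human genome-wide
value).  `apply_edits` plants non-overlapping inversions, deletions,
and translocations, recording truth 1-based on the unedited reference
frame — the same frame calls are reported in, so truth and calls
compare directly.  `fragment_and_scaffold` splits chromosomes and
re-joins them with runs of exactly 100 N, the convention of Hi-C
scaffolding tools that separate adjacent contigs with a fixed 100-N
spacer.  `add_substitutions` applies uniform substitution noise
(default 0.1%, the scale of SNV divergence between two human
individuals).  `simulate_reads` draws uniform, strand-random long reads
(normal lengths, mean 15 kb) until total bases reach coverage × genome
size.

What the simulator does **not** emulate: indels and structural noise
other than the planted events, repeats and segmental duplications
(the main real-world source of ambiguous markers), centromeric satellite
arrays, diploidy/heterozygosity, and non-uniform read quality.  Passing
the planted-recovery tests therefore demonstrates the order/strand
logic, coordinate bookkeeping, and thresholds are correct under clean
substitution-level divergence; it does not certify performance inside
repeat-rich or centromeric regions, where real data show ambiguous and
low-identity marker clusters and calls should be read alongside the
dot plots.

## Numerical and design choices

* Internal coordinates are 0-based half-open; every file and report
  string is 1-based inclusive (BED-like call files carry both).  All
  conversion happens in `io_formats`.
* Non-ACGTN input characters become N rather than erroring (real
  assemblies contain IUPAC codes).
* Subject k-mer scanning uses an injective base-5 rolling hash (N is a
  fifth symbol) built by binary doubling, with an 8-mer prefix mask as
  a prefilter; candidate loci are then verified at full length, so
  hashing introduces no false matches.
* Degenerate inputs: chromosomes shorter than one marker are skipped
  with a warning; markers with no seed hit simply produce no rows;
  empty FASTA or duplicate ids are errors; an all-tie best hit is
  resolved deterministically and flagged ambiguous.
* The LIS-based collinearity statistic (longest strictly increasing run
  of normalized subject positions / placed markers) is this package's
  quantification of "dots lining up along the diagonal"; it is a
  relative diagnostic, not calibrated against any external value.

## Test problem sizes

Unit tests run the full stack at a reduced geometry (10-kb spacing,
500-bp markers, 100–200-kb chromosomes), which exercises identical code
paths at negligible cost.  The planted-inversion acceptance study uses
20 seeded genomes of two chromosomes × 8–25 Mb at the genome-scale
1-Mb/2-kb geometry, one inversion per chromosome with length between
1× and 3× the guaranteed-detectable limit, 0.1% substitution noise,
and three 100-N scaffold splits per chromosome, plus unedited,
reverse-complemented, and scaffold-split controls.

## Known limitations

* Substitution-only matcher: loci with indels relative to the reference
  need an external aligner.
* Detection is grid-bound: events shorter than the guaranteed limit are
  missed or called with a single marker (below `min_markers`), and
  breakpoints are never finer than one grid step.
* Translocation calling requires the destination scaffold to be
  majority-assigned to another chromosome; reciprocal translocations of
  near-equal arms can flip the majority and be reported from the other
  chromosome's perspective.
* The genotype matrix records presence/absence only; zygosity is out of
  scope.
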