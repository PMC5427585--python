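# Methods

## Model and assumptions

`hlatyper` types the five classical HLA genes by exact-match read
placement against a panel of allele exon sequences.  The underlying model
is deliberately simple: a read belongs to an allele's evidence only if it
matches the allele's typing sequence at 100% identity over its full
length, on either strand.  This trades sensitivity (any sequencing error
discards the read) for specificity (no alignment-score heuristics), and it
presumes coverage deep enough that losing error-bearing reads still leaves
the true alleles tiled evenly — the regime the defaults are tuned for is
150 bp reads at 30×–90×.

Reads are matched against *typing sequences*: the concatenation of the
typing exons (2–3 for class I, 2 for class II), not genomic sequence.  A
read that in reality straddles an exon–intron junction cannot match and is
lost; conversely a read spanning the splice junction of two concatenated
exons can match even though no genomic read would.  Both effects are
accepted: the method operates on spliced references throughout.  Paired
mates are treated as independent single-end reads, since all downstream
statistics are defined per read.  A read containing N is unplaceable by
definition — 100% identity is read literally.

## The read-distribution score

For one candidate allele let the placed-read centers, sorted along the
typing sequence, be $r_1 \le \dots \le r_n$ (a center is
$(\text{start} + \text{end})/2$; internally centers are stored as the
integer $\text{start} + \text{end}$, i.e. doubled units, so half-integer
midpoints of even-length reads stay exact).  The inter-center distances
are $D_j = r_{j+1} - r_j$, and

$$\mathrm{Score} = \sum_j (D_j / c)^{e}.$$

Parameters, defaults, and rationale:

- **c = 30 bp.**  The expected center spacing when each position is
  covered about five times; equivalently `read_length / 5` for 150 bp
  reads (`recommended_c` computes this for other read lengths).  Gaps
  shorter than c contribute less than 1 each; longer gaps are amplified.
- **exponent e = 3.**  Cubic amplification separates even from uneven
  profiles sharply while leaving routine spacing jitter negligible.
- **cutoff = 125.**  Equal to $(150/30)^3$: the score of a single gap of
  one full read length.  The filter discards alleles scoring *strictly
  above* the cutoff, so an allele with exactly one read-length gap — the
  canonical borderline case — is retained.  Alleles with zero placed reads
  are always discarded regardless of score.
- **include_boundaries (default on).**  Two extra distances are scored:
  from the region start to the first center and from the last center to
  the region end.  This penalizes alleles covered only in their middle
  (an allele with empty terminal stretches is as suspect as one with an
  interior hole); an empty profile degenerates to the single distance
  `region_length`.  With boundaries off the sum runs over interior gaps
  only, matching a strict two-adjacent-reads reading.  Note that with
  boundaries on, even a perfectly tiled allele carries a floor of roughly
  $2 \times (75/30)^3 \approx 32$ from the two half-read boundary
  distances, so cutoffs below ~35 reject everything; the cutoff is a free
  parameter but values near 125 are the intended operating point.

The textual alternative of defining $D_j$ as the count of positions
*between* reads (one less than the center difference) was considered and
rejected: both worked values the score is anchored to — 5 bp spacing under
ideal 30× tiling, and a 150 bp gap scoring exactly 125 — are consistent
with plain center differences.

## Candidate pruning and the genotype call

Alleles whose typing-exon sequences are identical are collapsed before
scoring into a representative group named by the longest shared leading
field prefix of the members (members sharing no field beyond the gene get
the lexicographically smallest member as stand-in, flagged).  When two
distinct groups would render the same prefix name, each falls back to its
smallest member name so representative names stay unique.

After score filtering, a candidate whose read set is a **proper subset**
of another candidate's is removed: such a candidate cannot own a unique
read, which is exactly the condition for being a duplicated allele.
Candidates with *equal* read sets are all retained and left to the
deterministic tie-breaks.  This removal is idempotent and order-invariant.

Unique reads are then recounted against all retained candidates (counts
made before duplicate removal can be deflated by false alleles), and
candidates are ranked by unique-read count, with ties broken by total
placed reads, then lower score, then name.  Two leaders with ≥ 1 unique
read each give a heterozygote; only one gives a homozygote.  If *no*
candidate has a unique read — legitimate when representative collapsing
leaves fully redundant candidates — the best-covered candidate is emitted
as a homozygote flagged `low_confidence` rather than failing.  The
reported confidence is the ratio of the runner-up's unique count to the
leader's: near 0 for a clean homozygote, near 1 for a balanced
heterozygote.

### Fallback exons

Typing runs on the primary exons first.  Fallback exons (4–5 for class I,
3–4 for class II) are engaged when the primary result is ambiguous, under
two triggers: more than two candidates remain tied at the top unique-read
count after phasing, or a called representative group contains members
that actually differ over the fallback exons (so more sequence can split
it — the identical-exon quartet, which differs nowhere, never triggers).
The rerun is restricted to the alleles still in contention, uses
primary ∪ fallback exons, and replaces the primary call unless it comes
back empty.  Alleles with differing sets of deposited exons are compared
over the exons they have (grouping keys on available requested exons), and
every call records `exons_used`.

## The simulator

The generator emulates the structural features the cascade must handle:

- **Panel:** per gene, 8 alleles mutated independently from one random
  ancestral exon set at a 2% per-base substitution rate (≈ 11 differences
  over a 546 bp class I typing region — comparable to divergence between
  unrelated allele groups).  Exon lengths follow typical sizes (class I:
  270/276/276/117 bp for exons 2–5; class II: 270/282/255 bp for 2–4).
- **Identical-exon quartet:** one base allele per gene is emitted as four
  records with identical exons and 8-digit names, exercising
  representative collapsing down to the shared 6-digit prefix.
- **Near-duplicate pair:** one pair per gene at Hamming distance exactly 1
  over the typing exons.  The variant is placed at least half a read
  length from the typing-region ends so that uniformly drawn reads can
  cover it; with a positive substitution rate the panel is regenerated
  (bounded retries) if chance creates additional distance-≤1 pairs, so
  the constructed pair is the only one.
- **Reads:** per haplotype, `depth × region / (2 × read_length)` reads
  with uniform start positions over the haplotype's exon concatenation
  (default: the primary typing exons), random orientation, and optional
  uniform substitution errors.  No PCR duplicates are generated, and no
  indel errors — an exact matcher discards an error-bearing read whatever
  the error type, so indels would be indistinguishable from
  substitutions in effect.

What the simulator does *not* emulate, and hence what passing tests do
not show: intronic flanks and exon–junction read loss, non-uniform
(GC-dependent) coverage, base-quality structure, chimeric or duplicate
reads, and the deep allele-frequency structure of a real allele catalogue.
Results on synthetic panels demonstrate the algorithm's internal
correctness, not field accuracy on real sequencing data.

Evaluation counts each diploid genotype as two allele slots matched as an
unordered pair after truncating both sides to the requested digit level; a
no-call leaves two missing slots, and correct + missing + wrong always
equals twice the genotype count.  The depth sweep reports allele-level
sensitivity (true representatives called) and specificity (non-true panel
representatives not called), with truth genotypes paired across depths and
cutoffs through shared replicate seeds.

## Problem sizes and numerical choices

The test suite validates recovery on 50 seeded heterozygous samples per
gene at 90× (error-free), depth monotonicity over 50 paired replicates at
5/30/60/90× on two genes, 1,000 random center configurations for score
convexity, and 10,000 mutated-read placement probes; the whole suite runs
in well under a minute on one core.  All randomness flows through
explicit `numpy.random.Generator` seeds; sorting and name-based tie-breaks
make every pipeline stage order-invariant, and reruns on identical inputs
are byte-identical.

Known limitations: homozygote calls without a competing candidate are
inherently weaker evidence than heterozygote calls (flagged, not
suppressed); alleles absent from the reference panel can only ever be
called as their nearest panel neighbour; and at depths ≲ 10× the score
filter removes true alleles often enough that no-calls dominate — by
design, since uneven coverage is indistinguishable from a false allele at
that depth.
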