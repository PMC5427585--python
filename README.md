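# hlatyper

Exact-match HLA genotyping from short sequencing reads.

The classical HLA genes (class I *A*, *B*, *C*; class II *DQB1*, *DRB1*) are
the most polymorphic loci in the human genome, with thousands of named
alleles per gene differing by sparse substitutions in their antigen-binding
exons.  Calling the two alleles a person carries from short-read data is
hard for two reasons: most reads match many alleles at once, and short-read
phasing ambiguity makes false "recombinant" alleles — chimeras of the two
true haplotypes — look well supported.  `hlatyper` is for anyone who wants
a transparent, fully testable implementation of the exact-match +
read-distribution-score approach to this problem, including a simulator
that generates the allele panels and diploid read sets needed to validate
every stage.

## Method

1. **Exact placement.** Reads are placed on each candidate allele's typing
   sequence (concatenated typing exons: exons 2–3 for class I, exon 2 for
   class II) only where they match at 100% identity, on either strand.
   Everything else is discarded.
2. **Read-distribution score.** For each allele, sort the midpoints
   (centers) of its placed reads and take the distances $D_j$ between
   consecutive centers (plus, by default, the distances from the region
   ends to the outermost centers).  The score

   $$\mathrm{Score} = \sum_{j=1}^{m} \left(\frac{D_j}{c}\right)^{3},
   \qquad c = 30\ \mathrm{bp}$$

   penalizes uncovered stretches: evenly tiled 150 bp reads at 30× put
   centers 5 bp apart (each gap contributes $(5/30)^3 \approx 0.005$),
   while a single gap of one read length contributes $(150/30)^3 = 125$
   on its own.  Alleles scoring **above** 125 are discarded; exactly 125
   survives.
3. **Representative collapsing.** Alleles whose typing exons are
   byte-identical are merged under the longest shared name prefix (e.g.
   four 8-digit alleles sharing all exons become one 6-digit
   representative).
4. **Duplicated-allele removal.** A candidate whose placed reads form a
   proper subset of another candidate's reads has no evidence of its own
   and is dropped.
5. **Unique-read phasing.** Candidates are ranked by *unique* reads (reads
   placed on exactly one retained candidate).  Two candidates with unique
   reads → heterozygote; only one → homozygote.  When the primary exons
   cannot separate the leaders, fallback exons (4–5 / 3–4) are engaged for
   the alleles still in contention.

## Worked example

Simulate a diploid sample at 90× over a synthetic two-gene panel, type it,
and score the calls against the simulation truth:

```
$ hlatyper simulate --seed 9 --genes A,DQB1 --depth 90 --out sim
wrote 24 alleles, 490 reads to sim

$ hlatyper typify --alleles sim/alleles.fasta --exon-map sim/exon_map.tsv \
      --reads sim/reads.fastq --genes A,DQB1 --out typed
[A] primary: n_records=12  n_groups=9  n_with_reads=6  n_passed_score=2  n_after_dedup=2  n_final=2
[A] call: het A*03:01 A*08:01
[DQB1] primary: n_records=12  n_groups=9  n_with_reads=2  n_passed_score=2  n_after_dedup=2  n_final=2
[DQB1] call: het DQB1*03:01 DQB1*08:02

$ hlatyper evaluate --calls typed/calls.tsv --truth sim/truth.tsv --digits 4
gene    correct missing wrong   n_slots accuracy
A       2       0       0       2       1.0
DQB1    2       0       0       2       1.0
overall 4       0       0       4       1.0
```

The per-stage log shows the filter cascade at work: of nine representative
allele groups per gene, six catch any reads at all, two survive the score
cutoff, none is a read-subset duplicate, and both finalists carry unique
reads (164 each for *A*), so each gene is called heterozygous.  The scores
of the called alleles (≈ 33) sit far below the cutoff of 125, as expected
for evenly covered true alleles at 90×.  Both calls match the simulated
truth, for 4/4 correct allele slots.

The same library surface is importable — `simulate_allele_db`,
`simulate_diploid_reads`, `type_gene`, `evaluate_calls`, `depth_sweep` —
for scripted experiments such as depth × cutoff sensitivity grids
(`hlatyper sweep`).

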