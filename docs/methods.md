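# Methods

`annodiff` compares two gene structure annotation sets (GFF3) over the
same genomic sequences. This note records the model, the numerical and
design choices, and what the synthetic test bed does and does not
establish.

## Locus identification

Genes from both inputs are nodes of a single undirected interval graph;
two nodes are joined when their gene spans (outermost transcript extent)
share at least one position on the same sequence. Edges are formed
regardless of strand and regardless of which input each gene comes from,
so reference–reference, prediction–prediction and cross-source overlaps
all merge into one component. Each connected component defines a *gene
locus*: the smallest region containing every member gene. Consequences:

- no quality judgement between the two inputs is baked into the locus
  definition — swapping the input roles yields identical locus intervals;
- loci on one sequence never overlap, and every gene belongs to exactly
  one locus;
- loci are independent units, which is what makes per-locus
  parallelism (`--workers`) a pure performance feature with no effect on
  output.

Adjacency is not overlap: under 1-based inclusive coordinates, a gene
ending at position *p* and one starting at *p*+1 share no position and
fall in different loci. Genes on opposite strands that share positions
share a locus; whether the original approach did this cross-strand is
unknowable from the available description, so it is recorded here as this
package's choice (overlap is purely positional).

## Model vectors

Within one source at one locus, transcripts are nodes of the *complement*
of their interval graph (edge = spans disjoint). Every maximal clique of
that graph — enumerated with Bron–Kerbosch with pivoting, no degeneracy
ordering, since per-locus transcript counts are small — is a set of
mutually non-overlapping transcripts drawn as one string over
`{C, F, G, I, T}`: coding, 5' UTR, intergenic, intron, 3' UTR. The string
has exactly the locus length. Within a member transcript's span,
un-exonic positions are `I`; positions covered by no member are `G`.
Strand is not encoded: a minus-strand transcript's `F` marks its
biological 5' UTR even though it lies at higher coordinates. Disjointness
is tested at transcript level, so transcripts of overlapping genes can
share a clique. All maximal cliques are carried into pairing; the
at-most-once pairing rule resolves any redundancy from transcripts
appearing in several cliques.

A source with no gene at a locus is represented by a single all-`G`
vector so the other side's annotation can still be scored in the locus
report; see *Aggregation* for how those comparisons are (not) counted.

## Structure inference

Comparison needs intron and UTR classes even when the input GFF3 supplies
only exon and CDS features. Introns are the inter-exon gaps. Exonic
positions upstream of the CDS span in transcription order are 5' UTR,
downstream ones 3' UTR (mirrored on the minus strand). Explicit UTR
features are validated against the inferred ones; a conflict logs a
warning and the inferred version wins, keeping every transcript's exonic
positions exactly partitioned into CDS + UTR5 + UTR3. mRNAs with CDS but
no exon features get exons synthesized from the (merged) CDS segments.
mRNAs with no CDS are skipped with a warning: the alphabet has no
plain-exon symbol and UTR polarity is undefined without a CDS, so
non-coding transcripts have no faithful encoding in this scheme. CDS
phase is read but ignored — no statistic here is codon-aware.

## Statistics

For equal-length vector pairs, per-position confusion counts are taken
for two nucleotide classes — coding (`C`) and untranslated (`F` and `T`
pooled, since one UTR panel is reported) — giving TP/FP/FN/TN from which:

- sensitivity Sn = TP/(TP+FN), specificity Sp = TP/(TP+FP) (precision,
  per the gene-finding convention),
- F1 = 2·TP/(2·TP+FP+FN),
- annotation edit distance AED = 1 − (Sn+Sp)/2,
- simple matching coefficient SMC = (TP+TN)/total,
- correlation coefficient CC (Matthews form).

Overall identity — the fraction of positions equal over the full
five-letter alphabet — is the generalization of SMC and the single scalar
used to rank comparisons. At feature level (exons, CDS segments, UTR
segments) a prediction feature is a true positive only when both ends
match a reference feature exactly, each reference feature consumable
once; TN is undefined there, so only Sn/Sp/F1/AED are reported. Any
statistic with a zero denominator is *undefined*, rendered `--`, and
excluded from aggregation — coercing to 0 would bias pooled summaries.

### Classification

Each comparison is classified by a strict exact-agreement hierarchy:
*perfect match* (identical vectors) → *CDS structure match* (identical
CDS segment coordinates) → *exon structure match* (identical exon
coordinates, CDS differs — e.g. alternative start/stop codons) → *UTR
structure match* (identical UTR segments, CDS and exons differ) →
*non-match*. Segment coordinates are taken from the clique's member
transcripts, not re-derived from symbol runs, so abutting transcripts
cannot artificially merge runs. Near-identity never upgrades a class:
similarity short of exactness shows up in the statistics, not the label.

### Pairing

All |R|×|P| clique comparisons at a locus are ranked by descending
overall identity, ties broken by ascending nucleotide CDS AED, then
ascending feature-level exon AED (undefined sorts last), then clique IDs
— the last step purely for determinism. Pairs are accepted greedily so
each clique is used at most once; leftovers are reported as unmatched
(novel) cliques and contribute no statistic counts.

### Splice complexity

Reported per source at each locus: the mean pairwise structural AED over
all unordered transcript pairs of that source (0 when fewer than two).
The pairwise AED encodes each transcript alone and pools per-position
agreement over the coding, untranslated and intron classes (intergenic
positions carry no structure); the cited definition is not reprinted in
the available description, so this mean-pairwise, length-weighted form is
this package's own concretization. Pairs are taken across the whole
source at the locus, not within cliques.

## Aggregation

Running totals of all confusion counts, identity positions and
classification tallies accumulate across loci, and the summary panels
are recomputed from the pooled counts — never averaged over per-locus
panels, so a 50 kb locus outweighs a 500 bp one exactly in proportion to
its size. Filtered loci contribute nothing (they are counted in a
`filtered` footer for auditability). Single-source loci contribute locus
tallies only; their all-`G` comparisons appear in the locus report but
not in any aggregate. Gene-level sensitivity is defined here as perfect
matches / reference cliques considered at shared loci (paired +
unmatched), and specificity as the prediction-side analogue; the
underlying method description never defines the gene level, and this
interpretation keeps the two denominators distinct, as published
gene-level figures require. Display rounding: statistics to 4 decimals,
percentages to 1.

## Filtering and reports

An optional flat `Key=value` configuration excludes loci by length, gene
count, transcript count, transcripts per gene, exon count or CDS length
(counts are totals over both sources; transcripts-per-gene is the
maximum over genes; CDS length the maximum over transcripts). Unknown
keys are an error. Reports are plain text with a stable grammar and no
timestamps, so identical inputs give byte-identical output across runs
and worker counts; per-locus files are named `{seqid}_{start}-{end}.txt`.
An optional GFF3 track carries one `locus` feature per unfiltered locus
for genome-browser integration. HTML/graphical report modes are
deliberately out of scope.

## Synthetic test bed

The generator lays out uniformly sampled multi-exon coding genes
(defaults: 2–5 exons of 100–300 bp, introns 60–200 bp, UTRs 20–80/40–150
bp, intergenic gaps 200–600 bp, 10 genes per 100 kb sequence) and derives
the prediction through per-gene perturbations designed to map one-to-one
onto classification rules: outer-UTR edits (CDS structure match), codon
CDS-start shifts (exon structure match), internal splice-site shifts
(UTR structure match), gene drops/additions (single-source loci), and
gap-bridging merges / exon-trimming splits (non-matches). Uniform length
distributions are intentional — the tests need controlled structure, not
biological realism — so green tests establish correctness of the
algorithmic contracts, not performance on the length/GC/isoform
distributions of real genomes. In particular the generator produces no
alternative isoforms, no overlapping reference genes outside merge
programs, and no non-coding transcripts; those paths are covered by
hand-built unit fixtures instead. For single-edit programs the exact
pooled nucleotide confusion counts implied by the coordinate deltas are
computed analytically and checked against the pipeline's running totals
with zero tolerance.

## Numerical notes and limitations

- All arithmetic is exact integer counting until the final divisions;
  no tolerances are needed anywhere in the pipeline itself.
- Worst-case clique enumeration is exponential; pathological loci with
  dozens of mutually overlapping transcripts would be slow. Real and
  synthetic loci are far below that regime.
- Vector encoding materializes one character per locus position;
  megabase loci (possible under extreme annotation disagreement) would
  be memory-heavy. Streaming per sequence keeps whole-genome runs flat.
- GTF input and nucleotide-sequence-aware checks (start/stop codon
  validity) are out of scope; conversion and validation belong to
  upstream tooling.
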