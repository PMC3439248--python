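# annodiff

Pairwise comparison of gene structure annotation sets.

Genome annotation workflows routinely produce several candidate gene
structure annotations for the same assembly — a curated release versus a
new predictor's output, two database releases, two parameterizations of
the same pipeline — with no a priori way to call one of them the truth.
`annodiff` takes two GFF3 annotation sets over the same sequences, a
*reference* and a *prediction* (labels only: the method treats them
symmetrically), and reports how and where they differ, at whole-set and
at individual-locus resolution. It is aimed at annotation producers,
gene-prediction developers and anyone curating a gene family who needs
more than one summary number.

## Method

1. **Gene loci.** All genes from both sets become nodes of one interval
   graph with an edge wherever two gene spans overlap (any strand, any
   source). Each connected component is a *gene locus* — the smallest
   region containing its genes. Loci partition the genes, never overlap,
   and are mutually independent.
2. **Model vectors.** Per source and locus, transcripts are collapsed
   into the maximal cliques of their non-overlap graph (Bron–Kerbosch
   with pivoting); each clique of mutually disjoint transcripts is
   encoded as one string over `{C, F, G, I, T}` (coding, 5' UTR,
   intergenic, intron, 3' UTR) spanning the locus. Introns and UTRs
   absent from the input are inferred from exon + CDS coordinates.
3. **Statistics.** For each paired vector pair: nucleotide-level
   Sn = TP/(TP+FN), Sp = TP/(TP+FP), F1, annotation edit distance
   AED = 1 − (Sn+Sp)/2, simple matching coefficient and Matthews
   correlation for the CDS and UTR classes, plus overall identity;
   feature-level Sn/Sp/F1/AED for exons, CDS segments and UTR segments,
   where a true positive requires exact start *and* end agreement. Each
   comparison is classified (perfect / CDS structure / exon structure /
   UTR structure match / non-match), cliques are paired greedily by rank
   so each is used at most once, and pooled running totals yield the
   aggregate summary. See `docs/methods.md` for the details and design
   rationale.

## Usage

```sh
annodiff REFERENCE.gff3 PREDICTION.gff3 [--outdir DIR] [--filterfile CFG]
         [--locus-gff3 TRACK.gff3] [--workers N] [--verbose]
```

Reports go to stdout, or to `DIR/{seqid}_{start}-{end}.txt` plus
`DIR/summary.txt` with `--outdir`. `--filterfile` excludes loci via flat
`Key=value` bounds (e.g. `MaxLocusLength=5000`; keys: Min/Max ×
LocusLength, GeneCount, TranscriptCount, TranscriptsPerGene, ExonCount,
CDSLength). `--locus-gff3` writes a browser-ready locus track.
`annodiff-simulate` generates paired synthetic annotation sets with
known ground truth for testing.

## Worked example

A two-exon gene whose predicted CDS start sits 30 bp (10 codons)
downstream of the reference's, exons identical:

```sh
annodiff ref.gff3 pred.gff3
```

```
  comparison 1
    reference transcripts:  mRNA1
    prediction transcripts: mRNA1
    classification: exon structure match
    nucleotide-level
    CDS          TP 470  FP 0  FN 30  TN 400
    CDS          Sn 0.9400  Sp 1.0000  F1 0.9691  AED 0.0300  SMC 0.9667  CC 0.9351
    UTR          TP 200  FP 30  FN 0  TN 670
    UTR          Sn 1.0000  Sp 0.8696  F1 0.9302  AED 0.0652  SMC 0.9667  CC 0.9123
    overall identity: 0.9667
    feature-level
    exon         TP 2  FP 0  FN 0
    exon         Sn 1.0000  Sp 1.0000  F1 1.0000  AED 0.0000
    CDS segment  TP 1  FP 1  FN 1
    CDS segment  Sn 0.5000  Sp 0.5000  F1 0.5000  AED 0.5000
```

Reading it: the 30 reference coding positions the prediction calls 5' UTR
appear as CDS false negatives and, simultaneously, UTR false positives;
exon coordinates agree perfectly (exon Sn = Sp = 1), so the comparison is
an *exon structure match* — exact CDS agreement would be needed for a CDS
structure match, and identical vectors for a perfect match. One of two
CDS segments still matches exactly at feature level. Undefined statistics
(zero denominators) print as `--`, never as 0.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

generates a seeded synthetic genome (200 genes over 4 sequences, mixed
structural perturbations), runs the complete pipeline on it, prints the
aggregate summary to stderr, and writes the results JSON to `--out`.
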