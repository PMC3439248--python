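"""Shared helpers: tiny hand-built annotations used across the suite."""

import pytest

from annodiff.gff3 import infer_structures
from annodiff.model import (
    AnnotationSet,
    GeneAnnotation,
    GenomicInterval,
    PREDICTION,
    REFERENCE,
    Transcript,
)


def iv(start, end, seqid="chr1", strand="+"):
    return GenomicInterval(seqid, start, end, strand)


def make_transcript(
    tid, exons, cds, strand="+", seqid="chr1", gene_id=None
):
    """Build a transcript from exon and CDS coordinate pairs and run
    structure inference (introns, UTRs)."""
    exon_ivs = tuple(iv(s, e, seqid, strand) for s, e in sorted(exons))
    cds_ivs = tuple(iv(s, e, seqid, strand) for s, e in sorted(cds))
    t = Transcript(
        tid,
        gene_id or f"gene:{tid}",
        iv(exon_ivs[0].start, exon_ivs[-1].end, seqid, strand),
        exon_ivs,
        cds_ivs,
    )
    return infer_structures(t)


def make_gene(gid, transcripts, source=REFERENCE):
    lo = min(t.interval.start for t in transcripts)
    hi = max(t.interval.end for t in transcripts)
    t0 = transcripts[0]
    return GeneAnnotation(
        gid,
        GenomicInterval(t0.interval.seqid, lo, hi, t0.strand),
        tuple(transcripts),
        source,
    )


def make_set(genes, source=REFERENCE):
    s = AnnotationSet(source)
    for g in genes:
        s.add_gene(g)
    return s.finalize()


def single_exon_gene(gid, start, end, source=REFERENCE, seqid="chr1", strand="+"):
    """A one-exon gene whose exon is entirely CDS."""
    t = make_transcript(f"{gid}.m1", [(start, end)], [(start, end)],
                        strand, seqid, gene_id=gid)
    return make_gene(gid, [t], source)


@pytest.fixture
def two_exon_transcript():
    """The canonical worked example: + strand, exons 11-40 and 61-90,
    CDS 21-40 and 61-80 (so UTRs 11-20 and 81-90, intron 41-60)."""
    return make_transcript("m1", [(11, 40), (61, 90)], [(21, 40), (61, 80)])


MINIMAL_GFF3 = """\
##gff-version 3
chr1\ttest\tgene\t11\t90\t.\t+\t.\tID=g1
chr1\ttest\tmRNA\t11\t90\t.\t+\t.\tID=m1;Parent=g1
chr1\ttest\texon\t11\t40\t.\t+\t.\tParent=m1
chr1\ttest\texon\t61\t90\t.\t+\t.\tParent=m1
chr1\ttest\tCDS\t21\t40\t.\t+\t0\tID=m1.c;Parent=m1
chr1\ttest\tCDS\t61\t80\t.\t+\t2\tID=m1.c;Parent=m1
"""
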