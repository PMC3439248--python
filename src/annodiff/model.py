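"""Core domain types: intervals, transcripts, genes, annotation sets.

All coordinates are GFF3-style: 1-based, inclusive on both ends. A feature
of length 1 has start == end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple

REFERENCE = "reference"
PREDICTION = "prediction"
SOURCE_TAGS = (REFERENCE, PREDICTION)


class AnnotationError(Exception):
    """Structural problem in an annotation set."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based inclusive interval on a named sequence.

    ``strand`` is one of ``+``, ``-`` or ``.`` (unstranded). Strand never
    participates in overlap tests; it only orients UTR inference.
    """

    seqid: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid interval {self.seqid}:{self.start}-{self.end} "
                "(need 1 <= start <= end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the intervals share at least one position (adjacency is
        not overlap under inclusive coordinates)."""
        return (
            self.seqid == other.seqid
            and self.start <= other.end
            and other.start <= self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.seqid == other.seqid
            and self.start <= other.start
            and other.end <= self.end
        )

    def with_strand(self, strand: str) -> "GenomicInterval":
        return GenomicInterval(self.seqid, self.start, self.end, strand)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.seqid}:{self.start}-{self.end}"


def _check_sorted_disjoint(segments: Tuple[GenomicInterval, ...], what: str, owner: str) -> None:
    for a, b in zip(segments, segments[1:]):
        if b.start <= a.end:
            raise AnnotationError(
                f"{what} of {owner} overlap or are unsorted: {a} vs {b}"
            )


@dataclass(frozen=True)
class Transcript:
    """A single mRNA: exons, CDS segments and the structure inferred from
    them (introns, 5'/3' UTR segments).

    Segment lists are tuples of :class:`GenomicInterval`, sorted by start.
    ``utr5``/``utr3`` are named in biological (transcription) order: on the
    minus strand the 5' UTR lies at the high-coordinate end.
    """

    id: str
    parent_gene_id: str
    interval: GenomicInterval
    exons: Tuple[GenomicInterval, ...]
    cds_segments: Tuple[GenomicInterval, ...] = ()
    utr5_segments: Tuple[GenomicInterval, ...] = ()
    utr3_segments: Tuple[GenomicInterval, ...] = ()
    introns: Tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"transcript {self.id} has no exons")
        _check_sorted_disjoint(self.exons, "exons", self.id)
        _check_sorted_disjoint(self.cds_segments, "CDS segments", self.id)

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def cds_length(self) -> int:
        return sum(s.length for s in self.cds_segments)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    def exon_coords(self) -> List[Tuple[int, int]]:
        return [(e.start, e.end) for e in self.exons]

    def cds_coords(self) -> List[Tuple[int, int]]:
        return [(c.start, c.end) for c in self.cds_segments]

    def utr_coords(self) -> List[Tuple[int, int, str]]:
        """UTR segments tagged by biological role ('5' or '3')."""
        out = [(u.start, u.end, "5") for u in self.utr5_segments]
        out += [(u.start, u.end, "3") for u in self.utr3_segments]
        return sorted(out)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene with at least one mRNA, tagged with the annotation source it
    came from (reference or prediction)."""

    id: str
    interval: GenomicInterval
    transcripts: Tuple[Transcript, ...]
    source_tag: str

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise AnnotationError(f"gene {self.id} has no transcripts")
        if self.source_tag not in SOURCE_TAGS:
            raise ValueError(f"unknown source tag {self.source_tag!r}")
        lo = min(t.interval.start for t in self.transcripts)
        hi = max(t.interval.end for t in self.transcripts)
        if self.interval.start > lo or self.interval.end < hi:
            raise AnnotationError(
                f"gene {self.id} interval {self.interval} does not span its "
                f"transcripts ({lo}-{hi})"
            )


class AnnotationSet:
    """Genes from one source, grouped by seqid and sorted by start."""

    def __init__(self, source_tag: str):
        if source_tag not in SOURCE_TAGS:
            raise ValueError(f"unknown source tag {source_tag!r}")
        self.source_tag = source_tag
        self._by_seqid: Dict[str, List[GeneAnnotation]] = {}
        self._ids: set = set()

    def add_gene(self, gene: GeneAnnotation) -> None:
        if gene.id in self._ids:
            raise AnnotationError(f"duplicate gene ID {gene.id!r}")
        self._ids.add(gene.id)
        self._by_seqid.setdefault(gene.interval.seqid, []).append(gene)

    def finalize(self) -> "AnnotationSet":
        for genes in self._by_seqid.values():
            genes.sort(key=lambda g: (g.interval.start, g.interval.end, g.id))
        return self

    def seqids(self) -> List[str]:
        return sorted(self._by_seqid)

    def genes_on(self, seqid: str) -> List[GeneAnnotation]:
        return list(self._by_seqid.get(seqid, []))

    def __iter__(self) -> Iterator[GeneAnnotation]:
        for seqid in self.seqids():
            yield from self._by_seqid[seqid]

    def __len__(self) -> int:
        return len(self._ids)

    def transcript_count(self) -> int:
        return sum(len(g.transcripts) for g in self)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return (
            self.source_tag == other.source_tag
            and {s: self._by_seqid[s] for s in self.seqids()}
            == {s: other._by_seqid[s] for s in other.seqids()}
        )


@dataclass(frozen=True)
class GeneLocus:
    """The smallest genomic region containing every gene of one connected
    component of the joint gene-overlap graph."""

    interval: GenomicInterval
    ref_genes: Tuple[GeneAnnotation, ...]
    pred_genes: Tuple[GeneAnnotation, ...]

    def __post_init__(self) -> None:
        if not self.ref_genes and not self.pred_genes:
            raise ValueError("locus with no genes")

    @property
    def genes(self) -> Tuple[GeneAnnotation, ...]:
        return self.ref_genes + self.pred_genes

    @property
    def shared(self) -> bool:
        """True iff both sources contribute at least one gene."""
        return bool(self.ref_genes) and bool(self.pred_genes)

    def transcripts(self, source_tag: str) -> List[Transcript]:
        genes = self.ref_genes if source_tag == REFERENCE else self.pred_genes
        out = [t for g in genes for t in g.transcripts]
        out.sort(key=lambda t: (t.interval.start, t.interval.end, t.id))
        return out

    @property
    def tag(self) -> str:
        iv = self.interval
        return f"{iv.seqid}_{iv.start}-{iv.end}"
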