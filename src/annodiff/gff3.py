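"""GFF3 reading, implicit-structure inference, and locus-track writing.

Reading is a two-pass process (features may precede their parents): lines
are parsed with :func:`gffutils.feature.feature_from_line`, then the
gene -> mRNA -> exon/CDS/UTR hierarchy is assembled from ID/Parent
attributes. Introns and UTR segments absent from the input are inferred
from exon + CDS coordinates; explicit UTR features, when present, are
checked against the inferred ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, TextIO, Tuple

from gffutils.feature import feature_from_line

from .model import (
    AnnotationError,
    AnnotationSet,
    GeneAnnotation,
    GenomicInterval,
    Transcript,
)

log = logging.getLogger(__name__)

#: feature types that define a transcript we can compare
TRANSCRIPT_TYPE = "mRNA"
CHILD_TYPES = ("exon", "CDS", "five_prime_UTR", "three_prime_UTR", "intron")


class GFF3ParseError(Exception):
    """Malformed GFF3 input; message names the offending line."""


@dataclass
class _RawFeature:
    line_no: int
    seqid: str
    ftype: str
    start: int
    end: int
    strand: str
    fid: Optional[str]
    parents: List[str]


def _parse_line(line: str, line_no: int) -> _RawFeature:
    cols = line.rstrip("\n").split("\t")
    if len(cols) != 9:
        raise GFF3ParseError(
            f"line {line_no}: expected 9 tab-separated columns, got {len(cols)}"
        )
    try:
        feat = feature_from_line(line)
    except Exception as exc:
        raise GFF3ParseError(f"line {line_no}: {exc}") from exc
    if feat.end < feat.start:
        raise GFF3ParseError(
            f"line {line_no}: end ({feat.end}) < start ({feat.start})"
        )
    fid = feat.attributes.get("ID", [None])[0]
    parents = list(feat.attributes.get("Parent", []))
    strand = feat.strand if feat.strand in ("+", "-") else "."
    return _RawFeature(
        line_no, feat.seqid, feat.featuretype, feat.start, feat.end,
        strand, fid, parents,
    )


def _merge_touching(ivs: List[GenomicInterval]) -> List[GenomicInterval]:
    """Merge overlapping/abutting intervals (used to synthesize exons from
    discontinuous CDS features)."""
    out: List[GenomicInterval] = []
    for iv in sorted(ivs, key=lambda i: (i.start, i.end)):
        if out and iv.start <= out[-1].end + 1:
            prev = out.pop()
            out.append(
                GenomicInterval(prev.seqid, prev.start, max(prev.end, iv.end), prev.strand)
            )
        else:
            out.append(iv)
    return out


def infer_structures(t: Transcript) -> Transcript:
    """Fill in introns and UTR segments implied by exon + CDS coordinates.

    Introns are the gaps between consecutive exons. Exonic positions
    upstream of the CDS span (in transcription order) become 5' UTR,
    downstream ones 3' UTR; on the minus strand "upstream" means higher
    coordinates. Pre-existing UTR segments on ``t`` are treated as explicit
    input: they are compared with the inferred ones and a mismatch logs a
    warning (the inferred version is kept).
    """
    introns = tuple(
        GenomicInterval(t.interval.seqid, a.end + 1, b.start - 1, t.strand)
        for a, b in zip(t.exons, t.exons[1:])
        if b.start > a.end + 1
    )
    if not t.cds_segments:
        return Transcript(
            t.id, t.parent_gene_id, t.interval, t.exons,
            (), (), (), introns,
        )
    for c in t.cds_segments:
        if not any(e.start <= c.start and c.end <= e.end for e in t.exons):
            raise AnnotationError(
                f"transcript {t.id}: CDS segment {c} not contained in any exon"
            )
    cds_lo = t.cds_segments[0].start
    cds_hi = t.cds_segments[-1].end
    left: List[GenomicInterval] = []
    right: List[GenomicInterval] = []
    for e in t.exons:
        if e.start < cds_lo:
            left.append(
                GenomicInterval(e.seqid, e.start, min(e.end, cds_lo - 1), t.strand)
            )
        if e.end > cds_hi:
            right.append(
                GenomicInterval(e.seqid, max(e.start, cds_hi + 1), e.end, t.strand)
            )
    if t.strand == "-":
        utr5, utr3 = tuple(right), tuple(left)
    else:
        utr5, utr3 = tuple(left), tuple(right)
    for explicit, inferred, label in (
        (t.utr5_segments, utr5, "5'"),
        (t.utr3_segments, utr3, "3'"),
    ):
        if explicit and tuple(explicit) != inferred:
            log.warning(
                "transcript %s: explicit %s UTR %s conflicts with inferred %s; "
                "keeping inferred",
                t.id, label,
                [(u.start, u.end) for u in explicit],
                [(u.start, u.end) for u in inferred],
            )
    return Transcript(
        t.id, t.parent_gene_id, t.interval, t.exons, t.cds_segments,
        utr5, utr3, introns,
    )


def parse_gff3(stream: Iterable[str], source_tag: str) -> AnnotationSet:
    """Read a GFF3 annotation set.

    Returns every gene with at least one comparable mRNA. mRNAs lacking
    exon features but having CDS segments get exons synthesized from the
    CDS; mRNAs with no CDS at all are skipped with a warning (the
    comparison alphabet is CDS-oriented). Non-mRNA transcript types under
    a gene are skipped with a warning. Standalone mRNAs (no gene Parent)
    receive a synthetic single-mRNA gene wrapper.
    """
    feats: List[_RawFeature] = []
    for line_no, line in enumerate(stream, start=1):
        if not line.strip():
            continue
        if line.startswith("##FASTA"):
            break
        if line.startswith("#"):
            continue
        if line.startswith(">"):  # naked FASTA section
            break
        feats.append(_parse_line(line, line_no))

    genes: Dict[str, _RawFeature] = {}
    mrnas: Dict[str, _RawFeature] = {}
    other_transcripts: set = set()
    known_ids: set = set()
    for f in feats:
        if f.fid is not None:
            known_ids.add(f.fid)
        if f.ftype == "gene":
            if f.fid is None:
                raise GFF3ParseError(f"line {f.line_no}: gene feature lacks ID")
            genes[f.fid] = f
    for f in feats:
        if f.ftype == TRANSCRIPT_TYPE:
            if f.fid is None:
                raise GFF3ParseError(f"line {f.line_no}: mRNA feature lacks ID")
            for p in f.parents:
                if p not in known_ids:
                    raise GFF3ParseError(
                        f"line {f.line_no}: Parent {p!r} refers to unknown ID"
                    )
            mrnas[f.fid] = f
        elif f.parents and any(p in genes for p in f.parents) and f.ftype not in CHILD_TYPES:
            other_transcripts.add(f.fid)
            log.warning(
                "skipping non-mRNA transcript type %s (%s)", f.ftype, f.fid
            )

    children: Dict[str, Dict[str, List[GenomicInterval]]] = {}
    for f in feats:
        if f.ftype not in CHILD_TYPES:
            continue
        for p in f.parents:
            if p in other_transcripts:
                continue
            if p not in known_ids:
                raise GFF3ParseError(
                    f"line {f.line_no}: Parent {p!r} refers to unknown ID"
                )
            if p not in mrnas:
                continue  # e.g. exon attached directly to a gene: ignore
            children.setdefault(p, {}).setdefault(f.ftype, []).append(
                GenomicInterval(f.seqid, f.start, f.end, f.strand)
            )

    transcripts_by_gene: Dict[str, List[Transcript]] = {}
    synthetic_genes: Dict[str, _RawFeature] = {}
    for mid, m in sorted(mrnas.items(), key=lambda kv: kv[1].line_no):
        kids = children.get(mid, {})
        exons = sorted(kids.get("exon", []), key=lambda i: (i.start, i.end))
        cds = sorted(kids.get("CDS", []), key=lambda i: (i.start, i.end))
        if not exons and cds:
            exons = _merge_touching(cds)
        if not exons:
            log.warning("skipping mRNA %s: no exon and no CDS features", mid)
            continue
        if not cds:
            log.warning("skipping mRNA %s: no CDS features (non-coding)", mid)
            continue
        iv = GenomicInterval(m.seqid, m.start, m.end, m.strand)
        lo = min(iv.start, exons[0].start)
        hi = max(iv.end, exons[-1].end)
        iv = GenomicInterval(m.seqid, lo, hi, m.strand)
        parent_gene = next((p for p in m.parents if p in genes), None)
        if parent_gene is None:
            parent_gene = f"gene:{mid}"
            synthetic_genes[parent_gene] = m
        t = Transcript(
            mid, parent_gene, iv, tuple(exons), tuple(cds),
            tuple(sorted(kids.get("five_prime_UTR", []), key=lambda i: i.start)),
            tuple(sorted(kids.get("three_prime_UTR", []), key=lambda i: i.start)),
        )
        transcripts_by_gene.setdefault(parent_gene, []).append(infer_structures(t))

    result = AnnotationSet(source_tag)
    all_gene_feats = dict(genes)
    all_gene_feats.update(synthetic_genes)
    for gid, gf in sorted(all_gene_feats.items(), key=lambda kv: kv[1].line_no):
        ts = transcripts_by_gene.get(gid)
        if not ts:
            continue
        ts.sort(key=lambda t: (t.interval.start, t.interval.end, t.id))
        lo = min(gf.start, min(t.interval.start for t in ts))
        hi = max(gf.end, max(t.interval.end for t in ts))
        result.add_gene(
            GeneAnnotation(
                gid,
                GenomicInterval(gf.seqid, lo, hi, gf.strand),
                tuple(ts),
                source_tag,
            )
        )
    return result.finalize()


def write_gff3_loci(loci, stream: TextIO) -> None:
    """Write one ``locus`` feature per gene locus, sorted by (seqid, start),
    with reference/prediction gene counts in the attributes column."""
    stream.write("##gff-version 3\n")
    for locus in sorted(loci, key=lambda l: (l.interval.seqid, l.interval.start)):
        iv = locus.interval
        attrs = (
            f"ID=locus_{locus.tag};ref_genes={len(locus.ref_genes)};"
            f"pred_genes={len(locus.pred_genes)}"
        )
        stream.write(
            f"{iv.seqid}\tannodiff\tlocus\t{iv.start}\t{iv.end}\t.\t.\t.\t{attrs}\n"
        )


def read_gff3_loci(stream: Iterable[str]) -> List[Tuple[str, int, int, int, int]]:
    """Read a locus track back as (seqid, start, end, n_ref, n_pred) tuples
    (round-trip counterpart of :func:`write_gff3_loci`)."""
    out = []
    for line_no, line in enumerate(stream, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        f = _parse_line(line, line_no)
        if f.ftype != "locus":
            continue
        feat = feature_from_line(line)
        nref = int(feat.attributes.get("ref_genes", ["0"])[0])
        npred = int(feat.attributes.get("pred_genes", ["0"])[0])
        out.append((f.seqid, f.start, f.end, nref, npred))
    return out
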