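"""Paired synthetic annotation sets with known ground truth.

The generator lays out non-overlapping multi-exon protein-coding genes
along one or more sequences, then derives the prediction set gene by gene
through a perturbation program with controlled structural edits:

====================  =====================================================
kind                  edit and expected classification
====================  =====================================================
``identical``         exact copy -> perfect match
``utr_edit``          outer transcript end moved, CDS and internal exon
                      boundaries untouched -> CDS structure match
``cds_shift``         CDS start moved inward by whole codons within the
                      same exon -> exon structure match
``splice_shift``      an internal, fully coding exon end moved into its
                      intron -> UTR structure match
``drop``              gene absent from the prediction -> locus unique to
                      the reference
``add``               gene copied, plus a novel prediction-only gene in
                      the following intergenic gap -> extra locus unique
                      to the prediction
``merge``             this gene and the next bridged into one transcript
                      (the gap becomes one continuous exon) -> non-match
``split``             gene cut at an intron into two prediction genes with
                      trimmed flanking exons -> non-match
====================  =====================================================

Edits are chosen so each maps one-to-one onto a classification rule, and
coordinate deltas are recorded so pooled nucleotide confusion counts can
be predicted analytically (:func:`expected_confusion`). Length
distributions are uniform over the stated bounds: the aim is controlled
structure, not biological realism.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .compare import ConfusionCounts

PERTURBATION_KINDS = (
    "utr_edit", "cds_shift", "splice_shift", "drop", "add", "merge", "split",
)

#: expected match classification per single-edit perturbation kind
EXPECTED_CLASS = {
    "identical": "perfect_match",
    "add": "perfect_match",  # the host gene itself is copied verbatim
    "utr_edit": "cds_structure_match",
    "cds_shift": "exon_structure_match",
    "splice_shift": "utr_structure_match",
    "merge": "non_match",
    "split": "non_match",
}


class GenerationError(Exception):
    """Requested parameters cannot be laid out (genes do not fit)."""


@dataclass
class GeneratorParams:
    """Knobs for the generator. Bounds are inclusive (lo, hi) and sampled
    uniformly. ``probabilities`` maps perturbation kinds to per-gene
    probabilities; they must sum to at most 1, the remainder being
    identical copies."""

    seed: int = 0
    n_sequences: int = 1
    sequence_length: int = 100_000
    genes_per_sequence: int = 10
    exon_count: Tuple[int, int] = (2, 5)
    exon_length: Tuple[int, int] = (100, 300)
    intron_length: Tuple[int, int] = (60, 200)
    utr5_length: Tuple[int, int] = (20, 80)
    utr3_length: Tuple[int, int] = (40, 150)
    intergenic_gap: Tuple[int, int] = (200, 600)
    explicit_utrs: bool = False
    probabilities: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k in self.probabilities:
            if k not in PERTURBATION_KINDS:
                raise ValueError(f"unknown perturbation kind {k!r}")
        if sum(self.probabilities.values()) > 1.0 + 1e-9:
            raise ValueError("perturbation probabilities sum to more than 1")
        if self.exon_length[0] < 60:
            raise GenerationError("exon_length lower bound must be >= 60")
        if self.intergenic_gap[0] < 80:
            raise GenerationError("intergenic_gap lower bound must be >= 80")


@dataclass
class GeneSpec:
    """One gene as the generator sees it: exon layout plus UTR lengths in
    transcription order (u5 at the 5' end of the mRNA)."""

    id: str
    seqid: str
    strand: str
    exons: List[Tuple[int, int]]
    u5: int
    u3: int

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


def carve(
    exons: Sequence[Tuple[int, int]], strand: str, u5: int, u3: int
) -> Tuple[List[Tuple[int, int]], List[Tuple[int, int]], List[Tuple[int, int]]]:
    """Split the exonic positions into (cds, utr5, utr3) coordinate lists:
    the first ``u5`` exonic positions in transcription order are 5' UTR,
    the last ``u3`` are 3' UTR, the middle is CDS."""
    total = sum(e - s + 1 for s, e in exons)
    left = u5 if strand == "+" else u3
    right = u3 if strand == "+" else u5
    a, b = left, total - right
    if a >= b:
        raise GenerationError("UTRs leave no room for CDS")
    cds: List[Tuple[int, int]] = []
    lsegs: List[Tuple[int, int]] = []
    rsegs: List[Tuple[int, int]] = []
    idx = 0
    for s, e in exons:
        ln = e - s + 1
        for lo, hi, out in ((0, a, lsegs), (a, b, cds), (b, total, rsegs)):
            l = max(lo, idx)
            h = min(hi, idx + ln)
            if l < h:
                out.append((s + (l - idx), s + (h - idx) - 1))
        idx += ln
    if strand == "+":
        return cds, lsegs, rsegs
    return cds, rsegs, lsegs


@dataclass
class EditRecord:
    """Per-gene coordinate deltas implied by one edit, for analytic
    prediction of pooled nucleotide confusion counts."""

    gene_id: str
    kind: str
    ref_cds_len: int = 0
    ref_utr_len: int = 0
    locus_length: int = 0
    cds_fp: int = 0
    cds_fn: int = 0
    utr_fp: int = 0
    utr_fn: int = 0


@dataclass
class GroundTruth:
    """What the pipeline should report for a generated pair."""

    expected_class: Dict[str, str] = field(default_factory=dict)
    n_ref_only: int = 0
    n_pred_only: int = 0
    records: List[EditRecord] = field(default_factory=list)


def _draw_kind(rng: random.Random, probs: Dict[str, float]) -> str:
    r = rng.random()
    acc = 0.0
    for k in sorted(probs):
        acc += probs[k]
        if r < acc:
            return k
    return "identical"


def _sample_gene(
    rng: random.Random,
    p: GeneratorParams,
    seqid: str,
    gid: str,
    start: int,
    strand: Optional[str] = None,
    min_exons: int = 1,
) -> GeneSpec:
    n_exons = rng.randint(max(p.exon_count[0], min_exons), max(p.exon_count[1], min_exons))
    lens = [rng.randint(*p.exon_length) for _ in range(n_exons)]
    gaps = [rng.randint(*p.intron_length) for _ in range(n_exons - 1)]
    exons: List[Tuple[int, int]] = []
    pos = start
    for i, ln in enumerate(lens):
        exons.append((pos, pos + ln - 1))
        if i < len(gaps):
            pos += ln + gaps[i]
    if strand is None:
        strand = rng.choice("+-")
    total = sum(lens)
    first_len = lens[0] if strand == "+" else lens[-1]
    last_len = lens[-1] if strand == "+" else lens[0]
    u5 = max(5, min(rng.randint(*p.utr5_length), first_len - 20))
    u3 = max(5, min(rng.randint(*p.utr3_length), last_len - 20, total - u5 - 15))
    return GeneSpec(gid, seqid, strand, exons, u5, u3)


def _identical_record(g: GeneSpec) -> EditRecord:
    return EditRecord(
        g.id, "identical",
        ref_cds_len=g.exonic_length - g.u5 - g.u3,
        ref_utr_len=g.u5 + g.u3,
        locus_length=g.end - g.start + 1,
    )


def _apply_utr_edit(rng: random.Random, g: GeneSpec) -> Tuple[GeneSpec, EditRecord]:
    """Move the genomic-left outer transcript end. Extending adds UTR
    positions where the reference is intergenic (UTR FP); shrinking loses
    reference UTR positions (UTR FN). CDS untouched."""
    left_u = g.u5 if g.strand == "+" else g.u3
    rec = _identical_record(g)
    rec.kind = "utr_edit"
    shrink = rng.random() < 0.5 and left_u > 8
    exons = list(g.exons)
    s, e = exons[0]
    if shrink:
        d = rng.randint(3, min(30, left_u - 3))
        exons[0] = (s + d, e)
        rec.utr_fn = d
        delta = -d
    else:
        d = rng.randint(5, 30)
        exons[0] = (s - d, e)
        rec.utr_fp = d
        rec.locus_length += d  # locus spans the union of both transcripts
        delta = d
    if g.strand == "+":
        pred = GeneSpec(g.id, g.seqid, g.strand, exons, g.u5 + delta, g.u3)
    else:
        pred = GeneSpec(g.id, g.seqid, g.strand, exons, g.u5, g.u3 + delta)
    return pred, rec


def _apply_cds_shift(rng: random.Random, g: GeneSpec) -> Tuple[GeneSpec, EditRecord]:
    """Move the CDS start inward by whole codons: former coding positions
    become 5' UTR in the prediction (CDS FN + UTR FP), exons unchanged."""
    d = rng.choice([3, 6, 9, 12])
    rec = _identical_record(g)
    rec.kind = "cds_shift"
    rec.cds_fn = d
    rec.utr_fp = d
    pred = GeneSpec(g.id, g.seqid, g.strand, list(g.exons), g.u5 + d, g.u3)
    return pred, rec


def _apply_splice_shift(rng: random.Random, g: GeneSpec) -> Tuple[GeneSpec, EditRecord]:
    """Shrink an internal, fully coding exon end into its intron: the lost
    positions are coding in the reference and intronic in the prediction
    (CDS FN only); UTRs untouched."""
    k = rng.randrange(len(g.exons) - 1)
    d = rng.randint(3, 15)
    exons = list(g.exons)
    s, e = exons[k]
    exons[k] = (s, e - d)
    rec = _identical_record(g)
    rec.kind = "splice_shift"
    rec.cds_fn = d
    pred = GeneSpec(g.id, g.seqid, g.strand, exons, g.u5, g.u3)
    return pred, rec


def _apply_merge(a: GeneSpec, b: GeneSpec) -> GeneSpec:
    """Bridge two adjacent genes into one transcript whose middle exon
    spans the intergenic gap; the inner UTRs vanish into CDS."""
    exons = list(a.exons[:-1]) + [(a.exons[-1][0], b.exons[0][1])] + list(b.exons[1:])
    return GeneSpec(a.id, a.seqid, "+", exons, a.u5, b.u3)


def _apply_split(rng: random.Random, g: GeneSpec) -> Tuple[GeneSpec, GeneSpec]:
    """Cut at an intron into two genes, trimming 10 bp off each flanking
    exon so exon structure (and hence UTR structure) genuinely differs."""
    k = rng.randrange(len(g.exons) - 1)
    left = list(g.exons[: k + 1])
    right = list(g.exons[k + 1:])
    s, e = left[-1]
    left[-1] = (s, e - 10)
    s, e = right[0]
    right[0] = (s + 10, e)
    # inherited UTRs may not fit the smaller halves; clamp to leave CDS room
    len_a = sum(e - s + 1 for s, e in left)
    len_b = sum(e - s + 1 for s, e in right)
    a = GeneSpec(f"{g.id}.1", g.seqid, "+", left, min(g.u5, len_a - 15), 10)
    b = GeneSpec(f"{g.id}.2", g.seqid, "+", right, 10, min(g.u3, len_b - 15))
    return a, b


def _gene_gff3(spec: GeneSpec, source: str, explicit_utrs: bool) -> List[str]:
    cds, utr5, utr3 = carve(spec.exons, spec.strand, spec.u5, spec.u3)
    mid = f"{spec.id}.m1"
    lines = [
        f"{spec.seqid}\t{source}\tgene\t{spec.start}\t{spec.end}\t.\t{spec.strand}\t.\tID={spec.id}",
        f"{spec.seqid}\t{source}\tmRNA\t{spec.start}\t{spec.end}\t.\t{spec.strand}\t.\tID={mid};Parent={spec.id}",
    ]
    for s, e in spec.exons:
        lines.append(
            f"{spec.seqid}\t{source}\texon\t{s}\t{e}\t.\t{spec.strand}\t.\tParent={mid}"
        )
    for s, e in cds:
        lines.append(
            f"{spec.seqid}\t{source}\tCDS\t{s}\t{e}\t.\t{spec.strand}\t0\tID={mid}.cds;Parent={mid}"
        )
    if explicit_utrs:
        for segs, ftype in ((utr5, "five_prime_UTR"), (utr3, "three_prime_UTR")):
            for s, e in segs:
                lines.append(
                    f"{spec.seqid}\t{source}\t{ftype}\t{s}\t{e}\t.\t{spec.strand}\t.\tParent={mid}"
                )
    return lines


def generate_pair(p: GeneratorParams) -> Tuple[str, str, GroundTruth]:
    """Generate (reference GFF3 text, prediction GFF3 text, ground truth).

    Same parameters (including seed) give byte-identical output. Raises
    :class:`GenerationError` when the requested genes do not fit on the
    sequences.
    """
    rng = random.Random(p.seed)
    truth = GroundTruth()
    ref_specs: List[GeneSpec] = []
    pred_specs: List[GeneSpec] = []

    for s in range(p.n_sequences):
        seqid = f"seq{s + 1}"
        kinds = [
            _draw_kind(rng, p.probabilities)
            for _ in range(p.genes_per_sequence)
        ]
        # a merge consumes the following gene; downgrade infeasible merges
        i = 0
        while i < len(kinds):
            if kinds[i] == "merge":
                if i + 1 < len(kinds):
                    kinds[i + 1] = "merge_consumed"
                    i += 1
                else:
                    kinds[i] = "identical"
            i += 1

        seq_refs: List[GeneSpec] = []
        cursor = 1 + rng.randint(*p.intergenic_gap)
        for i, kind in enumerate(kinds):
            strand = "+" if kind in ("merge", "merge_consumed", "split") else None
            min_exons = 2 if kind in ("splice_shift", "split") else 1
            spec = _sample_gene(
                rng, p, seqid, f"gene{s + 1}.{i + 1}", cursor, strand, min_exons
            )
            if spec.end + 60 > p.sequence_length:
                raise GenerationError(
                    f"gene {spec.id} does not fit in sequence of length "
                    f"{p.sequence_length}; reduce genes_per_sequence or sizes"
                )
            cursor = spec.end + 1 + rng.randint(*p.intergenic_gap)
            seq_refs.append(spec)
        ref_specs.extend(seq_refs)

        i = 0
        while i < len(kinds):
            g = seq_refs[i]
            kind = kinds[i]
            if kind == "identical":
                pred_specs.append(g)
                truth.expected_class[g.id] = EXPECTED_CLASS[kind]
                truth.records.append(_identical_record(g))
            elif kind == "utr_edit":
                pred, rec = _apply_utr_edit(rng, g)
                pred_specs.append(pred)
                truth.expected_class[g.id] = EXPECTED_CLASS[kind]
                truth.records.append(rec)
            elif kind == "cds_shift":
                pred, rec = _apply_cds_shift(rng, g)
                pred_specs.append(pred)
                truth.expected_class[g.id] = EXPECTED_CLASS[kind]
                truth.records.append(rec)
            elif kind == "splice_shift":
                pred, rec = _apply_splice_shift(rng, g)
                pred_specs.append(pred)
                truth.expected_class[g.id] = EXPECTED_CLASS[kind]
                truth.records.append(rec)
            elif kind == "drop":
                truth.n_ref_only += 1
                truth.records.append(EditRecord(g.id, "drop"))
            elif kind == "add":
                pred_specs.append(g)
                truth.expected_class[g.id] = EXPECTED_CLASS[kind]
                truth.records.append(_identical_record(g))
                nxt = (
                    seq_refs[i + 1].start - 1
                    if i + 1 < len(seq_refs)
                    else p.sequence_length
                )
                if nxt - g.end >= 200:
                    lo = g.end + 60
                    pred_specs.append(
                        GeneSpec(
                            f"novel{s + 1}.{i + 1}", seqid, "+",
                            [(lo, lo + 89)], 10, 10,
                        )
                    )
                    truth.n_pred_only += 1
            elif kind == "merge":
                nxt = seq_refs[i + 1]
                pred_specs.append(_apply_merge(g, nxt))
                truth.expected_class[g.id] = EXPECTED_CLASS[kind]
                truth.expected_class[nxt.id] = EXPECTED_CLASS[kind]
                truth.records.append(EditRecord(g.id, "merge"))
                i += 1  # consumed
            elif kind == "split":
                a, b = _apply_split(rng, g)
                pred_specs.extend([a, b])
                truth.expected_class[g.id] = EXPECTED_CLASS[kind]
                truth.records.append(EditRecord(g.id, "split"))
            else:  # pragma: no cover - merge_consumed handled by merge
                raise AssertionError(kind)
            i += 1

    def render(specs: List[GeneSpec], source: str) -> str:
        lines = ["##gff-version 3"]
        for s in range(p.n_sequences):
            lines.append(f"##sequence-region seq{s + 1} 1 {p.sequence_length}")
        for spec in sorted(specs, key=lambda g: (g.seqid, g.start, g.id)):
            lines.extend(_gene_gff3(spec, source, p.explicit_utrs))
        return "\n".join(lines) + "\n"

    return render(ref_specs, "sim-ref"), render(pred_specs, "sim-pred"), truth


def expected_confusion(
    truth: GroundTruth, records: Optional[Sequence[EditRecord]] = None
) -> Dict[str, ConfusionCounts]:
    """Pooled nucleotide confusion counts implied by the edit records, for
    exact comparison against the pipeline's running totals.

    Dropped genes' loci are single-source and contribute nothing. Merge,
    split and novel-gene records have no closed-form per-class deltas and
    raise ``ValueError``.
    """
    records = truth.records if records is None else records
    out = {"CDS": ConfusionCounts(), "UTR": ConfusionCounts()}
    for rec in records:
        if rec.kind == "drop":
            continue
        if rec.kind in ("merge", "split"):
            raise ValueError(
                f"no analytic confusion counts for {rec.kind!r} edits"
            )
        cds_tp = rec.ref_cds_len - rec.cds_fn
        utr_tp = rec.ref_utr_len - rec.utr_fn
        out["CDS"].add(
            ConfusionCounts(
                cds_tp, rec.cds_fp, rec.cds_fn,
                rec.locus_length - cds_tp - rec.cds_fp - rec.cds_fn,
            )
        )
        out["UTR"].add(
            ConfusionCounts(
                utr_tp, rec.utr_fp, rec.utr_fn,
                rec.locus_length - utr_tp - rec.utr_fp - rec.utr_fn,
            )
        )
    return out
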