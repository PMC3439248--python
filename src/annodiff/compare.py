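"""Pairwise comparison of reference and prediction model vectors.

Statistics are computed at two resolutions. At nucleotide level, each
position is tested for membership in a class (coding C, or untranslated
F/T pooled as UTR) in both vectors, giving TP/FP/FN/TN counts from which
sensitivity, specificity, F1, annotation edit distance (AED), simple
matching coefficient and correlation coefficient follow; overall identity
over the full five-letter alphabet is also computed. At feature level
(exons, CDS segments, UTR segments) a prediction feature counts as a true
positive only when both its start and end coordinates match a reference
feature exactly; true negatives are undefined at this resolution.

Any statistic whose denominator vanishes is *undefined* (``None``),
rendered downstream as ``--`` and excluded from aggregation, never
coerced to zero.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .model import GeneLocus, GenomicInterval, PREDICTION, REFERENCE, Transcript
from .vectors import (
    ModelVector,
    TranscriptClique,
    model_vectors_for,
    placeholder_vector,
)

# classification labels, from most to least congruent
PERFECT_MATCH = "perfect_match"
CDS_MATCH = "cds_structure_match"
EXON_MATCH = "exon_structure_match"
UTR_MATCH = "utr_structure_match"
NON_MATCH = "non_match"
CLASSIFICATIONS = (PERFECT_MATCH, CDS_MATCH, EXON_MATCH, UTR_MATCH, NON_MATCH)

NUCLEOTIDE_CLASSES = ("CDS", "UTR")
FEATURE_TYPES = ("exon", "cds_segment", "utr_segment")

_CLASS_SYMBOLS = {"CDS": frozenset("C"), "UTR": frozenset("FT")}


@dataclass
class ConfusionCounts:
    """TP/FP/FN/TN tallies at one resolution. At feature level ``tn`` is
    meaningless and held at 0."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def add(self, other: "ConfusionCounts") -> None:
        self.tp += other.tp
        self.fp += other.fp
        self.fn += other.fn
        self.tn += other.tn

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def swapped(self) -> "ConfusionCounts":
        """Counts with the roles of reference and prediction exchanged."""
        return ConfusionCounts(self.tp, self.fn, self.fp, self.tn)


@dataclass(frozen=True)
class StatPanel:
    """Similarity statistics derived from one set of confusion counts.

    ``smc`` and ``cc`` are populated only at nucleotide level. ``None``
    means undefined (zero denominator).
    """

    sensitivity: Optional[float]
    specificity: Optional[float]
    f1: Optional[float]
    aed: Optional[float]
    smc: Optional[float] = None
    cc: Optional[float] = None


def compute_stats(c: ConfusionCounts, level: str = "nucleotide") -> StatPanel:
    """Sn = TP/(TP+FN); Sp = TP/(TP+FP) (precision, per the gene-finding
    convention); F1 = 2TP/(2TP+FP+FN); AED = 1 - (Sn+Sp)/2;
    SMC = (TP+TN)/total; CC = Matthews correlation."""
    sn = c.tp / (c.tp + c.fn) if c.tp + c.fn else None
    sp = c.tp / (c.tp + c.fp) if c.tp + c.fp else None
    f1 = 2 * c.tp / (2 * c.tp + c.fp + c.fn) if 2 * c.tp + c.fp + c.fn else None
    aed = 1.0 - (sn + sp) / 2.0 if sn is not None and sp is not None else None
    if level == "feature":
        return StatPanel(sn, sp, f1, aed)
    smc = (c.tp + c.tn) / c.total if c.total else None
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    cc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom) if denom else None
    return StatPanel(sn, sp, f1, aed, smc, cc)


def count_nucleotides(
    ref: ModelVector, pred: ModelVector, cls: str
) -> ConfusionCounts:
    """Per-position confusion for one nucleotide class (CDS: symbol C;
    UTR: symbol in {F, T}, both untranslated classes pooled)."""
    if len(ref.symbols) != len(pred.symbols):
        raise ValueError("model vectors differ in length")
    members = _CLASS_SYMBOLS[cls]
    c = ConfusionCounts()
    for a, b in zip(ref.symbols, pred.symbols):
        in_ref = a in members
        in_pred = b in members
        if in_ref and in_pred:
            c.tp += 1
        elif in_pred:
            c.fp += 1
        elif in_ref:
            c.fn += 1
        else:
            c.tn += 1
    return c


def overall_identity(ref: ModelVector, pred: ModelVector) -> float:
    """Fraction of positions with identical symbols over the full
    five-letter alphabet."""
    if len(ref.symbols) != len(pred.symbols):
        raise ValueError("model vectors differ in length")
    n = len(ref.symbols)
    matches = sum(a == b for a, b in zip(ref.symbols, pred.symbols))
    return matches / n if n else 1.0


def match_features(
    ref_segments: Sequence[Tuple], pred_segments: Sequence[Tuple]
) -> ConfusionCounts:
    """Exact-coordinate feature matching: a prediction segment is a TP only
    when its (start, end) equals a reference segment's; each reference
    segment is consumable once. TN is undefined at this resolution."""
    avail = Counter(ref_segments)
    c = ConfusionCounts()
    for seg in pred_segments:
        if avail[seg] > 0:
            avail[seg] -= 1
            c.tp += 1
        else:
            c.fp += 1
    c.fn = sum(avail.values())
    return c


def classify(ref: ModelVector, pred: ModelVector) -> str:
    """Similarity classification, a strict hierarchy of exact agreement:

    - perfect match: identical model vectors;
    - CDS structure match: not perfect, but CDS segment coordinates agree
      exactly;
    - exon structure match: CDS differs but exon coordinates agree
      (e.g. alternative start/stop codons within shared exons);
    - UTR structure match: CDS and exons differ but UTR segment
      coordinates agree;
    - non-match: everything else.
    """
    if ref.symbols == pred.symbols:
        return PERFECT_MATCH
    ref_cds, pred_cds = ref.clique.cds_coords(), pred.clique.cds_coords()
    if ref_cds and ref_cds == pred_cds:
        return CDS_MATCH
    ref_ex, pred_ex = ref.clique.exon_coords(), pred.clique.exon_coords()
    if ref_ex and ref_ex == pred_ex:
        return EXON_MATCH
    ref_utr, pred_utr = ref.clique.utr_coords(), pred.clique.utr_coords()
    if ref_utr and ref_utr == pred_utr:
        return UTR_MATCH
    return NON_MATCH


@dataclass
class ComparisonResult:
    """One reference-clique / prediction-clique comparison: raw counts,
    derived panels and the match classification."""

    ref_vector: ModelVector
    pred_vector: ModelVector
    nuc_counts: Dict[str, ConfusionCounts]
    feat_counts: Dict[str, ConfusionCounts]
    identity_matches: int
    length: int
    classification: str

    @property
    def identity(self) -> float:
        return self.identity_matches / self.length if self.length else 1.0

    def nuc_panel(self, cls: str) -> StatPanel:
        return compute_stats(self.nuc_counts[cls], "nucleotide")

    def feat_panel(self, ftype: str) -> StatPanel:
        return compute_stats(self.feat_counts[ftype], "feature")


def compare_vectors(ref: ModelVector, pred: ModelVector) -> ComparisonResult:
    nuc = {cls: count_nucleotides(ref, pred, cls) for cls in NUCLEOTIDE_CLASSES}
    feat = {
        "exon": match_features(ref.clique.exon_coords(), pred.clique.exon_coords()),
        "cds_segment": match_features(ref.clique.cds_coords(), pred.clique.cds_coords()),
        "utr_segment": match_features(
            [c[:2] for c in ref.clique.utr_coords()],
            [c[:2] for c in pred.clique.utr_coords()],
        ),
    }
    n = len(ref.symbols)
    matches = sum(a == b for a, b in zip(ref.symbols, pred.symbols))
    return ComparisonResult(
        ref, pred, nuc, feat, matches, n, classify(ref, pred)
    )


@dataclass
class LocusComparison:
    """All comparison output for one locus: accepted clique pairs,
    unmatched cliques, pooled locus-level panels and splice complexity."""

    locus: GeneLocus
    pairs: List[ComparisonResult]
    unmatched_ref: List[TranscriptClique]
    unmatched_pred: List[TranscriptClique]
    splice_complexity_ref: float
    splice_complexity_pred: float

    @property
    def counted_pairs(self) -> List[ComparisonResult]:
        """Pairs that feed running totals: only shared loci contribute;
        comparisons against the all-G placeholder are report-only."""
        return self.pairs if self.locus.shared else []

    def aggregate_counts(self) -> Tuple[Dict[str, ConfusionCounts], Dict[str, ConfusionCounts], int, int]:
        nuc = {cls: ConfusionCounts() for cls in NUCLEOTIDE_CLASSES}
        feat = {ft: ConfusionCounts() for ft in FEATURE_TYPES}
        matches = positions = 0
        for p in self.counted_pairs:
            for cls in NUCLEOTIDE_CLASSES:
                nuc[cls].add(p.nuc_counts[cls])
            for ft in FEATURE_TYPES:
                feat[ft].add(p.feat_counts[ft])
            matches += p.identity_matches
            positions += p.length
        return nuc, feat, matches, positions


def _rank_key(pair: ComparisonResult):
    """Ranking for greedy pairing: best overall identity first, ties broken
    by nucleotide CDS AED, then feature-level exon AED (undefined sorts
    last), then clique IDs for full determinism."""
    cds_aed = pair.nuc_panel("CDS").aed
    exon_aed = pair.feat_panel("exon").aed
    return (
        -pair.identity,
        cds_aed if cds_aed is not None else math.inf,
        exon_aed if exon_aed is not None else math.inf,
        pair.ref_vector.clique.id,
        pair.pred_vector.clique.id,
    )


def pair_cliques(
    ref_vectors: Sequence[ModelVector],
    pred_vectors: Sequence[ModelVector],
    locus: GeneLocus,
) -> LocusComparison:
    """Rank all |R| x |P| comparisons and greedily accept pairs so each
    clique is considered at most once; leftovers become unmatched (novel)
    cliques. When one source is absent the other side is compared against
    the all-G placeholder for reporting, and all of its cliques are also
    listed as unmatched."""
    ref_vectors = list(ref_vectors)
    pred_vectors = list(pred_vectors)
    unmatched_ref: List[TranscriptClique] = []
    unmatched_pred: List[TranscriptClique] = []
    pairs: List[ComparisonResult] = []

    if not ref_vectors and pred_vectors:
        ghost = placeholder_vector(locus.interval, REFERENCE)
        pairs = [compare_vectors(ghost, pv) for pv in pred_vectors]
        unmatched_pred = [pv.clique for pv in pred_vectors]
    elif ref_vectors and not pred_vectors:
        ghost = placeholder_vector(locus.interval, PREDICTION)
        pairs = [compare_vectors(rv, ghost) for rv in ref_vectors]
        unmatched_ref = [rv.clique for rv in ref_vectors]
    else:
        all_pairs = [
            compare_vectors(rv, pv) for rv in ref_vectors for pv in pred_vectors
        ]
        all_pairs.sort(key=_rank_key)
        used_ref: set = set()
        used_pred: set = set()
        for p in all_pairs:
            rid = p.ref_vector.clique.id
            pid = p.pred_vector.clique.id
            if rid in used_ref or pid in used_pred:
                continue
            used_ref.add(rid)
            used_pred.add(pid)
            pairs.append(p)
        unmatched_ref = [
            rv.clique for rv in ref_vectors if rv.clique.id not in used_ref
        ]
        unmatched_pred = [
            pv.clique for pv in pred_vectors if pv.clique.id not in used_pred
        ]

    return LocusComparison(
        locus,
        pairs,
        unmatched_ref,
        unmatched_pred,
        splice_complexity(locus.transcripts(REFERENCE), locus.interval),
        splice_complexity(locus.transcripts(PREDICTION), locus.interval),
    )


_STRUCT_CLASS = {"C": "C", "F": "U", "T": "U", "I": "I", "G": None}


def structural_aed(a: ModelVector, b: ModelVector) -> float:
    """AED between two single-transcript vectors, pooling agreement over
    the coding, untranslated (F/T) and intron classes; intergenic
    positions carry no structure. Degenerate zero-denominator cases
    (possible only for structureless vectors) return 1."""
    tp = fp = fn = 0
    for x, y in zip(a.symbols, b.symbols):
        cx, cy = _STRUCT_CLASS[x], _STRUCT_CLASS[y]
        if cx is not None and cx == cy:
            tp += 1
        else:
            if cy is not None:
                fp += 1
            if cx is not None:
                fn += 1
    if tp + fn == 0 or tp + fp == 0:
        return 1.0
    sn = tp / (tp + fn)
    sp = tp / (tp + fp)
    return 1.0 - (sn + sp) / 2.0


def splice_complexity(
    transcripts: Sequence[Transcript], locus: GenomicInterval
) -> float:
    """Mean pairwise structural AED over all unordered pairs of one
    source's transcripts at the locus; 0 when fewer than two."""
    n = len(transcripts)
    if n < 2:
        return 0.0
    vecs = [
        # each transcript alone, as its own single-member clique
        model_vectors_for([t], locus, REFERENCE)[0]
        for t in transcripts
    ]
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            total += structural_aed(vecs[i], vecs[j])
    return total / (n * (n - 1) / 2)


def compare_locus(locus: GeneLocus) -> LocusComparison:
    """Full comparison for one locus: build each source's model vectors and
    pair them."""
    ref_vecs = model_vectors_for(
        locus.transcripts(REFERENCE), locus.interval, REFERENCE
    )
    pred_vecs = model_vectors_for(
        locus.transcripts(PREDICTION), locus.interval, PREDICTION
    )
    return pair_cliques(ref_vecs, pred_vecs, locus)
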