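"""Locus filtering and plain-text report rendering.

The report grammar is deliberately stable: fixed field labels, fixed
ordering, statistics to four decimals, percentages to one decimal,
undefined values as ``--``. Identical inputs yield byte-identical text
(there are no timestamps), which is what makes the determinism contract
across worker counts testable.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Dict, List, Optional, TextIO

from .aggregate import RunningTotals, SummaryPanels
from .compare import (
    CLASSIFICATIONS,
    ComparisonResult,
    ConfusionCounts,
    LocusComparison,
    NUCLEOTIDE_CLASSES,
    StatPanel,
    compute_stats,
)
from .model import GeneLocus, PREDICTION, REFERENCE

CLASS_LABELS = {
    "perfect_match": "perfect match",
    "cds_structure_match": "CDS structure match",
    "exon_structure_match": "exon structure match",
    "utr_structure_match": "UTR structure match",
    "non_match": "non-match",
}
FEATURE_LABELS = {
    "exon": "exon",
    "cds_segment": "CDS segment",
    "utr_segment": "UTR segment",
}


class FilterConfigError(Exception):
    """Bad filter configuration file."""


@dataclass
class FilterConfig:
    """Optional min/max bounds for excluding loci from the analysis.

    Counts are totals over both sources; transcripts-per-gene uses the
    maximum over genes; CDS length uses the maximum transcript CDS length
    at the locus.
    """

    min_locus_length: Optional[int] = None
    max_locus_length: Optional[int] = None
    min_gene_count: Optional[int] = None
    max_gene_count: Optional[int] = None
    min_transcript_count: Optional[int] = None
    max_transcript_count: Optional[int] = None
    min_transcripts_per_gene: Optional[int] = None
    max_transcripts_per_gene: Optional[int] = None
    min_exon_count: Optional[int] = None
    max_exon_count: Optional[int] = None
    min_cds_length: Optional[int] = None
    max_cds_length: Optional[int] = None

    def __post_init__(self) -> None:
        for crit in (
            "locus_length", "gene_count", "transcript_count",
            "transcripts_per_gene", "exon_count", "cds_length",
        ):
            lo = getattr(self, f"min_{crit}")
            hi = getattr(self, f"max_{crit}")
            if lo is not None and hi is not None and lo > hi:
                raise FilterConfigError(
                    f"min exceeds max for {crit}: {lo} > {hi}"
                )


_KEYMAP = {
    "minlocuslength": "min_locus_length",
    "maxlocuslength": "max_locus_length",
    "mingenecount": "min_gene_count",
    "maxgenecount": "max_gene_count",
    "mintranscriptcount": "min_transcript_count",
    "maxtranscriptcount": "max_transcript_count",
    "mintranscriptspergene": "min_transcripts_per_gene",
    "maxtranscriptspergene": "max_transcripts_per_gene",
    "minexoncount": "min_exon_count",
    "maxexoncount": "max_exon_count",
    "mincdslength": "min_cds_length",
    "maxcdslength": "max_cds_length",
}


def parse_filter_config(text: str) -> FilterConfig:
    """Flat ``Key=value`` lines (e.g. ``MaxLocusLength=5000``); blank lines
    and ``#`` comments ignored; unknown keys are an error."""
    values: Dict[str, int] = {}
    for line_no, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise FilterConfigError(
                f"filter config line {line_no}: expected Key=value, got {line!r}"
            )
        key, _, val = line.partition("=")
        attr = _KEYMAP.get(key.strip().lower())
        if attr is None:
            raise FilterConfigError(
                f"filter config line {line_no}: unknown key {key.strip()!r}"
            )
        try:
            values[attr] = int(val.strip())
        except ValueError as exc:
            raise FilterConfigError(
                f"filter config line {line_no}: {val.strip()!r} is not an integer"
            ) from exc
    return FilterConfig(**values)


def passes_filters(locus: GeneLocus, cfg: FilterConfig) -> bool:
    """True iff every configured bound is satisfied (empty config passes
    everything)."""
    transcripts = [t for g in locus.genes for t in g.transcripts]
    measures = {
        "locus_length": locus.interval.length,
        "gene_count": len(locus.genes),
        "transcript_count": len(transcripts),
        "transcripts_per_gene": max(len(g.transcripts) for g in locus.genes),
        "exon_count": sum(t.exon_count for t in transcripts),
        "cds_length": max(t.cds_length for t in transcripts),
    }
    for crit, value in measures.items():
        lo = getattr(cfg, f"min_{crit}")
        hi = getattr(cfg, f"max_{crit}")
        if lo is not None and value < lo:
            return False
        if hi is not None and value > hi:
            return False
    return True


def fmt_stat(x: Optional[float]) -> str:
    return "--" if x is None else f"{x:.4f}"


def fmt_pct(x: Optional[float]) -> str:
    return "--" if x is None else f"{x:.1f}%"


def _panel_line(label: str, p: StatPanel, nucleotide: bool) -> str:
    parts = [
        f"Sn {fmt_stat(p.sensitivity)}",
        f"Sp {fmt_stat(p.specificity)}",
        f"F1 {fmt_stat(p.f1)}",
        f"AED {fmt_stat(p.aed)}",
    ]
    if nucleotide:
        parts += [f"SMC {fmt_stat(p.smc)}", f"CC {fmt_stat(p.cc)}"]
    return f"    {label:<12s} " + "  ".join(parts)


def _counts_line(label: str, c: ConfusionCounts, with_tn: bool) -> str:
    parts = [f"TP {c.tp}", f"FP {c.fp}", f"FN {c.fn}"]
    if with_tn:
        parts.append(f"TN {c.tn}")
    return f"    {label:<12s} " + "  ".join(parts)


def _render_pair(idx: int, pair: ComparisonResult, out: List[str]) -> None:
    rc, pc = pair.ref_vector.clique, pair.pred_vector.clique
    out.append(f"  comparison {idx}")
    out.append(f"    reference transcripts:  {rc.id}")
    out.append(f"    prediction transcripts: {pc.id}")
    out.append(f"    classification: {CLASS_LABELS[pair.classification]}")
    out.append("    nucleotide-level")
    for cls in NUCLEOTIDE_CLASSES:
        out.append(_counts_line(cls, pair.nuc_counts[cls], True))
        out.append(_panel_line(cls, pair.nuc_panel(cls), True))
    out.append(f"    overall identity: {fmt_stat(pair.identity)}")
    out.append("    feature-level")
    for ft, label in FEATURE_LABELS.items():
        out.append(_counts_line(label, pair.feat_counts[ft], False))
        out.append(_panel_line(label, pair.feat_panel(ft), False))


def render_locus_report(lc: LocusComparison) -> str:
    """One locus's full report as a text block."""
    locus = lc.locus
    iv = locus.interval
    out: List[str] = []
    out.append("=" * 70)
    out.append(f"locus {locus.tag} ({iv.length} bp)")
    out.append("=" * 70)
    for label, genes in (("reference", locus.ref_genes), ("prediction", locus.pred_genes)):
        out.append(f"  {label} genes: {len(genes)}")
        for g in genes:
            mrnas = ",".join(t.id for t in g.transcripts)
            out.append(
                f"    {g.id} ({g.interval}, {g.interval.strand}) mRNAs: {mrnas}"
            )
    for idx, pair in enumerate(lc.pairs, start=1):
        _render_pair(idx, pair, out)
    for label, cliques in (
        ("reference", lc.unmatched_ref),
        ("prediction", lc.unmatched_pred),
    ):
        if cliques:
            out.append(f"  unmatched {label} cliques: " + "; ".join(c.id for c in cliques))
    if len(lc.pairs) > 1:
        nuc, feat, matches, positions = lc.aggregate_counts()
        out.append("  locus aggregate")
        out.append("    nucleotide-level")
        for cls in NUCLEOTIDE_CLASSES:
            out.append(_panel_line(cls, compute_stats(nuc[cls], "nucleotide"), True))
        ident = matches / positions if positions else None
        out.append(f"    overall identity: {fmt_stat(ident)}")
        out.append("    feature-level")
        for ft, label in FEATURE_LABELS.items():
            out.append(_panel_line(label, compute_stats(feat[ft], "feature"), False))
    out.append(
        f"  splice complexity: reference {lc.splice_complexity_ref:.4f}, "
        f"prediction {lc.splice_complexity_pred:.4f}"
    )
    out.append("")
    return "\n".join(out)


def render_summary(t: RunningTotals, panels: SummaryPanels) -> str:
    """The aggregate summary report."""
    out: List[str] = []
    out.append("=" * 70)
    out.append("annotation comparison summary")
    out.append("=" * 70)
    out.append(f"  gene loci ................ {t.total_loci}")
    out.append(f"    shared ................. {t.shared_loci}")
    out.append(f"    unique to reference .... {t.ref_only_loci}")
    out.append(f"    unique to prediction ... {t.pred_only_loci}")
    out.append("")
    out.append(f"  total comparisons ........ {t.comparison_count}")
    for cls in CLASSIFICATIONS:
        n = t.classification_tallies[cls]
        pct = panels.classification_percent[cls]
        label = CLASS_LABELS[cls] + "es" if cls != "non_match" else "non-matches"
        out.append(f"    {label:<24s} {n} ({fmt_pct(pct)})")
    out.append("")
    out.append(
        f"  novel reference cliques .. {t.unmatched_ref_cliques}"
    )
    out.append(
        f"  novel prediction cliques . {t.unmatched_pred_cliques}"
    )
    out.append("")
    out.append("  gene-level")
    out.append(f"    sensitivity {fmt_stat(panels.gene_sensitivity)}")
    out.append(f"    specificity {fmt_stat(panels.gene_specificity)}")
    out.append("")
    out.append("  nucleotide-level (pooled)")
    for cls in NUCLEOTIDE_CLASSES:
        out.append(_panel_line(cls, panels.nucleotide[cls], True))
    out.append(f"    overall identity: {fmt_stat(panels.identity)}")
    out.append("")
    out.append("  feature-level (pooled)")
    for ft, label in FEATURE_LABELS.items():
        out.append(_panel_line(label, panels.feature[ft], False))
    out.append("")
    out.append(f"  filtered loci ............ {t.filtered_loci}")
    out.append("")
    return "\n".join(out)
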