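"""Running totals across loci and the aggregate summary panels.

Aggregate statistics are recomputed from pooled confusion counts, never
averaged over per-locus panels, so large loci weigh in proportion to
their size. Unmatched (novel) cliques and single-source loci contribute
tallies only, never statistic counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

from .compare import (
    CLASSIFICATIONS,
    ConfusionCounts,
    FEATURE_TYPES,
    LocusComparison,
    NUCLEOTIDE_CLASSES,
    PERFECT_MATCH,
    StatPanel,
    compute_stats,
)
from .model import GeneLocus


@dataclass
class RunningTotals:
    """Element-wise accumulator over all compared loci."""

    nuc_counts: Dict[str, ConfusionCounts] = field(
        default_factory=lambda: {c: ConfusionCounts() for c in NUCLEOTIDE_CLASSES}
    )
    feat_counts: Dict[str, ConfusionCounts] = field(
        default_factory=lambda: {t: ConfusionCounts() for t in FEATURE_TYPES}
    )
    identity_matches: int = 0
    identity_positions: int = 0
    classification_tallies: Dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in CLASSIFICATIONS}
    )
    total_loci: int = 0
    shared_loci: int = 0
    ref_only_loci: int = 0
    pred_only_loci: int = 0
    filtered_loci: int = 0
    comparison_count: int = 0
    # cliques considered at shared loci (paired + unmatched), per source:
    # the denominators of the gene-level sensitivity/specificity
    ref_cliques: int = 0
    pred_cliques: int = 0
    unmatched_ref_cliques: int = 0
    unmatched_pred_cliques: int = 0


def count_filtered(t: RunningTotals, locus: GeneLocus) -> None:
    """Record a locus excluded by the filter configuration; it contributes
    nothing else."""
    t.filtered_loci += 1


def accumulate(t: RunningTotals, lc: LocusComparison) -> RunningTotals:
    """Add one locus comparison to the running totals (in place; also
    returned). Filtered loci must not be passed here. Only shared loci
    contribute comparisons; placeholder (all-G) comparisons at
    single-source loci are report-only."""
    t.total_loci += 1
    locus = lc.locus
    if locus.shared:
        t.shared_loci += 1
    elif locus.ref_genes:
        t.ref_only_loci += 1
    else:
        t.pred_only_loci += 1

    for pair in lc.counted_pairs:
        t.comparison_count += 1
        t.classification_tallies[pair.classification] += 1
        for cls in NUCLEOTIDE_CLASSES:
            t.nuc_counts[cls].add(pair.nuc_counts[cls])
        for ft in FEATURE_TYPES:
            t.feat_counts[ft].add(pair.feat_counts[ft])
        t.identity_matches += pair.identity_matches
        t.identity_positions += pair.length

    if locus.shared:
        t.ref_cliques += len(lc.pairs) + len(lc.unmatched_ref)
        t.pred_cliques += len(lc.pairs) + len(lc.unmatched_pred)
        t.unmatched_ref_cliques += len(lc.unmatched_ref)
        t.unmatched_pred_cliques += len(lc.unmatched_pred)
    return t


@dataclass(frozen=True)
class SummaryPanels:
    """Aggregate statistics recomputed from pooled counts."""

    nucleotide: Dict[str, StatPanel]
    feature: Dict[str, StatPanel]
    identity: Optional[float]
    classification_percent: Dict[str, Optional[float]]
    gene_sensitivity: Optional[float]
    gene_specificity: Optional[float]


def summarize(t: RunningTotals) -> SummaryPanels:
    """Recompute every panel from the pooled counts.

    Gene-level sensitivity is the fraction of reference cliques whose best
    pairing was a perfect match (perfect matches / reference cliques
    considered at shared loci); specificity is the prediction-side
    analogue. With zero comparisons everything is undefined.
    """
    nuc = {
        cls: compute_stats(t.nuc_counts[cls], "nucleotide")
        for cls in NUCLEOTIDE_CLASSES
    }
    feat = {
        ft: compute_stats(t.feat_counts[ft], "feature") for ft in FEATURE_TYPES
    }
    identity = (
        t.identity_matches / t.identity_positions if t.identity_positions else None
    )
    pct = {
        c: (100.0 * n / t.comparison_count if t.comparison_count else None)
        for c, n in t.classification_tallies.items()
    }
    perfect = t.classification_tallies[PERFECT_MATCH]
    gene_sn = perfect / t.ref_cliques if t.ref_cliques else None
    gene_sp = perfect / t.pred_cliques if t.pred_cliques else None
    return SummaryPanels(nuc, feat, identity, pct, gene_sn, gene_sp)
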