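"""Gene locus identification via the joint gene-overlap interval graph.

Every gene from either source is a node; two nodes are joined when their
gene spans share at least one position on the same sequence, regardless of
strand and regardless of which source each comes from. Each connected
component defines one gene locus: the smallest region containing all of
its genes.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Set, Tuple

import networkx as nx

from .model import (
    AnnotationSet,
    GeneAnnotation,
    GeneLocus,
    GenomicInterval,
    PREDICTION,
    REFERENCE,
)

#: graph nodes are (source_tag, gene_id) pairs so that identical gene IDs
#: in the two inputs never collide
NodeId = Tuple[str, str]


def build_interval_graph(
    ref: AnnotationSet, pred: AnnotationSet, seqid: str
) -> nx.Graph:
    """Overlap graph over all genes of both sources on one sequence.

    Overlap is by gene span (outermost transcript extent) and ignores
    strand; adjacency (end == other.start - 1) is not overlap.
    """
    g = nx.Graph()
    genes: List[Tuple[NodeId, GeneAnnotation]] = []
    for aset in (ref, pred):
        for gene in aset.genes_on(seqid):
            node = (aset.source_tag, gene.id)
            g.add_node(node, gene=gene)
            genes.append((node, gene))
    # sweep over genes sorted by start; active set holds genes whose span
    # has not yet ended
    genes.sort(key=lambda ng: (ng[1].interval.start, ng[1].interval.end, ng[0]))
    active: List[Tuple[NodeId, GeneAnnotation]] = []
    for node, gene in genes:
        active = [(n, o) for n, o in active if o.interval.end >= gene.interval.start]
        for n, _ in active:
            g.add_edge(n, node)
        active.append((node, gene))
    return g


def connected_components(g: nx.Graph) -> List[Set[NodeId]]:
    """Connected components, ordered by the smallest member gene start
    (ties broken by node id) for deterministic downstream output."""

    def sort_key(comp: Set[NodeId]):
        starts = sorted(
            (g.nodes[n]["gene"].interval.start, n) for n in comp
        )
        return starts[0]

    return sorted((set(c) for c in nx.connected_components(g)), key=sort_key)


def define_loci(
    components: Sequence[Set[NodeId]], genes: Dict[NodeId, GeneAnnotation]
) -> List[GeneLocus]:
    """One locus per component: the min/max span over all member genes,
    members partitioned into reference and prediction lists."""
    loci: List[GeneLocus] = []
    for comp in components:
        members = [genes[n] for n in comp]
        seqid = members[0].interval.seqid
        lo = min(m.interval.start for m in members)
        hi = max(m.interval.end for m in members)
        key = lambda m: (m.interval.start, m.interval.end, m.id)
        loci.append(
            GeneLocus(
                GenomicInterval(seqid, lo, hi),
                tuple(sorted((m for m in members if m.source_tag == REFERENCE), key=key)),
                tuple(sorted((m for m in members if m.source_tag == PREDICTION), key=key)),
            )
        )
    loci.sort(key=lambda l: (l.interval.seqid, l.interval.start, l.interval.end))
    return loci


def build_loci(ref: AnnotationSet, pred: AnnotationSet) -> List[GeneLocus]:
    """Full locus partition over the union of sequences in both sets."""
    loci: List[GeneLocus] = []
    for seqid in sorted(set(ref.seqids()) | set(pred.seqids())):
        g = build_interval_graph(ref, pred, seqid)
        comps = connected_components(g)
        gene_lookup = {n: g.nodes[n]["gene"] for n in g.nodes}
        loci.extend(define_loci(comps, gene_lookup))
    loci.sort(key=lambda l: (l.interval.seqid, l.interval.start, l.interval.end))
    return loci
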