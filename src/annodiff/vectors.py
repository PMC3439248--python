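"""Model vectors: collapsing transcripts into {C,F,G,I,T} strings.

Transcripts from one source at a locus are nodes of a graph whose edges
join *non-overlapping* transcripts (the complement of their interval
graph). Every maximal clique of that graph is a set of mutually disjoint
transcripts that can be drawn on one line — encoded as a single model
vector over the locus:

    C  coding sequence        F  5' UTR          T  3' UTR
    I  intron                 G  intergenic (no transcript)

Positions inside a member transcript's span that belong to no exon are
introns; positions covered by no member at all are intergenic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Sequence, Set, Tuple

import networkx as nx

from .model import GenomicInterval, Transcript

ALPHABET = "CFGIT"


@dataclass(frozen=True)
class TranscriptClique:
    """A maximal set of mutually non-overlapping transcripts from one
    source at one locus. May be empty: the placeholder for a source with
    no annotation at the locus (encoded as an all-G vector)."""

    members: Tuple[Transcript, ...]
    source_tag: str

    def __post_init__(self) -> None:
        ivs = sorted((m.interval for m in self.members), key=lambda i: i.start)
        for a, b in zip(ivs, ivs[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"clique members overlap: {a} vs {b} ({self.source_tag})"
                )

    @property
    def id(self) -> str:
        if not self.members:
            return "(none)"
        return "+".join(sorted(m.id for m in self.members))

    def exon_coords(self) -> List[Tuple[int, int]]:
        return sorted(c for m in self.members for c in m.exon_coords())

    def cds_coords(self) -> List[Tuple[int, int]]:
        return sorted(c for m in self.members for c in m.cds_coords())

    def utr_coords(self) -> List[Tuple[int, int, str]]:
        return sorted(c for m in self.members for c in m.utr_coords())


@dataclass(frozen=True)
class ModelVector:
    """Per-position structure encoding of one transcript clique across a
    locus; ``symbols`` has exactly the locus length."""

    locus: GenomicInterval
    symbols: str
    clique: TranscriptClique

    def __post_init__(self) -> None:
        if len(self.symbols) != self.locus.length:
            raise ValueError(
                f"vector length {len(self.symbols)} != locus length "
                f"{self.locus.length}"
            )


def build_nonoverlap_graph(transcripts: Sequence[Transcript]) -> nx.Graph:
    """Edge iff two transcripts' spans are disjoint (the complement of the
    transcript interval graph). Disjointness is at transcript level: two
    transcripts of overlapping genes may still share an edge."""
    g = nx.Graph()
    for t in transcripts:
        g.add_node(t.id, transcript=t)
    ts = list(transcripts)
    for i, a in enumerate(ts):
        for b in ts[i + 1:]:
            if not a.interval.overlaps(b.interval):
                g.add_edge(a.id, b.id)
    return g


def enumerate_maximal_cliques(g: nx.Graph) -> List[List[str]]:
    """All maximal cliques via Bron-Kerbosch with pivoting.

    Returns each clique once as a sorted node list; cliques are ordered
    lexicographically for determinism. Locus transcript counts are small,
    so the worst-case exponential behaviour is acceptable.
    """
    adj: Dict[str, Set[str]] = {v: set(g[v]) for v in g.nodes}
    cliques: List[List[str]] = []

    def expand(r: Set[str], p: Set[str], x: Set[str]) -> None:
        if not p and not x:
            cliques.append(sorted(r))
            return
        pivot = max(sorted(p | x), key=lambda u: len(adj[u] & p))
        for v in sorted(p - adj[pivot]):
            expand(r | {v}, p & adj[v], x & adj[v])
            p = p - {v}
            x = x | {v}

    if adj:
        expand(set(), set(adj), set())
    return sorted(cliques)


def encode_model_vector(
    clique: TranscriptClique, locus: GenomicInterval
) -> ModelVector:
    """Paint the clique onto the locus: G outside all members; inside a
    member, I by default, then F/C/T on UTR/CDS exonic positions."""
    offset = locus.start
    chars = ["G"] * locus.length
    for m in clique.members:
        if m.interval.start < locus.start or m.interval.end > locus.end:
            raise AssertionError(
                f"transcript {m.id} ({m.interval}) extends beyond locus {locus}"
            )
        for pos in range(m.interval.start, m.interval.end + 1):
            chars[pos - offset] = "I"
        for seg, sym in (
            (m.utr5_segments, "F"),
            (m.utr3_segments, "T"),
            (m.cds_segments, "C"),
        ):
            for iv in seg:
                for pos in range(iv.start, iv.end + 1):
                    chars[pos - offset] = sym
    return ModelVector(locus, "".join(chars), clique)


def model_vectors_for(
    transcripts: Sequence[Transcript], locus: GenomicInterval, source_tag: str
) -> List[ModelVector]:
    """All model vectors for one source at a locus, one per maximal clique
    of the non-overlap graph; deterministic (lexicographic clique) order.
    An empty transcript list yields no vectors — callers that need the
    all-G placeholder use :func:`placeholder_vector`."""
    if not transcripts:
        return []
    by_id = {t.id: t for t in transcripts}
    g = build_nonoverlap_graph(transcripts)
    return [
        encode_model_vector(
            TranscriptClique(tuple(by_id[i] for i in ids), source_tag), locus
        )
        for ids in enumerate_maximal_cliques(g)
    ]


def placeholder_vector(locus: GenomicInterval, source_tag: str) -> ModelVector:
    """The all-G vector standing in for a source with no annotation at the
    locus."""
    return encode_model_vector(TranscriptClique((), source_tag), locus)
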