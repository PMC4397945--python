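"""Transcript candidate enumeration and finalization.

All source-to-sink paths of a splice graph are enumerated depth-first;
whenever the path count exceeds the cap, the edge-coverage threshold is
raised by one, under-covered edges are pruned and the search restarts.
Each locus also receives a pre-mRNA candidate spanning its whole interval,
multi-exon candidates must have fragment support across every junction, and
candidates of genomically overlapping graphs are combined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property

from bayestx.alignment_io import Fragment
from bayestx.splice_graph import SpliceGraph

log = logging.getLogger(__name__)

DEFAULT_MAX_CANDIDATES = 100

Chain = tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class TranscriptCandidate:
    """A candidate transcript: an ordered chain of merged exons."""

    chrom: str
    strand: str
    exons: Chain  # sorted, non-overlapping, non-abutting; 0-based half-open
    is_premrna: bool = False

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError("candidate must have at least one exon")
        for s, e in self.exons:
            if e <= s:
                raise ValueError("empty exon in candidate")
        for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]):
            if s1 <= e0:
                raise ValueError("candidate exons must be sorted with intron gaps")

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @cached_property
    def intron_chain(self) -> Chain:
        return tuple((e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]))

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass
class CandidateSet:
    """The inference unit: m candidates plus the fragments of their locus."""

    locus_id: str
    chrom: str
    strand: str
    candidates: list[TranscriptCandidate]
    fragments: list[Fragment] = field(default_factory=list)

    @property
    def m(self) -> int:
        return len(self.candidates)


def _paths_at_threshold(
    graph: SpliceGraph, threshold: int, limit: int | None = None
) -> tuple[list[tuple[int, ...]], bool]:
    """Source-to-sink vertex paths using edges with coverage >= threshold.

    Returns ``(paths, aborted)``; ``aborted`` is True when the search was cut
    short because the path count exceeded ``limit``.
    """
    active = [(i, j) for (i, j), cov in graph.edges.items() if cov >= threshold]
    n_vertices = len(graph.exons)
    if not active:
        return [(i,) for i in range(n_vertices)], False

    reverse = graph.strand == "reverse"
    adjacency: dict[int, list[int]] = {}
    indegree = [0] * n_vertices
    for i, j in sorted(active):
        adjacency.setdefault(i, []).append(j)
        indegree[j] += 1
    for children in adjacency.values():
        children.sort(reverse=reverse)

    sources = [v for v in range(n_vertices) if indegree[v] == 0]
    if reverse:
        sources.reverse()

    paths: list[tuple[int, ...]] = []
    aborted = False

    def dfs(vertex: int, path: list[int]) -> None:
        nonlocal aborted
        children = adjacency.get(vertex)
        if not children:
            paths.append(tuple(path))
            if limit is not None and len(paths) > limit:
                aborted = True
            return
        for child in children:
            path.append(child)
            dfs(child, path)
            path.pop()
            if aborted:
                return

    for source in sources:
        dfs(source, [source])
        if aborted:
            break
    return paths, aborted


def _path_to_candidate(graph: SpliceGraph, path: tuple[int, ...]) -> TranscriptCandidate:
    exons: list[list[int]] = []
    for idx in path:
        seg = graph.exons[idx]
        if exons and seg.start == exons[-1][1]:  # read-through: merge abutting segments
            exons[-1][1] = seg.end
        else:
            exons.append([seg.start, seg.end])
    return TranscriptCandidate(
        chrom=graph.chrom, strand=graph.strand, exons=tuple((s, e) for s, e in exons)
    )


def enumerate_paths(
    graph: SpliceGraph, max_candidates: int = DEFAULT_MAX_CANDIDATES
) -> list[TranscriptCandidate]:
    """Enumerate candidate transcripts with iterative coverage pruning.

    The search terminates when a complete enumeration yields at most
    ``max_candidates`` paths, or when all edges have been pruned away (the
    remaining isolated segments each yield a single-exon candidate).
    """
    threshold = 1
    while True:
        paths, aborted = _paths_at_threshold(graph, threshold, limit=max_candidates)
        if not aborted:
            break
        threshold += 1
    if threshold > 1:
        log.debug("pruned %s:%d graph to edge-coverage threshold %d",
                  graph.chrom, graph.start, threshold)
    return [_path_to_candidate(graph, p) for p in paths]


def _premrna_candidate(graph: SpliceGraph) -> TranscriptCandidate:
    return TranscriptCandidate(
        chrom=graph.chrom,
        strand=graph.strand,
        exons=((graph.start, graph.end),),
        is_premrna=True,
    )


def _junctions_supported(candidate: TranscriptCandidate, supported: frozenset) -> bool:
    return all(intron in supported for intron in candidate.intron_chain)


def cluster_graphs(graphs: list[SpliceGraph]) -> list[list[SpliceGraph]]:
    """Group same-strand graphs whose genomic intervals overlap by >= 1 bp."""
    clusters: list[list[SpliceGraph]] = []
    keyed = sorted(graphs, key=lambda g: (g.chrom, g.strand, g.start, g.end))
    for graph in keyed:
        last = clusters[-1] if clusters else None
        if (
            last
            and last[-1].chrom == graph.chrom
            and last[-1].strand == graph.strand
            and graph.start < max(g.end for g in last)
        ):
            last.append(graph)
        else:
            clusters.append([graph])
    return clusters


def finalize_candidates(
    graphs: list[SpliceGraph], max_candidates: int = DEFAULT_MAX_CANDIDATES
) -> CandidateSet | None:
    """Build the final candidate set of one cluster of overlapping graphs.

    Per graph: enumerated paths plus the pre-mRNA candidate, then removal of
    multi-exon candidates lacking fragment support on any junction. Survivors
    of all graphs are unioned with their fragments pooled. Returns ``None``
    when nothing survives.
    """
    if not graphs:
        return None
    chrom, strand = graphs[0].chrom, graphs[0].strand
    assert all(g.chrom == chrom and g.strand == strand for g in graphs)

    chosen: dict[Chain, TranscriptCandidate] = {}
    fragments: list[Fragment] = []
    for graph in graphs:
        supported = frozenset(
            intron for frag in graph.fragments for intron in frag.introns()
        )
        survivors = [
            c
            for c in enumerate_paths(graph, max_candidates=max_candidates)
            if _junctions_supported(c, supported)
        ]
        survivors.append(_premrna_candidate(graph))
        for cand in survivors:
            prev = chosen.get(cand.exons)
            if prev is None or (prev.is_premrna and not cand.is_premrna):
                chosen[cand.exons] = cand
        fragments.extend(graph.fragments)

    if not chosen:
        log.info("cluster at %s:%d yielded no candidates; skipped", chrom, graphs[0].start)
        return None
    candidates = sorted(chosen.values(), key=lambda c: (c.start, c.end, c.exons))
    locus_id = f"{chrom}_{min(g.start for g in graphs)}_{strand[0]}"
    return CandidateSet(
        locus_id=locus_id, chrom=chrom, strand=strand,
        candidates=candidates, fragments=fragments,
    )
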