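"""Per-locus splice graph construction.

Fragments are clustered into loci (maximal groups whose read coverage is
not interrupted by an uncovered base), strand-resolved, and turned into one
DAG per locus: vertices are minimal exonic segments (coverage intervals
split at every junction donor/acceptor), edges are observed junctions plus
read-through adjacencies, each weighted by supporting-fragment count.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from collections import Counter
from dataclasses import dataclass, field

from bayestx.alignment_io import Fragment, FragmentSet, infer_fragment_strand

log = logging.getLogger(__name__)

MIN_FRAGMENTS_PER_LOCUS = 2  # '-c 2'
MIN_LOCUS_GAP = 1  # '-g 1'


@dataclass(frozen=True, order=True)
class Exon:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty exon [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SpliceGraph:
    """Strand-resolved DAG of exonic segments for one locus."""

    chrom: str
    strand: str  # 'forward' | 'reverse'
    exons: list[Exon]  # sorted by coordinate; vertex i == exons[i]
    edges: dict[tuple[int, int], int]  # (i, j) -> supporting fragment count
    fragments: list[Fragment] = field(default_factory=list)

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    def out_edges(self, i: int) -> list[int]:
        return [j for (a, j) in self.edges if a == i]

    def validate(self) -> None:
        for (i, j), cov in self.edges.items():
            assert 0 <= i < j < len(self.exons), "edges must go strictly left to right"
            assert cov >= 1, "edge coverage must be >= 1"
        assert len(self.fragments) >= MIN_FRAGMENTS_PER_LOCUS


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of intervals; abutting intervals merge (no uncovered base between)."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _cluster_fragments(fragments: list[Fragment]) -> list[list[Fragment]]:
    """Group fragments into loci: coverage components, fragments as links.

    Two covered intervals separated by >= 1 uncovered base are distinct
    components, but a fragment whose mates fall in two components joins them
    (the pair is physical evidence of one transcript).
    """
    if not fragments:
        return []
    covered = _merge_intervals([b for f in fragments for b in f.blocks()])
    starts = [s for s, _ in covered]

    parent = list(range(len(covered)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    frag_component: list[int] = []
    for frag in fragments:
        idxs = {bisect_right(starts, s) - 1 for s, _ in frag.blocks()}
        first = min(idxs)
        for i in idxs:
            union(first, i)
        frag_component.append(first)

    clusters: dict[int, list[Fragment]] = {}
    for frag, comp in zip(fragments, frag_component):
        clusters.setdefault(find(comp), []).append(frag)
    return [clusters[k] for k in sorted(clusters)]


def _build_graph(fragments: list[Fragment], chrom: str, strand: str) -> SpliceGraph | None:
    covered = _merge_intervals([b for f in fragments for b in f.blocks()])

    intron_support: Counter[tuple[int, int]] = Counter()
    for frag in fragments:
        intron_support.update(frag.introns())

    # split covered intervals at every internal donor/acceptor position
    cut_points: set[int] = set()
    for donor, acceptor in intron_support:
        cut_points.add(donor)
        cut_points.add(acceptor)
    exons: list[Exon] = []
    for s, e in covered:
        cuts = sorted(p for p in cut_points if s < p < e)
        prev = s
        for p in cuts:
            exons.append(Exon(chrom, prev, p))
            prev = p
        exons.append(Exon(chrom, prev, e))

    end_index = {ex.end: i for i, ex in enumerate(exons)}
    start_index = {ex.start: i for i, ex in enumerate(exons)}

    edges: dict[tuple[int, int], int] = {}
    for (donor, acceptor), count in sorted(intron_support.items()):
        i, j = end_index.get(donor), start_index.get(acceptor)
        if i is None or j is None or i >= j:
            log.warning("skipping inconsistent junction (%d, %d) on %s", donor, acceptor, chrom)
            continue
        edges[(i, j)] = count

    # read-through edges between abutting segments within one covered interval
    for i, (a, b) in enumerate(zip(exons, exons[1:])):
        if a.end != b.start:
            continue
        boundary = a.end
        cov = sum(
            1
            for frag in fragments
            if any(s < boundary < e for s, e in frag.blocks())
        )
        if cov >= 1:
            edges[(i, i + 1)] = edges.get((i, i + 1), 0) + cov

    graph = SpliceGraph(chrom=chrom, strand=strand, exons=exons, edges=edges, fragments=fragments)
    graph.validate()
    return graph


def build_splice_graphs(fragment_set: FragmentSet, library_type: str = "unstranded") -> list[SpliceGraph]:
    """Build one strand-resolved splice graph per locus.

    Loci with fewer than two fragments are dropped; loci whose strand cannot
    be resolved (unstranded mode, no spliced evidence) are discarded.
    Undetermined fragments inherit the locus strand when it is unambiguous.
    """
    by_chrom: dict[str, list[Fragment]] = {}
    for frag in fragment_set.fragments:
        by_chrom.setdefault(frag.chrom, []).append(frag)

    graphs: list[SpliceGraph] = []
    n_unresolved_loci = 0
    n_dropped_small = 0
    n_dropped_frags = 0

    for chrom in sorted(by_chrom):
        frags = sorted(by_chrom[chrom], key=lambda f: (f.start, f.end, f.fragment_id))
        for superlocus in _cluster_fragments(frags):
            strand_of = {id(f): infer_fragment_strand(f, library_type) for f in superlocus}
            strands = sorted({s for s in strand_of.values() if s != "undetermined"})
            if not strands:
                n_unresolved_loci += 1
                n_dropped_frags += len(superlocus)
                continue
            by_strand: dict[str, list[Fragment]] = {s: [] for s in strands}
            for frag in superlocus:
                s = strand_of[id(frag)]
                if s == "undetermined":
                    if len(strands) == 1:
                        s = strands[0]  # inherit the resolvable locus strand
                    else:
                        n_dropped_frags += 1
                        continue
                by_strand[s].append(frag)
            for strand in strands:
                for cluster in _cluster_fragments(by_strand[strand]):
                    if len(cluster) < MIN_FRAGMENTS_PER_LOCUS:
                        n_dropped_small += 1
                        n_dropped_frags += len(cluster)
                        continue
                    graph = _build_graph(cluster, chrom, strand)
                    if graph is not None:
                        graphs.append(graph)

    if n_unresolved_loci or n_dropped_small or n_dropped_frags:
        log.info(
            "build_splice_graphs: %d graphs; %d strand-unresolvable loci, "
            "%d sub-minimum clusters, %d fragments dropped",
            len(graphs), n_unresolved_loci, n_dropped_small, n_dropped_frags,
        )
    return graphs
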