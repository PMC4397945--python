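"""Loading and filtering of paired-end spliced alignments.

A *fragment* is one paired-end read: both mates' aligned blocks plus the
strand evidence needed to place it on a transcribed strand. Only proper
pairs are kept; multimapping pairs and PCR-duplicate fragments are removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pysam

log = logging.getLogger(__name__)

LIBRARY_TYPES = ("unstranded", "fr-firststrand", "fr-secondstrand")

#: genomic intervals, 0-based half-open, sorted, gaps between blocks = introns
Blocks = tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class Fragment:
    """One paired-end sequencing fragment (a read pair)."""

    fragment_id: str
    chrom: str
    blocks_mate1: Blocks
    blocks_mate2: Blocks
    strand_evidence: str = "none"  # 'forward' | 'reverse' | 'none'
    mate1_is_reverse: bool = False
    quality: str | None = None

    def __post_init__(self) -> None:
        for blocks in (self.blocks_mate1, self.blocks_mate2):
            if not blocks:
                raise ValueError("mate must have at least one aligned block")
            for s, e in blocks:
                if e <= s:
                    raise ValueError(f"empty block ({s}, {e})")
            for (s0, e0), (s1, e1) in zip(blocks, blocks[1:]):
                if s1 <= e0:
                    raise ValueError("mate blocks must be sorted with intron gaps")

    @property
    def start(self) -> int:
        return min(self.blocks_mate1[0][0], self.blocks_mate2[0][0])

    @property
    def end(self) -> int:
        return max(self.blocks_mate1[-1][1], self.blocks_mate2[-1][1])

    @property
    def observed_span(self) -> int:
        return self.end - self.start

    def introns(self) -> frozenset[tuple[int, int]]:
        """All introns implied by either mate's block structure."""
        out: set[tuple[int, int]] = set()
        for blocks in (self.blocks_mate1, self.blocks_mate2):
            for (_, e0), (s1, _) in zip(blocks, blocks[1:]):
                out.add((e0, s1))
        return frozenset(out)

    def blocks(self) -> Iterable[tuple[int, int]]:
        yield from self.blocks_mate1
        yield from self.blocks_mate2

    def dedup_key(self) -> tuple:
        return (self.chrom, self.blocks_mate1, self.blocks_mate2, self.strand_evidence)


@dataclass
class FragmentSet:
    """Retained fragments plus bookkeeping counters for dropped records."""

    fragments: list[Fragment]
    dropped: dict[str, int] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.fragments)


def _reference_blocks(cigartuples, reference_start: int) -> Blocks:
    """Aligned reference blocks; only N (intron) splits a block."""
    blocks: list[tuple[int, int]] = []
    pos = reference_start
    block_start = pos
    for op, length in cigartuples:
        if op in (0, 2, 7, 8):  # M, D, =, X consume reference within a block
            pos += length
        elif op == 3:  # N: intron
            if pos > block_start:
                blocks.append((block_start, pos))
            pos += length
            block_start = pos
        # I, S, H, P consume no reference
    if pos > block_start:
        blocks.append((block_start, pos))
    return tuple(blocks)


def _strand_from_orientation(library_type: str, mate1_is_reverse: bool) -> str:
    # fr-firststrand (dUTP): mate1 aligns antisense to the transcript.
    if library_type == "fr-firststrand":
        return "forward" if mate1_is_reverse else "reverse"
    return "reverse" if mate1_is_reverse else "forward"


def _strand_from_tags(xs_values: set[str]) -> str:
    if xs_values == {"+"}:
        return "forward"
    if xs_values == {"-"}:
        return "reverse"
    return "none"  # untagged, or contradictory tags between the mates


def load_fragments(alignment_source: str | Path, library_type: str = "unstranded") -> FragmentSet:
    """Load proper read pairs from a SAM/BAM file, applying all read filters.

    Multimapping pairs (reported hit count > 1, or multiple primary records
    for one mate) are removed, then coordinate-identical duplicate fragments
    are collapsed to a single representative.
    """
    if library_type not in LIBRARY_TYPES:
        raise ValueError(f"library_type must be one of {LIBRARY_TYPES}")

    pending: dict[str, dict[int, tuple]] = {}
    multimapped: set[str] = set()
    dropped = {"unmapped_or_secondary": 0, "unpaired": 0, "multimapping": 0,
               "orphan": 0, "improper_pair": 0, "duplicate": 0}

    try:
        handle = pysam.AlignmentFile(str(alignment_source), check_sq=False)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read alignment file {alignment_source}: {exc}") from exc

    with handle:
        for rec in handle.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                dropped["unmapped_or_secondary"] += 1
                continue
            if not rec.is_paired:
                dropped["unpaired"] += 1
                continue
            name = rec.query_name
            if rec.has_tag("NH") and rec.get_tag("NH") > 1:
                multimapped.add(name)
            mate = 1 if rec.is_read1 else 2
            info = (
                rec.reference_name,
                _reference_blocks(rec.cigartuples, rec.reference_start),
                rec.is_reverse,
                rec.get_tag("XS") if rec.has_tag("XS") else None,
                rec.is_proper_pair,
                rec.qual,
            )
            slot = pending.setdefault(name, {})
            if mate in slot:
                # two primary records for the same mate: treat as multimapping
                multimapped.add(name)
            slot[mate] = info

    fragments: list[Fragment] = []
    seen: set[tuple] = set()
    for name, mates in pending.items():
        if name in multimapped:
            dropped["multimapping"] += 1
            continue
        if len(mates) != 2:
            dropped["orphan"] += 1
            continue
        m1, m2 = mates[1], mates[2]
        if not (m1[4] and m2[4]) or m1[0] != m2[0] or not m1[1] or not m2[1]:
            dropped["improper_pair"] += 1
            continue
        if library_type == "unstranded":
            evidence = _strand_from_tags({v for v in (m1[3], m2[3]) if v is not None})
        else:
            evidence = _strand_from_orientation(library_type, m1[2])
        frag = Fragment(
            fragment_id=name,
            chrom=m1[0],
            blocks_mate1=m1[1],
            blocks_mate2=m2[1],
            strand_evidence=evidence,
            mate1_is_reverse=m1[2],
            quality=m1[5],
        )
        key = frag.dedup_key()
        if key in seen:
            dropped["duplicate"] += 1
            continue
        seen.add(key)
        fragments.append(frag)

    n_dropped = sum(dropped.values())
    if n_dropped:
        log.info("load_fragments: kept %d fragments, dropped %s", len(fragments), dropped)
    return FragmentSet(fragments=fragments, dropped=dropped)


def infer_fragment_strand(fragment: Fragment, library_type: str) -> str:
    """Strand of transcription for one fragment.

    Stranded protocols fix the strand from mate orientation; for unstranded
    data the spliced-alignment tag is the only evidence and unspliced,
    untagged fragments are ``undetermined``.
    """
    if library_type not in LIBRARY_TYPES:
        raise ValueError(f"library_type must be one of {LIBRARY_TYPES}")
    if library_type != "unstranded":
        return _strand_from_orientation(library_type, fragment.mate1_is_reverse)
    if fragment.strand_evidence in ("forward", "reverse"):
        return fragment.strand_evidence
    return "undetermined"
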