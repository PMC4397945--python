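"""Shared fixtures: hand-built SAM text, fragments and splice graphs."""

from __future__ import annotations

import numpy as np
import pytest

from bayestx.alignment_io import Fragment
from bayestx.splice_graph import Exon, SpliceGraph


def cigar_from_blocks(blocks) -> str:
    cigar = ""
    for i, (s, e) in enumerate(blocks):
        if i:
            cigar += f"{s - blocks[i - 1][1]}N"
        cigar += f"{e - s}M"
    return cigar


def sam_pair(
    qname: str,
    chrom: str,
    blocks1,
    blocks2,
    mate1_reverse: bool = False,
    xs: str | None = None,
    nh: int = 1,
    proper: bool = True,
) -> list[str]:
    """Two SAM lines for one read pair (mate2 oriented opposite to mate1)."""
    base = 0x1 | (0x2 if proper else 0)
    flag1 = base | 0x40 | (0x10 if mate1_reverse else 0x20)
    flag2 = base | 0x80 | (0x20 if mate1_reverse else 0x10)
    lines = []
    for blocks, flag, mate_blocks in ((blocks1, flag1, blocks2), (blocks2, flag2, blocks1)):
        aligned = sum(e - s for s, e in blocks)
        fields = [
            qname, str(flag), chrom, str(blocks[0][0] + 1), "50",
            cigar_from_blocks(blocks), "=", str(mate_blocks[0][0] + 1), "0",
            "A" * aligned, "I" * aligned, f"NH:i:{nh}",
        ]
        if xs is not None:
            fields.append(f"XS:A:{xs}")
        lines.append("\t".join(fields))
    return lines


def sam_text(body_lines, chroms=None) -> str:
    chroms = chroms or {"chr1": 100_000}
    header = ["@HD\tVN:1.6\tSO:coordinate"]
    header += [f"@SQ\tSN:{c}\tLN:{length}" for c, length in chroms.items()]
    return "\n".join(header + list(body_lines)) + "\n"


def write_sam(path, body_lines, chroms=None):
    path.write_text(sam_text(body_lines, chroms))
    return path


def fragments_to_sam_lines(fragments) -> list[str]:
    """Serialize fragments back to SAM lines (idempotency checks)."""
    lines = []
    for frag in fragments:
        xs = {"forward": "+", "reverse": "-"}.get(frag.strand_evidence)
        lines.extend(
            sam_pair(
                frag.fragment_id, frag.chrom, frag.blocks_mate1, frag.blocks_mate2,
                mate1_reverse=frag.mate1_is_reverse, xs=xs,
            )
        )
    return lines


def make_fragment(
    fid: str,
    blocks1,
    blocks2,
    chrom: str = "chr1",
    strand_evidence: str = "none",
    mate1_is_reverse: bool = False,
) -> Fragment:
    return Fragment(
        fragment_id=fid, chrom=chrom,
        blocks_mate1=tuple(tuple(b) for b in blocks1),
        blocks_mate2=tuple(tuple(b) for b in blocks2),
        strand_evidence=strand_evidence, mate1_is_reverse=mate1_is_reverse,
    )


def make_graph(exon_intervals, edges, strand="forward", chrom="chr1", fragments=()):
    """SpliceGraph from raw intervals and an {(i, j): coverage} edge dict."""
    return SpliceGraph(
        chrom=chrom,
        strand=strand,
        exons=[Exon(chrom, s, e) for s, e in exon_intervals],
        edges=dict(edges),
        fragments=list(fragments),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
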