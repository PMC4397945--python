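"""Posterior summaries, final thresholding and GTF output.

Confidence is the fraction of retained iterations in which a candidate is
expressed; abundance is the mean of the per-iteration abundances normalized
to effective transcript length and total library size (FPKM convention);
the expected count is the posterior mean of the assignment counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from bayestx.candidates import CandidateSet, TranscriptCandidate
from bayestx.inference import PosteriorSamples

log = logging.getLogger(__name__)

DEFAULT_CONFIDENCE_THRESHOLD = 0.5
DEFAULT_MIN_EXPECTED_COUNT = 12.0


@dataclass
class TranscriptRecord:
    """One candidate with its posterior summary."""

    candidate: TranscriptCandidate
    locus_id: str
    confidence: float
    fpkm: float
    expected_count: float
    gene_id: str | None = None
    transcript_id: str | None = None


@dataclass
class Assembly:
    transcripts: list[TranscriptRecord]
    provenance: dict = field(default_factory=dict)


def summarize_posterior(
    samples: PosteriorSamples,
    candidate_set: CandidateSet,
    effective_lengths: np.ndarray,
    library_size: int,
) -> list[TranscriptRecord]:
    """Per-candidate confidence, FPKM-normalized abundance and expected count.

    The normalized abundance of an expressed iteration is
    ``e_j * n_locus / effective_length_j * 1e9 / library_size``; the reported
    value is its mean over the iterations where the candidate is expressed
    (0 when never expressed).
    """
    n_locus = samples.n
    scale = n_locus * 1e9 / (np.asarray(effective_lengths) * max(library_size, 1))
    fpkm = samples.mean_e_expressed * scale
    confidence = samples.confidence
    expected = samples.mean_count
    return [
        TranscriptRecord(
            candidate=cand,
            locus_id=candidate_set.locus_id,
            confidence=float(confidence[j]),
            fpkm=float(fpkm[j]),
            expected_count=float(expected[j]),
        )
        for j, cand in enumerate(candidate_set.candidates)
    ]


def _assign_gene_ids(records: list[TranscriptRecord]) -> None:
    """Cluster retained transcripts by same-strand genomic overlap."""
    order = sorted(
        range(len(records)),
        key=lambda i: (records[i].candidate.chrom, records[i].candidate.strand,
                       records[i].candidate.start, records[i].candidate.end),
    )
    gene_no = 0
    cluster_end = None
    cluster_key = None
    for rank, i in enumerate(order):
        cand = records[i].candidate
        key = (cand.chrom, cand.strand)
        if cluster_key != key or cand.start >= cluster_end:
            gene_no += 1
            cluster_key = key
            cluster_end = cand.end
        else:
            cluster_end = max(cluster_end, cand.end)
        records[i].gene_id = f"BTX_G{gene_no:06d}"
        records[i].transcript_id = f"BTX_T{rank + 1:06d}"


def select_final_assembly(
    records: list[TranscriptRecord],
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
    min_expected_count: float = DEFAULT_MIN_EXPECTED_COUNT,
    provenance: dict | None = None,
) -> Assembly:
    """Keep transcripts with confidence strictly above the threshold and an
    expected paired-end count of at least ``min_expected_count``."""
    kept = [
        r
        for r in records
        if r.confidence > confidence_threshold and r.expected_count >= min_expected_count
    ]
    _assign_gene_ids(kept)
    kept.sort(key=lambda r: (r.candidate.chrom, r.candidate.start, r.candidate.end))
    return Assembly(transcripts=kept, provenance=dict(provenance or {}))


_STRAND_SYMBOL = {"forward": "+", "reverse": "-"}


def format_gtf_lines(
    chrom: str,
    strand: str,
    exons,
    gene_id: str,
    transcript_id: str,
    extra_attrs: dict | None = None,
    source: str = "bayestx",
) -> list[str]:
    """GTF transcript + exon lines; converts to 1-based inclusive coordinates."""
    symbol = _STRAND_SYMBOL.get(strand, strand)
    attrs = f'gene_id "{gene_id}"; transcript_id "{transcript_id}";'
    for key, value in (extra_attrs or {}).items():
        attrs += f' {key} "{value}";'
    start = min(s for s, _ in exons) + 1
    end = max(e for _, e in exons)
    lines = [
        f"{chrom}\t{source}\ttranscript\t{start}\t{end}\t.\t{symbol}\t.\t{attrs}"
    ]
    for s, e in exons:
        lines.append(f"{chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{symbol}\t.\t{attrs}")
    return lines


def write_gtf(assembly: Assembly, output_path: str | Path) -> None:
    path = Path(output_path)
    lines = [f"## bayestx assembly; {len(assembly.transcripts)} transcripts"]
    for key, value in sorted(assembly.provenance.items()):
        lines.append(f"## {key}: {value}")
    for rec in assembly.transcripts:
        lines.extend(
            format_gtf_lines(
                rec.candidate.chrom,
                rec.candidate.strand,
                rec.candidate.exons,
                gene_id=rec.gene_id or rec.locus_id,
                transcript_id=rec.transcript_id or rec.locus_id,
                extra_attrs={
                    "confidence": f"{rec.confidence:.6f}",
                    "FPKM": f"{rec.fpkm:.6f}",
                    "expected_count": f"{rec.expected_count:.6f}",
                },
            )
        )
    path.write_text("\n".join(lines) + "\n")
    log.info("wrote %d transcripts to %s", len(assembly.transcripts), path)


def _parse_attrs(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path: str | Path) -> list[dict]:
    """Parse a GTF into transcript dicts with 0-based half-open exon chains."""
    transcripts: dict[str, dict] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9 or fields[2] != "exon":
            continue
        attrs = _parse_attrs(fields[8])
        tid = attrs.get("transcript_id", "")
        entry = transcripts.setdefault(
            tid,
            {"transcript_id": tid, "chrom": fields[0], "strand": fields[6],
             "exons": [], "attrs": attrs},
        )
        entry["exons"].append((int(fields[3]) - 1, int(fields[4])))
    for entry in transcripts.values():
        entry["exons"] = tuple(sorted(entry["exons"]))
    return sorted(transcripts.values(), key=lambda t: (t["chrom"], t["exons"]))
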