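"""Self-contained simulator and assembly scorer.

Generates toy loci and paired-end spliced alignments from the assembler's
own generative model — truncated-Bernoulli expression, symmetric-Dirichlet
abundances, Gaussian fragment lengths, uniform fragment starts — and scores
assemblies with intron-chain matching (75% containment rule for single-exon
transcripts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from bayestx.assembly import format_gtf_lines

log = logging.getLogger(__name__)

Chain = tuple[tuple[int, int], ...]

_MAX_REJECTION = 100_000


@dataclass(frozen=True)
class LocusSpec:
    """One toy gene: a set of possible transcripts as genomic exon chains."""

    chrom: str
    strand: str  # 'forward' | 'reverse'
    transcripts: tuple[Chain, ...]

    @property
    def m(self) -> int:
        return len(self.transcripts)


@dataclass
class SimulationSpec:
    loci: list[LocusSpec]
    pi_true: float = 0.5
    gamma_true: float = 1.0
    mu_true: float = 250.0
    sigma_true: float = 25.0
    n_fragments: int = 1000  # per locus
    read_length: int = 100
    seed: int = 0
    n_expressed: int | None = None  # fix b_z instead of Bernoulli draws
    min_expressed_abundance: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.pi_true <= 1.0):
            raise ValueError("pi_true must be in (0, 1]")
        if self.sigma_true < 0 or self.mu_true <= 0:
            raise ValueError("invalid fragment length parameters")
        for locus in self.loci:
            if locus.m < 1:
                raise ValueError("each locus needs at least one transcript")


@dataclass
class LocusTruth:
    spec: LocusSpec
    z: np.ndarray
    e: np.ndarray
    t: np.ndarray  # per-fragment source transcript index

    @property
    def expressed_transcripts(self) -> list[Chain]:
        return [tr for tr, zj in zip(self.spec.transcripts, self.z) if zj]


@dataclass
class SimulationTruth:
    loci: list[LocusTruth] = field(default_factory=list)


def _chain_length(chain: Chain) -> int:
    return sum(e - s for s, e in chain)


def _interval_to_blocks(chain: Chain, a: int, b: int) -> Chain:
    """Map transcript interval [a, b) (plus orientation) to genomic blocks."""
    blocks: list[tuple[int, int]] = []
    offset = 0
    for s, e in chain:
        length = e - s
        lo, hi = max(a, offset), min(b, offset + length)
        if lo < hi:
            blocks.append((s + lo - offset, s + hi - offset))
        offset += length
    return tuple(blocks)


def _draw_expression(spec: SimulationSpec, m: int, rng: np.random.Generator) -> np.ndarray:
    if spec.n_expressed is not None:
        if spec.n_expressed < 1:
            raise ValueError("n_expressed must be >= 1")
        k = min(spec.n_expressed, m)
        z = np.zeros(m, dtype=np.int8)
        z[rng.choice(m, size=k, replace=False)] = 1
        return z
    for _ in range(_MAX_REJECTION):
        z = (rng.random(m) < spec.pi_true).astype(np.int8)
        if z.any():  # all-zero rejected: the K_z0-truncated prior
            return z
    raise RuntimeError("expression rejection sampling failed")


def _draw_abundances(spec: SimulationSpec, z: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    b = int(z.sum())
    for _ in range(_MAX_REJECTION):
        e_plus = rng.dirichlet(np.full(b, spec.gamma_true))
        if e_plus.min() >= spec.min_expressed_abundance:
            e = np.zeros(len(z))
            e[np.flatnonzero(z)] = e_plus
            return e
    raise RuntimeError("abundance rejection sampling failed (min_expressed_abundance too high)")


def _draw_length(spec: SimulationSpec, transcript_length: int, rng: np.random.Generator) -> int:
    lo = min(spec.read_length, transcript_length)
    if spec.sigma_true == 0:
        length = int(round(spec.mu_true))
        if not (lo <= length <= transcript_length):
            raise ValueError("degenerate fragment length outside transcript")
        return length
    for _ in range(_MAX_REJECTION):
        length = int(round(rng.normal(spec.mu_true, spec.sigma_true)))
        if lo <= length <= transcript_length:
            return length
    raise ValueError("transcript too short for the fragment length distribution")


def _sam_record(
    qname: str, chrom: str, blocks: Chain, flag: int, mate_pos: int, tlen: int,
    xs: str | None,
) -> tuple[str, int, str]:
    cigar = ""
    for i, (s, e) in enumerate(blocks):
        if i:
            cigar += f"{s - blocks[i - 1][1]}N"
        cigar += f"{e - s}M"
    aligned = sum(e - s for s, e in blocks)
    seq = "A" * aligned
    qual = "I" * aligned
    fields = [
        qname, str(flag), chrom, str(blocks[0][0] + 1), "50", cigar,
        "=", str(mate_pos + 1), str(tlen), seq, qual, "NH:i:1",
    ]
    if xs is not None and len(blocks) > 1:
        fields.append(f"XS:A:{xs}")
    return chrom, blocks[0][0], "\t".join(fields)


def simulate_dataset(spec: SimulationSpec) -> tuple[SimulationTruth, str]:
    """Draw the generative model and render the fragments as SAM text.

    Reads follow the fr-firststrand protocol (mate1 antisense to the
    transcript) and spliced reads additionally carry XS strand tags, so the
    output is consumable under both stranded and unstranded library modes.
    """
    rng = np.random.default_rng(spec.seed)
    truth = SimulationTruth()
    records: list[tuple[str, int, str]] = []

    for locus_index, locus in enumerate(spec.loci):
        z = _draw_expression(spec, locus.m, rng)
        e = _draw_abundances(spec, z, rng)
        t = rng.choice(locus.m, size=spec.n_fragments, p=e)
        truth.loci.append(LocusTruth(spec=locus, z=z, e=e, t=t))

        xs = "+" if locus.strand == "forward" else "-"
        for i, j in enumerate(t):
            chain = locus.transcripts[j]
            total = _chain_length(chain)
            length = _draw_length(spec, total, rng)
            read_len = min(spec.read_length, length)
            p = int(rng.integers(0, total - length + 1))
            sense_iv = (p, p + read_len)
            anti_iv = (p + length - read_len, p + length)
            if locus.strand == "reverse":
                # transcript coordinates run right-to-left genomically
                sense_iv = (total - sense_iv[1], total - sense_iv[0])
                anti_iv = (total - anti_iv[1], total - anti_iv[0])
            sense_blocks = _interval_to_blocks(chain, *sense_iv)
            anti_blocks = _interval_to_blocks(chain, *anti_iv)
            sense_rev = locus.strand == "reverse"
            anti_rev = not sense_rev

            # fr-firststrand: mate1 is the antisense read
            m1_blocks, m1_rev = anti_blocks, anti_rev
            m2_blocks, m2_rev = sense_blocks, sense_rev
            left = min(m1_blocks[0][0], m2_blocks[0][0])
            right = max(m1_blocks[-1][1], m2_blocks[-1][1])
            span = right - left
            qname = f"L{locus_index}_F{i}"
            flag1 = 0x1 | 0x2 | 0x40 | (0x10 if m1_rev else 0) | (0x20 if m2_rev else 0)
            flag2 = 0x1 | 0x2 | 0x80 | (0x10 if m2_rev else 0) | (0x20 if m1_rev else 0)
            tlen1 = span if m1_blocks[0][0] <= m2_blocks[0][0] else -span
            records.append(
                _sam_record(qname, locus.chrom, m1_blocks, flag1, m2_blocks[0][0], tlen1, xs)
            )
            records.append(
                _sam_record(qname, locus.chrom, m2_blocks, flag2, m1_blocks[0][0], -tlen1, xs)
            )

    chrom_ends: dict[str, int] = {}
    for locus in spec.loci:
        end = max(e for chain in locus.transcripts for _, e in chain)
        chrom_ends[locus.chrom] = max(chrom_ends.get(locus.chrom, 0), end)
    chroms = sorted(chrom_ends)
    header = ["@HD\tVN:1.6\tSO:coordinate"]
    header += [f"@SQ\tSN:{c}\tLN:{chrom_ends[c] + 1000}" for c in chroms]
    chrom_rank = {c: i for i, c in enumerate(chroms)}
    records.sort(key=lambda r: (chrom_rank[r[0]], r[1], r[2]))
    sam_text = "\n".join(header + [r[2] for r in records]) + "\n"
    return truth, sam_text


_STRAND_SYMBOL = {"forward": "+", "reverse": "-"}


def truth_gtf(truth: SimulationTruth, expressed_only: bool = True) -> str:
    """Render the (expressed) truth transcripts as GTF text."""
    lines = ["## bayestx simulation truth"]
    for locus_index, locus in enumerate(truth.loci):
        for j, chain in enumerate(locus.spec.transcripts):
            if expressed_only and not locus.z[j]:
                continue
            lines.extend(
                format_gtf_lines(
                    locus.spec.chrom, locus.spec.strand, chain,
                    gene_id=f"SIM_G{locus_index:04d}",
                    transcript_id=f"SIM_G{locus_index:04d}_T{j:02d}",
                    extra_attrs={"abundance": f"{locus.e[j]:.6f}"},
                    source="bayestx_sim",
                )
            )
    return "\n".join(lines) + "\n"


def truth_table(truth: SimulationTruth) -> str:
    """TSV of per-transcript truth: locus, transcript, expressed, abundance."""
    rows = ["locus\ttranscript\texpressed\tabundance"]
    for locus_index, locus in enumerate(truth.loci):
        for j in range(locus.spec.m):
            rows.append(
                f"SIM_G{locus_index:04d}\tSIM_G{locus_index:04d}_T{j:02d}\t"
                f"{int(locus.z[j])}\t{locus.e[j]:.6f}"
            )
    return "\n".join(rows) + "\n"


def write_simulation(spec: SimulationSpec, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth, sam_text = simulate_dataset(spec)
    paths = {
        "sam": out / "simulated.sam",
        "truth_gtf": out / "truth.gtf",
        "truth_tsv": out / "truth.tsv",
    }
    paths["sam"].write_text(sam_text)
    paths["truth_gtf"].write_text(truth_gtf(truth))
    paths["truth_tsv"].write_text(truth_table(truth))
    return paths


def _intron_chain(exons: Chain) -> Chain:
    return tuple((e0, s1) for (_, e0), (s1, _) in zip(exons, exons[1:]))


def _matches(pred: dict, truth_entry: dict, strand_specific: bool) -> bool:
    if pred["chrom"] != truth_entry["chrom"]:
        return False
    if strand_specific and pred["strand"] != truth_entry["strand"]:
        return False
    p_exons, t_exons = pred["exons"], truth_entry["exons"]
    if len(p_exons) > 1 or len(t_exons) > 1:
        p_chain, t_chain = _intron_chain(p_exons), _intron_chain(t_exons)
        return bool(p_chain) and p_chain == t_chain
    (ps, pe), (ts, te) = p_exons[0], t_exons[0]
    if ps < ts or pe > te:
        return False  # must be contained in the truth single-exon transcript
    return (pe - ps) >= 0.75 * (te - ts)


def match_transcripts(
    predicted: list[dict], truth: list[dict], strand_specific: bool = False
) -> tuple[float, float]:
    """(sensitivity, precision) of a predicted assembly against a truth set.

    Multi-exon transcripts match on identical intron chains; a single-exon
    prediction matches when contained in and covering >= 75% of a truth
    single-exon transcript. Inputs are ``read_gtf``-style transcript dicts.
    """
    if not truth or not predicted:
        return 0.0, 0.0
    matched_truth = sum(
        1 for t in truth if any(_matches(p, t, strand_specific) for p in predicted)
    )
    matched_pred = sum(
        1 for p in predicted if any(_matches(p, t, strand_specific) for t in truth)
    )
    return matched_truth / len(truth), matched_pred / len(predicted)


def _exon_run(rng: np.random.Generator, pos: int, count: int) -> tuple[list[tuple[int, int]], int]:
    exons = []
    for _ in range(count):
        length = int(rng.integers(150, 401))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(100, 501))
    return exons, pos


def random_locus(
    rng: np.random.Generator,
    chrom: str,
    offset: int,
    n_transcripts: int = 6,
    strand: str | None = None,
) -> LocusSpec:
    """A toy multi-isoform gene with mutually exclusive internal exons.

    Every transcript shares flanking exon runs but carries its own internal
    exon, so each has a unique pair of junctions: intron chains are distinct
    and every expressed transcript is identifiable from junction-spanning
    fragments.
    """
    left, pos = _exon_run(rng, offset, int(rng.integers(1, 3)))
    arms, pos = _exon_run(rng, pos, n_transcripts)
    right, _ = _exon_run(rng, pos, int(rng.integers(2, 4)))
    transcripts = tuple(tuple(left) + (arm,) + tuple(right) for arm in arms)
    if strand is None:
        strand = "forward" if rng.random() < 0.5 else "reverse"
    return LocusSpec(chrom=chrom, strand=strand, transcripts=transcripts)


def calibration_locus(chrom: str, offset: int, length: int = 3000) -> LocusSpec:
    """A single-transcript, single-exon locus for fragment-length estimation."""
    return LocusSpec(chrom=chrom, strand="forward", transcripts=(((offset, offset + length),),))
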