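"""Fragment-length model, effective lengths and fragment likelihoods.

The fragment-length distribution is Gaussian, estimated robustly (median and
scaled median absolute deviation) from fragments mapping to long transcripts
of single-transcript graphs. The likelihood of a fragment given a candidate
is zero when the alignment is incompatible with the candidate's exon chain,
otherwise the truncated-Gaussian probability of its implied transcript-
coordinate length divided by the candidate's effective length.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_right
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import median_abs_deviation, norm

from bayestx.alignment_io import Fragment
from bayestx.candidates import CandidateSet, TranscriptCandidate, enumerate_paths
from bayestx.splice_graph import SpliceGraph

log = logging.getLogger(__name__)

DEFAULT_MIN_EST_TRANSCRIPT_LEN = 2500
DEFAULT_FALLBACK = (250.0, 50.0)


@dataclass(frozen=True)
class FragmentLengthModel:
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass
class LikelihoodMatrix:
    """Dense n x m fragment-by-candidate likelihood values for one locus."""

    values: np.ndarray  # shape (n, m); finite, non-negative, rows non-zero
    effective_lengths: np.ndarray  # shape (m,)
    fragments: list[Fragment]  # rows, after dropping all-zero rows
    n_dropped: int = 0

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]


def robust_location_scale(values) -> tuple[float, float]:
    """Median and Gaussian-consistent scaled MAD (x 1.4826) of a sample."""
    arr = np.asarray(values, dtype=float)
    return float(np.median(arr)), float(median_abs_deviation(arr, scale="normal"))


def _mate_transcript_span(
    blocks, exon_starts: list[int], exons, cumlen: list[int]
) -> tuple[int, int] | None:
    """Map a mate's genomic blocks to a contiguous transcript interval.

    Returns ``None`` if any aligned base falls outside the candidate's exons
    or the blocks are not contiguous in transcript coordinates (i.e. the
    mate's introns do not exactly match candidate introns).
    """
    tstart = tend = None
    for s, e in blocks:
        k = bisect_right(exon_starts, s) - 1
        if k < 0:
            return None
        es, ee = exons[k]
        if s < es or e > ee:
            return None
        t0 = cumlen[k] + (s - es)
        t1 = t0 + (e - s)
        if tstart is None:
            tstart = t0
        elif t0 != tend:
            return None
        tend = t1
    return tstart, tend


def implied_fragment_length(fragment: Fragment, candidate: TranscriptCandidate) -> int | None:
    """Fragment length in transcript coordinates, or ``None`` if incompatible."""
    exons = candidate.exons
    exon_starts = [s for s, _ in exons]
    cumlen = [0]
    for s, e in exons:
        cumlen.append(cumlen[-1] + (e - s))
    span1 = _mate_transcript_span(fragment.blocks_mate1, exon_starts, exons, cumlen)
    if span1 is None:
        return None
    span2 = _mate_transcript_span(fragment.blocks_mate2, exon_starts, exons, cumlen)
    if span2 is None:
        return None
    length = max(span1[1], span2[1]) - min(span1[0], span2[0])
    if length < 1 or length > candidate.length:
        return None
    return length


@lru_cache(maxsize=65536)
def _truncated_length_stats(length: int, mu: float, sigma: float) -> tuple[float, float]:
    """(normalizer Z_L, effective length) of the length pmf truncated to [1, L].

    The pmf is the Gaussian density evaluated on the integers 1..L and
    renormalized; sigma == 0 degenerates to a point mass at round(mu).
    """
    grid = np.arange(1, length + 1, dtype=float)
    if sigma == 0:
        weights = (grid == round(mu)).astype(float)
    else:
        weights = norm.pdf(grid, loc=mu, scale=sigma)
    z = float(weights.sum())
    if z <= 0.0:
        # no plausible length fits; fall back to a uniform pmf on [1, L]
        weights = np.ones_like(grid)
        z = float(length)
    eff = float((weights * (length - grid + 1.0)).sum() / z)
    return z, max(eff, 1.0)


def _length_pmf(length_t: int, transcript_length: int, model: FragmentLengthModel) -> float:
    z, _ = _truncated_length_stats(transcript_length, model.mu, model.sigma)
    if model.sigma == 0:
        density = 1.0 if length_t == round(model.mu) else 0.0
    else:
        u = (length_t - model.mu) / model.sigma
        density = math.exp(-0.5 * u * u) / (model.sigma * math.sqrt(2.0 * math.pi))
        if density == 0.0 and z == float(transcript_length):
            density = 1.0  # uniform fallback regime
    return density / z


def effective_length(transcript_length: int, model: FragmentLengthModel) -> float:
    """Expected number of valid fragment start positions, clamped to >= 1."""
    if transcript_length < 1:
        raise ValueError("transcript length must be >= 1")
    _, eff = _truncated_length_stats(transcript_length, model.mu, model.sigma)
    return eff


def fragment_likelihood(
    fragment: Fragment, candidate: TranscriptCandidate, model: FragmentLengthModel
) -> float:
    """P(fragment | candidate): compatibility x length pmf / effective length."""
    length_t = implied_fragment_length(fragment, candidate)
    if length_t is None:
        return 0.0
    eff = effective_length(candidate.length, model)
    return _length_pmf(length_t, candidate.length, model) / eff


def estimate_fragment_length_model(
    graphs: list[SpliceGraph],
    min_transcript_length: int = DEFAULT_MIN_EST_TRANSCRIPT_LEN,
    fallback: tuple[float, float] = DEFAULT_FALLBACK,
) -> FragmentLengthModel:
    """Estimate (mu, sigma) from fragments of long single-transcript graphs.

    Uses the median and scaled MAD of transcript-coordinate fragment lengths
    across all graphs whose enumeration yields exactly one candidate of at
    least ``min_transcript_length`` nt. Falls back to configured defaults
    (with a warning) when no qualifying fragments exist.
    """
    lengths: list[int] = []
    for graph in graphs:
        cands = enumerate_paths(graph)
        if len(cands) != 1 or cands[0].length < min_transcript_length:
            continue
        cand = cands[0]
        for frag in graph.fragments:
            length = implied_fragment_length(frag, cand)
            if length is not None:
                lengths.append(length)
    if not lengths:
        log.warning(
            "no fragments on single-transcript graphs >= %d nt; "
            "falling back to mu=%.1f sigma=%.1f",
            min_transcript_length, *fallback,
        )
        return FragmentLengthModel(*fallback)
    mu, sigma = robust_location_scale(lengths)
    sigma = max(sigma, 1e-3)  # MAD can degenerate to 0 on tiny samples
    log.info("fragment length model: mu=%.2f sigma=%.2f (from %d fragments)", mu, sigma, len(lengths))
    return FragmentLengthModel(mu, sigma)


def build_likelihood_matrix(
    candidate_set: CandidateSet, model: FragmentLengthModel
) -> LikelihoodMatrix:
    """Likelihood values for one locus; all-zero rows are dropped from n."""
    candidates = candidate_set.candidates
    eff = np.array([effective_length(c.length, model) for c in candidates])
    rows = []
    kept: list[Fragment] = []
    n_dropped = 0
    for frag in candidate_set.fragments:
        row = np.array([fragment_likelihood(frag, c, model) for c in candidates])
        if row.sum() > 0.0:
            rows.append(row)
            kept.append(frag)
        else:
            n_dropped += 1
    if n_dropped:
        log.info("locus %s: dropped %d fragments with zero likelihood everywhere",
                 candidate_set.locus_id, n_dropped)
    values = np.array(rows) if rows else np.zeros((0, len(candidates)))
    return LikelihoodMatrix(values=values, effective_lengths=eff, fragments=kept, n_dropped=n_dropped)
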