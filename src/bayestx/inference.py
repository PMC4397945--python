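"""Spike-and-slab Gibbs sampler over expression indicators, abundances and
fragment assignments, plus the greedy set-cover estimator of the sparsity
hyperparameter and an exhaustive-enumeration posterior oracle for testing.

One Gibbs iteration draws, in order: the number of expressed candidates
b_z, the binary expression vector z, the Dirichlet abundances e, and the
per-fragment candidate assignments t. All probability arithmetic is done in
log space.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

DEFAULT_GAMMA = 1.0


@dataclass(frozen=True)
class SparsityPrior:
    """Truncated-Bernoulli prior on the expression vector (all-zero excluded)."""

    pi: float
    m: int

    def __post_init__(self) -> None:
        if not (0.0 < self.pi <= 1.0):
            raise ValueError("pi must be in (0, 1]")
        if self.m < 1:
            raise ValueError("m must be >= 1")

    @property
    def k_z0(self) -> float:
        return 1.0 / (1.0 - (1.0 - self.pi) ** self.m)


@dataclass(frozen=True)
class GibbsSchedule:
    burn_in: int
    samples: int
    seed: int | None = None

    @classmethod
    def for_candidates(cls, m: int, seed: int | None = None) -> "GibbsSchedule":
        burn_in = 60 * m + 1000
        return cls(burn_in=burn_in, samples=10 * burn_in, seed=seed)


@dataclass
class PosteriorSamples:
    """Streaming accumulators over the retained (post burn-in) iterations."""

    n: int
    m: int
    retained: int
    expressed_count: np.ndarray  # per candidate: iterations with z_j = 1
    e_sum: np.ndarray  # per candidate: sum of e_j (zero when unexpressed)
    e_sq_sum: np.ndarray
    c_sum: np.ndarray  # per candidate: sum of assignment counts
    z_trace: np.ndarray | None = None
    e_trace: np.ndarray | None = None

    @property
    def confidence(self) -> np.ndarray:
        return self.expressed_count / self.retained

    @property
    def mean_e(self) -> np.ndarray:
        """Posterior mean abundance over all retained iterations."""
        return self.e_sum / self.retained

    @property
    def mean_e_expressed(self) -> np.ndarray:
        """Mean abundance over the iterations where the candidate is expressed."""
        with np.errstate(invalid="ignore"):
            out = np.where(self.expressed_count > 0, self.e_sum / self.expressed_count, 0.0)
        return out

    @property
    def mean_count(self) -> np.ndarray:
        """Posterior expected fragment count per candidate."""
        return self.c_sum / self.retained


def estimate_pi(likelihood_values: np.ndarray) -> SparsityPrior:
    """Greedy minimum set cover of fragments by candidates; pi = m_min / m.

    Fragments are the universe; a candidate covers the fragments it has
    positive likelihood for. Ties go to the lowest candidate index.
    """
    values = np.asarray(likelihood_values)
    n, m = values.shape
    coverable = values > 0.0
    if n == 0:
        return SparsityPrior(pi=1.0, m=m)
    if not coverable.any(axis=1).all():
        raise ValueError("every fragment must be coverable by some candidate")
    uncovered = np.ones(n, dtype=bool)
    m_min = 0
    while uncovered.any():
        gains = coverable[uncovered].sum(axis=0)
        j = int(np.argmax(gains))  # argmax returns the lowest index on ties
        uncovered &= ~coverable[:, j]
        m_min += 1
    return SparsityPrior(pi=m_min / m, m=m)


def _log_comb(n: int, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def num_expressed_distribution(
    c: np.ndarray, prior: SparsityPrior, gamma: float, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Support and probabilities of the conditional of b_z given counts c.

    Support is {|J+|, ..., m}; each weight combines the choose term over
    unoccupied candidates, the Gamma-ratio collapse of the Dirichlet and the
    Bernoulli prior. Computed with log-Gamma and normalized by log-sum-exp.
    """
    c = np.asarray(c)
    m = prior.m
    if c.shape != (m,):
        raise ValueError("counts vector must have length m")
    k = int((c > 0).sum())
    j0 = m - k
    support = np.arange(max(k, 1), m + 1)
    logw = (
        _log_comb(j0, support - k)
        + gammaln(support * gamma)
        - gammaln(n + support * gamma)
    )
    if prior.pi >= 1.0:
        logw = logw + np.where(support == m, 0.0, -np.inf)
    else:
        logw = logw + support * math.log(prior.pi) + (m - support) * math.log1p(-prior.pi)
    total = logsumexp(logw)
    assert np.isfinite(total), "all b_z weights underflowed"
    probs = np.exp(logw - total)
    probs /= probs.sum()
    return support, probs


def sample_num_expressed(
    c: np.ndarray, prior: SparsityPrior, gamma: float, n: int, rng: np.random.Generator
) -> int:
    support, probs = num_expressed_distribution(c, prior, gamma, n)
    return int(rng.choice(support, p=probs))


def sample_expression_vector(b_z: int, c: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """z with z_j = 1 on J+ plus a uniform without-replacement draw from J0."""
    c = np.asarray(c)
    j_plus = np.flatnonzero(c > 0)
    j_zero = np.flatnonzero(c == 0)
    extra = b_z - len(j_plus)
    assert 0 <= extra <= len(j_zero), "b_z out of range"
    z = np.zeros(len(c), dtype=np.int8)
    z[j_plus] = 1
    if extra:
        z[rng.choice(j_zero, size=extra, replace=False)] = 1
    return z


def sample_abundances(
    z: np.ndarray, c: np.ndarray, gamma: float, rng: np.random.Generator
) -> np.ndarray:
    """e with e+ ~ Dirichlet(c+ + gamma) scattered to the expressed indices."""
    z = np.asarray(z)
    c = np.asarray(c)
    assert np.all(z[c > 0] == 1), "counts inconsistent with z"
    idx = np.flatnonzero(z == 1)
    e_plus = rng.dirichlet(c[idx] + gamma)
    e_plus = e_plus / e_plus.sum()
    e = np.zeros(len(z))
    e[idx] = e_plus
    return e


def sample_assignments(
    e: np.ndarray, likelihood_values: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """t_i ~ Categorical( P(f_i | j) * e_j ) independently; c tallied from t."""
    values = np.asarray(likelihood_values)
    n, m = values.shape
    weights = values * e
    totals = weights.sum(axis=1)
    assert np.all(totals > 0.0), "fragment with zero posterior mass under expressed candidates"
    cumulative = np.cumsum(weights, axis=1)
    u = rng.random(n) * totals
    t = np.minimum((cumulative < u[:, None]).sum(axis=1), m - 1)
    c = np.bincount(t, minlength=m)
    return t, c


def _initial_assignment(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniform draw among positive-likelihood candidates per fragment."""
    positive = values > 0.0
    counts = positive.sum(axis=1)
    r = (rng.random(len(values)) * counts).astype(int)
    cum = positive.cumsum(axis=1)
    return (cum <= r[:, None]).sum(axis=1)


def run_gibbs(
    likelihood_values: np.ndarray,
    prior: SparsityPrior,
    gamma: float = DEFAULT_GAMMA,
    schedule: GibbsSchedule | None = None,
    seed: int | np.random.SeedSequence | None = None,
    check_invariants: bool = False,
    keep_trace: bool = False,
) -> PosteriorSamples:
    """Run the Gibbs sampler on one locus and return posterior accumulators.

    Identical seed and input give bit-identical output. ``keep_trace``
    additionally stores the per-iteration (z, e) records (tests only).
    """
    values = np.asarray(likelihood_values, dtype=float)
    n, m = values.shape
    assert n >= 1 and m >= 1
    if schedule is None:
        schedule = GibbsSchedule.for_candidates(m)
    rng = np.random.default_rng(seed if seed is not None else schedule.seed)

    t = _initial_assignment(values, rng)
    c = np.bincount(t, minlength=m)

    expressed_count = np.zeros(m, dtype=np.int64)
    e_sum = np.zeros(m)
    e_sq_sum = np.zeros(m)
    c_sum = np.zeros(m)
    z_trace = np.empty((schedule.samples, m), dtype=np.int8) if keep_trace else None
    e_trace = np.empty((schedule.samples, m)) if keep_trace else None

    total = schedule.burn_in + schedule.samples
    for iteration in range(total):
        b_z = sample_num_expressed(c, prior, gamma, n, rng)
        z = sample_expression_vector(b_z, c, rng)
        e = sample_abundances(z, c, gamma, rng)
        t, c = sample_assignments(e, values, rng)

        if check_invariants:
            assert c.sum() == n
            assert abs(e.sum() - 1.0) < 1e-9
            assert np.all(z[c > 0] == 1)
            assert z.sum() == b_z

        if iteration >= schedule.burn_in:
            kept = iteration - schedule.burn_in
            expressed_count += z
            e_sum += e
            e_sq_sum += e * e
            c_sum += c
            if keep_trace:
                z_trace[kept] = z
                e_trace[kept] = e

    return PosteriorSamples(
        n=n, m=m, retained=schedule.samples,
        expressed_count=expressed_count, e_sum=e_sum, e_sq_sum=e_sq_sum, c_sum=c_sum,
        z_trace=z_trace, e_trace=e_trace,
    )


MAX_ENUMERATION = 1_000_000


def exact_posterior(
    likelihood_values: np.ndarray, prior: SparsityPrior, gamma: float = DEFAULT_GAMMA
) -> dict[str, np.ndarray]:
    """Exact posterior marginals by enumeration of all assignment vectors.

    Sums the collapsed joint over every t in {0..m-1}^n and every consistent
    expression vector (analytically, via the choose terms over unoccupied
    candidates). Guarded to m**n <= 1e6. Returns per-candidate expression
    probabilities, unconditional posterior-mean abundances, and mean
    abundances conditional on expression.
    """
    values = np.asarray(likelihood_values, dtype=float)
    n, m = values.shape
    if m**n > MAX_ENUMERATION:
        raise ValueError(f"instance too large for enumeration: {m}**{n} > {MAX_ENUMERATION}")
    if prior.pi >= 1.0:
        log_pi, log_1mpi = 0.0, -np.inf
    else:
        log_pi, log_1mpi = math.log(prior.pi), math.log1p(-prior.pi)

    with np.errstate(divide="ignore"):
        log_values = np.log(values)

    log_weights: list[float] = []
    pz_rows: list[np.ndarray] = []
    ee_rows: list[np.ndarray] = []
    for t in itertools.product(range(m), repeat=n):
        base = float(log_values[np.arange(n), t].sum())
        if not np.isfinite(base):
            continue
        c = np.bincount(t, minlength=m)
        occupied = c > 0
        k = int(occupied.sum())
        j0 = m - k
        base += float((gammaln(c[occupied] + gamma) - gammaln(gamma)).sum())
        for b in range(k, m + 1):
            extra = b - k
            lw = (
                base
                + float(_log_comb(j0, np.array(extra)))
                + float(gammaln(b * gamma) - gammaln(n + b * gamma))
            )
            if log_1mpi == -np.inf:
                if b < m:
                    continue
                lw += b * log_pi
            else:
                lw += b * log_pi + (m - b) * log_1mpi
            p_extra = extra / j0 if j0 else 0.0
            pz = np.where(occupied, 1.0, p_extra)
            ee = pz * (c + gamma) / (n + b * gamma)
            log_weights.append(lw)
            pz_rows.append(pz)
            ee_rows.append(ee)

    lw_arr = np.array(log_weights)
    shift = lw_arr.max()
    w = np.exp(lw_arr - shift)
    z_total = w.sum()
    pz_mat = np.array(pz_rows)
    ee_mat = np.array(ee_rows)
    p_expressed = (w[:, None] * pz_mat).sum(axis=0) / z_total
    mean_e = (w[:, None] * ee_mat).sum(axis=0) / z_total
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_e_expressed = np.where(p_expressed > 0, mean_e / p_expressed, 0.0)
    return {
        "p_expressed": p_expressed,
        "mean_e": mean_e,
        "mean_e_expressed": mean_e_expressed,
    }
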