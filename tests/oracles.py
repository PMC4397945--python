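"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately share no code with the package: plain-Python enumeration
over all binary expression vectors of the collapsed joint.
"""

from __future__ import annotations

import itertools
import math


def bz_distribution_bruteforce(c, pi: float, gamma: float) -> dict[int, float]:
    """P(b_z | c, pi, gamma) by summing the collapsed joint over all z.

    Enumerates every binary z consistent with the counts (z_j = 1 wherever
    c_j > 0, all-zero excluded), weights it by the truncated-Bernoulli prior
    times the Dirichlet-multinomial collapse, and marginalizes onto b_z.
    """
    c = list(c)
    m = len(c)
    n = sum(c)
    log_weights: dict[int, list[float]] = {}
    for z in itertools.product((0, 1), repeat=m):
        if not any(z):
            continue  # excluded by the truncated prior
        if any(cj > 0 and zj == 0 for cj, zj in zip(c, z)):
            continue  # zero probability: an occupied candidate must be expressed
        b = sum(z)
        if pi >= 1.0:
            if b < m:
                continue
            lw = 0.0
        else:
            lw = b * math.log(pi) + (m - b) * math.log1p(-pi)
        lw += math.lgamma(b * gamma) - math.lgamma(n + b * gamma)
        lw += sum(
            math.lgamma(cj + gamma) - math.lgamma(gamma)
            for cj, zj in zip(c, z)
            if zj == 1
        )
        log_weights.setdefault(b, []).append(lw)

    all_lw = [lw for lws in log_weights.values() for lw in lws]
    shift = max(all_lw)
    totals = {b: sum(math.exp(lw - shift) for lw in lws) for b, lws in log_weights.items()}
    z_total = sum(totals.values())
    return {b: w / z_total for b, w in sorted(totals.items())}
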