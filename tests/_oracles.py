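"""Independent brute-force oracles used by the unit and acceptance suites."""

import itertools

import numpy as np


def rank_sum_exact_oracle(x, y):
    """Two-sided exact rank-sum p-value by full enumeration of splits."""
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    nx = len(x)
    w_obs = sum(ranks[v] for v in x)
    u_obs = w_obs - nx * (nx + 1) / 2
    us = []
    for combo in itertools.combinations(range(1, len(pooled) + 1), nx):
        us.append(sum(combo) - nx * (nx + 1) / 2)
    us = np.asarray(us)
    p_low = np.mean(us <= u_obs)
    p_high = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(p_low, p_high))


def coverage_feasibility_oracle(n, coverage, n_reps, rng):
    """Monte-Carlo P(extreme-order-statistic interval covers >= P).

    For U(0,1) samples the coverage of (min, max) is simply max - min,
    so the simulation needs no distribution-specific code.
    """
    samples = rng.uniform(size=(n_reps, n))
    spread = samples.max(axis=1) - samples.min(axis=1)
    return float(np.mean(spread >= coverage))
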