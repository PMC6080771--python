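"""Independent oracles used by the test suite.

Everything here is deliberately brute-force and shares no code with the
package: exhaustive grid search on the simplex, enumeration of latent
contribution vectors, and hypergeometric table enumeration.
"""

from __future__ import annotations

import itertools
from math import comb, inf, log

import numpy as np


def simplex_grid_best(
    spans, g: int, step: float = 0.01, chunk: int = 400_000
) -> tuple[np.ndarray, float]:
    """Exhaustive maximization of the observed-data log-likelihood
    sum_i log(sum of p over span_i) over the step-discretized simplex."""
    m = round(1.0 / step)
    best_ll, best_p = -np.inf, None
    it = itertools.combinations(range(m + g - 1), g - 1)
    while True:
        block = list(itertools.islice(it, chunk))
        if not block:
            break
        d = np.asarray(block, dtype=np.int64).reshape(len(block), g - 1)
        bounds = np.hstack(
            [np.full((len(d), 1), -1), d, np.full((len(d), 1), m + g - 1)]
        )
        counts = np.diff(bounds) - 1
        P = counts * step
        ll = np.zeros(len(P))
        for k, l in spans:
            ll += np.log(np.clip(P[:, k : l + 1].sum(axis=1), 1e-300, None))
        i = int(np.argmax(ll))
        if ll[i] > best_ll:
            best_ll, best_p = float(ll[i]), P[i].copy()
    return best_p, best_ll


def single_contributor_pmf(q: np.ndarray) -> np.ndarray:
    """P(X = e_j | sum X = 1) for independent Bernoulli(q_j) components,
    by direct enumeration of the G one-hot outcomes."""
    q = np.asarray(q, dtype=float)
    g = q.size
    probs = np.empty(g)
    for j in range(g):
        x = np.zeros(g)
        x[j] = 1
        probs[j] = np.prod(np.where(x == 1, q, 1 - q))
    return probs / probs.sum()


def truncated_vector_pmf(q: np.ndarray) -> dict[tuple[int, ...], float]:
    """P(X = x | sum X >= 1) for every binary vector x, by enumeration."""
    q = np.asarray(q, dtype=float)
    g = q.size
    pmf = {}
    total = 0.0
    for bits in itertools.product((0, 1), repeat=g):
        if sum(bits) == 0:
            continue
        x = np.asarray(bits)
        p = float(np.prod(np.where(x == 1, q, 1 - q)))
        pmf[bits] = p
        total += p
    return {k: v / total for k, v in pmf.items()}


def span_probability(spans_row: tuple[int, int], p: np.ndarray) -> float:
    """P(the single contributing site lies in the span), enumerated over all
    one-hot assignments."""
    k, l = spans_row
    return float(sum(p[j] for j in range(k, l + 1)))


def fisher_two_sided(a: int, total_a: int, b: int, total_b: int) -> float:
    """Two-sided Fisher p-value by enumerating all 2x2 tables with the same
    margins and summing probabilities <= that of the observed table."""
    # margins: row sums total_a, total_b; first-column sum a + b
    s = a + b
    n = total_a + total_b

    def table_prob(x: int) -> float:
        # first cell = x, hypergeometric probability
        if x < 0 or x > total_a or s - x < 0 or s - x > total_b:
            return 0.0
        return comb(total_a, x) * comb(total_b, s - x) / comb(n, s)

    p_obs = table_prob(a)
    tol = p_obs * (1 + 1e-7)
    return min(1.0, sum(table_prob(x) for x in range(s + 1) if table_prob(x) <= tol))


def bh_stepup(p_values) -> np.ndarray:
    """Reference BH implementation via statsmodels."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]
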