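"""Per-CpG differential methylation testing between two samples.

The default statistic is a two-sided exact conditional (Fisher) test on the
2x2 table of a site's count against the remainder of its library in each
sample; alternative statistics can be registered. Multiple testing is
handled with Benjamini-Hochberg step-up q-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from cpgdecon.genome_io import CpGIndex
from cpgdecon.model_core import allocate_sample


def _fisher(count_a: int, total_a: int, count_b: int, total_b: int) -> float:
    table = [[count_a, total_a - count_a], [count_b, total_b - count_b]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


#: Registry of per-site test statistics; each maps
#: (count_A, total_A, count_B, total_B) -> two-sided p-value.
TEST_METHODS: dict[str, Callable[[int, int, int, int], float]] = {
    "fisher": _fisher,
}


def test_site(
    count_a: int,
    total_a: int,
    count_b: int,
    total_b: int,
    method: str = "fisher",
) -> float:
    """Two-sided p-value for a single site's 2x2 count-vs-library table."""
    if total_a <= 0 or total_b <= 0:
        raise ValueError("library totals must be positive")
    if not (0 <= count_a <= total_a and 0 <= count_b <= total_b):
        raise ValueError("counts must lie in [0, total]")
    try:
        fn = TEST_METHODS[method]
    except KeyError:
        raise ValueError(f"unknown test method {method!r}") from None
    return fn(int(count_a), int(total_a), int(count_b), int(total_b))


def adjust_qvalues(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank downward
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class CutoffReport:
    """Number of sites below each significance cutoff, largest cutoff first."""

    cutoffs: np.ndarray
    counts: np.ndarray
    rates: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"cutoff": self.cutoffs, "n_below": self.counts})
        if self.rates is not None:
            df["rate"] = self.rates
        return df


def cutoff_report(
    values: Sequence[float],
    cutoffs: Sequence[float],
    total_sites: int | None = None,
) -> CutoffReport:
    """Count values strictly below each cutoff; optionally report them as a
    rate over ``total_sites`` (the false-positive-rate denominator when the
    values come from a replicate comparison)."""
    v = np.asarray(values, dtype=float)
    c = np.sort(np.asarray(cutoffs, dtype=float))[::-1]
    if np.any(c <= 0):
        raise ValueError("cutoffs must be positive")
    counts = np.array([(v < ci).sum() for ci in c], dtype=np.int64)
    rates = counts / total_sites if total_sites else None
    return CutoffReport(cutoffs=c, counts=counts, rates=rates)


def site_pair_table(
    index: CpGIndex,
    count_a: np.ndarray,
    count_b: np.ndarray,
    total_a: int | None = None,
    total_b: int | None = None,
    mre_a: np.ndarray | None = None,
    mre_b: np.ndarray | None = None,
    method: str = "fisher",
) -> pd.DataFrame:
    """Per-site comparison table with p- and q-values.

    Library totals default to the column sums. Identical (count, total)
    tuples are tested once and cached, which matters when many sites share
    small counts.
    """
    count_a = np.asarray(count_a, dtype=np.int64)
    count_b = np.asarray(count_b, dtype=np.int64)
    g = index.n_sites
    if count_a.shape != (g,) or count_b.shape != (g,):
        raise ValueError("count vectors must have one entry per site")
    ta = int(count_a.sum()) if total_a is None else int(total_a)
    tb = int(count_b.sum()) if total_b is None else int(total_b)
    cache: dict[tuple[int, int], float] = {}
    p_values = np.empty(g)
    for i in range(g):
        key = (int(count_a[i]), int(count_b[i]))
        if key not in cache:
            cache[key] = test_site(key[0], ta, key[1], tb, method=method)
        p_values[i] = cache[key]
    zeros = np.zeros(g, dtype=np.int64)
    df = pd.DataFrame(
        {
            "chrom": index.chrom,
            "pos0": index.positions,
            "count_A": count_a,
            "count_B": count_b,
            "total_A": ta,
            "total_B": tb,
            "mre_A": zeros if mre_a is None else np.asarray(mre_a, dtype=np.int64),
            "mre_B": zeros if mre_b is None else np.asarray(mre_b, dtype=np.int64),
            "p_value": p_values,
            "q_value": adjust_qvalues(p_values),
        }
    )
    return df


DEFAULT_CUTOFFS = (1e-3, 1e-4, 1e-5, 1e-6, 1e-7, 1e-8)


def replicate_null_calibration(
    reads_a,
    reads_b,
    index: CpGIndex,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
    model: str = "multinomial",
    counts: str = "allocated",
    method: str = "fisher",
    **allocate_kwargs,
) -> tuple[CutoffReport, pd.DataFrame]:
    """Empirical type-I profile from a replicate pair sharing one truth.

    Runs the full allocation pipeline on both read sets, tests every site,
    and reports how many fall below each p-value cutoff — every such site is
    a false positive because the replicates share identical methylation.
    ``counts`` selects the allocated (deconvolved) or raw (every-covered-site)
    count vectors.
    """
    if counts not in ("allocated", "raw"):
        raise ValueError("counts must be 'allocated' or 'raw'")
    sc_a, _ = allocate_sample(reads_a, index, model=model, **allocate_kwargs)
    sc_b, _ = allocate_sample(reads_b, index, model=model, **allocate_kwargs)
    vec_a = getattr(sc_a, counts)
    vec_b = getattr(sc_b, counts)
    table = site_pair_table(index, vec_a, vec_b, method=method)
    report = cutoff_report(
        table["p_value"].to_numpy(), cutoffs, total_sites=index.n_sites
    )
    return report, table
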