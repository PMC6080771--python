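"""Latent-variable models allocating reads to single CpG sites.

Two models resolve which covered CpG site caused a read to be
immunoprecipitated:

* **single-contributor** — exactly one covered site contributed; conditioning
  a vector of independent per-site contribution indicators on a row sum of 1
  gives a multinomial law with probabilities ``p_j``. Fitted by EM over the
  latent site assignment of each read.
* **at-least-one contributor** — at least one covered site contributed;
  conditioning on a row sum >= 1 gives a truncated product-Bernoulli law with
  per-site probabilities ``q_j``. Fitted by the printed EM updates for that
  truncation.

Fitted parameters are converted to integer per-site read counts by rounding
``n * p_j`` (multinomial) or ``n * q_j / (1 - prod(1 - q_s))`` (Bernoulli).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cpgdecon.genome_io import CoverageMatrix, CpGIndex, build_coverage_matrix

_FLOOR = 1e-300  # clamp for span probabilities before log/division


@dataclass
class MultinomialParams:
    """Per-site contribution probabilities of the single-contributor model."""

    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 1:
            raise ValueError("p must be a vector")
        if np.any(self.p < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(self.p.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")

    def __len__(self) -> int:
        return self.p.size


@dataclass
class BernoulliParams:
    """Per-site contribution probabilities of the at-least-one model."""

    q: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 1:
            raise ValueError("q must be a vector")
        if np.any(self.q < 0) or np.any(self.q > 1):
            raise ValueError("probabilities must lie in [0, 1]")

    def __len__(self) -> int:
        return self.q.size


@dataclass
class EMResult:
    """Outcome of an EM fit.

    ``responsibilities`` is the dense (n, G) matrix of conditional
    expectations of the latent contribution indicators at the final
    parameters; ``loglik_trace`` holds the observed-data log-likelihood at
    each parameter iterate (including the final one).
    """

    params: MultinomialParams | BernoulliParams
    responsibilities: np.ndarray
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool
    degenerate: bool = False


@dataclass
class SiteCounts:
    """Integer read counts per CpG site of one region or sample."""

    site_positions: np.ndarray
    allocated: np.ndarray
    raw: np.ndarray = field(default=None)  # type: ignore[assignment]
    mre: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_reads: int = 0

    def __post_init__(self) -> None:
        self.site_positions = np.asarray(self.site_positions, dtype=np.int64)
        g = self.site_positions.size
        self.allocated = np.asarray(self.allocated, dtype=np.int64)
        if self.raw is None:
            self.raw = np.zeros(g, dtype=np.int64)
        if self.mre is None:
            self.mre = np.zeros(g, dtype=np.int64)
        self.raw = np.asarray(self.raw, dtype=np.int64)
        self.mre = np.asarray(self.mre, dtype=np.int64)
        for name in ("allocated", "raw", "mre"):
            if getattr(self, name).shape != (g,):
                raise ValueError(f"{name} must have one entry per site")


# ---------------------------------------------------------------------------
# likelihoods
# ---------------------------------------------------------------------------


def _span_sums(values: np.ndarray, spans: np.ndarray) -> np.ndarray:
    """Sum of ``values`` over each inclusive index span, via prefix sums."""
    cs = np.concatenate([[0.0], np.cumsum(values)])
    return cs[spans[:, 1] + 1] - cs[spans[:, 0]]


def loglik_multinomial(cm: CoverageMatrix, params: MultinomialParams) -> float:
    """Observed-data log-likelihood of the single-contributor model.

    Each read contributes ``log(sum of p over its covered span)``; a span of
    total probability zero yields ``-inf``.
    """
    if len(params) != cm.n_sites:
        raise ValueError("parameter dimension does not match region size")
    span_p = _span_sums(params.p, cm.spans)
    if np.any(span_p <= 0):
        return float("-inf")
    return float(np.log(span_p).sum())


def loglik_truncated_bernoulli(cm: CoverageMatrix, params: BernoulliParams) -> float:
    """Observed-data log-likelihood of the at-least-one-contributor model.

    The observation for read i is: indicators outside the covered span are 0
    and at least one indicator inside the span is 1, conditional on the row
    having at least one contributor anywhere in the region.
    """
    if len(params) != cm.n_sites:
        raise ValueError("parameter dimension does not match region size")
    log1mq = np.log(np.clip(1.0 - params.q, _FLOOR, 1.0))
    total = log1mq.sum()
    span_log = _span_sums(log1mq, cm.spans)
    p_span_any = np.clip(1.0 - np.exp(span_log), _FLOOR, 1.0)
    p_any = np.clip(1.0 - np.exp(total), _FLOOR, 1.0)
    ll = (total - span_log) + np.log(p_span_any) - np.log(p_any)
    return float(ll.sum())


# ---------------------------------------------------------------------------
# EM algorithms
# ---------------------------------------------------------------------------


def _init_probs(
    g: int,
    init,
    kind: str,
    rng: np.random.Generator | None,
) -> np.ndarray:
    if isinstance(init, MultinomialParams):
        return init.p.copy()
    if isinstance(init, BernoulliParams):
        return init.q.copy()
    if isinstance(init, np.ndarray) or isinstance(init, (list, tuple)):
        return np.asarray(init, dtype=float).copy()
    if init == "uniform":
        return np.full(g, 1.0 / g) if kind == "multinomial" else np.full(g, 0.5)
    if init == "random":
        if rng is None:
            rng = np.random.default_rng()
        if kind == "multinomial":
            return rng.dirichlet(np.ones(g))
        return rng.uniform(0.05, 0.95, size=g)
    raise ValueError(f"unknown init {init!r}")


def _multinomial_responsibilities(
    p: np.ndarray, spans: np.ndarray, n_sites: int
) -> np.ndarray:
    mask = (spans[:, :1] <= np.arange(n_sites)) & (np.arange(n_sites) <= spans[:, 1:])
    resp = np.where(mask, p, 0.0)
    denom = np.clip(resp.sum(axis=1, keepdims=True), _FLOOR, None)
    return resp / denom


def em_multinomial(
    cm: CoverageMatrix,
    init="uniform",
    tol: float = 1e-8,
    max_iter: int = 10_000,
    rng: np.random.Generator | None = None,
) -> EMResult:
    """Fit the single-contributor multinomial model by EM.

    E-step: responsibility of site j for read i is ``p_j`` renormalized over
    the read's covered span. M-step: ``p_j`` becomes the mean responsibility
    over reads. Iteration stops when the max-norm parameter change drops
    below ``tol``. A site covered by no read keeps probability 0 from the
    first iteration onward.
    """
    if cm.n < 1:
        raise ValueError("coverage matrix holds no reads")
    if tol <= 0:
        raise ValueError("tol must be positive")
    g, n = cm.n_sites, cm.n
    spans = cm.spans
    p = _init_probs(g, init, "multinomial", rng)
    if p.size != g:
        raise ValueError("init dimension does not match region size")
    k, l1 = spans[:, 0], spans[:, 1] + 1
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        span_p = np.clip(_span_sums(p, spans), _FLOOR, None)
        trace.append(float(np.log(span_p).sum()))
        # column sums of responsibilities without materializing the matrix:
        # sum over reads covering j of p_j / span_p_i
        w = 1.0 / span_p
        edge = np.bincount(k, weights=w, minlength=g + 1) - np.bincount(
            l1, weights=w, minlength=g + 1
        )
        # prefix-sum cancellation can leave tiny negatives; clamp and renorm
        col = np.clip(p * np.cumsum(edge[:g]), 0.0, None)
        p_new = col / n
        p_new /= p_new.sum()
        delta = float(np.max(np.abs(p_new - p)))
        p = p_new
        if delta < tol:
            converged = True
            break
    trace.append(loglik_multinomial(cm, MultinomialParams(p)))
    params = MultinomialParams(p)
    resp = _multinomial_responsibilities(p, spans, g)
    return EMResult(
        params=params,
        responsibilities=resp,
        loglik_trace=np.asarray(trace),
        n_iter=it,
        converged=converged,
    )


def _bernoulli_responsibilities(
    q: np.ndarray, spans: np.ndarray, n_sites: int
) -> np.ndarray:
    log1mq = np.log(np.clip(1.0 - q, _FLOOR, 1.0))
    span_any = np.clip(1.0 - np.exp(_span_sums(log1mq, spans)), _FLOOR, None)
    mask = (spans[:, :1] <= np.arange(n_sites)) & (np.arange(n_sites) <= spans[:, 1:])
    return np.where(mask, q / span_any[:, None], 0.0)


def em_truncated_bernoulli(
    cm: CoverageMatrix,
    init="uniform",
    tol: float = 1e-8,
    max_iter: int = 10_000,
    rng: np.random.Generator | None = None,
) -> EMResult:
    """Fit the at-least-one-contributor truncated-Bernoulli model.

    E-step: for a latent entry j of read i,
    ``x~_ij = q_j / (1 - prod_{s in span_i} (1 - q_s))``; entries outside the
    span stay at their observed 0. M-step (printed update, followed
    verbatim): ``q_j = (sum_i x~_ij) * (1 - prod_{s=1..G} (1 - q_s)) / n``.

    If all parameters collapse toward zero the fit is flagged degenerate and
    returned with ``converged=False``.
    """
    if cm.n < 1:
        raise ValueError("coverage matrix holds no reads")
    if tol <= 0:
        raise ValueError("tol must be positive")
    g, n = cm.n_sites, cm.n
    spans = cm.spans
    q = _init_probs(g, init, "bernoulli", rng)
    if q.size != g:
        raise ValueError("init dimension does not match region size")
    if np.any(q <= 0) or np.any(q >= 1):
        raise ValueError("initial q must lie strictly inside (0, 1)")
    trace = [loglik_truncated_bernoulli(cm, BernoulliParams(q))]
    converged = False
    degenerate = False
    it = 0
    for it in range(1, max_iter + 1):
        log1mq = np.log(np.clip(1.0 - q, _FLOOR, 1.0))
        span_any = np.clip(1.0 - np.exp(_span_sums(log1mq, spans)), _FLOOR, None)
        w = 1.0 / span_any
        edge = np.bincount(spans[:, 0], weights=w, minlength=g + 1) - np.bincount(
            spans[:, 1] + 1, weights=w, minlength=g + 1
        )
        col = np.clip(q * np.cumsum(edge[:g]), 0.0, None)
        p_any = np.clip(1.0 - np.exp(log1mq.sum()), _FLOOR, None)
        q_new = np.clip(col * p_any / n, 0.0, 1.0)
        delta = float(np.max(np.abs(q_new - q)))
        q = q_new
        trace.append(loglik_truncated_bernoulli(cm, BernoulliParams(q)))
        # collapse toward the all-zero fixed point: parameters vanish while
        # the observed likelihood stagnates (geometric decay never trips tol)
        if np.all(q < 1e-8) or (
            np.max(q) < 1e-3 and abs(trace[-1] - trace[-2]) < 1e-12
        ):
            degenerate = True
            break
        if delta < tol:
            converged = True
            break
    if not converged and not degenerate and np.max(q) < 1e-3:
        degenerate = True
    params = BernoulliParams(q)
    resp = _bernoulli_responsibilities(q, spans, g)
    return EMResult(
        params=params,
        responsibilities=resp,
        loglik_trace=np.asarray(trace),
        n_iter=it,
        converged=converged,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# count allocation
# ---------------------------------------------------------------------------


def _round_conserving(target: np.ndarray, total: int) -> np.ndarray:
    """Half-even rounding with largest-remainder correction to hit ``total``.

    Ties in the remainder ranking break deterministically toward the lower
    index.
    """
    counts = np.rint(target).astype(np.int64)
    resid = int(total - counts.sum())
    if resid != 0:
        frac = (target - counts) * np.sign(resid)
        order = np.argsort(-frac, kind="stable")
        for idx in order[: abs(resid)]:
            counts[idx] += int(np.sign(resid))
    return counts


def allocate_counts(result: EMResult, n: int, model: str) -> SiteCounts:
    """Turn fitted contribution probabilities into integer per-site counts.

    Multinomial: ``[n * p_j]`` with the rounding residual redistributed so
    counts sum to exactly ``n``. Bernoulli: ``[n * q_j / (1 - prod(1-q_s))]``
    rounded half-even, no conservation correction (the model does not
    partition reads among sites).
    """
    g = len(result.params)
    positions = np.arange(g, dtype=np.int64)  # placeholder when detached from a region
    if model == "multinomial":
        if not isinstance(result.params, MultinomialParams):
            raise TypeError("multinomial allocation requires MultinomialParams")
        counts = _round_conserving(n * result.params.p, n)
    elif model == "bernoulli":
        if not isinstance(result.params, BernoulliParams):
            raise TypeError("bernoulli allocation requires BernoulliParams")
        q = result.params.q
        denom = max(1.0 - np.prod(1.0 - q), _FLOOR)
        counts = np.rint(n * q / denom).astype(np.int64)
    else:
        raise ValueError(f"unknown model {model!r}")
    return SiteCounts(site_positions=positions, allocated=counts, n_reads=n)


def raw_counts(cm: CoverageMatrix) -> SiteCounts:
    """The no-deconvolution comparator: credit a read to every covered site."""
    g = cm.n_sites
    edge = np.zeros(g + 1, dtype=np.int64)
    np.add.at(edge, cm.spans[:, 0], 1)
    np.add.at(edge, cm.spans[:, 1] + 1, -1)
    raw = np.cumsum(edge[:-1])
    return SiteCounts(
        site_positions=cm.site_positions,
        allocated=np.zeros(g, dtype=np.int64),
        raw=raw,
        n_reads=cm.n,
    )


def allocate_region(
    cm: CoverageMatrix,
    model: str = "multinomial",
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> tuple[SiteCounts, EMResult]:
    """Fit the chosen model on one region and return allocated + raw counts."""
    fit = (
        em_multinomial(cm, tol=tol, max_iter=max_iter)
        if model == "multinomial"
        else em_truncated_bernoulli(cm, tol=tol, max_iter=max_iter)
    )
    counts = allocate_counts(fit, cm.n, model)
    counts.site_positions = cm.site_positions.copy()
    counts.raw = raw_counts(cm).raw
    return counts, fit


def allocate_sample(
    reads,
    index: CpGIndex,
    model: str = "multinomial",
    min_overlap: int = 1,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    mre_counts: np.ndarray | None = None,
) -> tuple[SiteCounts, dict]:
    """Allocate one sample's reads over every site of a segmented index.

    Sites in regions without reads keep count 0. Returns the genome-wide
    :class:`SiteCounts` plus a diagnostics dict (retained/discarded read
    tallies, per-region EM iteration counts, degenerate-fit region ids).
    """
    matrices, discarded = build_coverage_matrix(reads, index, min_overlap=min_overlap)
    g = index.n_sites
    allocated = np.zeros(g, dtype=np.int64)
    raw = np.zeros(g, dtype=np.int64)
    iters: dict[int, int] = {}
    degenerate_regions: list[int] = []
    n_retained = 0
    for cm in matrices:
        counts, fit = allocate_region(cm, model=model, tol=tol, max_iter=max_iter)
        offset = int(np.searchsorted(index.positions, cm.site_positions[0]))
        sl = slice(offset, offset + cm.n_sites)
        allocated[sl] = counts.allocated
        raw[sl] = counts.raw
        iters[cm.region_id] = fit.n_iter
        if fit.degenerate:
            degenerate_regions.append(cm.region_id)
        n_retained += cm.n
    counts = SiteCounts(
        site_positions=index.positions.copy(),
        allocated=allocated,
        raw=raw,
        mre=mre_counts,
        n_reads=n_retained,
    )
    diagnostics = {
        "n_retained": n_retained,
        "n_discarded": discarded,
        "em_iterations": iters,
        "degenerate_regions": degenerate_regions,
    }
    return counts, diagnostics


def write_counts_tsv(counts: SiteCounts, index: CpGIndex, path) -> None:
    """Write the per-sample count table.

    Columns: chrom, pos0, allocated_count, raw_count, mre_count, region_id,
    n_region (reads retained in the site's region).
    """
    import pandas as pd

    region_ids = (
        index.region_ids
        if index.region_ids is not None
        else np.zeros(index.n_sites, dtype=np.int64)
    )
    n_region = np.zeros(index.n_sites, dtype=np.int64)
    # region read total = sum of allocated counts in the region (multinomial
    # conservation); raw totals differ by construction
    for rid in np.unique(region_ids):
        mask = region_ids == rid
        n_region[mask] = counts.allocated[mask].sum()
    df = pd.DataFrame(
        {
            "chrom": index.chrom,
            "pos0": counts.site_positions,
            "allocated_count": counts.allocated,
            "raw_count": counts.raw,
            "mre_count": counts.mre,
            "region_id": region_ids,
            "n_region": n_region,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path) -> "pd.DataFrame":
    import pandas as pd

    return pd.read_csv(path, sep="\t")
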