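"""Generative simulation of MeDIP-seq and MRE-seq reads over synthetic CpG maps.

The MeDIP generative story: sonication breaks DNA at uniform random points,
a fragment is immunoprecipitated only if it carries at least one methylated
CpG, and the sequenced read is the fragment's 5' end truncated to the read
length. Which covered methylated site *contributed* (caused capture) is drawn
according to the configured model variant and recorded as ground truth.

Two placement schemes are available for the single-contributor variant:

* ``"fragment"`` — breakpoint first, then the contributor is drawn from the
  configured probabilities restricted to the covered methylated sites and
  renormalized (the sonication story).
* ``"contributor"`` — contributor site first (multinomial draw), then the
  read is placed uniformly among placements covering it. This samples spans
  exactly under the single-contributor observation law and is the right
  input for parameter-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cpgdecon.genome_io import CpGIndex, ReadInterval, segment_regions

_BATCH = 4096


@dataclass
class SimulationConfig:
    seed: int
    n_regions: int = 1
    sites_per_region: int = 5
    gap: int = 30
    gap_jitter: int = 0
    meth_prob: float = 1.0
    frag_len: int = 200
    read_len: int = 50
    read_len_b: int | None = None  # sample-B read length in replicate pairs
    depth: int = 100
    depth_law: str = "fixed"  # "fixed" | "poisson" (per-region read count)
    model: str = "single"  # "single" | "at-least-one"
    placement: str = "fragment"  # "fragment" | "contributor"
    capture_prob: float = 1.0
    q_contrib: float = 0.3
    mre_depth: float = 5.0
    mre_availability: float = 0.8
    chrom: str = "chrSIM"
    region_spacing: int = 5000
    sample: str = ""

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for name in ("gap", "frag_len", "read_len", "region_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.gap_jitter < self.gap:
            raise ValueError("gap_jitter must lie in [0, gap)")
        for name in ("meth_prob", "capture_prob", "q_contrib", "mre_availability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.depth_law not in ("fixed", "poisson"):
            raise ValueError("depth_law must be 'fixed' or 'poisson'")
        if self.model not in ("single", "at-least-one"):
            raise ValueError("model must be 'single' or 'at-least-one'")
        if self.placement not in ("fragment", "contributor"):
            raise ValueError("placement must be 'fragment' or 'contributor'")
        if self.model == "at-least-one" and self.placement == "contributor":
            raise ValueError("contributor-first placement applies to the single model")
        if self.region_spacing <= max(
            self.read_len, self.read_len_b or 0, self.frag_len
        ):
            raise ValueError("region_spacing must exceed read and fragment length")

    @property
    def max_read_len(self) -> int:
        return max(self.read_len, self.read_len_b or 0)


@dataclass
class GroundTruth:
    """Truth channel for recovery tests.

    ``params`` holds the per-site contribution probabilities actually used
    (zero at unmethylated sites); ``contributors`` records, per read, the
    global site indices that caused its capture.
    """

    states: np.ndarray
    params: np.ndarray
    contributors: list = field(default_factory=list)
    model: str = "single"


def _gaps(config: SimulationConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """Inter-site gaps: fixed, or uniform in [gap - jitter, gap + jitter]."""
    if n <= 0:
        return np.zeros(0, dtype=np.int64)
    if config.gap_jitter == 0:
        return np.full(n, config.gap, dtype=np.int64)
    return rng.integers(
        config.gap - config.gap_jitter, config.gap + config.gap_jitter + 1, size=n
    )


def _covered_span(positions: np.ndarray, start: int, read_len: int) -> tuple[int, int]:
    lo = int(np.searchsorted(positions, start - 1, side="left"))
    hi = int(np.searchsorted(positions, start + read_len - 1, side="right"))
    return lo, hi


def _region_params(
    states: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Default true contribution probabilities over one region's sites."""
    params = np.zeros(states.size)
    meth = np.flatnonzero(states)
    if meth.size == 0:
        return params
    if config.model == "single":
        params[meth] = rng.dirichlet(np.ones(meth.size) * 5.0)
    else:
        params[meth] = config.q_contrib
    return params


def _draw_reads_region(
    positions: np.ndarray,
    states: np.ndarray,
    params: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    read_len: int | None = None,
) -> tuple[np.ndarray, list]:
    """Draw read start coordinates and per-read contributor lists for one region."""
    meth = np.flatnonzero(states)
    n_target = (
        config.depth
        if config.depth_law == "fixed"
        else int(rng.poisson(config.depth))
    )
    if meth.size == 0 or n_target == 0:
        return np.zeros(0, dtype=np.int64), []
    L = read_len or config.read_len
    if config.placement == "contributor":
        # contributor site first, read placed uniformly among covering starts
        p_meth = params[meth] / params[meth].sum()
        contributors = rng.choice(meth, size=n_target, p=p_meth)
        offsets = rng.integers(-L + 1, 2, size=n_target)
        starts = positions[contributors] + offsets
        return starts.astype(np.int64), [int(c) for c in contributors]
    lo_start = int(positions[0]) - L + 1
    hi_start = int(positions[-1]) + 1  # inclusive; any start here covers >=1 site
    starts_out: list[np.ndarray] = []
    contribs: list = []
    n_kept = 0
    site_idx = np.arange(positions.size)
    while n_kept < n_target:
        starts = rng.integers(lo_start, hi_start + 1, size=_BATCH)
        lo = np.searchsorted(positions, starts - 1, side="left")
        hi = np.searchsorted(positions, starts + L - 1, side="right")
        covered = (lo[:, None] <= site_idx) & (site_idx < hi[:, None])
        cov_meth = covered & states
        keep = cov_meth.any(axis=1)
        if config.capture_prob < 1.0:
            keep &= rng.random(_BATCH) < config.capture_prob
        starts, cov_meth = starts[keep], cov_meth[keep]
        if starts.size == 0:
            continue
        if config.model == "single":
            w = np.where(cov_meth, params, 0.0)
            rowsum = w.sum(axis=1)
            u = rng.random(starts.size) * rowsum
            chosen = (np.cumsum(w, axis=1) > u[:, None]).argmax(axis=1)
            batch_contribs: list = [int(c) for c in chosen]
        else:
            q = np.where(cov_meth, params, 0.0)
            draws = rng.random(q.shape) < q
            # truncation: resample rows until at least one site contributes
            bad = ~draws.any(axis=1)
            while bad.any():
                draws[bad] = rng.random((int(bad.sum()), q.shape[1])) < q[bad]
                bad = ~draws.any(axis=1)
            batch_contribs = [np.flatnonzero(row) for row in draws]
        take = min(n_target - n_kept, starts.size)
        starts_out.append(starts[:take])
        contribs.extend(batch_contribs[:take])
        n_kept += take
    return np.concatenate(starts_out).astype(np.int64), contribs


def simulate_region(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    states: np.ndarray | None = None,
    params: np.ndarray | None = None,
    start: int = 1000,
) -> tuple[list[ReadInterval], CpGIndex, GroundTruth]:
    """Simulate one region of CpG sites and its captured MeDIP reads.

    ``states``/``params`` override the random methylation states and true
    contribution probabilities. A region with no methylated site yields zero
    reads (nothing immunoprecipitates).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    positions = start + np.concatenate(
        [[0], np.cumsum(_gaps(config, rng, config.sites_per_region - 1))]
    ).astype(np.int64)
    if states is None:
        states = rng.random(config.sites_per_region) < config.meth_prob
    states = np.asarray(states, dtype=bool)
    if params is None:
        params = _region_params(states, config, rng)
    params = np.asarray(params, dtype=float)
    starts, contribs = _draw_reads_region(positions, states, params, config, rng)
    reads = [
        ReadInterval(config.chrom, int(s), int(s) + config.read_len, sample=config.sample)
        for s in starts
    ]
    index = segment_regions(
        CpGIndex(config.chrom, positions), link_dist=config.read_len
    )
    truth = GroundTruth(
        states=states, params=params, contributors=contribs, model=config.model
    )
    return reads, index, truth


def _genome_skeleton(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Positions, methylation states and true params for all regions."""
    g = config.sites_per_region
    positions = np.empty(config.n_regions * g, dtype=np.int64)
    states = np.empty(config.n_regions * g, dtype=bool)
    params = np.empty(config.n_regions * g, dtype=float)
    pos0 = 1000
    for r in range(config.n_regions):
        sl = slice(r * g, (r + 1) * g)
        positions[sl] = pos0 + np.concatenate([[0], np.cumsum(_gaps(config, rng, g - 1))])
        states[sl] = rng.random(g) < config.meth_prob
        params[sl] = _region_params(states[sl], config, rng)
        pos0 = int(positions[sl][-1]) + config.region_spacing
    return positions, states, params


def _draw_genome_reads(
    positions: np.ndarray,
    states: np.ndarray,
    params: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    sample: str,
    read_len: int | None = None,
) -> tuple[list[ReadInterval], list]:
    g = config.sites_per_region
    rl = read_len or config.read_len
    reads: list[ReadInterval] = []
    contribs: list = []
    for r in range(config.n_regions):
        sl = slice(r * g, (r + 1) * g)
        starts, c = _draw_reads_region(
            positions[sl], states[sl], params[sl], config, rng, read_len=rl
        )
        reads.extend(
            ReadInterval(config.chrom, int(s), int(s) + rl, sample=sample)
            for s in starts
        )
        offset = r * g
        for item in c:
            if isinstance(item, np.ndarray):
                contribs.append(item + offset)
            else:
                contribs.append(item + offset)
    return reads, contribs


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[ReadInterval], CpGIndex, GroundTruth]:
    """Simulate ``n_regions`` well-separated regions and their MeDIP reads."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    positions, states, params = _genome_skeleton(config, rng)
    reads, contribs = _draw_genome_reads(
        positions, states, params, config, rng, config.sample
    )
    index = segment_regions(CpGIndex(config.chrom, positions), config.max_read_len)
    truth = GroundTruth(
        states=states, params=params, contributors=contribs, model=config.model
    )
    return reads, index, truth


def simulate_mre(
    config: SimulationConfig,
    truth: GroundTruth,
    index: CpGIndex,
    rng: np.random.Generator | None = None,
) -> list[ReadInterval]:
    """Simulate MRE-seq reads: enzymes cut only at unmethylated CpGs.

    Each unmethylated site is enzyme-compatible with probability
    ``mre_availability``; compatible sites receive a Poisson(``mre_depth``)
    number of reads anchored exactly at the site. Methylated sites never
    produce reads.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    reads: list[ReadInterval] = []
    for pos, meth in zip(index.positions, truth.states):
        if meth or rng.random() >= config.mre_availability:
            continue
        for _ in range(int(rng.poisson(config.mre_depth))):
            reads.append(
                ReadInterval(
                    index.chrom, int(pos), int(pos) + config.read_len, sample=config.sample
                )
            )
    return reads


def simulate_replicate_pair(
    config: SimulationConfig,
) -> tuple[list[ReadInterval], list[ReadInterval], CpGIndex, GroundTruth]:
    """Two independent read draws from one shared ground truth.

    The synthetic analogue of comparing biological replicates: any site
    called differentially methylated between the two draws is a false
    positive.
    """
    rng = np.random.default_rng(config.seed)
    positions, states, params = _genome_skeleton(config, rng)
    rng_a, rng_b = rng.spawn(2)
    reads_a, contribs = _draw_genome_reads(positions, states, params, config, rng_a, "A")
    reads_b, _ = _draw_genome_reads(
        positions, states, params, config, rng_b, "B", read_len=config.read_len_b
    )
    index = segment_regions(CpGIndex(config.chrom, positions), config.max_read_len)
    truth = GroundTruth(
        states=states, params=params, contributors=contribs, model=config.model
    )
    return reads_a, reads_b, index, truth


def standard_null_config(seed: int = 20240807, n_regions: int = 2000) -> SimulationConfig:
    """The package's standard replicate-null benchmark (10^4 CpG sites).

    Well-separated 5-site regions, 45 +- 4 bp gaps against 50 bp reads (about
    one read in ten covers two sites), all sites methylated, Poisson read
    depth of 150 per region. Used for type-I-error calibration of the
    two-sample pipeline.
    """
    return SimulationConfig(
        seed=seed,
        n_regions=n_regions,
        sites_per_region=5,
        gap=45,
        gap_jitter=4,
        read_len=50,
        meth_prob=1.0,
        depth=150,
        depth_law="poisson",
        model="single",
    )
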