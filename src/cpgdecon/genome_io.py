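"""Genomic input handling: CpG site discovery, region segmentation, and
construction of per-region read-by-site coverage matrices.

Coordinates are 0-based half-open throughout (BED convention). A CpG site is
recorded at the position of the C of the forward-strand ``CG`` dinucleotide;
reads from either strand are counted against that position.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Methylation-sensitive restriction enzyme recognition sequences with the
#: cut-site CpG starting at offset 1 (HpaII C^CGG, Hin6I G^CGC, AciI C^CGC).
DEFAULT_MRE_MOTIFS: tuple[str, ...] = ("CCGG", "GCGC", "CCGC")

_CG_RE = re.compile("CG")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class CpGIndex:
    """Ordered CpG positions on one chromosome, optionally segmented into
    regions of mutually reachable sites.

    ``region_ids`` are consecutive integers in genomic order; two neighboring
    sites share a region iff their distance does not exceed the linking
    distance used at segmentation time.
    """

    chrom: str
    positions: np.ndarray
    region_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.positions.ndim != 1:
            raise ValueError("positions must be one-dimensional")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("CpG positions must be strictly increasing")
        if self.region_ids is not None:
            self.region_ids = np.asarray(self.region_ids, dtype=np.int64)
            if self.region_ids.shape != self.positions.shape:
                raise ValueError("region_ids must match positions in length")

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    @property
    def n_regions(self) -> int:
        if self.region_ids is None or self.region_ids.size == 0:
            return 0
        return int(self.region_ids[-1]) + 1


@dataclass(frozen=True)
class ReadInterval:
    """A mapped read as a genomic interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    sample: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")


@dataclass
class CoverageMatrix:
    """Per-region binary observation matrix in sparse span form.

    Row ``i`` covers the contiguous site-index range ``spans[i] = (k_i, l_i)``
    (inclusive) of the region's ``site_positions``; entries inside the span
    are the EM's missing data, entries outside are observed zeros.
    """

    region_id: int
    chrom: str
    site_positions: np.ndarray
    spans: np.ndarray

    def __post_init__(self) -> None:
        self.site_positions = np.asarray(self.site_positions, dtype=np.int64)
        self.spans = np.asarray(self.spans, dtype=np.int64).reshape(-1, 2)
        if self.spans.size:
            k, l = self.spans[:, 0], self.spans[:, 1]
            if np.any(k > l):
                raise ValueError("every read must cover at least one site")
            if np.any(k < 0) or np.any(l >= self.n_sites):
                raise ValueError("span indices out of range")

    @property
    def n(self) -> int:
        """Number of retained reads."""
        return int(self.spans.shape[0])

    @property
    def n_sites(self) -> int:
        return int(self.site_positions.size)

    def coverage_mask(self) -> np.ndarray:
        """Dense boolean (n, G) matrix: True where site j is covered by read i."""
        j = np.arange(self.n_sites)
        return (self.spans[:, :1] <= j) & (j <= self.spans[:, 1:])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def find_cpg_sites(
    sequence: str,
    chrom: str = "chr1",
    blacklist: Sequence[tuple[int, int]] | None = None,
) -> CpGIndex:
    """Locate forward-strand ``CG`` dinucleotides in a reference sequence.

    The scan is case-insensitive; characters other than A/C/G/T (including N)
    simply never match, so N-containing stretches yield no sites. Sites whose
    2-bp dinucleotide overlaps a blacklist interval are removed.
    """
    seq = sequence.upper()
    positions = np.fromiter(
        (m.start() for m in _CG_RE.finditer(seq)), dtype=np.int64
    )
    if blacklist is not None and positions.size:
        keep = np.ones(positions.size, dtype=bool)
        for bstart, bend in blacklist:
            keep &= (positions + 2 <= bstart) | (positions >= bend)
        positions = positions[keep]
    return CpGIndex(chrom=chrom, positions=positions)


def segment_regions(index: CpGIndex, link_dist: int) -> CpGIndex:
    """Assign region ids by single-linkage chaining of neighboring sites.

    Consecutive sites whose gap is at most ``link_dist`` share a region; an
    isolated site forms a singleton region.
    """
    if link_dist <= 0:
        raise ValueError("link_dist must be positive")
    pos = index.positions
    if pos.size == 0:
        return CpGIndex(index.chrom, pos, np.zeros(0, dtype=np.int64))
    region_ids = np.concatenate(
        [[0], np.cumsum(np.diff(pos) > link_dist)]
    ).astype(np.int64)
    return CpGIndex(index.chrom, pos, region_ids)


def _covered_range(
    positions: np.ndarray, start: int, end: int, min_overlap: int
) -> tuple[int, int]:
    """Half-open index range of sites covered by read [start, end).

    A site at ``pos`` (dinucleotide ``[pos, pos + 2)``) is covered when the
    overlap with the read is at least ``min_overlap`` basepairs (1 or 2).
    """
    lo = int(np.searchsorted(positions, start - (2 - min_overlap), side="left"))
    hi = int(np.searchsorted(positions, end - min_overlap, side="right"))
    return lo, hi


def build_coverage_matrix(
    reads: Iterable[ReadInterval],
    index: CpGIndex,
    min_overlap: int = 1,
) -> tuple[list[CoverageMatrix], int]:
    """Build one coverage matrix per region holding at least one read.

    Reads covering no CpG site are discarded and tallied; the function returns
    ``(matrices, n_discarded)``. A read whose covered sites straddle two
    regions is a hard error: it means the linking distance used for
    segmentation is smaller than the read length.
    """
    if index.region_ids is None:
        raise ValueError("index must be segmented (run segment_regions first)")
    if min_overlap not in (1, 2):
        raise ValueError("min_overlap must be 1 or 2")
    positions = index.positions
    region_ids = index.region_ids
    per_region: dict[int, list[tuple[int, int]]] = {}
    discarded = 0
    for read in reads:
        if read.chrom != index.chrom:
            discarded += 1
            continue
        lo, hi = _covered_range(positions, read.start, read.end, min_overlap)
        if hi <= lo:
            discarded += 1
            continue
        rid_lo, rid_hi = int(region_ids[lo]), int(region_ids[hi - 1])
        if rid_lo != rid_hi:
            raise ValueError(
                f"read {read.chrom}:{read.start}-{read.end} covers sites in "
                f"regions {rid_lo} and {rid_hi}; re-segment with a larger "
                f"--link-dist (at least the read length)"
            )
        # span indices are relative to the region's first site
        first = int(np.searchsorted(region_ids, rid_lo, side="left"))
        per_region.setdefault(rid_lo, []).append((lo - first, hi - 1 - first))
    matrices = []
    for rid in sorted(per_region):
        in_region = region_ids == rid
        matrices.append(
            CoverageMatrix(
                region_id=rid,
                chrom=index.chrom,
                site_positions=positions[in_region],
                spans=np.array(per_region[rid], dtype=np.int64),
            )
        )
    if discarded:
        logger.info("discarded %d reads covering no CpG site", discarded)
    return matrices, discarded


def mre_site_counts(
    mre_reads: Iterable[ReadInterval],
    index: CpGIndex,
    enzyme_motifs: Sequence[str] = DEFAULT_MRE_MOTIFS,
    reference: str | None = None,
    anchor_window: int = 2,
) -> tuple[np.ndarray, int]:
    """Count methylation-sensitive restriction enzyme reads per CpG site.

    Each read is assigned to the single eligible CpG site nearest its 5'
    start (ties toward the lower coordinate), provided the site lies within
    ``anchor_window`` bp of the start; other reads are discarded and tallied.
    When a reference sequence is supplied, eligible sites are restricted to
    those whose 4-bp context ``[pos - 1, pos + 3)`` matches one of the enzyme
    recognition motifs (cut-site CpG at motif offset 1).

    Returns ``(counts, n_discarded)`` with one count per site of ``index``.
    """
    positions = index.positions
    eligible = np.ones(positions.size, dtype=bool)
    if reference is not None:
        seq = reference.upper()
        motifs = {m.upper() for m in enzyme_motifs}
        for i, pos in enumerate(positions):
            eligible[i] = pos >= 1 and seq[pos - 1 : pos + 3] in motifs
    anchor_pos = positions[eligible]
    anchor_idx = np.flatnonzero(eligible)
    counts = np.zeros(positions.size, dtype=np.int64)
    discarded = 0
    for read in mre_reads:
        if read.chrom != index.chrom or anchor_pos.size == 0:
            discarded += 1
            continue
        j = int(np.searchsorted(anchor_pos, read.start))
        best, best_dist = -1, anchor_window + 1
        for cand in (j - 1, j):
            if 0 <= cand < anchor_pos.size:
                dist = abs(int(anchor_pos[cand]) - read.start)
                if dist < best_dist:
                    best, best_dist = cand, dist
        if best < 0:
            discarded += 1
        else:
            counts[anchor_idx[best]] += 1
    if discarded:
        logger.info("discarded %d MRE reads anchoring no CpG site", discarded)
    return counts, discarded


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def read_bed(path: str | Path, sample: str = "") -> list[ReadInterval]:
    """Read intervals from a BED3/BED6 file (extra columns ignored)."""
    reads: list[ReadInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            reads.append(ReadInterval(fields[0], start, end, sample=sample))
    return reads


def write_bed(reads: Sequence[ReadInterval], path: str | Path) -> None:
    """Write intervals as BED6 (name=sample, score=0, strand=+)."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.sample or '.'}\t0\t+\n")


def read_blacklist(path: str | Path) -> list[tuple[int, int]]:
    """Read a BED3 blacklist into (start, end) interval pairs."""
    return [(r.start, r.end) for r in read_bed(path)]


def read_sam(path: str | Path, sample: str = "") -> list[ReadInterval]:
    """Read mapped reads from a SAM/BAM file via pysam."""
    import pysam

    reads = []
    with pysam.AlignmentFile(str(path)) as af:
        for aln in af.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            reads.append(
                ReadInterval(
                    aln.reference_name,
                    aln.reference_start,
                    aln.reference_end,
                    sample=sample,
                )
            )
    return reads


def write_sites_tsv(index: CpGIndex, path: str | Path) -> None:
    """Write a CpG site table: chrom, pos0 and (if segmented) region_id."""
    df = pd.DataFrame({"chrom": index.chrom, "pos0": index.positions})
    if index.region_ids is not None:
        df["region_id"] = index.region_ids
    df.to_csv(path, sep="\t", index=False)


def read_sites_tsv(path: str | Path) -> CpGIndex:
    """Read a CpG site table written by :func:`write_sites_tsv`."""
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        return CpGIndex("chr1", np.zeros(0, dtype=np.int64))
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError("site tables are per-chromosome; found " f"{list(chroms)}")
    region_ids = df["region_id"].to_numpy() if "region_id" in df else None
    return CpGIndex(str(chroms[0]), df["pos0"].to_numpy(), region_ids)


def write_coverage_tsv(matrices: Sequence[CoverageMatrix], path: str | Path) -> None:
    """Dump coverage matrices to TSV.

    Two record types share the file: ``R`` rows describe a region
    (region_id, chrom, comma-joined site positions) and ``D`` rows one read
    each (region_id, k_i, l_i).
    """
    with open(path, "w") as fh:
        fh.write("record\tregion_id\tchrom_or_k\tpositions_or_l\n")
        for cm in matrices:
            joined = ",".join(str(p) for p in cm.site_positions)
            fh.write(f"R\t{cm.region_id}\t{cm.chrom}\t{joined}\n")
            for k, l in cm.spans:
                fh.write(f"D\t{cm.region_id}\t{k}\t{l}\n")


def read_coverage_tsv(path: str | Path) -> list[CoverageMatrix]:
    """Re-read a coverage dump written by :func:`write_coverage_tsv`."""
    regions: dict[int, tuple[str, np.ndarray]] = {}
    spans: dict[int, list[tuple[int, int]]] = {}
    order: list[int] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("record\t"):
            raise ValueError(f"{path}: not a coverage dump")
        for line in fh:
            rec, rid_s, a, b = line.rstrip("\n").split("\t")
            rid = int(rid_s)
            if rec == "R":
                regions[rid] = (a, np.array([int(x) for x in b.split(",")]))
                spans[rid] = []
                order.append(rid)
            elif rec == "D":
                spans[rid].append((int(a), int(b)))
            else:
                raise ValueError(f"{path}: unknown record type {rec!r}")
    return [
        CoverageMatrix(
            region_id=rid,
            chrom=regions[rid][0],
            site_positions=regions[rid][1],
            spans=np.array(spans[rid], dtype=np.int64).reshape(-1, 2),
        )
        for rid in order
    ]


def load_reference(path: str | Path) -> dict[str, str]:
    """Load chromosome sequences from a FASTA file via pyfaidx."""
    from pyfaidx import Fasta

    with Fasta(str(path)) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}
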