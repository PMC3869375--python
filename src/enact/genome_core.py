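"""Genomic coordinate primitives, interval arithmetic and plain-text I/O.

All coordinates are 0-based half-open (BED convention).  The module provides
the small vocabulary the rest of the pipeline is written in: intervals,
tag libraries (mapped reads reduced to single shifted positions), TSS and
gene-model annotation, overlap queries, nearest-TSS assignment, and
BED/bedGraph/WIG readers and writers.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "GenomicInterval",
    "TagLibrary",
    "TSSRecord",
    "GeneModel",
    "overlaps",
    "interval_center",
    "merge_intervals",
    "check_disjoint",
    "overlap_partition",
    "nearest_tss",
    "read_bed",
    "write_bed",
    "read_annotation",
    "read_chrom_sizes",
    "coverage_track",
    "write_bedgraph",
    "write_wig",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: Optional[str] = None
    score: Optional[float] = None
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.chrom or any(c.isspace() for c in self.chrom):
            raise ValueError(f"invalid chromosome name: {self.chrom!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand is not None and self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand: {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def sort_key(self) -> Tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def interval_center(iv: GenomicInterval) -> int:
    """Midpoint of an interval, rounded down."""
    return (iv.start + iv.end) // 2


@dataclass(frozen=True)
class TSSRecord:
    """A transcription start site of a gene."""

    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"negative TSS for {self.gene_id}")


@dataclass(frozen=True)
class GeneModel:
    """A gene with its exon structure; expression is quantified on the
    union of exons."""

    gene_id: str
    chrom: str
    strand: str
    exons: Tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise ValueError(f"exon off-chromosome in gene {self.gene_id}")

    @property
    def tss(self) -> int:
        if self.strand == "-":
            return max(ex.end for ex in self.exons) - 1
        return min(ex.start for ex in self.exons)

    @property
    def exon_union(self) -> List[GenomicInterval]:
        return merge_intervals(self.exons)

    @property
    def exonic_length(self) -> int:
        return sum(iv.length for iv in self.exon_union)

    def tss_record(self) -> TSSRecord:
        return TSSRecord(self.gene_id, self.chrom, self.tss, self.strand)


class TagLibrary:
    """A ChIP/RNA tag library: per-chromosome sorted arrays of shifted tag
    positions.

    A *tag* is a mapped read reduced to a single base-pair position (the
    5' end shifted by half the fragment size toward the fragment middle).
    """

    def __init__(self, positions: Mapping[str, Sequence[int]],
                 fragment_size: int = 150) -> None:
        self.positions: Dict[str, np.ndarray] = {}
        for chrom, pos in positions.items():
            arr = np.asarray(pos, dtype=np.int64)
            arr = np.sort(arr)
            if arr.size:
                self.positions[chrom] = arr
        self.fragment_size = int(fragment_size)

    @property
    def total_count(self) -> int:
        return int(sum(a.size for a in self.positions.values()))

    def count_in(self, chrom: str, start: int, end: int) -> int:
        """Number of tags with position in ``[start, end)``."""
        arr = self.positions.get(chrom)
        if arr is None:
            return 0
        return int(np.searchsorted(arr, end) - np.searchsorted(arr, start))

    def chroms(self) -> List[str]:
        return sorted(self.positions)


# ---------------------------------------------------------------------------
# interval arithmetic
# ---------------------------------------------------------------------------

def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share at least 1 bp."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def merge_intervals(ivs: Iterable[GenomicInterval]) -> List[GenomicInterval]:
    """Union of intervals: sorted, overlapping/adjacent-overlapping members
    merged.  Touching (half-open adjacent) intervals stay separate unless
    they actually share a base."""
    ivs = sorted(ivs, key=GenomicInterval.sort_key)
    out: List[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start < out[-1].end:
            prev = out[-1]
            if iv.end > prev.end:
                out[-1] = GenomicInterval(prev.chrom, prev.start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def check_disjoint(ivs: Sequence[GenomicInterval], label: str = "set") -> None:
    """Raise if any two members of a set overlap (sets fed to overlap
    counting must be merged first so counts are well defined)."""
    ordered = sorted(ivs, key=GenomicInterval.sort_key)
    for prev, cur in zip(ordered, ordered[1:]):
        if prev.chrom == cur.chrom and cur.start < prev.end:
            raise ValueError(
                f"{label} contains overlapping members "
                f"{prev.chrom}:{prev.start}-{prev.end} and "
                f"{cur.chrom}:{cur.start}-{cur.end}; merge the set first"
            )


class _IntervalIndex:
    """Sorted per-chromosome index for 1-bp overlap queries against a set
    of internally disjoint intervals."""

    def __init__(self, ivs: Sequence[GenomicInterval]):
        self.by_chrom: Dict[str, Tuple[List[int], List[int], List[int]]] = {}
        order = sorted(range(len(ivs)), key=lambda i: ivs[i].sort_key())
        for i in order:
            iv = ivs[i]
            starts, ends, idx = self.by_chrom.setdefault(iv.chrom, ([], [], []))
            starts.append(iv.start)
            ends.append(iv.end)
            idx.append(i)

    def query(self, iv: GenomicInterval) -> List[int]:
        """Indices (into the original sequence) of members overlapping iv."""
        entry = self.by_chrom.get(iv.chrom)
        if entry is None:
            return []
        starts, ends, idx = entry
        # disjoint + sorted: candidates are a contiguous run
        lo = bisect.bisect_right(ends, iv.start)
        hi = bisect.bisect_left(starts, iv.end)
        return [idx[j] for j in range(lo, hi)]


def overlap_partition(
    set_a: Sequence[GenomicInterval],
    set_b: Sequence[GenomicInterval],
) -> Tuple[int, int, int, Dict[int, List[int]]]:
    """Venn-style overlap partition of two internally disjoint interval sets.

    Returns ``(n_both, n_a_only, n_b_only, mapping)`` where ``n_both`` is the
    number of A members overlapping at least one B member (counted per A
    member), ``n_a_only``/``n_b_only`` the members of each set overlapping
    nothing in the other, and ``mapping`` maps each A index to the indices of
    the B members it overlaps.
    """
    check_disjoint(set_a, "set A")
    check_disjoint(set_b, "set B")
    index_b = _IntervalIndex(set_b)
    mapping: Dict[int, List[int]] = {}
    hit_b: set = set()
    n_both = 0
    for i, iv in enumerate(set_a):
        hits = index_b.query(iv)
        if hits:
            n_both += 1
            mapping[i] = sorted(hits)
            hit_b.update(hits)
    n_a_only = len(set_a) - n_both
    n_b_only = len(set_b) - len(hit_b)
    return n_both, n_a_only, n_b_only, mapping


def nearest_tss(
    center: Tuple[str, int],
    tss_list: Sequence[TSSRecord],
    max_dist: int,
) -> Optional[Tuple[str, int]]:
    """Nearest TSS on the same chromosome within ``max_dist`` bp.

    Returns ``(gene_id, signed_distance)`` with distance ``tss - center``
    (positive = TSS to the right), or None if no TSS lies within range.
    Exact distance ties go to the lexicographically smaller gene_id.
    """
    if not tss_list:
        raise ValueError("empty TSS list")
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    chrom, pos = center
    best: Optional[Tuple[int, str, int]] = None  # (|d|, gene_id, signed d)
    for rec in tss_list:
        if rec.chrom != chrom:
            continue
        d = rec.tss - pos
        key = (abs(d), rec.gene_id, d)
        if best is None or key < best:
            best = key
    if best is None or best[0] > max_dist:
        return None
    return best[1], best[2]


# ---------------------------------------------------------------------------
# plain-text I/O
# ---------------------------------------------------------------------------

def read_bed(path) -> List[GenomicInterval]:
    """Read a 3-6 column BED file into intervals (0-based half-open)."""
    out: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed BED line {lineno}: {line!r}")
            try:
                chrom = fields[0]
                start = int(fields[1])
                end = int(fields[2])
                name = fields[3] if len(fields) > 3 else None
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else None
                strand = fields[5] if len(fields) > 5 and fields[5] != "." else None
                out.append(GenomicInterval(chrom, start, end, strand=strand,
                                           score=score, name=name))
            except ValueError as exc:
                raise ValueError(f"{path}: malformed BED line {lineno}: {exc}") from exc
    return out


def write_bed(ivs: Iterable[GenomicInterval], path) -> None:
    """Write intervals as BED, emitting as many columns as are populated."""
    with open(path, "w") as fh:
        for iv in ivs:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand is not None:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None or iv.strand is not None:
                fields.append(f"{iv.score:g}" if iv.score is not None else "0")
            if iv.strand is not None:
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


def read_annotation(path) -> List[GeneModel]:
    """Read a tab-separated gene table.

    Columns: gene_id, chrom, strand, tss, exon_starts, exon_ends where the
    last two are comma-separated lists of equal length.
    """
    genes: List[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: malformed annotation line {lineno}")
            gene_id, chrom, strand, _tss, starts_s, ends_s = fields[:6]
            starts = [int(x) for x in starts_s.rstrip(",").split(",")]
            ends = [int(x) for x in ends_s.rstrip(",").split(",")]
            if len(starts) != len(ends):
                raise ValueError(
                    f"{path}: line {lineno}: exon_starts/exon_ends length mismatch")
            exons = tuple(GenomicInterval(chrom, s, e) for s, e in zip(starts, ends))
            genes.append(GeneModel(gene_id, chrom, strand, exons))
    return genes


def write_annotation(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\texon_starts\texon_ends\n")
        for g in genes:
            starts = ",".join(str(ex.start) for ex in g.exons)
            ends = ",".join(str(ex.end) for ex in g.exons)
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t{starts}\t{ends}\n")


def read_chrom_sizes(path) -> Dict[str, int]:
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            chrom, size = line.split("\t")[:2]
            sizes[chrom] = int(size)
    return sizes


# ---------------------------------------------------------------------------
# coverage export
# ---------------------------------------------------------------------------

def coverage_track(
    tags: TagLibrary,
    bin_size: int = 10,
) -> List[Tuple[str, int, int, float]]:
    """Binned, depth-normalized coverage records (bedGraph tuples).

    Per-bin tag counts are scaled to reads-per-million (1e6 / total tag
    count); bins with zero tags are omitted.  An empty library yields an
    empty track.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    total = tags.total_count
    if total == 0:
        return []
    scale = 1e6 / total
    records: List[Tuple[str, int, int, float]] = []
    for chrom in tags.chroms():
        arr = tags.positions[chrom]
        bins = arr // bin_size
        uniq, counts = np.unique(bins, return_counts=True)
        for b, c in zip(uniq.tolist(), counts.tolist()):
            records.append((chrom, b * bin_size, (b + 1) * bin_size, c * scale))
    return records


def write_bedgraph(records: Iterable[Tuple[str, int, int, float]], path,
                   track_name: str = "coverage") -> None:
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track_name}"\n')
        for chrom, start, end, value in records:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


def write_wig(records: Sequence[Tuple[str, int, int, float]], path,
              bin_size: int, track_name: str = "coverage") -> None:
    """Fixed-step WIG export of a binned coverage track (1-based starts per
    the WIG format)."""
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{track_name}"\n')
        prev = None  # (chrom, expected next start)
        for chrom, start, end, value in records:
            if prev is None or prev[0] != chrom or prev[1] != start:
                fh.write(f"fixedStep chrom={chrom} start={start + 1} "
                         f"step={bin_size} span={bin_size}\n")
            fh.write(f"{value:.6g}\n")
            prev = (chrom, end)
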