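"""Orthogonal-evidence validation filters.

Short-read per-base coverage over novel exons, split-read support for
junctions, a minimum-expression filter on the count matrix, and an
internal-priming check on the genomic sequence downstream of transcript
3' ends.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import Annotation, GenomicInterval, SpliceJunction
from .novelty import NoveltyReport

__all__ = [
    "CoverageTrack",
    "JunctionSupport",
    "ValidationParams",
    "read_bedgraph",
    "read_junction_table",
    "write_junction_table",
    "exon_coverage_pass",
    "filter_by_exon_coverage",
    "junction_validated",
    "expression_filter",
    "internal_priming_flag",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


@dataclass
class ValidationParams:
    min_depth: int = 15
    min_fraction: float = 0.75
    junction_min_reads: int = 3
    expr_min_count: int = 5
    expr_min_samples: int = 3
    t_window: int = 20
    a_fraction: float = 0.5

    def __post_init__(self) -> None:
        if min(self.min_depth, self.junction_min_reads, self.expr_min_count,
               self.expr_min_samples, self.t_window) < 0:
            raise ValueError("validation parameters must be >= 0")
        for frac in (self.min_fraction, self.a_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


class CoverageTrack:
    """Run-length encoded per-base read depth.

    Segments per chromosome are non-overlapping and sorted; any base not
    covered by a segment has depth 0.
    """

    def __init__(self, segments: dict[str, list[tuple[int, int, int]]] | None = None):
        self._segments: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        if segments:
            for chrom, segs in segments.items():
                self.set_chrom(chrom, segs)

    def set_chrom(self, chrom: str, segs: list[tuple[int, int, int]]) -> None:
        segs = sorted(segs)
        starts = np.array([s for s, _, _ in segs], dtype=np.int64)
        ends = np.array([e for _, e, _ in segs], dtype=np.int64)
        depths = np.array([d for _, _, d in segs], dtype=np.int64)
        if np.any(starts >= ends):
            raise ValueError(f"{chrom}: empty or inverted coverage segment")
        if np.any(ends[:-1] > starts[1:]):
            raise ValueError(f"{chrom}: overlapping coverage segments")
        if np.any(depths < 0):
            raise ValueError(f"{chrom}: negative depth")
        self._segments[chrom] = (starts, ends, depths)

    def chroms(self) -> list[str]:
        return sorted(self._segments)

    def segments(self, chrom: str) -> list[tuple[int, int, int]]:
        if chrom not in self._segments:
            return []
        starts, ends, depths = self._segments[chrom]
        return list(zip(starts.tolist(), ends.tolist(), depths.tolist()))

    def depth_at(self, chrom: str, pos: int) -> int:
        if chrom not in self._segments:
            return 0
        starts, ends, depths = self._segments[chrom]
        i = bisect_right(starts, pos) - 1
        if i >= 0 and pos < ends[i]:
            return int(depths[i])
        return 0

    def bases_at_least(self, chrom: str, start: int, end: int, min_depth: int) -> int:
        """Number of bases in [start, end) with depth >= min_depth."""
        if chrom not in self._segments or start >= end:
            return 0
        starts, ends, depths = self._segments[chrom]
        lo = bisect_right(ends, start)
        hi = bisect_right(starts, end)
        total = 0
        for i in range(lo, hi):
            if depths[i] >= min_depth:
                total += max(0, min(end, ends[i]) - max(start, starts[i]))
        return total


def read_bedgraph(path) -> CoverageTrack:
    """Load a 4-column BedGraph (chrom, start, end, depth) into a track."""
    per_chrom: dict[str, list[tuple[int, int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"bedgraph line {lineno}: expected 4 columns")
            chrom, start, end, depth = fields[:4]
            per_chrom.setdefault(chrom, []).append(
                (int(start), int(end), int(float(depth)))
            )
    return CoverageTrack(per_chrom)


def write_bedgraph(track: CoverageTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms():
            for start, end, depth in track.segments(chrom):
                fh.write(f"{chrom}\t{start}\t{end}\t{depth}\n")


@dataclass
class JunctionSupport:
    """Split-read counts keyed by exact intron coordinates."""

    counts: dict[SpliceJunction, int] = field(default_factory=dict)

    def get(self, j: SpliceJunction) -> int:
        return self.counts.get(j, 0)


def read_junction_table(path) -> JunctionSupport:
    """TSV columns: chrom, intron_start (0-based), intron_end (exclusive),
    strand, read_count. A header row is permitted."""
    counts: dict[SpliceJunction, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in ("chrom", "chromosome"):
                continue
            chrom, start, end, strand, n = fields[:5]
            j = SpliceJunction(chrom, strand, int(start), int(end))
            counts[j] = counts.get(j, 0) + int(n)
    return JunctionSupport(counts)


def write_junction_table(sup: JunctionSupport, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tintron_start\tintron_end\tstrand\tread_count\n")
        for j in sorted(sup.counts):
            fh.write(
                f"{j.chrom}\t{j.intron_start}\t{j.intron_end}\t{j.strand}\t{sup.counts[j]}\n"
            )


def exon_coverage_pass(
    exon: GenomicInterval, cov: CoverageTrack, p: ValidationParams
) -> bool:
    """True iff the fraction of exon bases at depth >= ``min_depth`` is at
    least ``min_fraction`` (both thresholds inclusive)."""
    covered = cov.bases_at_least(exon.chrom, exon.start, exon.end, p.min_depth)
    return covered / len(exon) >= p.min_fraction


def filter_by_exon_coverage(
    ann: Annotation,
    reports: dict[str, NoveltyReport],
    cov: CoverageTrack,
    p: ValidationParams,
) -> tuple[Annotation, set[str]]:
    """Remove novel transcripts any of whose novel exons (cassette or
    both-novel-boundary) fails the coverage rule. Reference transcripts are
    never removed; genes left empty are dropped."""
    removed: set[str] = set()
    for tid, t in ann.transcripts.items():
        if t.source != "novel":
            continue
        rep = reports.get(tid)
        if rep is None:
            raise KeyError(f"no novelty report for novel transcript {tid}")
        for exon in rep.novel_exons:
            if not exon_coverage_pass(exon, cov, p):
                removed.add(tid)
                break
    kept = [tid for tid in ann.transcripts if tid not in removed]
    return ann.subset(kept), removed


def junction_validated(
    j: SpliceJunction, sup: JunctionSupport, p: ValidationParams
) -> bool:
    """Exact-coordinate split-read support at or above the threshold."""
    return sup.get(j) >= p.junction_min_reads


def expression_filter(counts: pd.DataFrame, p: ValidationParams) -> list[str]:
    """Ids retained by the minimum-expression rule: count >=
    ``expr_min_count`` in at least ``expr_min_samples`` samples."""
    ok = (counts >= p.expr_min_count).sum(axis=1) >= p.expr_min_samples
    return list(counts.index[ok])


def internal_priming_flag(
    chrom: str,
    three_prime_pos: int,
    strand: str,
    genome: dict[str, str],
    p: ValidationParams,
) -> bool:
    """Flag transcript ends where the sense-strand genomic window
    immediately 3' of the end is A-rich (template-driven priming).

    On '+' the window is the ``t_window`` bases after the end; on '-' it is
    the bases before the end, reverse-complemented. Windows running off the
    chromosome are truncated.
    """
    seq = genome[chrom]
    if strand == "+":
        window = seq[three_prime_pos + 1 : three_prime_pos + 1 + p.t_window]
    else:
        lo = max(0, three_prime_pos - p.t_window)
        window = seq[lo:three_prime_pos][::-1].translate(_COMPLEMENT)
    if not window:
        return False
    a = window.upper().count("A")
    return a / len(window) >= p.a_fraction
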