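"""CAGE-peak support for putative novel transcription start sites."""

from __future__ import annotations

from dataclasses import dataclass

from .annotation import Annotation, GenomicInterval, TranscriptModel

__all__ = [
    "CagePeakSet",
    "TssValidationSummary",
    "read_bed",
    "write_bed",
    "tss_window",
    "intersect_cage",
]


class CagePeakSet:
    """Sorted peak intervals per chromosome; strand is optional and
    ignored unless strand-matching is requested."""

    def __init__(self, peaks: list[GenomicInterval]):
        self.per_chrom: dict[str, list[GenomicInterval]] = {}
        for p in peaks:
            self.per_chrom.setdefault(p.chrom, []).append(p)
        for chrom in self.per_chrom:
            self.per_chrom[chrom].sort(key=lambda p: (p.start, p.end))

    def __len__(self) -> int:
        return sum(len(v) for v in self.per_chrom.values())

    def all_peaks(self) -> list[GenomicInterval]:
        return [p for chrom in sorted(self.per_chrom) for p in self.per_chrom[chrom]]


def read_bed(path) -> CagePeakSet:
    """BED with >= 3 columns; strand read from column 6 when present."""
    peaks = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "+"
            peaks.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
            )
    return CagePeakSet(peaks)


def write_bed(peaks: CagePeakSet, path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks.all_peaks()):
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tpeak{i}\t0\t{p.strand}\n")


def tss_window(t: TranscriptModel, mode: str = "symmetric", w: int = 500) -> GenomicInterval:
    """Window around the strand-aware TSS.

    ``upstream``: the TSS base plus ``w`` bases upstream of it (mirrored on
    the minus strand); ``symmetric``: ±``w`` around the TSS. Clamped at 0.
    """
    if w < 0:
        raise ValueError("w must be >= 0")
    tss = t.tss
    if mode == "symmetric":
        lo, hi = tss - w, tss + w + 1
    elif mode == "upstream":
        if t.strand == "+":
            lo, hi = tss - w, tss + 1
        else:
            lo, hi = tss, tss + w + 1
    else:
        raise ValueError(f"unknown window mode {mode!r}")
    return GenomicInterval(t.chrom, max(0, lo), hi, t.strand)


@dataclass
class TssValidationSummary:
    n_novel_tss_transcripts: int
    n_supported_transcripts: int
    n_overlapping_peaks: int


def intersect_cage(
    windows: dict[str, GenomicInterval],
    peaks: CagePeakSet,
    match_strand: bool = False,
) -> tuple[dict[str, int], TssValidationSummary]:
    """Per-window overlapping-peak counts (half-open interval semantics)
    and the roll-up summary."""
    counts: dict[str, int] = {}
    for tid, win in windows.items():
        n = 0
        for p in peaks.per_chrom.get(win.chrom, []):
            if p.start >= win.end:
                break
            if p.end > win.start and (not match_strand or p.strand == win.strand):
                n += 1
        counts[tid] = n
    summary = TssValidationSummary(
        n_novel_tss_transcripts=len(windows),
        n_supported_transcripts=sum(1 for n in counts.values() if n >= 1),
        n_overlapping_peaks=sum(counts.values()),
    )
    return counts, summary
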