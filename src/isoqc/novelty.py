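"""Novelty classification of candidate transcripts against a reference.

Each candidate transcript is decomposed into disjoint novel-feature
categories relative to the reference annotation's splice-site, junction and
end-site indexes:

* cassette exon — internal exon overlapping no reference exon on the same
  (chrom, strand);
* novel donor / novel acceptor — an exon overlapping a reference exon with
  exactly one splice boundary absent from the strand-aware site sets;
* both-novel exon — both splice boundaries novel (excluded from the
  single-site tallies);
* novel junction between known sites — both sites annotated, pairing not;
* novel TSS / TTS — strand-aware 5'/3' end not matching any reference end
  within a configurable tolerance (default exact);
* antisense duplicate — exon chain identical to a reference transcript on
  the opposite strand.

Categories are disjoint at the exon level: a cassette exon contributes
nothing to the splice-site tallies, and a both-novel exon contributes to
neither single-site tally.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field

import pandas as pd

from .annotation import (
    Annotation,
    GenomicInterval,
    SpliceJunction,
    TranscriptModel,
    transcript_junctions,
)

__all__ = [
    "NoveltyReport",
    "FeatureCatalog",
    "classify_transcript",
    "classify_annotation",
    "detect_antisense_duplicates",
    "classify_end_sites",
    "aggregate_catalog",
    "reports_to_frame",
]


@dataclass
class NoveltyReport:
    transcript_id: str
    cassette_exons: list[GenomicInterval] = field(default_factory=list)
    novel_donor_sites: list[int] = field(default_factory=list)
    novel_acceptor_sites: list[int] = field(default_factory=list)
    both_novel_exons: list[GenomicInterval] = field(default_factory=list)
    novel_junctions_known_sites: list[SpliceJunction] = field(default_factory=list)
    novel_tss: bool = False
    novel_tts: bool = False
    antisense_duplicate: bool = False
    no_reference_context: bool = False

    @property
    def novel_exons(self) -> list[GenomicInterval]:
        """Exons subject to short-read coverage validation."""
        return list(self.cassette_exons) + list(self.both_novel_exons)

    def is_empty(self) -> bool:
        return not (
            self.cassette_exons
            or self.novel_donor_sites
            or self.novel_acceptor_sites
            or self.both_novel_exons
            or self.novel_junctions_known_sites
            or self.novel_tss
            or self.novel_tts
            or self.antisense_duplicate
        )


@dataclass
class FeatureCatalog:
    n_transcripts: int = 0
    n_cassette_exons: int = 0
    n_frame_conserving_cassette: int = 0
    n_novel_donor: int = 0
    n_novel_acceptor: int = 0
    n_both_novel: int = 0
    n_novel_junctions_known_sites: int = 0
    n_novel_tss: int = 0
    n_novel_tts: int = 0
    n_antisense_removed: int = 0
    # unique-site variants (sites shared by several transcripts counted once)
    n_unique_novel_donor: int = 0
    n_unique_novel_acceptor: int = 0


def _any_overlap(
    exon: GenomicInterval,
    sorted_exons: list[GenomicInterval],
    starts: list[int],
) -> bool:
    """True iff ``exon`` overlaps any interval in a start-sorted list."""
    # First exon starting at or past exon.end, then scan leftwards. An
    # earlier-starting exon may still reach past exon.start, so the scan
    # is bounded by a generous maximum exon width rather than broken at
    # the first non-overlap.
    hi = bisect_left(starts, exon.end)
    for i in range(hi - 1, -1, -1):
        ref = sorted_exons[i]
        if ref.end > exon.start:
            return True
        if exon.start - ref.start > 1_000_000:
            break
    return False


def classify_end_sites(
    t: TranscriptModel, reference: Annotation, tolerance_bp: int = 0
) -> tuple[bool, bool]:
    """Flag novel TSS/TTS: no reference end on the same (chrom, strand)
    within ``tolerance_bp`` of the transcript's strand-aware end."""
    if tolerance_bp < 0:
        raise ValueError("tolerance_bp must be >= 0")
    key = (t.chrom, t.strand)
    ref_tss = reference.index.tss.get(key, set())
    ref_tts = reference.index.tts.get(key, set())

    def _near(pos: int, sites: set[int]) -> bool:
        if tolerance_bp == 0:
            return pos in sites
        return any(abs(pos - s) <= tolerance_bp for s in sites)

    return (not _near(t.tss, ref_tss), not _near(t.tts, ref_tts))


def detect_antisense_duplicates(
    novel: Annotation, reference: Annotation
) -> set[str]:
    """Transcript ids in ``novel`` whose exon chain perfectly matches a
    reference transcript on the same chrom but the opposite strand."""
    chains: dict[tuple, set[str]] = {}
    for t in reference.transcripts.values():
        chains.setdefault((t.chrom, t.strand, t.exon_chain()), set()).add(
            t.transcript_id
        )
    flagged: set[str] = set()
    opposite = {"+": "-", "-": "+"}
    for tid, t in novel.transcripts.items():
        if (t.chrom, opposite[t.strand], t.exon_chain()) in chains:
            flagged.add(tid)
    return flagged


def classify_transcript(
    t: TranscriptModel,
    reference: Annotation,
    tss_tolerance_bp: int = 0,
) -> NoveltyReport:
    """Classify one candidate transcript's novel features.

    Splice boundaries are only tested on the intron-facing sides of exons
    (the outermost transcript edges are end sites, handled separately), so
    a reference transcript classified against its own reference yields an
    empty report.
    """
    key = (t.chrom, t.strand)
    donors = reference.index.donor_sites.get(key, set())
    acceptors = reference.index.acceptor_sites.get(key, set())
    junctions = reference.index.junctions.get(key, set())
    ref_exons = reference.index.exons.get(key, [])
    ref_starts = reference.index.exon_starts(key)

    report = NoveltyReport(transcript_id=t.transcript_id)
    report.no_reference_context = not (
        ref_exons
        or reference.index.tss.get(key)
    )

    n = len(t.exons)
    for i, exon in enumerate(t.exons):
        internal = 0 < i < n - 1
        if internal and not _any_overlap(exon, ref_exons, ref_starts):
            report.cassette_exons.append(exon)
            continue
        # Intron-facing boundaries only: left edge is a splice site unless
        # this is the first exon, right edge unless it is the last.
        novel_left = i > 0 and exon.start not in (
            acceptors if t.strand == "+" else donors
        )
        novel_right = i < n - 1 and exon.end not in (
            donors if t.strand == "+" else acceptors
        )
        if novel_left and novel_right:
            report.both_novel_exons.append(exon)
        elif novel_left:
            if t.strand == "+":
                report.novel_acceptor_sites.append(exon.start)
            else:
                report.novel_donor_sites.append(exon.start)
        elif novel_right:
            if t.strand == "+":
                report.novel_donor_sites.append(exon.end)
            else:
                report.novel_acceptor_sites.append(exon.end)

    for j in transcript_junctions(t):
        if (
            (j.intron_start, j.intron_end) not in junctions
            and j.donor in donors
            and j.acceptor in acceptors
        ):
            report.novel_junctions_known_sites.append(j)

    report.novel_tss, report.novel_tts = classify_end_sites(
        t, reference, tss_tolerance_bp
    )
    return report


def classify_annotation(
    novel: Annotation,
    reference: Annotation,
    tss_tolerance_bp: int = 0,
) -> dict[str, NoveltyReport]:
    """Classify every transcript of ``novel``, including antisense flags."""
    antisense = detect_antisense_duplicates(novel, reference)
    reports = {}
    for tid, t in novel.transcripts.items():
        rep = classify_transcript(t, reference, tss_tolerance_bp)
        rep.antisense_duplicate = tid in antisense
        reports[tid] = rep
    return reports


def aggregate_catalog(reports: list[NoveltyReport]) -> FeatureCatalog:
    cat = FeatureCatalog(n_transcripts=len(reports))
    unique_donors: set[int] = set()
    unique_acceptors: set[int] = set()
    for r in reports:
        cat.n_cassette_exons += len(r.cassette_exons)
        cat.n_novel_donor += len(r.novel_donor_sites)
        cat.n_novel_acceptor += len(r.novel_acceptor_sites)
        cat.n_both_novel += len(r.both_novel_exons)
        cat.n_novel_junctions_known_sites += len(r.novel_junctions_known_sites)
        cat.n_novel_tss += int(r.novel_tss)
        cat.n_novel_tts += int(r.novel_tts)
        cat.n_antisense_removed += int(r.antisense_duplicate)
        unique_donors.update(r.novel_donor_sites)
        unique_acceptors.update(r.novel_acceptor_sites)
    cat.n_unique_novel_donor = len(unique_donors)
    cat.n_unique_novel_acceptor = len(unique_acceptors)
    return cat


def reports_to_frame(reports: dict[str, NoveltyReport]) -> pd.DataFrame:
    """One row per transcript with per-category counts and flags."""
    rows = []
    for tid in sorted(reports):
        r = reports[tid]
        rows.append(
            {
                "transcript_id": tid,
                "n_cassette_exons": len(r.cassette_exons),
                "n_novel_donor": len(r.novel_donor_sites),
                "n_novel_acceptor": len(r.novel_acceptor_sites),
                "n_both_novel": len(r.both_novel_exons),
                "n_novel_junctions_known_sites": len(r.novel_junctions_known_sites),
                "novel_tss": r.novel_tss,
                "novel_tts": r.novel_tts,
                "antisense_duplicate": r.antisense_duplicate,
                "no_reference_context": r.no_reference_context,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id",
            "n_cassette_exons",
            "n_novel_donor",
            "n_novel_acceptor",
            "n_both_novel",
            "n_novel_junctions_known_sites",
            "novel_tss",
            "novel_tts",
            "antisense_duplicate",
            "no_reference_context",
        ],
    )
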