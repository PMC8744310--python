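"""Annotation data model and GTF I/O.

Transcripts are strand-aware exon chains. All internal coordinates are
0-based half-open; GTF files (1-based inclusive) are converted at the I/O
boundary. The :class:`Annotation` container keeps per-``(chrom, strand)``
indexes of splice sites, junctions and transcript end positions that the
novelty classifier queries.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field, replace

__all__ = [
    "GenomicInterval",
    "SpliceJunction",
    "TranscriptModel",
    "GeneRecord",
    "Annotation",
    "AnnotationIndex",
    "GtfParseError",
    "AnnotationIntegrityError",
    "read_gtf",
    "write_gtf",
    "transcript_junctions",
    "merge_annotations",
]


class GtfParseError(ValueError):
    """Raised for a malformed GTF line; message names the line number."""


class AnnotationIntegrityError(ValueError):
    """Raised when an annotation violates a structural invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True, order=True)
class SpliceJunction:
    chrom: str
    strand: str
    intron_start: int  # first intronic base, 0-based
    intron_end: int  # one past last intronic base

    def __post_init__(self) -> None:
        if not self.intron_start < self.intron_end:
            raise ValueError("intron_start must be < intron_end")

    @property
    def donor(self) -> int:
        """5' splice-site position (strand-aware)."""
        return self.intron_start if self.strand == "+" else self.intron_end

    @property
    def acceptor(self) -> int:
        """3' splice-site position (strand-aware)."""
        return self.intron_end if self.strand == "+" else self.intron_start


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    cds: GenomicInterval | None = None
    source: str = "reference"  # {reference, novel}
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationIntegrityError(
                f"transcript {self.transcript_id} has no exons"
            )
        exons = sorted(self.exons, key=lambda e: e.start)
        for e in exons:
            if e.chrom != self.chrom or e.strand != self.strand:
                raise AnnotationIntegrityError(
                    f"transcript {self.transcript_id}: exon on "
                    f"{e.chrom}{e.strand}, transcript on {self.chrom}{self.strand}"
                )
        for a, b in zip(exons, exons[1:]):
            if a.end > b.start:
                raise AnnotationIntegrityError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
        self.exons = exons
        if self.cds is not None:
            if not (self.start <= self.cds.start < self.cds.end <= self.end):
                raise AnnotationIntegrityError(
                    f"transcript {self.transcript_id}: CDS outside exon footprint"
                )

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def tss(self) -> int:
        """Strand-aware 5' end (as a 0-based position)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        """Strand-aware 3' end (as a 0-based position)."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    def exon_chain(self) -> tuple[tuple[int, int], ...]:
        return tuple((e.start, e.end) for e in self.exons)


def transcript_junctions(t: TranscriptModel) -> list[SpliceJunction]:
    """Introns of ``t`` in genomic order; empty for single-exon models."""
    return [
        SpliceJunction(t.chrom, t.strand, a.end, b.start)
        for a, b in zip(t.exons, t.exons[1:])
    ]


@dataclass
class GeneRecord:
    gene_id: str
    transcript_ids: list[str]
    biotype: str  # {coding, noncoding}


class AnnotationIndex:
    """Per-(chrom, strand) lookup sets derived from a transcript set."""

    def __init__(self) -> None:
        self._exon_starts: dict[tuple[str, str], list[int]] = {}
        self.donor_sites: dict[tuple[str, str], set[int]] = {}
        self.acceptor_sites: dict[tuple[str, str], set[int]] = {}
        self.junctions: dict[tuple[str, str], set[tuple[int, int]]] = {}
        self.tss: dict[tuple[str, str], set[int]] = {}
        self.tts: dict[tuple[str, str], set[int]] = {}
        self.exons: dict[tuple[str, str], list[GenomicInterval]] = {}

    @staticmethod
    def build(transcripts: dict[str, TranscriptModel]) -> "AnnotationIndex":
        idx = AnnotationIndex()
        for t in transcripts.values():
            key = (t.chrom, t.strand)
            for j in transcript_junctions(t):
                idx.donor_sites.setdefault(key, set()).add(j.donor)
                idx.acceptor_sites.setdefault(key, set()).add(j.acceptor)
                idx.junctions.setdefault(key, set()).add(
                    (j.intron_start, j.intron_end)
                )
            idx.tss.setdefault(key, set()).add(t.tss)
            idx.tts.setdefault(key, set()).add(t.tts)
            idx.exons.setdefault(key, []).extend(t.exons)
        for key in idx.exons:
            idx.exons[key] = sorted(set(idx.exons[key]))
        idx._exon_starts = {
            key: [e.start for e in exons] for key, exons in idx.exons.items()
        }
        return idx

    def exon_starts(self, key: tuple[str, str]) -> list[int]:
        return self._exon_starts.get(key, [])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationIndex):
            return NotImplemented
        return (
            self.donor_sites == other.donor_sites
            and self.acceptor_sites == other.acceptor_sites
            and self.junctions == other.junctions
            and self.tss == other.tss
            and self.tts == other.tts
            and self.exons == other.exons
        )


class Annotation:
    """A set of transcripts with gene grouping and derived indexes."""

    def __init__(
        self,
        transcripts: dict[str, TranscriptModel] | None = None,
        gene_biotypes: dict[str, str] | None = None,
    ) -> None:
        self.transcripts: dict[str, TranscriptModel] = dict(transcripts or {})
        self.genes: dict[str, GeneRecord] = {}
        explicit = dict(gene_biotypes or {})
        for tid, t in self.transcripts.items():
            rec = self.genes.get(t.gene_id)
            if rec is None:
                rec = GeneRecord(t.gene_id, [], "noncoding")
                self.genes[t.gene_id] = rec
            rec.transcript_ids.append(tid)
        for gid, rec in self.genes.items():
            if gid in explicit:
                rec.biotype = explicit[gid]
            else:
                rec.biotype = (
                    "coding"
                    if any(
                        self.transcripts[tid].cds is not None
                        for tid in rec.transcript_ids
                    )
                    else "noncoding"
                )
        self.index = AnnotationIndex.build(self.transcripts)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Annotation):
            return NotImplemented
        return (
            self.transcripts == other.transcripts
            and {g: (r.biotype, sorted(r.transcript_ids)) for g, r in self.genes.items()}
            == {g: (r.biotype, sorted(r.transcript_ids)) for g, r in other.genes.items()}
        )

    def subset(self, transcript_ids) -> "Annotation":
        keep = set(transcript_ids)
        txs = {tid: t for tid, t in self.transcripts.items() if tid in keep}
        biotypes = {
            g: rec.biotype
            for g, rec in self.genes.items()
            if any(tid in keep for tid in rec.transcript_ids)
        }
        return Annotation(txs, biotypes)

    def gene_biotype(self, gene_id: str) -> str:
        return self.genes[gene_id].biotype


# ---------------------------------------------------------------------------
# GTF I/O (GENCODE attribute dialect)
# ---------------------------------------------------------------------------

_GTF_COLUMNS = 9


def _open_text(path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _parse_attributes(field_text: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in field_text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        try:
            key, raw = chunk.split(" ", 1)
        except ValueError as exc:
            raise GtfParseError(
                f"line {lineno}: malformed attribute chunk {chunk!r}"
            ) from exc
        attrs[key] = raw.strip().strip('"')
    return attrs


def _format_attributes(attrs: dict[str, str]) -> str:
    return " ".join(f'{k} "{v}";' for k, v in attrs.items())


def read_gtf(path) -> Annotation:
    """Read a GENCODE-dialect GTF into an :class:`Annotation`.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    CDS features are merged into a single genomic span per transcript.
    Gene biotype is taken from a ``gene_type``/``gene_biotype`` attribute
    when present, otherwise inferred (coding iff any transcript has a CDS).
    """
    exon_rows: dict[str, list[tuple]] = {}
    cds_rows: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict] = {}
    biotypes: dict[str, str] = {}

    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != _GTF_COLUMNS:
                raise GtfParseError(
                    f"line {lineno}: expected {_GTF_COLUMNS} tab-separated "
                    f"fields, got {len(fields)}"
                )
            chrom, source, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
            if feature not in ("exon", "CDS", "gene"):
                continue
            try:
                start = int(start_s) - 1
                end = int(end_s)
            except ValueError as exc:
                raise GtfParseError(
                    f"line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
                ) from exc
            attrs = _parse_attributes(attr_s, lineno)
            if feature == "gene":
                bt = attrs.get("gene_type", attrs.get("gene_biotype"))
                if bt and "gene_id" in attrs:
                    biotypes[attrs["gene_id"]] = (
                        "coding" if bt in ("coding", "protein_coding") else "noncoding"
                    )
                continue
            if "transcript_id" not in attrs or "gene_id" not in attrs:
                raise GtfParseError(
                    f"line {lineno}: {feature} lacks transcript_id/gene_id"
                )
            tid = attrs["transcript_id"]
            if feature == "exon":
                exon_rows.setdefault(tid, []).append((chrom, start, end, strand))
                info = meta.setdefault(
                    tid,
                    {
                        "gene_id": attrs["gene_id"],
                        "chrom": chrom,
                        "strand": strand,
                        "source_tag": source,
                        "attrs": {},
                    },
                )
                if info["strand"] != strand or info["chrom"] != chrom:
                    raise AnnotationIntegrityError(
                        f"line {lineno}: transcript {tid} spans mixed "
                        "chrom/strand"
                    )
                for k, v in attrs.items():
                    if k not in ("gene_id", "transcript_id", "gene_type", "gene_biotype"):
                        info["attrs"].setdefault(k, v)
                bt = attrs.get("gene_type", attrs.get("gene_biotype"))
                if bt:
                    biotypes.setdefault(
                        attrs["gene_id"],
                        "coding" if bt in ("coding", "protein_coding") else "noncoding",
                    )
            else:  # CDS
                cds_rows.setdefault(tid, []).append((start, end))

    transcripts: dict[str, TranscriptModel] = {}
    for tid, rows in exon_rows.items():
        info = meta[tid]
        exons = [
            GenomicInterval(c, s, e, st) for (c, s, e, st) in sorted(rows)
        ]
        cds = None
        if tid in cds_rows:
            spans = cds_rows[tid]
            cds = GenomicInterval(
                info["chrom"],
                min(s for s, _ in spans),
                max(e for _, e in spans),
                info["strand"],
            )
        transcripts[tid] = TranscriptModel(
            transcript_id=tid,
            gene_id=info["gene_id"],
            chrom=info["chrom"],
            strand=info["strand"],
            exons=exons,
            cds=cds,
            source="novel" if info["source_tag"] == "novel" else "reference",
            attributes=info["attrs"],
        )
    return Annotation(transcripts, biotypes)


def write_gtf(annotation: Annotation, path) -> None:
    """Write exon (and CDS) features, 1-based inclusive, deterministically
    ordered by (chrom, start, transcript_id). Gene biotype is emitted on
    every exon row so round-trips preserve it."""
    lines: list[tuple] = []
    for tid in annotation.transcripts:
        t = annotation.transcripts[tid]
        biotype = annotation.gene_biotype(t.gene_id)
        attrs = {"gene_id": t.gene_id, "transcript_id": tid, "gene_type": biotype}
        attrs.update(t.attributes)
        attr_s = _format_attributes(attrs)
        src = "novel" if t.source == "novel" else "reference"
        for e in t.exons:
            lines.append(
                (t.chrom, e.start, tid, "exon", e.end, t.strand, src, attr_s)
            )
        if t.cds is not None:
            lines.append(
                (
                    t.chrom,
                    t.cds.start,
                    tid,
                    "CDS",
                    t.cds.end,
                    t.strand,
                    src,
                    attr_s,
                )
            )
    lines.sort()
    buf = io.StringIO()
    buf.write("##format: gtf\n")
    for chrom, start, _tid, feature, end, strand, src, attr_s in lines:
        buf.write(
            f"{chrom}\t{src}\t{feature}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attr_s}\n"
        )
    with open(path, "wt") as fh:
        fh.write(buf.getvalue())


def merge_annotations(reference: Annotation, novel: Annotation) -> Annotation:
    """Union of two annotations; novel transcripts of existing genes attach
    to those genes. Colliding transcript ids abort the merge atomically."""
    collisions = sorted(
        set(reference.transcripts) & set(novel.transcripts)
    )
    if collisions:
        raise AnnotationIntegrityError(
            f"transcript_id collision(s): {', '.join(collisions)}"
        )
    merged = dict(reference.transcripts)
    merged.update(novel.transcripts)
    biotypes = {g: r.biotype for g, r in reference.genes.items()}
    for g, r in novel.genes.items():
        biotypes.setdefault(g, r.biotype)
    return Annotation(merged, biotypes)


def with_source(t: TranscriptModel, source: str) -> TranscriptModel:
    return replace(t, source=source)
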