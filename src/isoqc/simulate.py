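"""Ground-truth synthetic data for every pipeline stage.

Generates a genome with multi-exon genes (FASTA + GTF with CDS), candidate
annotations with injected novel features of each category, coverage tracks
with designed pass/fail exons, negative-binomial count matrices with
planted differential expression and usage, spike-in mixes with a
concentration-dependent detection floor, and CAGE peaks. Every output is a
pure function of (config, seed) so downstream modules can be tested by
parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import Annotation, GenomicInterval, TranscriptModel, transcript_junctions
from .coding import STOP_CODONS, reverse_complement
from .spikein import SequinMix
from .validation import CoverageTrack, JunctionSupport

__all__ = [
    "SimConfig",
    "TruthSet",
    "make_reference",
    "inject_novel_features",
    "simulate_coverage",
    "simulate_counts",
    "simulate_sequins",
    "make_cage_peaks",
    "make_training_sequences",
    "make_validation_cohort",
    "make_coding_cohort",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASES_NO_A = np.frombuffer(b"CGT", dtype=np.uint8)
_SAFE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if (a + b + c) not in STOP_CODONS and (a + b + c) != "ATG"
]


@dataclass
class SimConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 150
    noncoding_fraction: float = 0.2
    two_isoform_fraction: float = 0.5
    # novelty injections
    n_cassette: int = 10
    frame_conserving_fraction: float = 0.4
    n_novel_donor: int = 8
    n_novel_acceptor: int = 8
    n_both_novel: int = 6
    n_novel_junction: int = 6
    n_novel_tss: int = 8
    n_antisense: int = 4
    # validation
    coverage_pass_fraction: float = 0.7
    junction_valid_fraction: float = 0.7
    background_depth: int = 20
    # counts
    nb_dispersion: float = 0.1
    base_mean: float = 100.0
    samples_per_condition: int = 5
    n_de: int = 20
    de_logfc: float = 2.0
    n_dtu: int = 10
    dtu_high_fraction: float = 0.8
    # sequins
    n_sequin_levels: int = 10
    sequin_min_conc: float = 0.05
    sequin_floor: float = 0.8  # c*, a value on the concentration ladder
    sequin_scale: float = 400.0
    sequin_dispersion: float = 0.02

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.chrom_length <= 0:
            raise ValueError("invalid genome dimensions")
        for frac in (
            self.noncoding_fraction,
            self.two_isoform_fraction,
            self.frame_conserving_fraction,
            self.coverage_pass_fraction,
            self.junction_valid_fraction,
            self.dtu_high_fraction,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


@dataclass
class TruthSet:
    category: dict[str, str] = field(default_factory=dict)  # tid -> category
    frame_conserving: dict[str, bool] = field(default_factory=dict)
    novel_exons: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    coverage_pass: dict[str, bool] = field(default_factory=dict)
    junction_valid: dict[tuple, bool] = field(default_factory=dict)
    coding_truth: dict[str, tuple[str, str]] = field(default_factory=dict)
    de_logfc: dict[str, float] = field(default_factory=dict)
    dtu_genes: dict[str, float] = field(default_factory=dict)
    cage_hits: set[str] = field(default_factory=set)
    sequin_floor: float = float("nan")


# ---------------------------------------------------------------------------
# reference genome + annotation
# ---------------------------------------------------------------------------


def _random_seq_codes(rng: np.random.Generator, n: int, no_a: bool = False) -> np.ndarray:
    pool = _BASES_NO_A if no_a else _BASES
    return pool[rng.integers(0, len(pool), n)]


def _paint(genome: dict[str, bytearray], chrom: str, t_exons, strand: str, seq: str) -> None:
    """Write a spliced sense-strand sequence back into the genome."""
    genomic = seq if strand == "+" else reverse_complement(seq)
    arr = genome[chrom]
    off = 0
    for e in t_exons:
        n = e.end - e.start
        arr[e.start : e.end] = genomic[off : off + n].encode()
        off += n


def _make_cds_sequence(rng: np.random.Generator, n_codons: int) -> str:
    body = "".join(
        _SAFE_CODONS[i] for i in rng.integers(0, len(_SAFE_CODONS), n_codons)
    )
    return "ATG" + body + "TAA"


def make_reference(
    cfg: SimConfig,
) -> tuple[dict[str, str], Annotation, dict[str, str]]:
    """Reference genome, annotation and per-gene biotype labels.

    Genes have 2-10 exons (introns >= 60 bp); ~``noncoding_fraction`` of
    genes carry no CDS; a configurable fraction of multi-exon coding genes
    get a second, exon-skipping isoform.
    """
    rng = np.random.default_rng(cfg.seed)
    genome: dict[str, bytearray] = {}
    for c in range(cfg.n_chroms):
        genome[f"chr{c + 1}"] = bytearray(
            _random_seq_codes(rng, cfg.chrom_length).tobytes()
        )

    per_chrom = int(np.ceil(cfg.n_genes / cfg.n_chroms))
    slot = cfg.chrom_length // per_chrom
    if slot < 9_000:
        raise ValueError("genes do not fit the chromosome; enlarge it")

    transcripts: dict[str, TranscriptModel] = {}
    biotypes: dict[str, str] = {}
    gi = 0
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        for s in range(per_chrom):
            if gi >= cfg.n_genes:
                break
            gid = f"G{gi + 1:05d}"
            strand = "+" if rng.random() < 0.5 else "-"
            noncoding = rng.random() < cfg.noncoding_fraction
            base = s * slot + 1_500  # margin for TSS shifts / CAGE windows
            n_exons = int(rng.integers(2, 11))
            exons = []
            pos = base + int(rng.integers(0, 200))
            for _ in range(n_exons):
                length = int(rng.integers(120, 301))
                exons.append(GenomicInterval(chrom, pos, pos + length, strand))
                pos += length + int(rng.integers(200, 400))
            if exons[-1].end > (s + 1) * slot - 1_500:
                # shrink introns deterministically if the gene overshoots
                raise ValueError("gene overshoots its slot; enlarge chrom")

            tid = f"T{gi + 1:05d}.1"
            primary = TranscriptModel(tid, gid, chrom, strand, exons)
            tx_len = primary.length
            cds = None
            if not noncoding:
                utr5 = int(rng.integers(40, 90))
                utr3 = int(rng.integers(40, 90))
                n_codons = (tx_len - utr5 - utr3 - 6) // 3
                cds_len = 3 * n_codons + 6  # ATG + body + stop
                seq = (
                    "".join(
                        "ACGT"[i] for i in rng.integers(0, 4, utr5)
                    )
                    + _make_cds_sequence(rng, n_codons)
                    + "".join(
                        "ACGT"[i] for i in rng.integers(0, 4, tx_len - utr5 - cds_len)
                    )
                )
                _paint(genome, chrom, exons, strand, seq)
                # genomic span of the CDS portion of the transcript
                gpos = []
                for e in exons:
                    gpos.extend(range(e.start, e.end))
                if strand == "-":
                    gpos = gpos[::-1]
                cds_pos = gpos[utr5 : utr5 + cds_len]
                cds = GenomicInterval(chrom, min(cds_pos), max(cds_pos) + 1, strand)
            primary = TranscriptModel(tid, gid, chrom, strand, exons, cds=cds)
            transcripts[tid] = primary
            biotypes[gid] = "noncoding" if noncoding else "coding"

            if n_exons >= 3 and rng.random() < cfg.two_isoform_fraction:
                skip = int(rng.integers(1, n_exons - 1))
                iso = TranscriptModel(
                    f"T{gi + 1:05d}.2",
                    gid,
                    chrom,
                    strand,
                    [e for k, e in enumerate(exons) if k != skip],
                )
                transcripts[iso.transcript_id] = iso
            gi += 1

    genome_str = {c: bytes(b).decode() for c, b in genome.items()}
    return genome_str, Annotation(transcripts, biotypes), biotypes


# ---------------------------------------------------------------------------
# novel-feature injection
# ---------------------------------------------------------------------------


def _primary_of(ann: Annotation, gid: str) -> TranscriptModel:
    return ann.transcripts[sorted(ann.genes[gid].transcript_ids)[0]]


def inject_novel_features(
    reference: Annotation, cfg: SimConfig
) -> tuple[Annotation, TruthSet]:
    """Create one novel transcript per injection, each in a distinct gene,
    with ground-truth category labels."""
    rng = np.random.default_rng(cfg.seed + 1)
    truth = TruthSet()
    novel: dict[str, TranscriptModel] = {}

    def eligible(min_exons: int, min_intron: int = 0, coding: bool | None = None):
        out = []
        for gid, rec in reference.genes.items():
            if gid in used_genes:
                continue
            t = _primary_of(reference, gid)
            if len(t.exons) < min_exons:
                continue
            if coding is True and rec.biotype != "coding":
                continue
            if coding is False and rec.biotype != "noncoding":
                continue
            if min_intron and not any(
                b.start - a.end >= min_intron
                for a, b in zip(t.exons, t.exons[1:])
            ):
                continue
            out.append(gid)
        return sorted(out)

    used_genes: set[str] = set()
    counter = [0]

    def new_id() -> str:
        counter[0] += 1
        return f"N{counter[0]:05d}"

    idx = reference.index

    def add(t: TranscriptModel, category: str, **extra) -> None:
        novel[t.transcript_id] = t
        truth.category[t.transcript_id] = category
        for k, v in extra.items():
            getattr(truth, k)[t.transcript_id] = v

    # cassette exons (some frame-conserving)
    n_fc = int(round(cfg.n_cassette * cfg.frame_conserving_fraction))
    pool = eligible(2, min_intron=260)
    if len(pool) < cfg.n_cassette:
        raise ValueError("not enough genes with roomy introns for cassettes")
    for i, gid in enumerate(rng.choice(pool, cfg.n_cassette, replace=False)):
        used_genes.add(gid)
        host = _primary_of(reference, gid)
        frame_ok = i < n_fc
        length = 90 if frame_ok else 91
        k = next(
            k
            for k in range(len(host.exons) - 1)
            if host.exons[k + 1].start - host.exons[k].end >= length + 140
        )
        lo = host.exons[k].end + 70
        exon = GenomicInterval(host.chrom, lo, lo + length, host.strand)
        t = TranscriptModel(
            new_id(), gid, host.chrom, host.strand,
            host.exons + [exon], source="novel",
        )
        add(t, "cassette", frame_conserving=frame_ok,
            novel_exons=[exon])

    # novel donors / acceptors: shift one splice boundary into the exon
    for category, count in (
        ("novel_donor", cfg.n_novel_donor),
        ("novel_acceptor", cfg.n_novel_acceptor),
    ):
        pool = eligible(2)
        if len(pool) < count:
            raise ValueError(f"not enough genes for {category}")
        for gid in rng.choice(pool, count, replace=False):
            used_genes.add(gid)
            host = _primary_of(reference, gid)
            k = int(rng.integers(0, len(host.exons) - 1))
            exons = list(host.exons)
            shift = 9
            want_donor = (category == "novel_donor") == (host.strand == "+")
            if want_donor:
                # move the intron's genomic-left boundary (exon k's end)
                e = exons[k]
                exons[k] = GenomicInterval(e.chrom, e.start, e.end - shift, e.strand)
            else:
                e = exons[k + 1]
                exons[k + 1] = GenomicInterval(
                    e.chrom, e.start + shift, e.end, e.strand
                )
            t = TranscriptModel(
                new_id(), gid, host.chrom, host.strand, exons, source="novel"
            )
            add(t, category)

    # both-novel internal exons: shrink both boundaries
    pool = eligible(3)
    if len(pool) < cfg.n_both_novel:
        raise ValueError("not enough genes for both-novel exons")
    for gid in rng.choice(pool, cfg.n_both_novel, replace=False):
        used_genes.add(gid)
        host = _primary_of(reference, gid)
        k = int(rng.integers(1, len(host.exons) - 1))
        exons = list(host.exons)
        e = exons[k]
        shrunk = GenomicInterval(e.chrom, e.start + 6, e.end - 6, e.strand)
        exons[k] = shrunk
        t = TranscriptModel(
            new_id(), gid, host.chrom, host.strand, exons, source="novel"
        )
        add(t, "both_novel", novel_exons=[shrunk])

    # novel junctions between known sites: skip an exon no reference
    # isoform skips
    pool = eligible(3)
    chosen = []
    for gid in pool:
        host = _primary_of(reference, gid)
        key = (host.chrom, host.strand)
        juncs = idx.junctions.get(key, set())
        ja = [(j.intron_start, j.intron_end) for j in transcript_junctions(host)]
        for k in range(1, len(host.exons) - 1):
            span = (ja[k - 1][0], ja[k][1])
            if span not in juncs:
                chosen.append((gid, k))
                break
        if len(chosen) >= cfg.n_novel_junction * 3:
            break
    if len(chosen) < cfg.n_novel_junction:
        raise ValueError("not enough genes for novel junctions")
    picks = rng.choice(len(chosen), cfg.n_novel_junction, replace=False)
    for p in picks:
        gid, k = chosen[p]
        used_genes.add(gid)
        host = _primary_of(reference, gid)
        exons = [e for i, e in enumerate(host.exons) if i != k]
        t = TranscriptModel(
            new_id(), gid, host.chrom, host.strand, exons, source="novel"
        )
        add(t, "novel_junction")

    # novel TSS: extend the 5' exon outward
    pool = eligible(2)
    if len(pool) < cfg.n_novel_tss:
        raise ValueError("not enough genes for novel TSS")
    for gid in rng.choice(pool, cfg.n_novel_tss, replace=False):
        used_genes.add(gid)
        host = _primary_of(reference, gid)
        exons = list(host.exons)
        if host.strand == "+":
            e = exons[0]
            exons[0] = GenomicInterval(e.chrom, e.start - 700, e.end, e.strand)
        else:
            e = exons[-1]
            exons[-1] = GenomicInterval(e.chrom, e.start, e.end + 700, e.strand)
        t = TranscriptModel(
            new_id(), gid, host.chrom, host.strand, exons, source="novel"
        )
        add(t, "novel_tss")

    # antisense duplicates: identical chain, opposite strand, own gene
    pool = eligible(2)
    if len(pool) < cfg.n_antisense:
        raise ValueError("not enough genes for antisense duplicates")
    for gid in rng.choice(pool, cfg.n_antisense, replace=False):
        used_genes.add(gid)
        host = _primary_of(reference, gid)
        flip = "-" if host.strand == "+" else "+"
        exons = [
            GenomicInterval(e.chrom, e.start, e.end, flip) for e in host.exons
        ]
        t = TranscriptModel(
            new_id(), f"{gid}AS", host.chrom, flip, exons, source="novel"
        )
        add(t, "antisense")

    return Annotation(novel), truth


# ---------------------------------------------------------------------------
# coverage + junction evidence
# ---------------------------------------------------------------------------


def _flatten(intervals: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Resolve overlapping painted intervals by taking the maximum depth."""
    points = sorted({p for s, e, _ in intervals for p in (s, e)})
    out = []
    for lo, hi in zip(points, points[1:]):
        depth = 0
        for s, e, d in intervals:
            if s <= lo and hi <= e:
                depth = max(depth, d)
        if depth > 0:
            if out and out[-1][1] == lo and out[-1][2] == depth:
                out[-1] = (out[-1][0], hi, depth)
            else:
                out.append((lo, hi, depth))
    return out


def simulate_coverage(
    novel: Annotation,
    reference: Annotation,
    truth: TruthSet,
    cfg: SimConfig,
) -> tuple[CoverageTrack, JunctionSupport]:
    """Coverage with designed pass/fail novel exons and a junction table.

    Novel transcripts with coverage-checkable exons (cassette and
    both-novel) pass or fail per ``coverage_pass_fraction``; a failing
    exon gets depth over only half its length. Transcripts without novel
    exons trivially pass. Junction support is set above or below the
    3-read default per ``junction_valid_fraction``.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    depth = cfg.background_depth
    painted: dict[str, list[tuple[int, int, int]]] = {}
    for t in reference.transcripts.values():
        for e in t.exons:
            painted.setdefault(t.chrom, []).append((e.start, e.end, depth))

    # only intronic novel exons (cassettes) can be made to fail: both-novel
    # exons sit inside reference exons, which carry background coverage
    failable = sorted(
        t for t in truth.novel_exons if truth.category.get(t) == "cassette"
    )
    n_pass = int(round(len(failable) * cfg.coverage_pass_fraction))
    pass_ids = (
        set(rng.choice(failable, n_pass, replace=False)) if failable else set()
    )
    for tid in novel.transcripts:
        exons = truth.novel_exons.get(tid, [])
        ok = tid not in failable or tid in pass_ids
        truth.coverage_pass[tid] = ok
        for e in exons:
            if ok:
                painted.setdefault(e.chrom, []).append((e.start, e.end, depth))
            else:
                half = e.start + len(e) // 2
                painted.setdefault(e.chrom, []).append((e.start, half, depth))

    track = CoverageTrack(
        {chrom: _flatten(iv) for chrom, iv in painted.items()}
    )

    counts: dict = {}
    for t in reference.transcripts.values():
        for j in transcript_junctions(t):
            counts[j] = 50
    novel_juncs = sorted(
        {
            j
            for t in novel.transcripts.values()
            for j in transcript_junctions(t)
            if j not in counts
        }
    )
    n_ok = int(round(len(novel_juncs) * cfg.junction_valid_fraction))
    ok_idx = set(rng.choice(len(novel_juncs), n_ok, replace=False)) if novel_juncs else set()
    for i, j in enumerate(novel_juncs):
        valid = i in ok_idx
        counts[j] = 10 if valid else 1
        truth.junction_valid[(j.chrom, j.strand, j.intron_start, j.intron_end)] = valid
    return track, JunctionSupport(counts)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-8)
    if phi <= 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def sample_names(cfg: SimConfig) -> tuple[list[str], pd.Series]:
    n = cfg.samples_per_condition
    names = [f"u{i + 1}" for i in range(n)] + [f"d{i + 1}" for i in range(n)]
    design = pd.Series(
        ["undifferentiated"] * n + ["differentiated"] * n, index=names
    )
    return names, design


def simulate_counts(
    annotation: Annotation, cfg: SimConfig, truth: TruthSet
) -> tuple[pd.DataFrame, pd.Series]:
    """Two-condition NB count matrix with planted DE transcripts and
    planted DTU genes whose gene totals are held fixed."""
    rng = np.random.default_rng(cfg.seed + 3)
    names, design = sample_names(cfg)
    n = cfg.samples_per_condition
    tids = sorted(annotation.transcripts)

    multi_iso = sorted(
        g for g, rec in annotation.genes.items()
        if len(rec.transcript_ids) >= 2
    )
    dtu_genes = list(
        rng.choice(multi_iso, min(cfg.n_dtu, len(multi_iso)), replace=False)
    )
    dtu_tids = {
        t for g in dtu_genes for t in annotation.genes[g].transcript_ids
    }
    de_pool = [t for t in tids if t not in dtu_tids]
    de_tids = list(
        rng.choice(de_pool, min(cfg.n_de, len(de_pool)), replace=False)
    )

    base = np.exp(rng.normal(np.log(cfg.base_mean), 0.7, len(tids)))
    mean1 = dict(zip(tids, base))
    mean2 = dict(zip(tids, base))
    half = cfg.de_logfc / 2
    for i, tid in enumerate(de_tids):
        sign = 1 if i % 2 == 0 else -1
        mean1[tid] = mean1[tid] * 2 ** (sign * half)
        mean2[tid] = mean2[tid] * 2 ** (-sign * half)
        truth.de_logfc[tid] = sign * cfg.de_logfc

    hi, lo = cfg.dtu_high_fraction, 1 - cfg.dtu_high_fraction
    for g in dtu_genes:
        iso = sorted(annotation.genes[g].transcript_ids)[:2]
        total = sum(base[tids.index(t)] for t in iso)
        mean1[iso[0]], mean2[iso[0]] = total * hi, total * lo
        mean1[iso[1]], mean2[iso[1]] = total * lo, total * hi
        truth.dtu_genes[g] = 2 * (hi - lo)

    m1 = np.array([mean1[t] for t in tids])
    m2 = np.array([mean2[t] for t in tids])
    cols = {}
    for i, name in enumerate(names):
        mu = m1 if i < n else m2
        cols[name] = _nb_draw(rng, mu, cfg.nb_dispersion)
    counts = pd.DataFrame(cols, index=tids)
    counts.index.name = "transcript_id"
    return counts, design


# ---------------------------------------------------------------------------
# sequins
# ---------------------------------------------------------------------------


def simulate_sequins(
    cfg: SimConfig, noise: bool = True
) -> tuple[SequinMix, pd.DataFrame, TruthSet]:
    """Mix tables and per-sample sequin counts with a detection floor.

    Concentrations sit on a doubling ladder; MixB/MixA ratios cycle
    through {1/4, 1/2, 1, 2, 4}. Counts are proportional to concentration
    above the floor c* and flat below it. Mixes alternate within each
    condition so both mixes appear in both conditions.
    """
    rng = np.random.default_rng(cfg.seed + 4)
    ratios = [0.25, 0.5, 1.0, 2.0, 4.0]
    mix_a, mix_b, lengths = {}, {}, {}
    for lvl in range(cfg.n_sequin_levels):
        for rep in range(2):
            sid = f"SQ{lvl:02d}{'ab'[rep]}"
            conc = cfg.sequin_min_conc * 2.0**lvl
            ratio = ratios[(lvl * 2 + rep) % len(ratios)]
            mix_a[sid] = conc
            mix_b[sid] = conc * ratio
            lengths[sid] = 1000
    names, design = sample_names(cfg)
    n = cfg.samples_per_condition
    assignment = {}
    for i, name in enumerate(names):
        within = i % n
        first = "A" if i < n else "B"
        other = "B" if first == "A" else "A"
        assignment[name] = first if within % 2 == 0 else other
    mix = SequinMix(mix_a, mix_b, lengths, assignment)

    floor = cfg.sequin_floor
    cols = {}
    for name in names:
        concs = np.array(
            [
                (mix_a if assignment[name] == "A" else mix_b)[sid]
                for sid in sorted(mix_a)
            ]
        )
        # flat below the floor: abundance stops tracking concentration and
        # sits at a noise level below the linear trend's value at c*
        mu = cfg.sequin_scale * np.where(concs >= floor, concs, 0.7 * floor)
        cols[name] = (
            _nb_draw(rng, mu, cfg.sequin_dispersion)
            if noise
            else np.rint(mu).astype(int)
        )
    counts = pd.DataFrame(cols, index=sorted(mix_a))
    counts.index.name = "sequin_id"
    truth = TruthSet(sequin_floor=floor)
    return mix, counts, truth


# ---------------------------------------------------------------------------
# CAGE peaks
# ---------------------------------------------------------------------------


def make_cage_peaks(
    novel: Annotation,
    truth: TruthSet,
    hit_fraction: float,
    cfg: SimConfig,
    window: int = 500,
):
    """Peaks inside the TSS windows of a ``hit_fraction`` subset of the
    injected novel-TSS transcripts, plus far-away decoys."""
    from .cage import CagePeakSet

    rng = np.random.default_rng(cfg.seed + 5)
    tss_tids = sorted(
        t for t, cat in truth.category.items() if cat == "novel_tss"
    )
    n_hit = int(round(len(tss_tids) * hit_fraction))
    hits = sorted(rng.choice(tss_tids, n_hit, replace=False)) if n_hit else []
    truth.cage_hits = set(hits)
    peaks = []
    for tid in hits:
        t = novel.transcripts[tid]
        offset = int(rng.integers(-window + 40, window - 40))
        center = t.tss + offset
        peaks.append(
            GenomicInterval(t.chrom, max(0, center - 15), center + 15, t.strand)
        )
    # decoys: way outside any gene slot margin
    for i in range(10):
        peaks.append(
            GenomicInterval("chr1", cfg.chrom_length - 500 + i * 40,
                            cfg.chrom_length - 480 + i * 40, "+")
        )
    return CagePeakSet(peaks)


# ---------------------------------------------------------------------------
# coding-model training sequences
# ---------------------------------------------------------------------------


def make_training_sequences(
    seed: int, n_coding: int = 60, n_noncoding: int = 60
) -> tuple[list[str], list[str]]:
    """Separable labelled sequences: long clean ORFs vs ATG-free RNA."""
    rng = np.random.default_rng(seed)
    coding = []
    for _ in range(n_coding):
        utr5 = "".join("CGT"[i] for i in rng.integers(0, 3, int(rng.integers(20, 60))))
        utr3 = "".join("ACGT"[i] for i in rng.integers(0, 4, int(rng.integers(30, 80))))
        coding.append(utr5 + _make_cds_sequence(rng, int(rng.integers(150, 300))) + utr3)
    noncoding = [
        "".join("CGT"[i] for i in rng.integers(0, 3, int(rng.integers(400, 900))))
        for _ in range(n_noncoding)
    ]
    return coding, noncoding


# ---------------------------------------------------------------------------
# purpose-built cohorts for the worked-example checks
# ---------------------------------------------------------------------------


def make_validation_cohort(
    n_total: int, n_pass: int, seed: int = 0
) -> tuple[Annotation, Annotation, CoverageTrack, TruthSet]:
    """A candidate set of ``n_total`` single-cassette novel transcripts of
    which exactly ``n_pass`` meet the 15-read / 75%-length coverage rule.

    Genes are laid out on a virtual chromosome; no genome sequence is
    needed for the coverage filter.
    """
    if not 0 <= n_pass <= n_total:
        raise ValueError("need 0 <= n_pass <= n_total")
    rng = np.random.default_rng(seed)
    slot = 2_000
    chrom = "vchr1"
    ref: dict[str, TranscriptModel] = {}
    novel: dict[str, TranscriptModel] = {}
    truth = TruthSet()
    painted: list[tuple[int, int, int]] = []
    pass_flags = np.zeros(n_total, dtype=bool)
    pass_flags[rng.choice(n_total, n_pass, replace=False)] = True

    for i in range(n_total):
        base = i * slot + 100
        strand = "+" if i % 2 == 0 else "-"
        exons = [
            GenomicInterval(chrom, base, base + 200, strand),
            GenomicInterval(chrom, base + 500, base + 700, strand),
            GenomicInterval(chrom, base + 1000, base + 1200, strand),
        ]
        gid, tid = f"VG{i:05d}", f"VT{i:05d}"
        ref[tid] = TranscriptModel(tid, gid, chrom, strand, exons)
        cassette = GenomicInterval(chrom, base + 280, base + 370, strand)
        nid = f"VN{i:05d}"
        novel[nid] = TranscriptModel(
            nid, gid, chrom, strand, exons + [cassette], source="novel"
        )
        truth.category[nid] = "cassette"
        truth.novel_exons[nid] = [cassette]
        truth.coverage_pass[nid] = bool(pass_flags[i])
        for e in exons:
            painted.append((e.start, e.end, 20))
        if pass_flags[i]:
            painted.append((cassette.start, cassette.end, 20))
        else:
            # 45 of 90 bases covered: 50% < 75% -> fail
            painted.append((cassette.start, cassette.start + 45, 20))

    track = CoverageTrack({chrom: sorted(painted)})
    return Annotation(ref), Annotation(novel), track, truth


def make_coding_cohort(
    n_frame_conserving: int,
    n_cpat_coding: int,
    n_noncoding_parent: int,
    n_frameshift: int,
    n_cpat_noncoding: int,
    seed: int = 0,
) -> tuple[dict[str, str], Annotation, Annotation, TruthSet]:
    """A validated novel-transcript set hitting each branch of the coding
    decision tree in the requested numbers.

    Returns (genome, reference annotation, novel annotation, truth). The
    CPAT branches use coding-biotype genes without CDS records whose
    transcript sequences are engineered to be ORF-rich or ATG-free.
    """
    groups = [
        ("frame_conserving", n_frame_conserving),
        ("cpat_coding", n_cpat_coding),
        ("noncoding_parent", n_noncoding_parent),
        ("frameshift", n_frameshift),
        ("cpat_noncoding", n_cpat_noncoding),
    ]
    n_total = sum(n for _, n in groups)
    rng = np.random.default_rng(seed)
    slot = 3_000
    chrom = "cchr1"
    genome_arr = bytearray(_random_seq_codes(rng, n_total * slot + slot).tobytes())
    genome = {chrom: genome_arr}

    ref: dict[str, TranscriptModel] = {}
    novel: dict[str, TranscriptModel] = {}
    biotypes: dict[str, str] = {}
    truth = TruthSet()

    reasons = [r for r, n in groups for _ in range(n)]
    order = rng.permutation(n_total)
    for slot_i, case_i in enumerate(order):
        reason = reasons[case_i]
        base = slot_i * slot + 600
        strand = "+"
        exons = [
            GenomicInterval(chrom, base, base + 240, strand),
            GenomicInterval(chrom, base + 540, base + 780, strand),
            GenomicInterval(chrom, base + 1080, base + 1320, strand),
        ]
        gid, tid = f"CG{case_i:05d}", f"CT{case_i:05d}"
        nid = f"CN{case_i:05d}"
        tx_len = sum(len(e) for e in exons)

        cds = None
        if reason in ("frame_conserving", "frameshift"):
            biotypes[gid] = "coding"
            utr5, n_codons = 60, (tx_len - 60 - 60 - 6) // 3
            seq = (
                "".join("CGT"[i] for i in rng.integers(0, 3, utr5))
                + _make_cds_sequence(rng, n_codons)
            )
            seq += "".join(
                "ACGT"[i] for i in rng.integers(0, 4, tx_len - len(seq))
            )
            _paint(genome, chrom, exons, strand, seq)
            cds_len = 3 * n_codons + 6
            # genomic CDS span across the exon chain
            gpos = [p for e in exons for p in range(e.start, e.end)]
            cds_pos = gpos[utr5 : utr5 + cds_len]
            cds = GenomicInterval(chrom, min(cds_pos), max(cds_pos) + 1, strand)
        elif reason == "noncoding_parent":
            biotypes[gid] = "noncoding"
        else:
            # coding-biotype gene without CDS records -> CPAT branch
            biotypes[gid] = "coding"
            if reason == "cpat_coding":
                n_codons = (tx_len - 12) // 3 - 2
                seq = "CGTCGT" + _make_cds_sequence(rng, n_codons)
                seq += "".join(
                    "CGT"[i] for i in rng.integers(0, 3, tx_len - len(seq))
                )
                _paint(genome, chrom, exons, strand, seq)
            else:  # cpat_noncoding: ATG-free gene body and upstream margin
                seq = "".join("CGT"[i] for i in rng.integers(0, 3, tx_len))
                _paint(genome, chrom, exons, strand, seq)
                up = _random_seq_codes(rng, 400, no_a=True).tobytes()
                genome_arr[base - 400 : base] = up

        ref[tid] = TranscriptModel(tid, gid, chrom, strand, exons, cds=cds)

        if reason in ("frame_conserving", "frameshift", "noncoding_parent"):
            length = 90 if reason != "frameshift" else 91
            lo = exons[0].end + 70
            cassette = GenomicInterval(chrom, lo, lo + length, strand)
            n_exons = sorted(exons + [cassette], key=lambda e: e.start)
            novel[nid] = TranscriptModel(
                nid, gid, chrom, strand, n_exons, source="novel"
            )
            truth.novel_exons[nid] = [cassette]
        else:
            shifted = [
                GenomicInterval(chrom, exons[0].start - 300, exons[0].end, strand)
            ] + exons[1:]
            novel[nid] = TranscriptModel(
                nid, gid, chrom, strand, shifted, source="novel"
            )
        status = (
            "coding" if reason in ("frame_conserving", "cpat_coding") else "noncoding"
        )
        truth.coding_truth[nid] = (status, reason)
        truth.category[nid] = "coding_case"

    genome_str = {chrom: bytes(genome_arr).decode()}
    return genome_str, Annotation(ref, biotypes), Annotation(novel, biotypes), truth
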