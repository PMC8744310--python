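"""Coding-status assessment for validated novel transcripts.

Combines a frame-conservation test against the best-matching reference
isoform with a trainable coding-potential score (logistic regression on
ORF length, ORF coverage, Fickett TESTCODE score and hexamer usage bias),
resolved through a fixed decision tree:

1. noncoding parent gene            -> noncoding / noncoding_parent
2. structural change breaks frame   -> noncoding / frameshift
3. structural change conserves frame-> coding / frame_conserving
4. otherwise coding probability     -> coding / cpat_coding
                                       or noncoding / cpat_noncoding

The frame test only applies to transcripts with splice-level novel
features (cassette exons, shifted splice sites, novel junctions); end-site
only novelty defers to the coding-potential model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product

import numpy as np
from sklearn.linear_model import LogisticRegression

from .annotation import Annotation, TranscriptModel, transcript_junctions
from .novelty import NoveltyReport

__all__ = [
    "ORFResult",
    "CodingModel",
    "CodingCall",
    "longest_orf",
    "transcript_sequence",
    "frame_conservation",
    "fickett_score",
    "build_hexamer_table",
    "hexamer_score",
    "coding_features",
    "train_coding_model",
    "coding_probability",
    "classify_coding_status",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
DEFAULT_CP_THRESHOLD = 0.364


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def transcript_sequence(t: TranscriptModel, genome: dict[str, str]) -> str:
    """Spliced, sense-strand transcript sequence."""
    if t.chrom not in genome:
        raise KeyError(f"chromosome {t.chrom} missing from genome")
    seq = "".join(genome[t.chrom][e.start : e.end] for e in t.exons)
    return reverse_complement(seq) if t.strand == "-" else seq


# ---------------------------------------------------------------------------
# ORF scanning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ORFResult:
    start: int  # transcript coordinates, 0-based half-open
    end: int
    frame: int
    length: int
    complete: bool


def longest_orf(seq: str) -> ORFResult | None:
    """Longest ATG-initiated ORF across the three forward frames.

    A stop codon terminates the ORF (stop included in its length); an ORF
    running off the end of the sequence is reported incomplete. Ties by
    length break toward the smaller start.
    """
    seq = seq.upper()
    best: ORFResult | None = None
    for frame in range(3):
        start: int | None = None
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            if start is None:
                if codon == "ATG":
                    start = pos
            elif codon in STOP_CODONS:
                cand = ORFResult(start, pos + 3, frame, pos + 3 - start, True)
                if best is None or cand.length > best.length or (
                    cand.length == best.length and cand.start < best.start
                ):
                    best = cand
                start = None
        if start is not None:
            # incomplete ORF to sequence end (truncated to full codons)
            end = start + ((len(seq) - start) // 3) * 3
            cand = ORFResult(start, end, frame, end - start, False)
            if best is None or cand.length > best.length or (
                cand.length == best.length and cand.start < best.start
            ):
                best = cand
    return best


# ---------------------------------------------------------------------------
# Fickett TESTCODE
# ---------------------------------------------------------------------------

# Published TESTCODE lookup tables: per-base probabilities for ten bins of
# the position and composition parameters, and per-base weights.
_POSITION_PROB = {
    "A": [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],
    "C": [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],
    "G": [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],
    "T": [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_POSITION_BINS = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]

_CONTENT_PROB = {
    "A": [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
    "C": [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31],
    "G": [0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29],
    "T": [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58],
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_BINS = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0]


def _lookup(value: float, bins: list[float], probs: list[float]) -> float:
    for idx, threshold in enumerate(bins):
        if value >= threshold:
            return probs[idx]
    return probs[-1]


def fickett_score(seq: str) -> float:
    """TESTCODE score: weighted sum of eight table-derived probabilities
    (a position and a composition parameter per base)."""
    seq = seq.upper()
    if len(seq) < 2:
        raise ValueError("sequence too short for Fickett score")
    total = len(seq)
    score = 0.0
    for base in "ACGT":
        phase_counts = [seq[i::3].count(base) for i in range(3)]
        position_value = max(phase_counts) / (min(phase_counts) + 1)
        content_value = seq.count(base) / total
        score += (
            _lookup(position_value, _POSITION_BINS, _POSITION_PROB[base])
            * _POSITION_WEIGHT[base]
        )
        score += (
            _lookup(content_value, _CONTENT_BINS, _CONTENT_PROB[base])
            * _CONTENT_WEIGHT[base]
        )
    return score


# ---------------------------------------------------------------------------
# Hexamer usage bias
# ---------------------------------------------------------------------------

_HEXAMERS = ["".join(p) for p in product("ACGT", repeat=6)]


def _hexamer_freqs(seqs: list[str], pseudocount: float) -> dict[str, float]:
    counts = dict.fromkeys(_HEXAMERS, pseudocount)
    total = pseudocount * len(_HEXAMERS)
    for seq in seqs:
        seq = seq.upper()
        for i in range(0, len(seq) - 5, 3):  # in-frame steps
            hx = seq[i : i + 6]
            if hx in counts:
                counts[hx] += 1
                total += 1
    return {h: c / total for h, c in counts.items()}


def build_hexamer_table(
    coding_seqs: list[str],
    noncoding_seqs: list[str],
    pseudocount: float = 1.0,
) -> dict[str, float]:
    """log(coding frequency / noncoding frequency) per hexamer, with a
    pseudocount of one occurrence per hexamer class in each set."""
    if not coding_seqs or not noncoding_seqs:
        raise ValueError("both training sets must be non-empty")
    fc = _hexamer_freqs(coding_seqs, pseudocount)
    fn = _hexamer_freqs(noncoding_seqs, pseudocount)
    return {h: math.log(fc[h] / fn[h]) for h in _HEXAMERS}


def hexamer_score(seq: str, table: dict[str, float]) -> float:
    """Mean log-ratio over the in-frame hexamers of ``seq`` (frame 0)."""
    seq = seq.upper()
    if len(seq) < 6:
        raise ValueError("sequence_too_short")
    vals = [
        table[seq[i : i + 6]]
        for i in range(0, len(seq) - 5, 3)
        if seq[i : i + 6] in table
    ]
    if not vals:
        return 0.0
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Coding-potential model
# ---------------------------------------------------------------------------


@dataclass
class CodingModel:
    hexamer_table: dict[str, float]
    logistic_weights: np.ndarray  # (orf_length, orf_coverage, fickett, hexamer)
    intercept: float
    threshold: float = DEFAULT_CP_THRESHOLD

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")


def coding_features(seq: str, table: dict[str, float]) -> np.ndarray:
    """(ORF length, ORF coverage, Fickett, hexamer) feature vector."""
    orf = longest_orf(seq)
    if orf is None:
        orf_len, orf_cov, hex_sc = 0.0, 0.0, 0.0
    else:
        orf_len = float(orf.length)
        orf_cov = orf.length / len(seq)
        orf_seq = seq[orf.start : orf.end]
        hex_sc = hexamer_score(orf_seq, table) if len(orf_seq) >= 6 else 0.0
    return np.array([orf_len, orf_cov, fickett_score(seq), hex_sc])


def train_coding_model(
    coding_seqs: list[str],
    noncoding_seqs: list[str],
    threshold: float = DEFAULT_CP_THRESHOLD,
    pseudocount: float = 1.0,
) -> CodingModel:
    """Fit the logistic coding-potential model on labelled sequences.

    Features are standardised for the optimiser; the returned weights are
    folded back to raw feature space so scoring needs no scaler.
    """
    if len(coding_seqs) < 20 or len(noncoding_seqs) < 20:
        raise ValueError("need >= 20 training sequences per class")
    table = build_hexamer_table(coding_seqs, noncoding_seqs, pseudocount)
    X = np.array(
        [coding_features(s, table) for s in coding_seqs + noncoding_seqs]
    )
    y = np.array([1] * len(coding_seqs) + [0] * len(noncoding_seqs))
    if len(set(y)) < 2:
        raise ValueError("degenerate training: single class")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    clf = LogisticRegression(C=1e4, max_iter=5000)
    clf.fit((X - mu) / sd, y)
    w_std = clf.coef_[0]
    w_raw = w_std / sd
    b_raw = float(clf.intercept_[0] - np.dot(w_std, mu / sd))
    return CodingModel(table, w_raw, b_raw, threshold)


def coding_probability(seq: str, model: CodingModel) -> float:
    x = coding_features(seq, model.hexamer_table)
    z = float(np.dot(model.logistic_weights, x) + model.intercept)
    return 1.0 / (1.0 + math.exp(-z))


# ---------------------------------------------------------------------------
# Frame conservation
# ---------------------------------------------------------------------------


def _exonic_length_within(t: TranscriptModel, start: int, end: int) -> int:
    return sum(
        max(0, min(end, e.end) - max(start, e.start)) for e in t.exons
    )


def _best_reference_match(
    t: TranscriptModel, reference: Annotation
) -> TranscriptModel | None:
    """CDS-bearing reference isoform of the same gene sharing the most
    junctions with ``t``; ties broken by longest CDS."""
    gene = reference.genes.get(t.gene_id)
    if gene is None:
        return None
    own = {
        (j.intron_start, j.intron_end) for j in transcript_junctions(t)
    }
    best, best_key = None, None
    for tid in gene.transcript_ids:
        ref = reference.transcripts[tid]
        if ref.cds is None:
            continue
        shared = len(
            own
            & {(j.intron_start, j.intron_end) for j in transcript_junctions(ref)}
        )
        key = (shared, len(ref.cds), ref.transcript_id)
        if best_key is None or key > best_key:
            best, best_key = ref, key
    return best


def frame_conservation(
    t: TranscriptModel,
    report: NoveltyReport,
    reference: Annotation,
) -> bool | None:
    """Whether the structural novel features preserve the reading frame.

    Returns None when not applicable: no splice-level novel features, or no
    CDS-bearing reference isoform of the gene. Otherwise the net change in
    CDS-overlapping exonic length against the best-matching reference
    isoform must be a multiple of 3 (changes confined to UTRs give a net
    change of 0 and count as conserving).
    """
    structural = (
        report.cassette_exons
        or report.both_novel_exons
        or report.novel_donor_sites
        or report.novel_acceptor_sites
        or report.novel_junctions_known_sites
    )
    if not structural:
        return None
    ref = _best_reference_match(t, reference)
    if ref is None or ref.cds is None:
        return None
    delta = _exonic_length_within(
        t, ref.cds.start, ref.cds.end
    ) - _exonic_length_within(ref, ref.cds.start, ref.cds.end)
    return delta % 3 == 0


# ---------------------------------------------------------------------------
# Decision tree
# ---------------------------------------------------------------------------


@dataclass
class CodingCall:
    transcript_id: str
    status: str  # {coding, noncoding}
    reason: str  # {frame_conserving, cpat_coding, frameshift,
    #               noncoding_parent, cpat_noncoding}
    coding_prob: float | None = None


def classify_coding_status(
    t: TranscriptModel,
    report: NoveltyReport,
    reference: Annotation,
    model: CodingModel,
    genome: dict[str, str],
) -> CodingCall:
    gene = reference.genes.get(t.gene_id)
    if gene is not None and gene.biotype == "noncoding":
        return CodingCall(t.transcript_id, "noncoding", "noncoding_parent")
    conserved = frame_conservation(t, report, reference)
    if conserved is False:
        return CodingCall(t.transcript_id, "noncoding", "frameshift")
    if conserved is True:
        return CodingCall(t.transcript_id, "coding", "frame_conserving")
    seq = transcript_sequence(t, genome)
    cp = coding_probability(seq, model)
    if cp >= model.threshold:
        return CodingCall(t.transcript_id, "coding", "cpat_coding", cp)
    return CodingCall(t.transcript_id, "noncoding", "cpat_noncoding", cp)
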