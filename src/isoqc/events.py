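"""Alternative-splicing event classification and differential isoform usage.

Pairwise events between isoforms of a gene are classified into the usual
taxonomy — exon skipping (ES), multiple exon skipping (MES), intron
retention (IR), alternative donor/acceptor (A5/A3), alternative first/last
exon (ATSS/ATTS) and mutually exclusive exons (MEE). Differential usage is
quantified through per-sample isoform fractions (IF); a gene's switch score
is the sum of absolute condition-mean IF differences (sum |dIF|), tested by
permutation of condition labels with Benjamini-Hochberg correction across
genes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import Annotation, TranscriptModel, transcript_junctions
from .coding import CodingCall
from .stats import bh_qvalues

__all__ = [
    "SpliceEvent",
    "SwitchResult",
    "pairwise_events",
    "isoform_fractions",
    "dtu_switch_test",
    "gene_event_summary",
    "functional_consequences",
]

EVENT_TYPES = ("ES", "MES", "IR", "A5", "A3", "ATSS", "ATTS", "MEE")


@dataclass(frozen=True)
class SpliceEvent:
    gene_id: str
    type: str
    coordinates: tuple[tuple[int, int], ...]
    isoform_pair: tuple[str, str]  # (inclusion-form isoform, other)

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.type!r}")


def _junction_tuples(t: TranscriptModel) -> list[tuple[int, int]]:
    return [(j.intron_start, j.intron_end) for j in transcript_junctions(t)]


def _skipping_events(a: TranscriptModel, b: TranscriptModel) -> list[SpliceEvent]:
    """ES/MES: runs of internal exons of ``a`` absent from ``b`` and
    spanned by a single junction of ``b`` whose outer sites match the
    flanking junctions of the run."""
    events = []
    b_exons = set(b.exon_chain())
    b_juncs = set(_junction_tuples(b))
    a_juncs = _junction_tuples(a)
    n = len(a.exons)
    i = 1
    while i < n - 1:
        if a.exon_chain()[i] in b_exons:
            i += 1
            continue
        j = i
        while j < n - 1 and a.exon_chain()[j] not in b_exons:
            j += 1
        # run of missing internal exons a[i:j]; flanking introns exist
        # because the run is internal
        span = (a_juncs[i - 1][0], a_juncs[j - 1][1])
        if span in b_juncs:
            coords = tuple((e.start, e.end) for e in a.exons[i:j])
            etype = "ES" if j - i == 1 else "MES"
            events.append(
                SpliceEvent(
                    a.gene_id, etype, coords, (a.transcript_id, b.transcript_id)
                )
            )
        i = j
    return events


def _retention_events(a: TranscriptModel, b: TranscriptModel) -> list[SpliceEvent]:
    """IR: an exon of ``a`` strictly contains an intron of ``b`` together
    with margins of both flanking exons of ``b``."""
    events = []
    for s, e in _junction_tuples(b):
        for exon in a.exons:
            if exon.start < s and e < exon.end:
                events.append(
                    SpliceEvent(
                        a.gene_id,
                        "IR",
                        ((s, e),),
                        (a.transcript_id, b.transcript_id),
                    )
                )
                break
    return events


def _altsite_events(a: TranscriptModel, b: TranscriptModel) -> list[SpliceEvent]:
    """A5/A3: junction pairs sharing exactly one site, where the exons
    adjacent to the differing site overlap (which excludes skipping)."""

    def _adjacent_exon(t: TranscriptModel, pos: int, side: str):
        # side 'end': exon ending at pos; side 'start': exon starting at pos
        for e in t.exons:
            if side == "end" and e.end == pos:
                return e
            if side == "start" and e.start == pos:
                return e
        return None

    events = []
    b_juncs = _junction_tuples(b)
    for ja in _junction_tuples(a):
        for jb in b_juncs:
            if ja == jb:
                continue
            if ja[1] == jb[1] and ja[0] != jb[0]:
                ea = _adjacent_exon(a, ja[0], "end")
                eb = _adjacent_exon(b, jb[0], "end")
                shifted_left = True
            elif ja[0] == jb[0] and ja[1] != jb[1]:
                ea = _adjacent_exon(a, ja[1], "start")
                eb = _adjacent_exon(b, jb[1], "start")
                shifted_left = False
            else:
                continue
            if ea is None or eb is None or not ea.overlaps(eb):
                continue
            # left boundary of an intron is the donor on '+', acceptor on '-'
            donor_side = shifted_left if a.strand == "+" else not shifted_left
            etype = "A5" if donor_side else "A3"
            coords = tuple(sorted([ja, jb]))
            # inclusion form: isoform with the shorter intron (more exon)
            incl, other = (
                (a.transcript_id, b.transcript_id)
                if ja[1] - ja[0] < jb[1] - jb[0]
                else (b.transcript_id, a.transcript_id)
            )
            events.append(SpliceEvent(a.gene_id, etype, coords, (incl, other)))
    return events


def _terminal_events(a: TranscriptModel, b: TranscriptModel) -> list[SpliceEvent]:
    """ATSS/ATTS: differing terminal exons with the rest of the chain
    shared (or non-overlapping alternatives whose inner chain matches)."""
    events = []
    ca, cb = a.exon_chain(), b.exon_chain()
    ja, jb = _junction_tuples(a), _junction_tuples(b)

    def _alt_terminal(first: bool) -> bool:
        ea = ca[0] if first else ca[-1]
        eb = cb[0] if first else cb[-1]
        if ea == eb:
            return False
        # the transcript-end-side boundary must differ, otherwise the
        # difference is splice-side (A5/A3/IR territory)
        if first and ea[0] == eb[0]:
            return False
        if not first and ea[1] == eb[1]:
            return False
        rest_a = ja[1:] if first else ja[:-1]
        rest_b = jb[1:] if first else jb[:-1]
        if rest_a != rest_b:
            return False
        if ja and jb:
            edge_a = ja[0] if first else ja[-1]
            edge_b = jb[0] if first else jb[-1]
            if edge_a != edge_b:
                # differing edge junction: only a clean alternative
                # terminal exon if the two candidates do not overlap
                if max(ea[0], eb[0]) < min(ea[1], eb[1]):
                    return False
        return True

    # genomic first/last mapped to transcriptional start/end by strand
    for first in (True, False):
        if _alt_terminal(first):
            is_start = first if a.strand == "+" else not first
            etype = "ATSS" if is_start else "ATTS"
            ea = ca[0] if first else ca[-1]
            eb = cb[0] if first else cb[-1]
            events.append(
                SpliceEvent(
                    a.gene_id,
                    etype,
                    tuple(sorted([ea, eb])),
                    (a.transcript_id, b.transcript_id),
                )
            )
    return events


def _mee_events(a: TranscriptModel, b: TranscriptModel) -> list[SpliceEvent]:
    """MEE: one internal exon exclusive to each isoform, mutually
    non-overlapping, with both flanking junction partners shared."""
    events = []
    ca, cb = set(a.exon_chain()), set(b.exon_chain())
    ja, jb = _junction_tuples(a), _junction_tuples(b)
    for i in range(1, len(a.exons) - 1):
        ea = a.exons[i]
        if (ea.start, ea.end) in cb:
            continue
        for k in range(1, len(b.exons) - 1):
            eb = b.exons[k]
            if (eb.start, eb.end) in ca or ea.overlaps(eb):
                continue
            if (
                ja[i - 1][0] == jb[k - 1][0]
                and ja[i][1] == jb[k][1]
            ):
                coords = tuple(sorted([(ea.start, ea.end), (eb.start, eb.end)]))
                events.append(
                    SpliceEvent(
                        a.gene_id, "MEE", coords, (a.transcript_id, b.transcript_id)
                    )
                )
    return events


def pairwise_events(a: TranscriptModel, b: TranscriptModel) -> list[SpliceEvent]:
    """Classify the splice events distinguishing two isoforms of a gene.

    Each event is reported once per unordered pair; for asymmetric event
    types the inclusion-form isoform is first in ``isoform_pair``.
    """
    if a.gene_id != b.gene_id or a.chrom != b.chrom or a.strand != b.strand:
        raise ValueError("pairwise_events requires isoforms of one gene")
    seen: set[tuple] = set()
    events: list[SpliceEvent] = []
    for ev in (
        _skipping_events(a, b)
        + _skipping_events(b, a)
        + _retention_events(a, b)
        + _retention_events(b, a)
        + _altsite_events(a, b)
        + _terminal_events(a, b)
        + _mee_events(a, b)
    ):
        key = (ev.type, ev.coordinates)
        if key not in seen:
            seen.add(key)
            events.append(ev)
    return events


# ---------------------------------------------------------------------------
# Isoform fractions and the switch test
# ---------------------------------------------------------------------------


def isoform_fractions(counts: pd.DataFrame, tx2gene: dict[str, str]) -> pd.DataFrame:
    """IF(i, s) = count(i, s) / gene count; NaN where the gene count is 0."""
    missing = [t for t in counts.index if t not in tx2gene]
    if missing:
        raise KeyError(f"transcripts without gene mapping: {missing[:5]}")
    genes = pd.Series({t: tx2gene[t] for t in counts.index}, name="gene")
    gene_totals = counts.groupby(genes).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        ifm = counts / gene_totals
    return ifm.where(gene_totals > 0)


@dataclass
class SwitchResult:
    gene_id: str
    dif: dict[str, float]
    gene_switch_score: float
    p_value: float
    q_value: float = float("nan")
    consequences: list[str] = field(default_factory=list)


def _gene_switch_score(sub: np.ndarray, mask1: np.ndarray) -> float:
    """sum |dIF| for one gene; sub is isoforms x samples, NaN-aware."""
    with np.errstate(invalid="ignore"):
        m1 = np.nanmean(sub[:, mask1], axis=1)
        m2 = np.nanmean(sub[:, ~mask1], axis=1)
    dif = m1 - m2
    dif[np.isnan(dif)] = 0.0
    return float(np.abs(dif).sum())


def dtu_switch_test(
    ifm: pd.DataFrame,
    tx2gene: dict[str, str],
    design: pd.Series,
    n_perm: int = 2000,
    seed: int = 0,
) -> dict[str, SwitchResult]:
    """Permutation test of the per-gene switch score sum |dIF|.

    Exhaustive over all condition-label arrangements when there are at
    most 10000 of them, Monte-Carlo otherwise. p counts arrangements whose
    statistic is at least the observed one (the identity included).
    """
    conditions = design.unique()
    if len(conditions) != 2:
        raise ValueError("exactly two conditions required")
    samples = list(ifm.columns)
    labels = design.loc[samples].to_numpy()
    n1 = int((labels == conditions[0]).sum())
    if n1 < 2 or len(samples) - n1 < 2:
        raise ValueError("each condition needs >= 2 samples")

    import math

    n_arrangements = math.comb(len(samples), n1)
    if n_arrangements <= 10000:
        masks = []
        for combo in itertools.combinations(range(len(samples)), n1):
            m = np.zeros(len(samples), dtype=bool)
            m[list(combo)] = True
            masks.append(m)
    else:
        rng = np.random.default_rng(seed)
        masks = [None]  # placeholder; observed mask inserted below
        obs = labels == conditions[0]
        masks[0] = obs
        for _ in range(n_perm - 1):
            perm = rng.permutation(len(samples))
            masks.append(obs[perm])

    obs_mask = labels == conditions[0]
    genes = pd.Series({t: tx2gene[t] for t in ifm.index})
    results: dict[str, SwitchResult] = {}
    mat = ifm.to_numpy()
    gene_rows: dict[str, list[int]] = {}
    for i, t in enumerate(ifm.index):
        gene_rows.setdefault(genes[t], []).append(i)

    for gene_id, rows in gene_rows.items():
        sub = mat[rows]
        observed = _gene_switch_score(sub, obs_mask)
        null = np.array([_gene_switch_score(sub, m) for m in masks])
        p = float((null >= observed - 1e-12).sum() / len(masks))
        with np.errstate(invalid="ignore"):
            m1 = np.nanmean(sub[:, obs_mask], axis=1)
            m2 = np.nanmean(sub[:, ~obs_mask], axis=1)
        dif = m1 - m2
        dif = np.where(np.isnan(dif), 0.0, dif)
        results[gene_id] = SwitchResult(
            gene_id,
            dict(zip([ifm.index[r] for r in rows], dif.tolist())),
            observed,
            p,
        )

    qs = bh_qvalues(np.array([r.p_value for r in results.values()]))
    for r, q in zip(results.values(), qs):
        r.q_value = float(q)
    return results


# ---------------------------------------------------------------------------
# Gene-level event usage summary
# ---------------------------------------------------------------------------


def _carries_event(t: TranscriptModel, ev: SpliceEvent) -> bool:
    """Whether an isoform carries the event's inclusion form."""
    chain = set(t.exon_chain())
    juncs = set(_junction_tuples(t))
    if ev.type in ("ES", "MES", "MEE", "ATSS", "ATTS"):
        # inclusion form: carries the first-listed coordinate exon(s)
        target = ev.coordinates if ev.type in ("ES", "MES") else ev.coordinates[:1]
        return all(c in chain for c in target)
    if ev.type == "IR":
        (s, e) = ev.coordinates[0]
        return any(x.start < s and e < x.end for x in t.exons)
    if ev.type in ("A5", "A3"):
        shorter = min(ev.coordinates, key=lambda j: j[1] - j[0])
        return shorter in juncs
    raise AssertionError(ev.type)


def gene_event_summary(
    ann: Annotation,
    ifm: pd.DataFrame,
    tx2gene: dict[str, str],
    design: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Enumerate events over all isoform pairs per gene and report, per
    event, the condition difference in inclusion usage (mean summed IF of
    inclusion-form isoforms) with a label-permutation p-value."""
    conditions = list(design.unique())
    if len(conditions) != 2:
        raise ValueError("exactly two conditions required")
    samples = list(ifm.columns)
    labels = design.loc[samples].to_numpy()
    rng = np.random.default_rng(seed)

    rows = []
    by_gene: dict[str, list[str]] = {}
    for tid in ifm.index:
        if tid in ann.transcripts:
            by_gene.setdefault(tx2gene[tid], []).append(tid)

    for gene_id in sorted(by_gene):
        tids = sorted(by_gene[gene_id])
        if len(tids) < 2:
            continue
        seen: set[tuple] = set()
        events = []
        for a_id, b_id in itertools.combinations(tids, 2):
            for ev in pairwise_events(
                ann.transcripts[a_id], ann.transcripts[b_id]
            ):
                key = (ev.type, ev.coordinates)
                if key not in seen:
                    seen.add(key)
                    events.append(ev)
        for ev in events:
            carriers = [
                t for t in tids if _carries_event(ann.transcripts[t], ev)
            ]
            usage = ifm.loc[carriers].sum(axis=0, min_count=1).to_numpy()

            def diff(lbl):
                with np.errstate(invalid="ignore"):
                    u1 = np.nanmean(usage[lbl == conditions[0]])
                    u2 = np.nanmean(usage[lbl == conditions[1]])
                d = u1 - u2
                return 0.0 if np.isnan(d) else d

            observed = diff(labels)
            null = np.array(
                [diff(rng.permutation(labels)) for _ in range(n_perm)]
            )
            p = float(
                ((np.abs(null) >= abs(observed) - 1e-12).sum() + 1)
                / (n_perm + 1)
            )
            rows.append(
                {
                    "gene_id": gene_id,
                    "event_type": ev.type,
                    "coordinates": ";".join(f"{s}-{e}" for s, e in ev.coordinates),
                    "usage_diff": observed,
                    "p_value": p,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "event_type", "coordinates", "usage_diff", "p_value"],
    )


# ---------------------------------------------------------------------------
# Functional consequences of a switch
# ---------------------------------------------------------------------------


def functional_consequences(
    switch: SwitchResult,
    calls: dict[str, CodingCall],
    orf_lengths: dict[str, int] | None = None,
    feature_table: pd.DataFrame | None = None,
    orf_change_fraction: float = 0.10,
) -> list[str]:
    """Flags for the dominant gaining vs losing isoform of a switch:
    coding-status change, >= 10% ORF-length change, and domain / signal
    peptide gain or loss when an external feature table is supplied."""
    if not switch.dif:
        return []
    gaining = max(switch.dif, key=lambda t: switch.dif[t])
    losing = min(switch.dif, key=lambda t: switch.dif[t])
    if gaining == losing or switch.dif[gaining] <= switch.dif[losing]:
        return []
    flags: list[str] = []
    cg, cl = calls.get(gaining), calls.get(losing)
    if cg and cl and cg.status != cl.status:
        flags.append("coding_gain" if cg.status == "coding" else "coding_loss")
    if orf_lengths is not None:
        lg = orf_lengths.get(gaining, 0)
        ll = orf_lengths.get(losing, 0)
        base = max(min(lg, ll), 1)
        if abs(lg - ll) / base >= orf_change_fraction:
            flags.append("orf_length_change")
    if feature_table is not None:
        for col in feature_table.columns:
            fg = bool(feature_table.at[gaining, col]) if gaining in feature_table.index else False
            fl = bool(feature_table.at[losing, col]) if losing in feature_table.index else False
            if fg and not fl:
                flags.append(f"{col}_gain")
            elif fl and not fg:
                flags.append(f"{col}_loss")
    return flags
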