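import itertools

import numpy as np
import pandas as pd
import pytest

from isoqc.annotation import Annotation
from isoqc.coding import CodingCall
from isoqc.events import (
    SwitchResult,
    dtu_switch_test,
    functional_consequences,
    gene_event_summary,
    isoform_fractions,
    pairwise_events,
)
from conftest import tx
from oracles import switch_p_oracle


def types(events):
    return sorted(e.type for e in events)


class TestPairwiseEvents:
    def test_exon_skipping(self):
        a = tx("a", [(0, 10), (20, 30), (40, 50)])
        b = tx("b", [(0, 10), (40, 50)])
        assert types(pairwise_events(a, b)) == ["ES"]

    def test_multiple_exon_skipping(self):
        a = tx("a", [(0, 10), (20, 30), (40, 50), (60, 70)])
        b = tx("b", [(0, 10), (60, 70)])
        assert types(pairwise_events(a, b)) == ["MES"]

    def test_intron_retention(self):
        a = tx("a", [(100, 400)])
        b = tx("b", [(100, 200), (300, 400)])
        assert types(pairwise_events(a, b)) == ["IR"]

    def test_alt_donor_plus_strand(self):
        a = tx("a", [(100, 200), (300, 400)])
        b = tx("b", [(100, 210), (300, 400)])
        assert types(pairwise_events(a, b)) == ["A5"]

    def test_alt_acceptor_plus_strand(self):
        a = tx("a", [(100, 200), (300, 400)])
        b = tx("b", [(100, 200), (290, 400)])
        assert types(pairwise_events(a, b)) == ["A3"]

    def test_donor_acceptor_swap_on_minus_strand(self):
        a = tx("a", [(100, 200), (300, 400)], strand="-")
        b = tx("b", [(100, 210), (300, 400)], strand="-")
        assert types(pairwise_events(a, b)) == ["A3"]
        a = tx("a", [(100, 200), (300, 400)], strand="-")
        b = tx("b", [(100, 200), (290, 400)], strand="-")
        assert types(pairwise_events(a, b)) == ["A5"]

    def test_alternative_first_exon(self):
        a = tx("a", [(0, 10), (40, 50), (60, 70)])
        b = tx("b", [(20, 30), (40, 50), (60, 70)])
        assert types(pairwise_events(a, b)) == ["ATSS"]

    def test_alternative_last_exon_minus_strand_is_atss(self):
        a = tx("a", [(0, 10), (40, 50), (60, 70)], strand="-")
        b = tx("b", [(0, 10), (40, 50), (80, 90)], strand="-")
        assert types(pairwise_events(a, b)) == ["ATSS"]

    def test_alternative_last_exon(self):
        a = tx("a", [(0, 10), (40, 50), (60, 70)])
        b = tx("b", [(0, 10), (40, 50), (80, 90)])
        assert types(pairwise_events(a, b)) == ["ATTS"]

    def test_mutually_exclusive_exons(self):
        a = tx("a", [(0, 10), (20, 30), (60, 70)])
        b = tx("b", [(0, 10), (40, 50), (60, 70)])
        assert types(pairwise_events(a, b)) == ["MEE"]

    def test_identical_isoforms_no_events(self):
        a = tx("a", [(0, 10), (20, 30)])
        b = tx("b", [(0, 10), (20, 30)])
        assert pairwise_events(a, b) == []

    def test_different_gene_rejected(self):
        a = tx("a", [(0, 10), (20, 30)], gene="G1")
        b = tx("b", [(0, 10), (20, 30)], gene="G2")
        with pytest.raises(ValueError):
            pairwise_events(a, b)

    def test_symmetric_in_argument_order(self):
        a = tx("a", [(0, 10), (20, 30), (40, 50)])
        b = tx("b", [(0, 10), (40, 50)])
        ab = {(e.type, e.coordinates) for e in pairwise_events(a, b)}
        ba = {(e.type, e.coordinates) for e in pairwise_events(b, a)}
        assert ab == ba

    def test_translation_invariance(self):
        rng = np.random.default_rng(17)
        universe = [(0, 10), (20, 30), (40, 50), (60, 70), (80, 90)]
        for _ in range(100):
            na = rng.integers(2, 6)
            nb = rng.integers(2, 6)
            ea = sorted(
                universe[i] for i in rng.choice(5, na, replace=False)
            )
            eb = sorted(
                universe[i] for i in rng.choice(5, nb, replace=False)
            )
            shift = int(rng.integers(1, 10_000))
            base = {
                (e.type, e.coordinates)
                for e in pairwise_events(tx("a", ea), tx("b", eb))
            }
            moved = {
                (
                    e.type,
                    tuple((s - shift, x - shift) for s, x in e.coordinates),
                )
                for e in pairwise_events(
                    tx("a", [(s + shift, x + shift) for s, x in ea]),
                    tx("b", [(s + shift, x + shift) for s, x in eb]),
                )
            }
            assert base == moved


def _events_oracle(ea, eb, strand="+"):
    """Independent rule evaluation on two exon chains (set logic)."""
    ja = [(e1[1], e2[0]) for e1, e2 in zip(ea, ea[1:])]
    jb = [(e1[1], e2[0]) for e1, e2 in zip(eb, eb[1:])]
    out = set()

    def skipping(x, jx, y_exons, jy):
        runs = []
        run = []
        for i in range(1, len(x) - 1):
            if x[i] not in y_exons:
                run.append(i)
            else:
                if run:
                    runs.append(run)
                run = []
        if run:
            runs.append(run)
        for run in runs:
            # split runs into maximal consecutive stretches
            for grp in np.split(run, np.where(np.diff(run) != 1)[0] + 1):
                grp = list(grp)
                span = (jx[grp[0] - 1][0], jx[grp[-1]][1])
                if span in set(jy):
                    coords = tuple(x[i] for i in grp)
                    out.add(("ES" if len(grp) == 1 else "MES", coords))

    skipping(ea, ja, set(eb), jb)
    skipping(eb, jb, set(ea), ja)
    for s, e in jb:
        if any(x[0] < s and e < x[1] for x in ea):
            out.add(("IR", ((s, e),)))
    for s, e in ja:
        if any(x[0] < s and e < x[1] for x in eb):
            out.add(("IR", ((s, e),)))
    for j1 in ja:
        for j2 in jb:
            if j1 == j2:
                continue
            if j1[1] == j2[1] and j1[0] != j2[0]:
                x1 = next((x for x in ea if x[1] == j1[0]), None)
                x2 = next((x for x in eb if x[1] == j2[0]), None)
                side_left = True
            elif j1[0] == j2[0] and j1[1] != j2[1]:
                x1 = next((x for x in ea if x[0] == j1[1]), None)
                x2 = next((x for x in eb if x[0] == j2[1]), None)
                side_left = False
            else:
                continue
            if x1 and x2 and max(x1[0], x2[0]) < min(x1[1], x2[1]):
                donor = side_left if strand == "+" else not side_left
                out.add(
                    ("A5" if donor else "A3", tuple(sorted((j1, j2))))
                )
    for first in (True, False):
        t1 = ea[0] if first else ea[-1]
        t2 = eb[0] if first else eb[-1]
        if t1 == t2:
            continue
        if (first and t1[0] == t2[0]) or (not first and t1[1] == t2[1]):
            continue
        rest1 = ja[1:] if first else ja[:-1]
        rest2 = jb[1:] if first else jb[:-1]
        if rest1 != rest2:
            continue
        if ja and jb:
            edge1 = ja[0] if first else ja[-1]
            edge2 = jb[0] if first else jb[-1]
            if edge1 != edge2 and max(t1[0], t2[0]) < min(t1[1], t2[1]):
                continue
        is_start = first if strand == "+" else not first
        out.add(("ATSS" if is_start else "ATTS", tuple(sorted((t1, t2)))))
    for i in range(1, len(ea) - 1):
        if ea[i] in set(eb):
            continue
        for k in range(1, len(eb) - 1):
            if eb[k] in set(ea):
                continue
            if max(ea[i][0], eb[k][0]) < min(ea[i][1], eb[k][1]):
                continue
            if ja[i - 1][0] == jb[k - 1][0] and ja[i][1] == jb[k][1]:
                out.add(("MEE", tuple(sorted((ea[i], eb[k])))))
    return out


def test_matches_rule_oracle_on_enumerated_toy_graphs():
    """Exhaustive comparison over all >=2-exon subsets of a 5-slot universe,
    with an extra merged exon to exercise intron retention."""
    universe = [(0, 10), (20, 30), (40, 50), (60, 70), (80, 90)]
    chains = []
    for r in range(2, 6):
        chains.extend(itertools.combinations(universe, r))
    chains.append(((0, 10), (20, 50), (60, 70)))  # merged slots 1+2
    chains.append(((0, 10), (20, 70), (80, 90)))  # merged slots 1..3
    n_checked = 0
    for ea, eb in itertools.combinations(chains, 2):
        got = {
            (e.type, e.coordinates)
            for e in pairwise_events(tx("a", list(ea)), tx("b", list(eb)))
        }
        want = _events_oracle(list(ea), list(eb))
        assert got == want, (ea, eb)
        n_checked += 1
    assert n_checked >= 200


class TestIsoformFractions:
    def test_basic_fractions(self):
        counts = pd.DataFrame(
            {"s1": [30, 70]}, index=["t1", "t2"]
        )
        ifm = isoform_fractions(counts, {"t1": "g", "t2": "g"})
        assert ifm["s1"].tolist() == [0.3, 0.7]

    def test_zero_gene_count_missing(self):
        counts = pd.DataFrame({"s1": [0, 0]}, index=["t1", "t2"])
        ifm = isoform_fractions(counts, {"t1": "g", "t2": "g"})
        assert ifm["s1"].isna().all()

    def test_sums_to_one_per_expressed_gene(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            rng.integers(0, 50, (6, 4)),
            index=[f"t{i}" for i in range(6)],
            columns=[f"s{i}" for i in range(4)],
        )
        tx2gene = {f"t{i}": f"g{i % 2}" for i in range(6)}
        ifm = isoform_fractions(counts, tx2gene)
        genes = pd.Series(tx2gene)
        sums = ifm.groupby(genes).sum()
        totals = counts.groupby(genes).sum()
        assert (((sums - 1).abs() < 1e-9) | (totals == 0)).all().all()

    def test_unmapped_transcript_errors(self):
        counts = pd.DataFrame({"s1": [1]}, index=["t1"])
        with pytest.raises(KeyError):
            isoform_fractions(counts, {})


class TestSwitchTest:
    def _design(self):
        samples = [f"s{i}" for i in range(10)]
        return pd.Series(["c1"] * 5 + ["c2"] * 5, index=samples)

    def test_identical_if_score_zero_p_one(self):
        design = self._design()
        ifm = pd.DataFrame(
            [[0.5] * 10, [0.5] * 10], index=["t1", "t2"], columns=design.index
        )
        res = dtu_switch_test(ifm, {"t1": "g", "t2": "g"}, design)
        assert res["g"].gene_switch_score == 0
        assert res["g"].p_value == 1.0

    def test_perfect_switch_minimal_p(self):
        design = self._design()
        ifm = pd.DataFrame(
            [[0.9] * 5 + [0.1] * 5, [0.1] * 5 + [0.9] * 5],
            index=["t1", "t2"],
            columns=design.index,
        )
        res = dtu_switch_test(ifm, {"t1": "g", "t2": "g"}, design)
        assert res["g"].p_value == pytest.approx(2 / 252)
        assert res["g"].gene_switch_score == pytest.approx(1.6)

    def test_signed_dif_sums_to_zero(self):
        rng = np.random.default_rng(8)
        design = self._design()
        raw = rng.random((3, 10))
        ifm = pd.DataFrame(
            raw / raw.sum(axis=0), index=["t1", "t2", "t3"], columns=design.index
        )
        res = dtu_switch_test(ifm, {t: "g" for t in ifm.index}, design)
        assert sum(res["g"].dif.values()) == pytest.approx(0, abs=1e-9)

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(15)
        design = pd.Series(
            ["c1"] * 3 + ["c2"] * 3, index=[f"s{i}" for i in range(6)]
        )
        for _ in range(20)[:20]:
            raw = rng.random((2, 6))
            ifm = pd.DataFrame(
                raw / raw.sum(axis=0), index=["t1", "t2"], columns=design.index
            )
            res = dtu_switch_test(ifm, {"t1": "g", "t2": "g"}, design)
            want = switch_p_oracle(
                ifm.to_numpy(), design.tolist(), "c1"
            )
            assert res["g"].p_value == pytest.approx(want)

    def test_single_sample_condition_rejected(self):
        design = pd.Series(["c1", "c2", "c2"], index=["s0", "s1", "s2"])
        ifm = pd.DataFrame([[0.5] * 3], index=["t1"], columns=design.index)
        with pytest.raises(ValueError):
            dtu_switch_test(ifm, {"t1": "g"}, design)

    def test_q_at_least_p(self):
        rng = np.random.default_rng(23)
        design = self._design()
        frames = {}
        tx2gene = {}
        rows = []
        for g in range(8):
            raw = rng.random((2, 10))
            for i in range(2):
                tid = f"g{g}t{i}"
                tx2gene[tid] = f"g{g}"
                rows.append(pd.Series(raw[i] / raw.sum(axis=0), index=design.index, name=tid))
        ifm = pd.DataFrame(rows)
        res = dtu_switch_test(ifm, tx2gene, design, seed=1)
        for r in res.values():
            assert r.q_value >= r.p_value - 1e-12


class TestGeneEventSummary:
    def test_single_isoform_genes_empty(self):
        ann = Annotation({"t1": tx("t1", [(0, 10), (20, 30)])})
        design = pd.Series(["c1", "c1", "c2", "c2"], index=list("abcd"))
        ifm = pd.DataFrame(
            [[1.0] * 4], index=["t1"], columns=design.index
        )
        out = gene_event_summary(ann, ifm, {"t1": "G1"}, design)
        assert out.empty

    def test_es_usage_difference(self):
        a = tx("a", [(0, 10), (20, 30), (40, 50)])
        b = tx("b", [(0, 10), (40, 50)])
        ann = Annotation({"a": a, "b": b})
        samples = [f"s{i}" for i in range(6)]
        design = pd.Series(["c1"] * 3 + ["c2"] * 3, index=samples)
        ifm = pd.DataFrame(
            [[0.8] * 3 + [0.2] * 3, [0.2] * 3 + [0.8] * 3],
            index=["a", "b"],
            columns=samples,
        )
        out = gene_event_summary(
            ann, ifm, {"a": "G1", "b": "G1"}, design, n_perm=200, seed=2
        )
        es = out[out.event_type == "ES"]
        assert len(es) == 1
        assert es.iloc[0].usage_diff == pytest.approx(0.6)


class TestConsequences:
    def _switch(self):
        return SwitchResult(
            "G1", {"gain": 0.4, "lose": -0.4}, 0.8, 0.001, 0.01
        )

    def test_coding_gain(self):
        calls = {
            "gain": CodingCall("gain", "coding", "cpat_coding"),
            "lose": CodingCall("lose", "noncoding", "cpat_noncoding"),
        }
        flags = functional_consequences(self._switch(), calls)
        assert flags == ["coding_gain"]

    def test_identical_no_consequence(self):
        calls = {
            "gain": CodingCall("gain", "coding", "cpat_coding"),
            "lose": CodingCall("lose", "coding", "cpat_coding"),
        }
        assert functional_consequences(
            self._switch(), calls, orf_lengths={"gain": 300, "lose": 300}
        ) == []

    def test_orf_doubling_flagged(self):
        calls = {
            "gain": CodingCall("gain", "coding", "cpat_coding"),
            "lose": CodingCall("lose", "coding", "cpat_coding"),
        }
        flags = functional_consequences(
            self._switch(), calls, orf_lengths={"gain": 600, "lose": 300}
        )
        assert flags == ["orf_length_change"]

    def test_domain_table(self):
        calls = {
            "gain": CodingCall("gain", "coding", "cpat_coding"),
            "lose": CodingCall("lose", "coding", "cpat_coding"),
        }
        table = pd.DataFrame(
            {"domain": [True, False]}, index=["gain", "lose"]
        )
        flags = functional_consequences(
            self._switch(), calls, feature_table=table
        )
        assert flags == ["domain_gain"]
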