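import copy

import numpy as np
import pandas as pd
import pytest

from isoqc.annotation import merge_annotations, read_gtf, write_gtf
from isoqc.coding import longest_orf, transcript_sequence
from isoqc.de import de_test, threshold_filter
from isoqc.events import dtu_switch_test, isoform_fractions
from isoqc.novelty import classify_annotation, detect_antisense_duplicates
from isoqc.simulate import (
    SimConfig,
    inject_novel_features,
    make_cage_peaks,
    make_coding_cohort,
    make_reference,
    make_validation_cohort,
    simulate_counts,
    simulate_coverage,
    simulate_sequins,
)
from isoqc.spikein import (
    estimate_loq,
    expected_logfc,
    sensitivity_report,
    tpm_from_counts,
)
from isoqc.validation import ValidationParams, filter_by_exon_coverage


class TestMakeReference:
    def test_deterministic(self, sim_cfg, sim_reference):
        genome, reference, biotypes = sim_reference
        genome2, reference2, biotypes2 = make_reference(sim_cfg)
        assert genome == genome2
        assert reference == reference2
        assert biotypes == biotypes2

    def test_cds_are_clean_orfs(self, sim_reference):
        genome, reference, _ = sim_reference
        n_checked = 0
        for t in reference.transcripts.values():
            if t.cds is None:
                continue
            seq = transcript_sequence(t, genome)
            orf = longest_orf(seq)
            assert orf is not None
            assert orf.length % 3 == 0
            assert seq[orf.start : orf.start + 3] == "ATG"
            assert seq[orf.end - 3 : orf.end] in ("TAA", "TAG", "TGA")
            n_checked += 1
        assert n_checked > 50

    def test_gtf_round_trip(self, sim_reference, tmp_path):
        _, reference, _ = sim_reference
        path = tmp_path / "ref.gtf"
        write_gtf(reference, path)
        assert read_gtf(path) == reference

    def test_structure_constraints(self, sim_reference):
        _, reference, _ = sim_reference
        for t in reference.transcripts.values():
            assert 2 <= len(t.exons) <= 10
            for a, b in zip(t.exons, t.exons[1:]):
                assert b.start - a.end >= 60

    def test_too_small_chromosome_rejected(self):
        with pytest.raises(ValueError):
            make_reference(SimConfig(chrom_length=10_000, n_genes=50))


class TestInjection:
    def test_truth_covers_every_novel_transcript(self, sim_novel):
        novel, truth = sim_novel
        assert set(truth.category) == set(novel.transcripts)

    def test_requested_counts(self, sim_cfg, sim_novel):
        novel, truth = sim_novel
        from collections import Counter

        c = Counter(truth.category.values())
        assert c["cassette"] == sim_cfg.n_cassette
        assert c["novel_donor"] == sim_cfg.n_novel_donor
        assert c["novel_acceptor"] == sim_cfg.n_novel_acceptor
        assert c["both_novel"] == sim_cfg.n_both_novel
        assert c["novel_junction"] == sim_cfg.n_novel_junction
        assert c["novel_tss"] == sim_cfg.n_novel_tss
        assert c["antisense"] == sim_cfg.n_antisense

    def test_frame_conserving_lengths(self, sim_cfg, sim_novel):
        novel, truth = sim_novel
        n_fc = sum(truth.frame_conserving.values())
        assert n_fc == round(
            sim_cfg.n_cassette * sim_cfg.frame_conserving_fraction
        )
        for tid, fc in truth.frame_conserving.items():
            (exon,) = truth.novel_exons[tid]
            assert (len(exon) % 3 == 0) == fc

    def test_antisense_recovered_exactly(self, sim_reference, sim_novel):
        _, reference, _ = sim_reference
        novel, truth = sim_novel
        flagged = detect_antisense_duplicates(novel, reference)
        want = {t for t, c in truth.category.items() if c == "antisense"}
        assert flagged == want


class TestCoverage:
    def test_filter_recovers_truth_pass_set(self, sim_cfg, sim_reference, sim_novel):
        _, reference, _ = sim_reference
        novel, truth = sim_novel
        truth = copy.deepcopy(truth)
        cov, sup = simulate_coverage(novel, reference, truth, sim_cfg)
        merged = merge_annotations(reference, novel)
        reports = classify_annotation(novel, reference)
        kept, removed = filter_by_exon_coverage(
            merged, reports, cov, ValidationParams()
        )
        want_removed = {t for t, ok in truth.coverage_pass.items() if not ok}
        assert removed == want_removed

    def test_junction_truth_consistent(self, sim_cfg, sim_reference, sim_novel):
        from isoqc.annotation import SpliceJunction
        from isoqc.validation import junction_validated

        _, reference, _ = sim_reference
        novel, truth = sim_novel
        truth = copy.deepcopy(truth)
        _, sup = simulate_coverage(novel, reference, truth, sim_cfg)
        p = ValidationParams()
        for (chrom, strand, s, e), valid in truth.junction_valid.items():
            j = SpliceJunction(chrom, strand, s, e)
            assert junction_validated(j, sup, p) == valid

    def test_deterministic(self, sim_cfg, sim_reference, sim_novel):
        _, reference, _ = sim_reference
        novel, truth = sim_novel
        cov1, _ = simulate_coverage(novel, reference, copy.deepcopy(truth), sim_cfg)
        cov2, _ = simulate_coverage(novel, reference, copy.deepcopy(truth), sim_cfg)
        for chrom in cov1.chroms():
            assert cov1.segments(chrom) == cov2.segments(chrom)


class TestValidationCohort:
    def test_exact_pass_count(self):
        ref, novel, cov, truth = make_validation_cohort(40, 31, seed=2)
        merged = merge_annotations(ref, novel)
        reports = classify_annotation(novel, ref)
        kept, removed = filter_by_exon_coverage(
            merged, reports, cov, ValidationParams()
        )
        n_novel_kept = sum(
            1 for t in kept.transcripts.values() if t.source == "novel"
        )
        assert n_novel_kept == 31
        assert len(removed) == 9

    def test_every_candidate_is_single_cassette(self):
        ref, novel, cov, truth = make_validation_cohort(10, 5, seed=0)
        reports = classify_annotation(novel, ref)
        for rep in reports.values():
            assert len(rep.cassette_exons) == 1


class TestCodingCohort:
    def test_branch_counts(self, coding_model):
        from isoqc.coding import classify_coding_status

        genome, ref, novel, truth = make_coding_cohort(4, 3, 5, 2, 6, seed=9)
        reports = classify_annotation(novel, ref)
        from collections import Counter

        got = Counter()
        for tid, t in novel.transcripts.items():
            call = classify_coding_status(t, reports[tid], ref, coding_model, genome)
            got[call.reason] += 1
            assert (call.status, call.reason) == truth.coding_truth[tid]
        assert got == Counter(
            frame_conserving=4,
            cpat_coding=3,
            noncoding_parent=5,
            frameshift=2,
            cpat_noncoding=6,
        )


class TestCounts:
    def test_deterministic(self, sim_cfg, sim_reference, sim_novel):
        _, reference, _ = sim_reference
        novel, truth = sim_novel
        ann = merge_annotations(reference, novel)
        c1, d1 = simulate_counts(ann, sim_cfg, copy.deepcopy(truth))
        c2, d2 = simulate_counts(ann, sim_cfg, copy.deepcopy(truth))
        assert c1.equals(c2)
        assert d1.equals(d2)

    def test_planted_dtu_without_gene_level_de(self, sim_cfg, sim_reference, sim_novel):
        _, reference, _ = sim_reference
        novel, truth = sim_novel
        truth = copy.deepcopy(truth)
        ann = merge_annotations(reference, novel)
        counts, design = simulate_counts(ann, sim_cfg, truth)
        tx2gene = {t: m.gene_id for t, m in ann.transcripts.items()}

        ifm = isoform_fractions(counts, tx2gene)
        dtu_tids = [
            t for t in counts.index if tx2gene[t] in truth.dtu_genes
        ]
        res = dtu_switch_test(ifm.loc[dtu_tids], tx2gene, design, seed=0)
        for gene, r in res.items():
            assert r.p_value == pytest.approx(2 / 252, abs=0.05)
            assert r.gene_switch_score > 0.5

        from isoqc.de import aggregate_gene_counts

        gene_counts = aggregate_gene_counts(counts, tx2gene)
        gres = de_test(
            gene_counts, design, norm_factors=pd.Series(1.0, index=design.index)
        )
        hits = threshold_filter(gres)
        assert not (set(hits.index) & set(truth.dtu_genes))

    def test_planted_logfc_recovered_at_mean_100(self):
        cfg = SimConfig(seed=33, n_genes=60, n_de=12, n_dtu=0, base_mean=100.0)
        _, reference, _ = make_reference(cfg)
        novel, truth = inject_novel_features(reference, cfg)
        ann = merge_annotations(reference, novel)
        counts, design = simulate_counts(ann, cfg, truth)
        res = de_test(
            counts, design, norm_factors=pd.Series(1.0, index=design.index)
        )
        for tid, lfc in truth.de_logfc.items():
            assert res.table.loc[tid, "logFC"] == pytest.approx(lfc, abs=1.0)


class TestSequins:
    def test_both_mixes_in_both_conditions(self, sim_cfg):
        mix, counts, truth = simulate_sequins(sim_cfg)
        u = [s for s in counts.columns if s.startswith("u")]
        d = [s for s in counts.columns if s.startswith("d")]
        for group in (u, d):
            assert {mix.sample_mix[s] for s in group} == {"A", "B"}

    def test_loq_recovers_floor_within_one_step(self, sim_cfg):
        mix, counts, truth = simulate_sequins(sim_cfg)
        tpm = tpm_from_counts(counts, pd.Series(mix.lengths))
        for name, conc_map in (("A", mix.mix_a), ("B", mix.mix_b)):
            samples = [s for s, m in mix.sample_mix.items() if m == name]
            mean_tpm = tpm[samples].mean(axis=1)
            concs = pd.Series(conc_map).loc[mean_tpm.index]
            res = estimate_loq(concs.to_numpy(), mean_tpm.to_numpy())
            ratio = res.breakpoint_concentration / truth.sequin_floor
            assert 0.45 <= ratio <= 2.2

    def test_noise_free_sensitivity_r2_one(self, sim_cfg):
        mix, counts, truth = simulate_sequins(sim_cfg, noise=False)
        a = [s for s, m in mix.sample_mix.items() if m == "A"]
        b = [s for s, m in mix.sample_mix.items() if m == "B"]
        # restrict to sequins quantified above the floor in both mixes
        detectable = [
            sid
            for sid in mix.ids()
            if mix.mix_a[sid] >= truth.sequin_floor
            and mix.mix_b[sid] >= truth.sequin_floor
        ]
        observed = np.log2(
            counts.loc[detectable, b].mean(axis=1)
            / counts.loc[detectable, a].mean(axis=1)
        )
        expected = expected_logfc(mix).loc[detectable]
        rep = sensitivity_report(expected, observed)
        assert rep.r_squared > 0.999
        assert rep.slope == pytest.approx(1.0, abs=0.05)

    def test_deterministic(self, sim_cfg):
        _, c1, _ = simulate_sequins(sim_cfg)
        _, c2, _ = simulate_sequins(sim_cfg)
        assert c1.equals(c2)


class TestCagePeaks:
    def test_recovers_exact_hit_subset(self, sim_cfg, sim_novel):
        from isoqc.cage import intersect_cage, tss_window

        novel, truth = sim_novel
        truth = copy.deepcopy(truth)
        peaks = make_cage_peaks(novel, truth, 0.6, sim_cfg)
        windows = {
            tid: tss_window(novel.transcripts[tid], "symmetric", 500)
            for tid, cat in truth.category.items()
            if cat == "novel_tss"
        }
        counts, summary = intersect_cage(windows, peaks)
        supported = {t for t, n in counts.items() if n >= 1}
        assert supported == truth.cage_hits
        assert summary.n_supported_transcripts == len(truth.cage_hits)

    def test_zero_hit_fraction(self, sim_cfg, sim_novel):
        from isoqc.cage import intersect_cage, tss_window

        novel, truth = sim_novel
        truth = copy.deepcopy(truth)
        peaks = make_cage_peaks(novel, truth, 0.0, sim_cfg)
        windows = {
            tid: tss_window(novel.transcripts[tid], "symmetric", 500)
            for tid, cat in truth.category.items()
            if cat == "novel_tss"
        }
        _, summary = intersect_cage(windows, peaks)
        assert summary.n_supported_transcripts == 0
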