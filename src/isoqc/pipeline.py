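"""End-to-end orchestration of the annotation validation pipeline.

Stages run in a fixed order — antisense removal, novelty classification,
coverage validation, expression filter, coding assessment, CAGE support,
merged GTF, differential expression (gene and transcript), differential
usage, splicing-event summary, spike-in report — and each stage's outputs
are listed in a JSON manifest together with record counts and checksums.
Stages whose inputs are absent are skipped and noted.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import cage as cage_mod
from . import coding as coding_mod
from . import de as de_mod
from . import events as events_mod
from . import io as io_mod
from . import novelty as novelty_mod
from . import simulate as sim_mod
from . import spikein as spikein_mod
from . import validation as val_mod
from .annotation import merge_annotations, read_gtf, write_gtf

logger = logging.getLogger("isoqc")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    out_dir: str
    reference_gtf: str
    candidate_gtf: str
    genome_fasta: str | None = None
    coverage_bedgraph: str | None = None
    junction_tsv: str | None = None
    counts_tsv: str | None = None
    design_tsv: str | None = None
    cage_bed: str | None = None
    sequin_mix_tsv: str | None = None
    sequin_counts_tsv: str | None = None
    validation: val_mod.ValidationParams = field(
        default_factory=val_mod.ValidationParams
    )
    lfc: float = 1.5
    fdr: float = 0.05
    cp_threshold: float = coding_mod.DEFAULT_CP_THRESHOLD
    cage_window: int = 500
    cage_mode: str = "symmetric"
    tss_tolerance_bp: int = 0
    seed: int = 0


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage whose inputs are available; return the manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "files": {}, "counts": {}, "skipped": []}

    def emit(name: str, path: Path, n_records: int | None = None) -> None:
        manifest["files"][name] = {"path": path.name, "sha256": _sha256(path)}
        if n_records is not None:
            manifest["counts"][name] = n_records

    def stage(name: str):
        t0 = time.perf_counter()
        logger.info("stage %s started", name)
        manifest["stages"][name] = "done"
        return t0

    def done(name: str, t0: float) -> None:
        logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)

    reference = read_gtf(cfg.reference_gtf)
    candidates = read_gtf(cfg.candidate_gtf)
    manifest["counts"]["candidates_total"] = len(candidates)

    # --- antisense removal ------------------------------------------------
    t0 = stage("antisense")
    antisense = novelty_mod.detect_antisense_duplicates(candidates, reference)
    candidates = candidates.subset(
        [t for t in candidates.transcripts if t not in antisense]
    )
    manifest["counts"]["antisense_removed"] = len(antisense)
    done("antisense", t0)

    # --- novelty classification ------------------------------------------
    t0 = stage("novelty")
    reports = novelty_mod.classify_annotation(
        candidates, reference, cfg.tss_tolerance_bp
    )
    frame = novelty_mod.reports_to_frame(reports)
    path = out / "novelty_report.tsv"
    frame.to_csv(path, sep="\t", index=False)
    emit("novelty_report", path, len(frame))
    catalog = novelty_mod.aggregate_catalog(list(reports.values()))
    path = out / "novelty_catalog.tsv"
    pd.Series(vars(catalog)).rename("count").to_frame().rename_axis(
        "category"
    ).to_csv(path, sep="\t")
    emit("novelty_catalog", path)
    done("novelty", t0)

    # --- coverage validation ---------------------------------------------
    if cfg.coverage_bedgraph:
        t0 = stage("coverage_validation")
        cov = val_mod.read_bedgraph(cfg.coverage_bedgraph)
        candidates, removed = val_mod.filter_by_exon_coverage(
            candidates, reports, cov, cfg.validation
        )
        manifest["counts"]["coverage_failed"] = len(removed)
        manifest["counts"]["validated"] = len(candidates)
        done("coverage_validation", t0)
    else:
        manifest["skipped"].append("coverage_validation")

    # --- junction validation (report only) -------------------------------
    if cfg.junction_tsv:
        t0 = stage("junction_validation")
        sup = val_mod.read_junction_table(cfg.junction_tsv)
        rows = []
        ref_juncs = reference.index.junctions
        from .annotation import transcript_junctions

        seen = set()
        for t in candidates.transcripts.values():
            if t.source != "novel":
                continue
            for j in transcript_junctions(t):
                key = (j.chrom, j.strand, j.intron_start, j.intron_end)
                if key in seen:
                    continue
                seen.add(key)
                if (j.intron_start, j.intron_end) in ref_juncs.get(
                    (j.chrom, j.strand), set()
                ):
                    continue
                rows.append(
                    {
                        "chrom": j.chrom,
                        "intron_start": j.intron_start,
                        "intron_end": j.intron_end,
                        "strand": j.strand,
                        "read_count": sup.get(j),
                        "validated": val_mod.junction_validated(
                            j, sup, cfg.validation
                        ),
                    }
                )
        jdf = pd.DataFrame(
            rows,
            columns=[
                "chrom", "intron_start", "intron_end", "strand",
                "read_count", "validated",
            ],
        ).sort_values(["chrom", "intron_start", "intron_end"]).reset_index(drop=True)
        path = out / "junction_validation.tsv"
        jdf.to_csv(path, sep="\t", index=False)
        emit("junction_validation", path, len(jdf))
        manifest["counts"]["junctions_validated"] = int(jdf["validated"].sum())
        done("junction_validation", t0)
    else:
        manifest["skipped"].append("junction_validation")

    counts = design = None
    if cfg.counts_tsv and cfg.design_tsv:
        counts = io_mod.read_counts(cfg.counts_tsv)
        design = io_mod.read_design(cfg.design_tsv)

    # --- expression filter ------------------------------------------------
    if counts is not None:
        t0 = stage("expression_filter")
        novel_ids = [
            t for t, m in candidates.transcripts.items() if m.source == "novel"
        ]
        expressed = set(
            val_mod.expression_filter(
                counts.loc[[t for t in novel_ids if t in counts.index]],
                cfg.validation,
            )
        )
        dropped = [t for t in novel_ids if t not in expressed]
        candidates = candidates.subset(
            [t for t in candidates.transcripts if t not in dropped]
        )
        manifest["counts"]["expression_filtered"] = len(dropped)
        manifest["counts"]["expressed_novel"] = len(expressed)
        done("expression_filter", t0)
    else:
        manifest["skipped"].append("expression_filter")
    manifest["counts"]["final_novel"] = sum(
        1 for t in candidates.transcripts.values() if t.source == "novel"
    )

    # --- coding assessment ------------------------------------------------
    genome = None
    calls: dict[str, coding_mod.CodingCall] = {}
    if cfg.genome_fasta:
        t0 = stage("coding")
        genome = io_mod.read_fasta(cfg.genome_fasta)
        coding_seqs, noncoding_seqs = sim_mod.make_training_sequences(cfg.seed)
        model = coding_mod.train_coding_model(
            coding_seqs, noncoding_seqs, threshold=cfg.cp_threshold
        )
        rows = []
        for tid, t in sorted(candidates.transcripts.items()):
            if t.source != "novel":
                continue
            call = coding_mod.classify_coding_status(
                t, reports[tid], reference, model, genome
            )
            calls[tid] = call
            rows.append(
                {
                    "transcript_id": tid,
                    "status": call.status,
                    "reason": call.reason,
                    "coding_prob": (
                        "" if call.coding_prob is None else f"{call.coding_prob:.6f}"
                    ),
                }
            )
        cdf = pd.DataFrame(
            rows, columns=["transcript_id", "status", "reason", "coding_prob"]
        )
        path = out / "coding_calls.tsv"
        cdf.to_csv(path, sep="\t", index=False)
        emit("coding_calls", path, len(cdf))
        if len(cdf):
            manifest["counts"]["coding"] = int((cdf["status"] == "coding").sum())
            manifest["counts"]["noncoding"] = int(
                (cdf["status"] == "noncoding").sum()
            )
        done("coding", t0)
    else:
        manifest["skipped"].append("coding")

    # --- CAGE TSS support -------------------------------------------------
    if cfg.cage_bed:
        t0 = stage("cage")
        peaks = cage_mod.read_bed(cfg.cage_bed)
        windows = {
            tid: cage_mod.tss_window(
                candidates.transcripts[tid], cfg.cage_mode, cfg.cage_window
            )
            for tid, rep in sorted(reports.items())
            if rep.novel_tss and tid in candidates.transcripts
        }
        per_id, summary = cage_mod.intersect_cage(windows, peaks)
        path = out / "cage_support.tsv"
        pd.Series(per_id).rename("n_peaks").to_frame().rename_axis(
            "transcript_id"
        ).to_csv(path, sep="\t")
        emit("cage_support", path, len(per_id))
        manifest["counts"]["novel_tss_transcripts"] = summary.n_novel_tss_transcripts
        manifest["counts"]["cage_supported"] = summary.n_supported_transcripts
        manifest["counts"]["cage_peak_overlaps"] = summary.n_overlapping_peaks
        done("cage", t0)
    else:
        manifest["skipped"].append("cage")

    # --- merged validated annotation -------------------------------------
    t0 = stage("merge")
    merged = merge_annotations(reference, candidates)
    path = out / "validated_annotation.gtf"
    write_gtf(merged, path)
    emit("validated_annotation", path, len(merged))
    done("merge", t0)

    # --- differential expression and usage --------------------------------
    if counts is not None:
        t0 = stage("de")
        tx2gene = {
            tid: t.gene_id for tid, t in merged.transcripts.items()
        }
        quantified = counts.loc[[t for t in counts.index if t in tx2gene]]
        quantified = quantified.loc[quantified.sum(axis=1) > 0]
        res_tx = de_mod.de_test(quantified, design)
        path = out / "de_transcript.tsv"
        res_tx.table.sort_index().to_csv(path, sep="\t")
        emit("de_transcript", path, len(res_tx.table))
        gene_counts = de_mod.aggregate_gene_counts(quantified, tx2gene)
        res_gene = de_mod.de_test(gene_counts, design)
        path = out / "de_gene.tsv"
        res_gene.table.sort_index().to_csv(path, sep="\t")
        emit("de_gene", path, len(res_gene.table))
        for label, res in (("transcript", res_tx), ("gene", res_gene)):
            hits = de_mod.threshold_filter(res, cfg.lfc, cfg.fdr)
            path = out / f"de_{label}_hits.tsv"
            hits.sort_index().to_csv(path, sep="\t")
            emit(f"de_{label}_hits", path, len(hits))
            manifest["counts"][f"de_{label}_significant"] = len(hits)
        done("de", t0)

        t0 = stage("dtu")
        ifm = events_mod.isoform_fractions(quantified, tx2gene)
        multi = [
            t for t in ifm.index
            if len(merged.genes[tx2gene[t]].transcript_ids) >= 2
        ]
        switches = events_mod.dtu_switch_test(
            ifm.loc[multi], tx2gene, design, seed=cfg.seed
        )
        rows = [
            {
                "gene_id": g,
                "gene_switch_score": r.gene_switch_score,
                "p_value": r.p_value,
                "q_value": r.q_value,
            }
            for g, r in sorted(switches.items())
        ]
        path = out / "dtu_switches.tsv"
        pd.DataFrame(
            rows, columns=["gene_id", "gene_switch_score", "p_value", "q_value"]
        ).to_csv(path, sep="\t", index=False)
        emit("dtu_switches", path, len(rows))
        done("dtu", t0)

        t0 = stage("events")
        summary = events_mod.gene_event_summary(
            merged, ifm.loc[multi], tx2gene, design, seed=cfg.seed
        )
        path = out / "splice_events.tsv"
        summary.to_csv(path, sep="\t", index=False)
        emit("splice_events", path, len(summary))
        bytype = (
            summary.groupby("event_type").size().rename("n_events").to_frame()
            if len(summary)
            else pd.DataFrame(columns=["n_events"])
        )
        path = out / "splice_events_by_type.tsv"
        bytype.rename_axis("event_type").to_csv(path, sep="\t")
        emit("splice_events_by_type", path)
        done("events", t0)
    else:
        manifest["skipped"].extend(["de", "dtu", "events"])

    # --- spike-ins ---------------------------------------------------------
    if cfg.sequin_mix_tsv and cfg.sequin_counts_tsv:
        t0 = stage("spikein")
        mix = spikein_mod.read_mix_table(cfg.sequin_mix_tsv)
        sq_counts = io_mod.read_counts(cfg.sequin_counts_tsv)
        lengths = pd.Series(mix.lengths)
        tpm = spikein_mod.tpm_from_counts(sq_counts, lengths)
        rows = []
        for mix_name, conc in (("A", mix.mix_a), ("B", mix.mix_b)):
            samples = [
                s for s, m in mix.sample_mix.items() if m == mix_name
            ] or list(sq_counts.columns)
            mean_tpm = tpm[samples].mean(axis=1)
            concs = pd.Series(conc).loc[mean_tpm.index]
            loq = spikein_mod.estimate_loq(
                concs.to_numpy(), mean_tpm.to_numpy()
            )
            rows.append(
                {
                    "mix": mix_name,
                    "loq_concentration": loq.breakpoint_concentration,
                    "total_sse": loq.total_sse,
                    "single_line_sse": loq.single_line_sse,
                }
            )
            manifest["counts"][f"loq_mix{mix_name}"] = loq.breakpoint_concentration
        path = out / "sequin_loq.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        emit("sequin_loq", path, len(rows))

        if mix.sample_mix:
            a_samples = [s for s, m in mix.sample_mix.items() if m == "A"]
            b_samples = [s for s, m in mix.sample_mix.items() if m == "B"]
            if len(a_samples) >= 2 and len(b_samples) >= 2:
                mix_design = pd.Series(
                    {s: ("B" if s in b_samples else "A") for s in sq_counts.columns}
                )
                res = de_mod.de_test(sq_counts, mix_design)
                observed = -res.table["logFC"] if res.condition_order[0] == "A" else res.table["logFC"]
                expected = spikein_mod.expected_logfc(mix)
                report = spikein_mod.sensitivity_report(expected, observed)
                path = out / "sequin_sensitivity.tsv"
                report.table.rename_axis("sequin_id").to_csv(path, sep="\t")
                emit("sequin_sensitivity", path, report.n_pairs)
                manifest["counts"]["sequin_r_squared"] = report.r_squared
        done("spikein", t0)
    else:
        manifest["skipped"].append("spikein")

    path = out / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
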