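"""End-to-end orchestration: reads -> families -> consensus -> calls -> QC -> cohort.

`run_sample` is the in-memory engine used by both the command line and
the test/acceptance harnesses; `run_pipeline` is the file-level wrapper
(FASTQ + panel + sample sheet in, VCF/TSV/JSON out).  Every run asserts
read conservation (assigned + unassigned = input reads; family sizes
sum to assigned reads) and logs each threshold in effect.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import calling, consensus as cons, qc as qcmod
from .calling import AlignedConsensus, SampleResult, VariantCall
from .panel import PatientPanel, load_panel
from .simulate import read_fastq

log = logging.getLogger("umicall")

_PUBLISHED_DEFAULTS = {
    "min_reads": 3,
    "snv_min": 7,
    "indel_min": 1,
    "rescue_anchor": 6,
    "low_input": 50,
    "undersequenced": 7.0,
    "contamination": 0.05,
}


@dataclass
class RunConfig:
    panel_path: str | Path | None = None
    sample_sheet: str | Path | None = None
    output_dir: str | Path = "umicall_out"
    umi_length: int = 12
    max_primer_mismatch: int = 2
    min_reads: int = 3
    min_agreement: float = 0.9
    snv_min: int = 7
    indel_min: int = 1
    rescue_anchor: int = 6
    low_input: int = 50
    undersequenced: float = 7.0
    contamination: float = 0.05
    report_all_events: bool = False
    seed: int = 0

    def __post_init__(self):
        for name in ("min_reads", "snv_min", "indel_min", "rescue_anchor", "low_input"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    def log_thresholds(self) -> None:
        for name, default in _PUBLISHED_DEFAULTS.items():
            value = getattr(self, name)
            provenance = "published default" if value == default else "user override"
            log.info("threshold %s=%s (%s)", name, value, provenance)


@dataclass
class SampleRunDetail:
    """Intermediate products kept for QC, auditing and tests."""

    n_reads: int = 0
    n_unassigned: int = 0
    families: list = field(default_factory=list)
    consensus: list = field(default_factory=list)
    alignments: dict[str, list[AlignedConsensus]] = field(default_factory=dict)
    pileups: dict = field(default_factory=dict)
    spikein_counts: dict[str, int] = field(default_factory=dict)
    n_unalignable: int = 0
    mean_family_size: float | None = None


def run_sample(
    reads: list[tuple[str, str]],
    panel: PatientPanel,
    config: RunConfig | None = None,
    sample_id: str = "sample",
    patient_id: str | None = None,
    timepoint: str = "presurgery",
    run: str = "run1",
) -> tuple[SampleResult, SampleRunDetail]:
    """Process one sample's reads through demultiplexing, consensus and calling.

    The returned classification is pre-rescue; apply
    :func:`umicall.calling.rescue_provisional` over all of a patient's
    samples to finalize it.
    """
    cfg = config or RunConfig()
    detail = SampleRunDetail(n_reads=len(reads))
    assigned, unassigned = cons.demultiplex_reads(
        reads, panel, umi_length=cfg.umi_length, max_primer_mismatch=cfg.max_primer_mismatch
    )
    detail.n_unassigned = len(unassigned)
    assert len(assigned) + len(unassigned) == len(reads), "read conservation violated at demultiplexing"
    families = cons.group_families(assigned)
    assert sum(f.size for f in families) == len(assigned), "read conservation violated at family grouping"
    detail.families = families
    detail.mean_family_size = cons.mean_family_size(families) if families else None
    consensus_reads = cons.build_all_consensus(families, cfg.min_reads, cfg.min_agreement)
    detail.consensus = consensus_reads
    log.info(
        "sample=%s reads=%d unassigned=%d families=%d consensus=%d mean_family_size=%s",
        sample_id, len(reads), len(unassigned), len(families), len(consensus_reads),
        f"{detail.mean_family_size:.2f}" if detail.mean_family_size is not None else "NA",
    )

    calls: list[VariantCall] = []
    align_cache: dict[tuple[str, str], tuple] = {}
    for assay in panel.assays:
        mine = [c for c in consensus_reads if c.key[0] == assay.assay_id]
        alignments: list[AlignedConsensus] = []
        for c in mine:
            cache_key = (assay.assay_id, c.sequence)
            if cache_key in align_cache:
                tmpl = align_cache[cache_key]
                if tmpl is None:
                    detail.n_unalignable += 1
                    continue
                alignments.append(
                    AlignedConsensus(c, assay.assay_id, tmpl[0], tmpl[1], tmpl[2], tmpl[3])
                )
                continue
            a = calling.align_consensus(c, assay)
            if a is None:
                align_cache[cache_key] = None
                detail.n_unalignable += 1
                log.debug("sample=%s assay=%s consensus unalignable", sample_id, assay.assay_id)
                continue
            align_cache[cache_key] = (a.ref_span, a.events, a.n_positions, a.identity)
            alignments.append(a)
        spike = panel.spikein_for(assay.assay_id)
        if spike is not None:
            detail.spikein_counts[assay.assay_id] = calling.count_spikein(alignments, assay, spike)
        pileup = calling.build_pileup(alignments, assay)
        detail.alignments[assay.assay_id] = alignments
        detail.pileups[assay.assay_id] = pileup
        calls.extend(
            calling.call_sample_variants(
                pileup,
                panel.variants_for(assay.assay_id),
                assay,
                snv_min=cfg.snv_min,
                indel_min=cfg.indel_min,
                report_all_events=cfg.report_all_events,
            )
        )

    tumor = panel.tumor_variant
    tumor_pileup = detail.pileups[tumor.assay_id]
    molecule_count = int(tumor_pileup.depth[tumor.pos])
    result = SampleResult(
        sample_id=sample_id,
        patient_id=patient_id or panel.patient_id,
        timepoint=timepoint,
        molecule_count=molecule_count,
        calls=calls,
        run=run,
        stats={
            "n_reads": len(reads),
            "n_unassigned": len(unassigned),
            "n_families": len(families),
            "n_consensus": len(consensus_reads),
            "n_unalignable": detail.n_unalignable,
            "mean_family_size": detail.mean_family_size,
        },
    )
    result.classification = calling.classify_sample(calls, molecule_count, cfg.low_input)
    if detail.mean_family_size is not None and qcmod.flag_undersequenced(detail.mean_family_size):
        result.qc_flags.add("undersequenced")
    if molecule_count < cfg.low_input:
        result.qc_flags.add("low_input")
    return result, detail


def run_pipeline(config: RunConfig) -> dict:
    """File-level pipeline over a panel, sample sheet and FASTQ inputs.

    The sample sheet is a TSV with columns sample_id, patient_id,
    timepoint, run, fastq (paths relative to the sheet).  Artifacts per
    sample: VCF 4.2 and a calls TSV; cohort-wide: a tidy sample table,
    QC report JSON and a MANIFEST of completed stages.
    """
    config.log_thresholds()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []
    manifest_path = outdir / "MANIFEST"

    def stage_done(name: str):
        stages.append(name)
        manifest_path.write_text("\n".join(stages) + "\n")

    try:
        panel = load_panel(config.panel_path)
        stage_done("load_panel")
        sheet = pd.read_csv(config.sample_sheet, sep="\t")
        base = Path(config.sample_sheet).parent
        stage_done("load_sample_sheet")

        results: list[SampleResult] = []
        details: dict[str, SampleRunDetail] = {}
        for row in sheet.itertuples(index=False):
            reads = read_fastq(base / row.fastq)
            res, det = run_sample(
                reads, panel, config,
                sample_id=row.sample_id, patient_id=row.patient_id,
                timepoint=row.timepoint, run=getattr(row, "run", "run1"),
            )
            results.append(res)
            details[row.sample_id] = det
        stage_done("call_samples")

        calling.rescue_provisional(results, config.rescue_anchor, config.low_input)
        stage_done("rescue")

        # spike-in centering across sequencing runs
        counts_by_run: dict[str, list[tuple[str, float]]] = {}
        for res in results:
            det = details[res.sample_id]
            for assay_id, count in det.spikein_counts.items():
                counts_by_run.setdefault(res.run, []).append((res.sample_id, float(count)))
        centered, spike_flags = ({}, {})
        if counts_by_run:
            centered, spike_flags = qcmod.center_spikein_counts(counts_by_run)
        qc_reports = []
        for res in results:
            det = details[res.sample_id]
            rep = qcmod.QcReport(
                sample_id=res.sample_id,
                mean_family_size=det.mean_family_size,
                spikein_centered_count=centered.get(res.sample_id),
                spikein_global_median=(
                    float(pd.Series([v for v in centered.values()]).median()) if centered else None
                ),
                molecule_count=res.molecule_count,
            )
            rep.derive_flags()
            res.qc_flags |= rep.flags
            qc_reports.append(rep.to_dict())
        stage_done("qc")

        for res in results:
            calling.write_vcf(res, panel, outdir / f"{res.sample_id}.vcf")
            calling.sample_calls_table(res).to_csv(outdir / f"{res.sample_id}.calls.tsv", sep="\t", index=False)
        rows = [
            {
                "sample_id": r.sample_id,
                "patient_id": r.patient_id,
                "timepoint": r.timepoint,
                "run": r.run,
                "classification": r.classification,
                "molecule_count": r.molecule_count,
                "mean_family_size": r.stats.get("mean_family_size"),
                "qc_flags": ";".join(sorted(r.qc_flags)),
            }
            for r in results
        ]
        pd.DataFrame(rows).to_csv(outdir / "samples.tsv", sep="\t", index=False)
        (outdir / "qc_report.json").write_text(json.dumps(qc_reports, indent=2))
        stage_done("write_outputs")
        return {"results": results, "details": details, "output_dir": str(outdir)}
    except Exception:
        log.exception("pipeline failed after stages: %s", stages)
        raise
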