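"""End-to-end orchestration: cohort in, reports out.

Consumes a cohort directory (probe tables, karyotypes, variant table, gene
and CNV BED files, genome model) and runs segmentation, CNA calling,
germline filtering, chromothripsis detection, mutation integration,
minimal-deleted-region computation, cytogenetic concordance and the cohort
summary, writing every result next to the exact configuration used.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import io
from .calling import (CallingConfig, CNACall, call_cnas, filter_germline_cnv,
                      retained, select_for_sequencing)
from .chromothripsis import (ChromothripsisCall, ChromothripsisConfig,
                             detect_chromothripsis, shared_affected_genes)
from .cytogenetics import (DegenerateTableError, categorical_association,
                           match_cc_to_acgh, parse_iscn, summarize_cohort)
from .genome import GeneInterval, GenomeModel, PANEL_GENES
from .mutations import (biallelic_status, classify_zygosity,
                        filter_scored_variants, load_mutation_table,
                        minimal_deleted_region)
from .segmentation import Segment, segment_profile

log = logging.getLogger("karyoshatter")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and the offending record."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"[{stage}] {detail}")


@dataclass
class PipelineConfig:
    input_dir: str
    output_dir: str
    calling: CallingConfig = field(default_factory=CallingConfig)
    chromothripsis: ChromothripsisConfig = field(
        default_factory=ChromothripsisConfig)
    hom_vaf_threshold: float = 80.0
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "input_dir": str(self.input_dir),
            "output_dir": str(self.output_dir),
            "calling": dataclasses.asdict(self.calling),
            "chromothripsis": dataclasses.asdict(self.chromothripsis),
            "hom_vaf_threshold": self.hom_vaf_threshold,
            "seed": self.seed,
            "log_level": self.log_level,
        }


def _group_by_chrom(segments: Sequence[Segment]) -> dict[str, list[Segment]]:
    out: dict[str, list[Segment]] = {}
    for s in segments:
        out.setdefault(s.chromosome, []).append(s)
    return out


@dataclass
class PatientResult:
    patient: str
    segments: list[Segment]
    calls: list[CNACall]
    chromothripsis_calls: list[ChromothripsisCall]

    @property
    def retained_calls(self) -> list[CNACall]:
        return retained(self.calls)

    @property
    def positive_chromothripsis(self) -> list[ChromothripsisCall]:
        return [c for c in self.chromothripsis_calls if c.positive]


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage over a cohort directory; returns the output directory."""
    logging.basicConfig(level=config.log_level)
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_json(config.to_dict(), outdir / "config_used.json")

    try:
        genome = GenomeModel.from_dict(io.read_json(indir / "genome.json"))
    except FileNotFoundError as exc:
        raise PipelineError("load_genome", f"missing file: {exc.filename}") from exc
    genes = [GeneInterval(name, chrom, s, e)
             for name, chrom, s, e in io.read_bed_named(indir / "genes.bed")]
    panel = [g for g in genes if g.name in PANEL_GENES] or genes
    cnv_path = indir / "cnv_regions.bed"
    cnv_regions = io.read_bed(cnv_path) if cnv_path.exists() else {}

    karyo_df = io.read_karyotype_table(indir / "karyotypes.tsv")
    patients = [str(p) for p in karyo_df["patient"]]
    log.info("cohort: %d patients", len(patients))

    results: list[PatientResult] = []
    for pid in patients:
        probe_path = indir / "probes" / f"{pid}.tsv"
        if not probe_path.exists():
            raise PipelineError("segmentation",
                                f"missing probe file {probe_path}")
        try:
            probes = io.read_probe_table(probe_path)
            segments = segment_profile(probes, config.calling)
        except ValueError as exc:
            raise PipelineError("segmentation", f"patient {pid}: {exc}") from exc
        try:
            calls = call_cnas(segments, config.calling)
            calls = filter_germline_cnv(calls, cnv_regions, config.calling)
            calls = select_for_sequencing(calls, panel, config.calling)
        except ValueError as exc:
            raise PipelineError("cna_calling", f"patient {pid}: {exc}") from exc
        ct = detect_chromothripsis(pid, _group_by_chrom(segments),
                                   config.chromothripsis, config.calling)
        results.append(PatientResult(pid, segments, calls, ct))
    n_germline = sum(c.germline_cnv for r in results for c in r.calls)
    log.info("calls: %d total, %d germline-flagged",
             sum(len(r.calls) for r in results), n_germline)

    io.write_seg({r.patient: r.segments for r in results},
                 outdir / "segments.seg")
    io.write_calls({r.patient: r.calls for r in results}, outdir / "calls.tsv")

    ct_rows = [
        (r.patient, c.chromosome, c.n_state_switches, c.n_distinct_states,
         int(c.positive))
        for r in results for c in r.chromothripsis_calls
    ]
    import pandas as pd
    pd.DataFrame(ct_rows, columns=[
        "patient", "chrom", "n_state_switches", "n_distinct_states",
        "positive"]).to_csv(outdir / "chromothripsis.tsv", sep="\t",
                            index=False)

    # shared genes across chromothripsis-positive patients, per chromosome
    shared: dict[str, dict[str, str]] = {}
    by_chrom: dict[str, dict[str, list[Segment]]] = {}
    for r in results:
        for c in r.positive_chromothripsis:
            by_chrom.setdefault(c.chromosome, {})[r.patient] = [
                s for s in r.segments if s.chromosome == c.chromosome]
    for chrom, per_patient in by_chrom.items():
        chrom_genes = [g for g in genes if g.chromosome == chrom]
        if chrom_genes:
            shared[chrom] = shared_affected_genes(per_patient, chrom_genes,
                                                  config.calling)
    io.write_json(
        {"positive_patients": {c: sorted(p) for c, p in
                               ((ch, list(pp)) for ch, pp in by_chrom.items())},
         "shared_genes": shared},
        outdir / "chromothripsis_shared_genes.json")

    # mutation integration
    mut_path = indir / "mutations.tsv"
    zygosity_calls = []
    if mut_path.exists():
        try:
            records = load_mutation_table(mut_path)
        except ValueError as exc:
            raise PipelineError("mutation_integration", str(exc)) from exc
        snp_path = indir / "snp_ids.txt"
        snp_ids = (snp_path.read_text().split() if snp_path.exists() else [])
        scored = filter_scored_variants(records, snp_ids)
        log.info("mutations: %d rows, %d scored", len(records), len(scored))
        zygosity_calls = [classify_zygosity(r, config.hom_vaf_threshold)
                          for r in scored]
        pd.DataFrame(
            [(z.record.sample, z.record.gene, z.record.protein_change,
              z.record.vaf, z.zygosity) for z in zygosity_calls],
            columns=["sample", "gene", "protein_change", "vaf", "zygosity"]
        ).to_csv(outdir / "zygosity.tsv", sep="\t", index=False)

    gene_map = {g.name: g for g in genes}
    bi_rows = []
    for r in results:
        losses = [c for c in r.retained_calls if c.direction == "loss"]
        for g in panel:
            st = biallelic_status(r.patient, g.name, losses, [
                z for z in zygosity_calls if z.record.sample == r.patient],
                gene_map)
            if st.category != "wild_type":
                bi_rows.append((st.patient, st.gene, st.category))
    pd.DataFrame(bi_rows, columns=["patient", "gene", "category"]).to_csv(
        outdir / "biallelic_status.tsv", sep="\t", index=False)

    # minimal deleted regions per panel gene
    mdrs = []
    for g in panel:
        dels = [
            (c.chromosome, c.interval)
            for r in results for c in r.retained_calls
            if c.direction == "loss" and c.chromosome == g.chromosome
            and c.start < g.end and g.start < c.end
        ]
        if dels:
            mdr = minimal_deleted_region(g.name, dels)
            if mdr is not None:
                mdrs.append(mdr)
    io.write_bed(((m.chromosome, m.start, m.end, m.label) for m in mdrs),
                 outdir / "mdr.bed")
    io.write_json(
        [{"label": m.label, "chromosome": m.chromosome, "start": m.start,
          "end": m.end, "size_kb": round(m.size_kb, 1),
          "n_supporting_patients": m.n_supporting_patients} for m in mdrs],
        outdir / "mdr.json")

    # cytogenetic concordance + cohort summary
    karyotypes = {}
    conc_rows = []
    for row in karyo_df.itertuples(index=False):
        pid = str(row.patient)
        try:
            rec = parse_iscn(str(row.iscn), patient=pid,
                             n_metaphases=int(row.n_metaphases))
        except ValueError as exc:
            raise PipelineError("cytogenetics", f"patient {pid}: {exc}") from exc
        karyotypes[pid] = rec
    result_map = {r.patient: r for r in results}
    for pid, rec in karyotypes.items():
        conc = match_cc_to_acgh(rec, result_map[pid].retained_calls, genome)
        for ab, status in conc.per_abnormality:
            conc_rows.append((pid, ab.token, ab.kind, status))
    pd.DataFrame(conc_rows, columns=["patient", "abnormality", "kind",
                                     "status"]).to_csv(
        outdir / "concordance.tsv", sep="\t", index=False)

    summary = summarize_cohort(
        [(karyotypes[pid], result_map[pid].retained_calls)
         for pid in karyotypes], genome)
    summary_dict = summary.to_dict()

    # association: abnormal aCGH profile vs informative CC status
    table = [[0, 0], [0, 0]]
    for pid, rec in karyotypes.items():
        if rec.status == "non_informative":
            continue
        i = 0 if rec.status == "normal" else 1
        j = 1 if result_map[pid].retained_calls else 0
        table[i][j] += 1
    try:
        test = categorical_association(table)
        summary_dict["association_cc_vs_acgh"] = {
            "test": test.test, "statistic": test.statistic,
            "p_value": test.p_value, "table": table}
    except (DegenerateTableError, ValueError):
        summary_dict["association_cc_vs_acgh"] = {
            "test": "fisher_exact", "status": "not_evaluable", "table": table}
    io.write_json(summary_dict, outdir / "cohort_summary.json")

    reports = {r.patient: render_patient_report(r, zygosity_calls, bi_rows)
               for r in results}
    io.write_json(reports, outdir / "patient_reports.json")
    log.info("pipeline complete: %s", outdir)
    return outdir


def render_patient_report(
    result: PatientResult,
    zygosity_calls=(),
    biallelic_rows=(),
) -> dict:
    """Per-patient JSON report: switch counts, CNAs (1-based, ISCN-style
    inclusive coordinates), zygosity and biallelic status."""
    calls = result.retained_calls
    report = {
        "patient": result.patient,
        "profile": "normal aCGH profile" if not calls else "abnormal aCGH profile",
        "n_cnas": len(calls),
        "switch_counts": {c.chromosome: c.n_state_switches
                          for c in result.chromothripsis_calls},
        "chromothripsis_chromosomes": [
            c.chromosome for c in result.positive_chromothripsis],
        "cnas": [
            {"chromosome": c.chromosome, "start_1based": c.start + 1,
             "end_1based": c.end, "direction": c.direction,
             "copy_state": c.copy_state, "size_bp": c.size_bp,
             "cryptic": c.cryptic, "followup": c.followup}
            for c in calls
        ],
        "mutations": [
            {"gene": z.record.gene, "protein_change": z.record.protein_change,
             "vaf": z.record.vaf, "zygosity": z.zygosity}
            for z in zygosity_calls if z.record.sample == result.patient
        ],
        "biallelic": [
            {"gene": gene, "category": cat}
            for pid, gene, cat in biallelic_rows if pid == result.patient
        ],
    }
    return report
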