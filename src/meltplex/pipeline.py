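"""End-to-end analysis of one well: QC → ratios → normalize → call → quantify."""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

from .calling import CallTable, QCReport, RatioTable, call_partitions, compute_ratios, normalize_ratios, qc_well
from .errors import MeltplexError
from .io import PartitionTable, ProbeResult, ResultsTable
from .panel import PanelConfig
from .quant import LocusSummary, TargetQuantification, allele_fractions, quantify_targets

__all__ = ["AnalysisResult", "analyze_well"]


@dataclass
class AnalysisResult:
    """All intermediate and final products of one well's analysis."""

    qc: QCReport
    ratios: RatioTable
    calls: CallTable
    quantifications: List[TargetQuantification]
    loci: List[LocusSummary]

    def results_table(self, panel: PanelConfig) -> ResultsTable:
        af_by_probe = {}
        loci_by_id = {l.locus_id: l for l in self.loci}
        for p in panel.probes:
            locus = loci_by_id.get(p.locus_id)
            if locus is not None:
                af_by_probe[p.probe_id] = (
                    locus.allele_fraction_A if p.allele == "A" else 1.0 - locus.allele_fraction_A
                )
        records = []
        for q in self.quantifications:
            flags = []
            if q.saturated:
                flags.append("saturated")
            if not self.qc.passed:
                flags.append("qc_fail")
            records.append(
                ProbeResult(
                    probe_id=q.probe_id,
                    positives=q.positives,
                    analyzed=q.analyzed,
                    lam=q.lambda_hat,
                    copies_per_uL=q.copies_per_uL,
                    total_copies=q.total_copies,
                    ci95_low=q.total_ci95[0],
                    ci95_high=q.total_ci95[1],
                    allele_fraction=af_by_probe.get(q.probe_id),
                    flags=flags,
                )
            )
        return ResultsTable(well_id=self.calls.well_id, records=records)


def analyze_well(
    table: PartitionTable,
    panel: PanelConfig,
    *,
    force: bool = False,
    compute_allele_fractions: bool = True,
) -> AnalysisResult:
    """Run the full calling/quantification pipeline on one well.

    QC failure aborts unless ``force``; zero-denominator partitions are
    excluded from the analyzed count.  Allele fractions are skipped for
    loci where they are undefined (both alleles zero, or saturation).
    """
    qc = qc_well(table, panel)
    if not qc.passed and not force:
        failed = ", ".join(c.name for c in qc.checks if not c.passed)
        raise MeltplexError(f"well {table.well_id}: QC failed ({failed}); use force to override")
    ratios = compute_ratios(table, panel, on_zero_denominator="exclude")
    ratios = normalize_ratios(ratios, panel.normalization)
    calls = call_partitions(ratios, panel)
    quants = quantify_targets(calls, panel)
    loci: List[LocusSummary] = []
    if compute_allele_fractions:
        loci = allele_fractions(quants, panel, on_undefined="skip")
    return AnalysisResult(qc=qc, ratios=ratios, calls=calls, quantifications=quants, loci=loci)
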