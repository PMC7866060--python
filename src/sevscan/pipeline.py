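"""End-to-end single-case deregulation pipeline.

Chains the module steps in their canonical order: probe QC filtering,
quantile normalization, control reference ranges, SEV detection for every
sample (cases and controls alike, each control analysed as if it were a
case), the sliding-window enrichment scan, subtraction of the control
retained profile from case profiles, gene-locus calling, and the raw and
retained burden GLMs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from sevscan.detection import detect_sevs, reference_ranges, saturated_fraction
from sevscan.enrichment import retained_sev_table, sliding_window_scan
from sevscan.qc import QCReport, filter_probes, quantile_normalize
from sevscan.regions import call_gene_loci, subtract_control_profile
from sevscan.stats import BurdenResult, burden_test


@dataclass
class PipelineResult:
    """All intermediate and final tables of one pipeline run."""

    beta: pd.DataFrame
    qc_report: QCReport
    ranges: pd.DataFrame
    saturated_fraction: float
    sevs: pd.DataFrame
    windows: pd.DataFrame
    retained: pd.DataFrame
    case_retained: pd.DataFrame
    loci: pd.DataFrame
    burden_raw: BurdenResult | None = None
    burden_retained: BurdenResult | None = None

    def sev_counts(self) -> pd.Series:
        """Raw SEV count per sample (zero-filled over all samples)."""
        return self._counts(self.sevs)

    def retained_counts(self) -> pd.Series:
        """Retained SEV count per sample (zero-filled over all samples)."""
        return self._counts(self.retained)

    def _counts(self, calls: pd.DataFrame) -> pd.Series:
        base = pd.Series(0, index=self.beta.columns, dtype=int)
        if len(calls):
            observed = calls.groupby("sample_id").size()
            base.loc[observed.index] = observed
        base.index.name = "sample_id"
        return base


def run_sev_pipeline(
    beta: pd.DataFrame,
    manifest: pd.DataFrame,
    sheet: pd.DataFrame,
    detection_p: pd.DataFrame | None = None,
    bead_counts: pd.DataFrame | None = None,
    k: float = 3.0,
    window: int = 11,
    alpha: float = 0.05,
    normalize: bool = True,
    fit_burden: bool = True,
) -> PipelineResult:
    """Run the full single-case analysis on one cohort.

    ``sheet`` must label every beta column as case or control; controls
    define the reference ranges and are themselves scanned for SEVs so the
    retained burden comparison and the control subtraction are possible.
    With ``fit_burden=False`` the (comparatively slow) GLM fits are
    skipped, which recovery-style simulations do not need.
    """
    filtered, qc_report = filter_probes(
        beta, manifest, detection_p=detection_p, bead_counts=bead_counts
    )
    if normalize:
        filtered = quantile_normalize(filtered)
    control_ids = list(sheet.index[sheet["group"] == "control"])
    case_ids = list(sheet.index[sheet["group"] == "case"])
    ranges = reference_ranges(filtered[control_ids], k=k)
    sevs = detect_sevs(filtered, ranges)
    windows = sliding_window_scan(sevs, manifest, filtered.index, n=window, alpha=alpha)
    retained = retained_sev_table(windows, sevs)

    is_case = retained["sample_id"].isin(case_ids) if len(retained) else pd.Series(dtype=bool)
    case_part = retained.loc[is_case] if len(retained) else retained
    control_part = retained.loc[~is_case] if len(retained) else retained
    case_retained = subtract_control_profile(case_part, control_part)
    loci = call_gene_loci(case_retained, manifest)

    result = PipelineResult(
        beta=filtered,
        qc_report=qc_report,
        ranges=ranges,
        saturated_fraction=saturated_fraction(ranges),
        sevs=sevs,
        windows=windows,
        retained=retained,
        case_retained=case_retained,
        loci=loci,
    )
    if fit_burden:
        try:
            result.burden_raw = burden_test(result.sev_counts(), sheet)
            result.burden_retained = burden_test(result.retained_counts(), sheet)
        except ValueError:
            # degenerate counts (e.g., no SEVs anywhere) leave the burdens unset
            pass
    return result
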