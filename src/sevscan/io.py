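"""Readers and writers for the pipeline's plain-text formats.

Beta, detection-p and bead-count matrices are TSV with probes as rows and a
header row of sample ids; manifests are TSV indexed by probe id; sample
sheets are CSV; region sets are BED (0-based half-open, at least
chrom/start/end, optional name); ground-truth and QC reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from sevscan.qc import QCReport
from sevscan.synthetic import CohortTruth, FLAG_COLUMNS


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a probe x sample TSV matrix (first column = probe id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="probe_id")


def read_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(
        path, sep="\t", index_col="probe_id", keep_default_na=False
    )
    for flag in FLAG_COLUMNS:
        if flag in manifest.columns:
            manifest[flag] = manifest[flag].astype(bool)
    return manifest


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, sep="\t", index_label="probe_id")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample_id")


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, index_label="sample_id")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Parse a BED file into a regions table.

    Accepts 3+ columns (chrom, start, end[, name]); unnamed intervals get
    ``region_<lineno>``. Malformed lines raise ``ValueError`` naming the
    line number. Track/browser/comment lines are skipped.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >=3 tab-separated fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if start < 0 or end < start:
                raise ValueError(f"{path}: line {lineno}: invalid interval [{start}, {end})")
            rows.append(
                {
                    "chromosome": parts[0],
                    "start": start,
                    "end": end,
                    "name": parts[3] if len(parts) > 3 and parts[3] else f"region_{lineno}",
                }
            )
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "name"])


def write_calls(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_loci(loci: pd.DataFrame, path: str | Path) -> None:
    out = loci.copy()
    if "probe_ids" in out.columns:
        out["probe_ids"] = out["probe_ids"].map(";".join)
    out.to_csv(path, sep="\t", index=False)


def write_truth(truth: CohortTruth, path: str | Path) -> None:
    payload = {
        "seed": truth.seed,
        "injected_sevs": [list(t) for t in truth.injected_sevs],
        "injected_regions": truth.injected_regions,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_truth(path: str | Path) -> CohortTruth:
    payload = json.loads(Path(path).read_text())
    return CohortTruth(
        injected_sevs=[tuple(t) for t in payload["injected_sevs"]],
        injected_regions=payload["injected_regions"],
        seed=payload["seed"],
    )


def write_qc_report(report: QCReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")
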