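"""Control subtraction, gene-locus calling and region-set intersection.

The specificity steps downstream of the enrichment scan: deregulations
also seen in healthy controls are treated as non-specific and removed from
case profiles; surviving retained SEVs are grouped into per-sample gene
loci (dropping intergenic probes and single-variant loci); loci are
summarised into shared-gene frequency tables per direction; and retained
SEVs are intersected with curated BED region sets (imprinted DMRs,
retinoic-acid response elements).
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)


def subtract_control_profile(
    case_retained: pd.DataFrame,
    control_retained: pd.DataFrame,
    gene_level: bool = False,
    manifest: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Remove case retained SEVs that also deregulate in controls.

    Default granularity is probe-level (the strictest reading): any case
    retained SEV whose probe appears in the union of control retained SEVs
    is dropped. With ``gene_level=True`` the union of control-deregulated
    *genes* is subtracted instead (requires ``manifest``).
    """
    if len(case_retained) == 0 or len(control_retained) == 0:
        return case_retained.copy()
    if gene_level:
        if manifest is None:
            raise ValueError("gene_level subtraction requires a manifest")
        control_genes = set(
            manifest.loc[
                manifest.index.intersection(control_retained["probe_id"].unique()), "gene"
            ]
        ) - {""}
        case_genes = manifest.loc[case_retained["probe_id"], "gene"].to_numpy()
        keep = ~np.isin(case_genes, list(control_genes))
    else:
        control_probes = set(control_retained["probe_id"])
        keep = ~case_retained["probe_id"].isin(control_probes).to_numpy()
    return case_retained.loc[keep].reset_index(drop=True)


def call_gene_loci(retained: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Group retained SEVs into per-sample gene loci.

    Probes are assigned the manifest gene string verbatim (multi-gene
    labels like ``"SIX3;SIX2"`` are single locus keys). Intergenic probes
    (empty gene) are dropped with a logged count, and loci backed by a
    single variant are excluded: a deregulated locus needs at least two
    retained SEVs of one sample in one gene.

    Returns a DataFrame with columns ``sample_id, gene, n_sevs, direction,
    probe_ids`` (direction ``hyper``/``hypo`` when unanimous, else
    ``mixed``; ``probe_ids`` is a list).
    """
    columns = ["sample_id", "gene", "n_sevs", "direction", "probe_ids"]
    if len(retained) == 0:
        return pd.DataFrame(columns=columns)
    missing = set(retained["probe_id"]) - set(manifest.index)
    if missing:
        raise KeyError(f"{len(missing)} retained probes missing from manifest")
    df = retained.copy()
    df["gene"] = manifest.loc[df["probe_id"], "gene"].to_numpy()
    intergenic = df["gene"] == ""
    if intergenic.any():
        logger.info("dropping %d intergenic retained SEVs", int(intergenic.sum()))
        df = df.loc[~intergenic]
    rows = []
    for (sample_id, gene), grp in df.groupby(["sample_id", "gene"], sort=True):
        if len(grp) < 2:
            continue
        directions = set(grp["direction"])
        rows.append(
            {
                "sample_id": sample_id,
                "gene": gene,
                "n_sevs": len(grp),
                "direction": directions.pop() if len(directions) == 1 else "mixed",
                "probe_ids": sorted(grp["probe_id"]),
            }
        )
    return pd.DataFrame(rows, columns=columns)


def shared_gene_table(loci: pd.DataFrame, direction: str) -> pd.DataFrame:
    """Shared-gene frequency table for one direction.

    One row per gene with a ``direction``-unanimous locus in at least one
    sample: the number of distinct cases and the per-case retained-SEV
    counts formatted ``"SAMPLE (n)"`` in descending-count order. Rows are
    sorted by case count (descending) then gene. Mixed-direction loci are
    excluded (the tables are strictly directional).
    """
    if direction not in ("hyper", "hypo"):
        raise ValueError("direction must be 'hyper' or 'hypo'")
    columns = ["gene", "n_cases", "cases"]
    sub = loci[loci["direction"] == direction] if len(loci) else loci
    if len(sub) == 0:
        return pd.DataFrame(columns=columns)
    rows = []
    for gene, grp in sub.groupby("gene"):
        entries = sorted(
            zip(grp["sample_id"], grp["n_sevs"]), key=lambda t: (-t[1], t[0])
        )
        rows.append(
            {
                "gene": gene,
                "n_cases": grp["sample_id"].nunique(),
                "cases": ", ".join(f"{s} ({n})" for s, n in entries),
            }
        )
    table = pd.DataFrame(rows, columns=columns)
    return table.sort_values(
        ["n_cases", "gene"], ascending=[False, True], ignore_index=True
    )


def intersect_region_sets(
    retained: pd.DataFrame,
    manifest: pd.DataFrame,
    regions: pd.DataFrame,
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Overlap retained SEVs with labelled genomic intervals.

    ``regions`` uses the BED convention: 0-based half-open intervals with
    columns ``chromosome, start, end, name``. Manifest positions are
    1-based, so a probe falls in a region iff
    ``start <= position - 1 < end``. For each (region, sample) with at
    least one retained SEV inside, reports the retained count, per-direction
    counts and the total universe probes in the interval (the "x of y
    probes" denominator). ``universe`` defaults to all manifest probes.
    """
    required = {"chromosome", "start", "end", "name"}
    if not required.issubset(regions.columns):
        raise ValueError(f"regions need columns {sorted(required)}")
    columns = [
        "region", "chromosome", "start", "end", "sample_id",
        "n_retained", "n_hyper", "n_hypo", "n_universe_probes",
    ]
    if len(regions) == 0:
        return pd.DataFrame(columns=columns)
    universe = pd.Index(universe) if universe is not None else manifest.index
    man = manifest.loc[universe]

    trees: dict[str, IntervalTree] = {}
    for i, row in regions.reset_index(drop=True).iterrows():
        start, end = int(row["start"]), int(row["end"])
        if end <= start:
            raise ValueError(f"region {row['name']!r}: empty interval [{start}, {end})")
        trees.setdefault(str(row["chromosome"]), IntervalTree()).addi(start, end, i)

    # universe probes per region
    n_universe = np.zeros(len(regions), dtype=int)
    for chrom, grp in man.groupby("chromosome", sort=False):
        tree = trees.get(str(chrom))
        if tree is None:
            continue
        for pos in grp["position"].to_numpy():
            for iv in tree.at(int(pos) - 1):
                n_universe[iv.data] += 1

    rows: list[dict] = []
    if len(retained):
        ret = retained.copy()
        ret["chromosome"] = manifest.loc[ret["probe_id"], "chromosome"].to_numpy()
        ret["position"] = manifest.loc[ret["probe_id"], "position"].to_numpy()
        counts: dict[tuple[int, str], dict[str, int]] = {}
        for _, call in ret.iterrows():
            tree = trees.get(str(call["chromosome"]))
            if tree is None:
                continue
            for iv in tree.at(int(call["position"]) - 1):
                key = (iv.data, call["sample_id"])
                c = counts.setdefault(key, {"hyper": 0, "hypo": 0})
                c[call["direction"]] += 1
        reg = regions.reset_index(drop=True)
        for (ri, sample_id), c in sorted(counts.items()):
            rows.append(
                {
                    "region": reg.at[ri, "name"],
                    "chromosome": reg.at[ri, "chromosome"],
                    "start": int(reg.at[ri, "start"]),
                    "end": int(reg.at[ri, "end"]),
                    "sample_id": sample_id,
                    "n_retained": c["hyper"] + c["hypo"],
                    "n_hyper": c["hyper"],
                    "n_hypo": c["hypo"],
                    "n_universe_probes": int(n_universe[ri]),
                }
            )
    return pd.DataFrame(rows, columns=columns)
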