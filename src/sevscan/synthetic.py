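"""Synthetic methylation-cohort generator with known ground truth.

Emulates the statistical structure a single-case epivariation analysis
assumes of Infinium 450K-style data: an ordered probe manifest, per-probe
bimodal beta-value baselines shared across samples, small technical noise,
rare isolated extreme outliers, and (on request) injected contiguous
multi-probe deregulated gene regions whose positions and directions are
recorded so detection can be scored against truth.

All randomness flows from one integer seed through a single
``numpy.random.Generator``; no global state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from sevscan.detection import reference_ranges

FLAG_COLUMNS = ("snp_affected", "multi_mapping", "non_cpg", "sex_chromosome")

#: default per-flag probe fractions, loosely mimicking 450K manifest annotation rates
DEFAULT_FLAG_FRACTIONS = {"snp_affected": 0.02, "multi_mapping": 0.002, "non_cpg": 0.005}

#: baseline beta mixture: (mode centre, weight); hyper/hypo/intermediate
BASELINE_MODES = ((0.85, 0.4), (0.10, 0.4), (0.50, 0.2))


@dataclass
class CohortTruth:
    """Ground-truth record of injected epivariations.

    ``injected_sevs`` lists isolated single-probe events as
    ``(sample_id, probe_id, direction)``; ``injected_regions`` lists
    contiguous same-gene events as dicts with keys ``sample_id``, ``gene``,
    ``probe_ids`` and ``direction``.
    """

    injected_sevs: list[tuple[str, str, str]] = field(default_factory=list)
    injected_regions: list[dict] = field(default_factory=list)
    seed: int = 0


def generate_manifest(
    n_probes: int,
    n_chromosomes: int = 2,
    genes_per_chromosome: int = 50,
    seed: int = 0,
    flag_fractions: dict[str, float] | None = None,
    intergenic_frac: float = 0.10,
    multi_gene_frac: float = 0.05,
    include_sex_chrom: bool = False,
) -> pd.DataFrame:
    """Build an ordered probe manifest.

    Probes are split evenly across chromosomes with strictly increasing
    positions; contiguous probe runs share gene labels (a fraction of runs
    is left intergenic, a fraction carries a two-gene ``"A;B"`` label).
    With ``include_sex_chrom`` the last chromosome becomes ``chrX`` and all
    of its probes carry the ``sex_chromosome`` flag.

    Returns a DataFrame indexed by probe id with columns ``chromosome``,
    ``position``, ``gene``, ``island_relation`` and one boolean column per
    QC flag, rows in genomic order.
    """
    if n_probes <= 0 or n_chromosomes <= 0 or genes_per_chromosome <= 0:
        raise ValueError("n_probes, n_chromosomes and genes_per_chromosome must be positive")
    if n_probes < n_chromosomes:
        raise ValueError("need at least one probe per chromosome")
    rng = np.random.default_rng(seed)
    fracs = dict(DEFAULT_FLAG_FRACTIONS if flag_fractions is None else flag_fractions)

    sizes = np.full(n_chromosomes, n_probes // n_chromosomes)
    sizes[: n_probes % n_chromosomes] += 1

    rows: list[dict] = []
    gene_counter = 0
    probe_counter = 0
    for ci, size in enumerate(sizes):
        is_sex = include_sex_chrom and ci == n_chromosomes - 1
        chrom = "chrX" if is_sex else f"chr{ci + 1}"
        positions = np.cumsum(rng.integers(200, 5000, size=size)) + 10_000
        # contiguous gene blocks
        n_blocks = min(genes_per_chromosome, size)
        bounds = np.linspace(0, size, n_blocks + 1).astype(int)
        genes = np.empty(size, dtype=object)
        for b in range(n_blocks):
            if rng.random() < intergenic_frac:
                label = ""
            elif rng.random() < multi_gene_frac:
                label = f"GENE{gene_counter:05d};GENE{gene_counter + 1:05d}"
                gene_counter += 2
            else:
                label = f"GENE{gene_counter:05d}"
                gene_counter += 1
            genes[bounds[b] : bounds[b + 1]] = label
        island = rng.choice(["island", "shore", "open_sea"], size=size, p=[0.3, 0.3, 0.4])
        for j in range(size):
            rows.append(
                {
                    "probe_id": f"cg{probe_counter:08d}",
                    "chromosome": chrom,
                    "position": int(positions[j]),
                    "gene": genes[j],
                    "island_relation": island[j],
                    "sex_chromosome": bool(is_sex),
                }
            )
            probe_counter += 1

    manifest = pd.DataFrame(rows).set_index("probe_id")
    n = len(manifest)
    for flag in ("snp_affected", "multi_mapping", "non_cpg"):
        manifest[flag] = rng.random(n) < fracs.get(flag, 0.0)
    # keep the column order stable
    manifest = manifest[
        ["chromosome", "position", "gene", "island_relation", *FLAG_COLUMNS]
    ]
    return manifest


def generate_cohort(
    manifest: pd.DataFrame,
    n_cases: int = 41,
    n_controls: int = 48,
    noise_sd: float = 0.03,
    outlier_rate: float = 3e-4,
    outlier_shift: tuple[float, float] = (0.25, 0.45),
    detection_fail_frac: float = 1e-4,
    low_bead_frac: float = 1e-4,
    bad_bead_probe_frac: float = 5e-4,
    bad_bead_prob: float = 0.15,
    noise_bound: float = 2.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a beta matrix, sample sheet and QC layers for one cohort.

    Each probe gets a baseline drawn from a three-mode mixture
    (hypermethylated ~0.85, hypomethylated ~0.10, intermediate ~0.5,
    weights 0.4/0.4/0.2) with per-probe jitter; samples observe
    baseline + truncated-normal noise (sd ``noise_sd``, truncated at
    ``noise_bound`` standard deviations), clipped to [0, 1]. Bounded
    technical noise keeps the k=3 fences strictly outside the noise
    support, so null outlier calls come from the explicit heavy-tail
    component rather than from fence-estimation artifacts.
    A rare heavy-tail component (``outlier_rate`` per probe-sample entry,
    shift magnitude uniform over ``outlier_shift``, random sign) models the
    stochastic epimutations real arrays show, so controls carry a small
    nonzero outlier count rather than none at all.

    Detection p-values are small (<0.01) except a ``detection_fail_frac``
    of entries (failure rates chosen so an any-sample rule removes on the
    order of 1% of probes, the scale real arrays show). Bead counts are
    >=3 except a ``low_bead_frac`` of random entries plus a
    ``bad_bead_probe_frac`` of systematically bad probes whose per-sample
    low-bead probability is ``bad_bead_prob`` — only such probe-correlated
    failures can trip the "low in >=5% of samples" removal rule. Sexes and
    ages are drawn per group: cases P(F)=19/41 and age median ~6 y,
    controls P(F)=34/48 and age median ~12.9 y.

    Returns ``(beta, sheet, detection_p, bead_counts)``.
    """
    if manifest.empty:
        raise ValueError("manifest is empty")
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("group sizes must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    n_probes = len(manifest)
    n_samples = n_cases + n_controls

    modes = np.array([m for m, _ in BASELINE_MODES])
    weights = np.array([w for _, w in BASELINE_MODES])
    baseline = modes[rng.choice(len(modes), size=n_probes, p=weights)]
    baseline = np.clip(baseline + rng.normal(0.0, 0.02, size=n_probes), 0.02, 0.98)

    # truncated-normal noise by inverse CDF (exact, vectorized)
    tail = ndtr(-noise_bound)
    u = rng.random((n_probes, n_samples))
    noise = noise_sd * ndtri(tail + u * (1.0 - 2.0 * tail))
    values = baseline[:, None] + noise
    if outlier_rate > 0:
        mask = rng.random((n_probes, n_samples)) < outlier_rate
        n_out = int(mask.sum())
        if n_out:
            shift = rng.uniform(*outlier_shift, size=n_out)
            sign = rng.choice([-1.0, 1.0], size=n_out)
            values[mask] += shift * sign
    values = np.clip(values, 0.0, 1.0)

    sample_ids = [f"CASE{i + 1:02d}" for i in range(n_cases)] + [
        f"CTRL{i + 1:02d}" for i in range(n_controls)
    ]
    beta = pd.DataFrame(values, index=manifest.index.copy(), columns=sample_ids)

    p_female = np.concatenate(
        [np.full(n_cases, 19 / 41), np.full(n_controls, 34 / 48)]
    )
    sex = np.where(rng.random(n_samples) < p_female, "F", "M")
    age_median = np.concatenate([np.full(n_cases, 6.0), np.full(n_controls, 12.9)])
    age = np.round(age_median * np.exp(rng.normal(0.0, 0.7, size=n_samples)), 1)
    sheet = pd.DataFrame(
        {
            "group": ["case"] * n_cases + ["control"] * n_controls,
            "sex": sex,
            "age": age,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    detection_p = rng.uniform(0.0, 0.005, size=(n_probes, n_samples))
    fail = rng.random((n_probes, n_samples)) < detection_fail_frac
    detection_p[fail] = rng.uniform(0.011, 0.2, size=int(fail.sum()))
    detection_p = pd.DataFrame(detection_p, index=beta.index, columns=beta.columns)

    beads = rng.poisson(12, size=(n_probes, n_samples)) + 3
    low_p = np.full(n_probes, low_bead_frac)
    bad = rng.random(n_probes) < bad_bead_probe_frac
    low_p[bad] = bad_bead_prob
    low = rng.random((n_probes, n_samples)) < low_p[:, None]
    beads[low] = rng.integers(0, 3, size=int(low.sum()))
    bead_counts = pd.DataFrame(beads, index=beta.index, columns=beta.columns)

    return beta, sheet, detection_p, bead_counts


def _gene_runs(manifest: pd.DataFrame, min_len: int) -> list[tuple[str, np.ndarray]]:
    """Maximal runs of consecutive manifest rows sharing a non-empty gene label."""
    genes = manifest["gene"].to_numpy()
    chroms = manifest["chromosome"].to_numpy()
    runs = []
    start = 0
    for i in range(1, len(manifest) + 1):
        if (
            i == len(manifest)
            or genes[i] != genes[start]
            or chroms[i] != chroms[start]
        ):
            if genes[start] != "" and i - start >= min_len:
                runs.append((genes[start], np.arange(start, i)))
            start = i
    return runs


def inject_epivariants(
    beta: pd.DataFrame,
    manifest: pd.DataFrame,
    sheet: pd.DataFrame,
    n_isolated: int = 0,
    n_regions: int = 0,
    region_length: int = 5,
    direction_mix: float = 0.5,
    fence_margin: float = 0.10,
    k: float = 3.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, CohortTruth]:
    """Plant isolated SEVs and contiguous deregulated gene regions in cases.

    Injection magnitude is defined relative to the control-derived fences
    (value = fence +/- ``fence_margin``), so every injected event is an SEV
    by construction regardless of the probe's own spread. Targets are drawn
    only among case samples; isolated events avoid reusing a (sample, gene)
    pair so they stay genuinely isolated, and candidate probes are restricted
    to those whose fence leaves room for the margin inside [0, 1].

    Returns the modified matrix (copy) and a :class:`CohortTruth`.
    """
    if n_regions > 0 and region_length < 2:
        raise ValueError("region_length must be >= 2")
    rng = np.random.default_rng(seed)
    out = beta.copy()
    truth = CohortTruth(seed=seed)
    if n_isolated == 0 and n_regions == 0:
        return out, truth

    cases = sheet.index[sheet["group"] == "case"]
    controls = sheet.index[sheet["group"] == "control"]
    if len(cases) == 0:
        raise ValueError("no case samples to inject into")
    ranges = reference_ranges(out[list(controls)], k=k)
    upper = ranges["upper"].to_numpy()
    lower = ranges["lower"].to_numpy()
    hyper_ok = upper + fence_margin <= 1.0
    hypo_ok = lower - fence_margin >= 0.0

    manifest = manifest.loc[out.index]
    pos_of = {p: i for i, p in enumerate(out.index)}
    used: set[tuple[str, str]] = set()  # (sample, gene) pairs already taken

    # contiguous regions first, so isolated events can avoid their genes
    runs = _gene_runs(manifest, region_length)
    placed = 0
    for ri in rng.permutation(len(runs)):
        gene, idx = runs[ri]
        if placed == n_regions:
            break
        sample = str(rng.choice(cases))
        if (sample, gene) in used:
            continue
        start = rng.integers(0, len(idx) - region_length + 1)
        sl = idx[start : start + region_length]
        want_hyper = rng.random() < direction_mix
        for direction in ([ "hyper", "hypo"] if want_hyper else ["hypo", "hyper"]):
            ok = hyper_ok[sl].all() if direction == "hyper" else hypo_ok[sl].all()
            if ok:
                col = out.columns.get_loc(sample)
                if direction == "hyper":
                    out.iloc[sl, col] = upper[sl] + fence_margin
                else:
                    out.iloc[sl, col] = lower[sl] - fence_margin
                probe_ids = list(out.index[sl])
                truth.injected_regions.append(
                    {
                        "sample_id": sample,
                        "gene": gene,
                        "probe_ids": probe_ids,
                        "direction": direction,
                    }
                )
                used.add((sample, gene))
                placed += 1
                break
    if placed < n_regions:
        raise ValueError(
            f"could only place {placed}/{n_regions} regions of length {region_length}"
        )

    genes = manifest["gene"].to_numpy()
    beta_values = out.to_numpy()
    outside = (beta_values > upper[:, None]) | (beta_values < lower[:, None])
    candidates = np.flatnonzero(hyper_ok | hypo_ok)
    rng.shuffle(candidates)
    placed_iso = 0
    for pi in candidates:
        if placed_iso == n_isolated:
            break
        sample = str(rng.choice(cases))
        gene = genes[pi]
        if gene != "" and (sample, gene) in used:
            continue
        if gene != "":
            # keep the event genuinely isolated: no pre-existing outlier of
            # this sample elsewhere in the same gene
            col = out.columns.get_loc(sample)
            same_gene = np.flatnonzero(genes == gene)
            if outside[same_gene, col].any():
                continue
        want_hyper = rng.random() < direction_mix
        order = ["hyper", "hypo"] if want_hyper else ["hypo", "hyper"]
        for direction in order:
            ok = hyper_ok[pi] if direction == "hyper" else hypo_ok[pi]
            if ok:
                col = out.columns.get_loc(sample)
                value = (
                    upper[pi] + fence_margin
                    if direction == "hyper"
                    else lower[pi] - fence_margin
                )
                out.iloc[pi, col] = value
                truth.injected_sevs.append((sample, out.index[pi], direction))
                if gene != "":
                    used.add((sample, gene))
                placed_iso += 1
                break
    if placed_iso < n_isolated:
        raise ValueError(
            f"could only place {placed_iso}/{n_isolated} isolated events"
        )
    return out, truth
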