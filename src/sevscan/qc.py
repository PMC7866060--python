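"""Probe-level quality filtering and quantile normalization.

Filtering removes, in a fixed order: probes failing the detection p-value
rule, probes with low bead counts in too many samples, then manifest-flagged
probes (non-CpG, SNP-affected, multi-mapping, sex-chromosome). Probes
failing several rules are counted under the first matching rule, so the
per-rule removal counts in the report are unambiguous and sum (with the
retained count) to the input probe count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

RULE_ORDER = (
    "detection_p",
    "bead_count",
    "non_cpg",
    "snp_affected",
    "multi_mapping",
    "sex_chromosome",
)


@dataclass
class QCReport:
    """Per-rule removal accounting for one `filter_probes` run."""

    removed_by_rule: dict[str, int] = field(default_factory=dict)
    retained: int = 0
    total: int = 0

    @property
    def removed(self) -> int:
        return sum(self.removed_by_rule.values())

    def to_dict(self) -> dict:
        return {
            "removed_by_rule": dict(self.removed_by_rule),
            "retained": self.retained,
            "total": self.total,
        }


def filter_probes(
    beta: pd.DataFrame,
    manifest: pd.DataFrame,
    detection_p: pd.DataFrame | None = None,
    bead_counts: pd.DataFrame | None = None,
    det_p_max: float = 0.01,
    bead_min: int = 3,
    bead_sample_frac: float = 0.05,
    det_p_frac: float | None = None,
) -> tuple[pd.DataFrame, QCReport]:
    """Remove unreliable and annotation-flagged probes from a beta matrix.

    Rules, applied in order with first-match accounting:

    1. ``detection_p``: p > ``det_p_max`` in any sample (or, when
       ``det_p_frac`` is given, in at least that fraction of samples);
    2. ``bead_count``: bead count < ``bead_min`` in at least
       ``bead_sample_frac`` of samples;
    3-6. manifest flags ``non_cpg``, ``snp_affected``, ``multi_mapping``,
       ``sex_chromosome``.

    QC layers are optional; omitted layers skip their rule. Returns the
    filtered matrix (row subset, same column order) and a :class:`QCReport`.
    """
    missing = beta.index.difference(manifest.index)
    if len(missing) > 0:
        raise ValueError(f"{len(missing)} probes in beta missing from manifest")
    for name, layer in (("detection_p", detection_p), ("bead_counts", bead_counts)):
        if layer is not None:
            if not layer.index.equals(beta.index) or not layer.columns.equals(beta.columns):
                raise ValueError(f"{name} axes do not match beta matrix")

    n_samples = beta.shape[1]
    man = manifest.loc[beta.index]
    fail: dict[str, np.ndarray] = {}
    if detection_p is not None:
        p = detection_p.to_numpy()
        if det_p_frac is None:
            fail["detection_p"] = (p > det_p_max).any(axis=1)
        else:
            fail["detection_p"] = (p > det_p_max).mean(axis=1) >= det_p_frac
    if bead_counts is not None:
        b = bead_counts.to_numpy()
        fail["bead_count"] = (b < bead_min).sum(axis=1) >= bead_sample_frac * n_samples
    for flag in ("non_cpg", "snp_affected", "multi_mapping", "sex_chromosome"):
        if flag in man.columns:
            fail[flag] = man[flag].to_numpy(dtype=bool)

    removed = np.zeros(len(beta), dtype=bool)
    report = QCReport(total=len(beta))
    for rule in RULE_ORDER:
        if rule not in fail:
            continue
        hit = fail[rule] & ~removed
        report.removed_by_rule[rule] = int(hit.sum())
        removed |= hit
    filtered = beta.loc[~removed]
    report.retained = len(filtered)
    if report.retained == 0:
        warnings.warn("all probes removed by QC filtering", stacklevel=2)
    return filtered, report


def drop_incomplete_probes(beta: pd.DataFrame) -> pd.DataFrame:
    """Drop probes with any missing value (pre-step for normalization)."""
    return beta.dropna(axis=0)


def quantile_normalize(beta: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize samples: force every column onto the mean sorted profile.

    After the call each sample's sorted values equal the across-sample mean
    of sorted values; within-sample rank order is preserved. Tied input
    values receive the mean of the reference values at their tied ranks
    (average-rank convention). Missing values are rejected; single-sample
    input is returned unchanged with a warning.
    """
    if beta.isna().to_numpy().any():
        raise ValueError(
            "quantile normalization requires complete data; "
            "use drop_incomplete_probes first"
        )
    if beta.shape[1] < 2:
        warnings.warn("single-sample matrix: quantile normalization is a no-op", stacklevel=2)
        return beta.copy()
    values = beta.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    grid = np.arange(values.shape[0], dtype=float)
    for j in range(values.shape[1]):
        ranks = rankdata(values[:, j], method="average") - 1.0
        out[:, j] = np.interp(ranks, grid, reference)
    return pd.DataFrame(out, index=beta.index.copy(), columns=beta.columns.copy())
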