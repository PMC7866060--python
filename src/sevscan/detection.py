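"""Per-probe control reference ranges and stochastic epigenetic variant calls.

A stochastic epigenetic variant (SEV) is a sample's beta-value falling
strictly outside the Tukey fences built from the healthy-control
distribution of the same probe:

    upper = Q3 + k * IQR,   lower = Q1 - k * IQR,   IQR = Q3 - Q1,  k = 3.

Quartiles use linear interpolation between order statistics ("type 7",
the numpy default); calls above the upper fence are hyper-methylated and
below the lower fence hypo-methylated relative to the control median.
Boundary equality is not an outlier.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd


def reference_ranges(
    control_beta: pd.DataFrame,
    k: float = 3.0,
    min_controls: int = 4,
    quartile_method: str = "linear",
) -> pd.DataFrame:
    """Compute per-probe quartiles, median and outlier fences from controls.

    Parameters
    ----------
    control_beta
        Probe x control-sample beta matrix.
    k
        Fence multiplier; ``k=3`` marks the conventional "extreme" outlier
        boundary, ``k=0`` collapses the fences onto the quartiles.
    min_controls
        Minimum number of control samples required.
    quartile_method
        Interpolation method handed to :func:`numpy.quantile`.

    Returns a DataFrame indexed like ``control_beta`` with columns
    ``q1, median, q3, iqr, lower, upper``; ``lower``/``upper`` may fall
    outside [0, 1] (the fence formula is applied verbatim). The multiplier
    is stored in ``.attrs["k"]``.
    """
    n = control_beta.shape[1]
    if n < min_controls:
        raise ValueError(
            f"need at least {min_controls} control samples, got {n}"
        )
    values = control_beta.to_numpy(dtype=float)
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75], axis=1, method=quartile_method)
    iqr = q3 - q1
    ranges = pd.DataFrame(
        {
            "q1": q1,
            "median": med,
            "q3": q3,
            "iqr": iqr,
            "lower": q1 - k * iqr,
            "upper": q3 + k * iqr,
        },
        index=control_beta.index.copy(),
    )
    ranges.attrs["k"] = k
    return ranges


def detect_sevs(
    beta: pd.DataFrame,
    ranges: pd.DataFrame,
    samples: Sequence[str] | None = None,
    min_fence_halfwidth: float = 0.0,
) -> pd.DataFrame:
    """Call SEVs: beta-values strictly outside the per-probe fences.

    ``samples`` restricts the scan to a subset of columns (default: all).
    ``min_fence_halfwidth`` optionally widens degenerate fences to at least
    ``median +/- halfwidth`` (default 0: the formula is applied verbatim,
    so an IQR of zero makes any deviation an SEV).

    Returns a DataFrame with columns ``sample_id, probe_id, direction,
    beta, excess`` sorted by (sample_id, probe_id); ``excess`` is the
    distance beyond the violated fence. Output is invariant to the row and
    column order of the inputs.
    """
    if samples is None:
        samples = list(beta.columns)
    missing = beta.index.difference(ranges.index)
    if len(missing) > 0:
        raise KeyError(
            f"{len(missing)} probes in beta have no reference range "
            f"(first: {missing[0]!r})"
        )
    r = ranges.loc[beta.index]
    lower = r["lower"].to_numpy()
    upper = r["upper"].to_numpy()
    if min_fence_halfwidth > 0:
        med = r["median"].to_numpy()
        lower = np.minimum(lower, med - min_fence_halfwidth)
        upper = np.maximum(upper, med + min_fence_halfwidth)

    values = beta[list(samples)].to_numpy(dtype=float)
    probe_ids = beta.index.to_numpy()
    records = []
    for j, sample in enumerate(samples):
        col = values[:, j]
        hyper = col > upper
        hypo = col < lower
        for mask, direction, fence, sign in (
            (hyper, "hyper", upper, 1.0),
            (hypo, "hypo", lower, -1.0),
        ):
            idx = np.flatnonzero(mask)
            if idx.size == 0:
                continue
            records.append(
                pd.DataFrame(
                    {
                        "sample_id": sample,
                        "probe_id": probe_ids[idx],
                        "direction": direction,
                        "beta": col[idx],
                        "excess": sign * (col[idx] - fence[idx]),
                    }
                )
            )
    columns = ["sample_id", "probe_id", "direction", "beta", "excess"]
    if not records:
        return pd.DataFrame(columns=columns)
    calls = pd.concat(records, ignore_index=True)
    return calls.sort_values(["sample_id", "probe_id"], ignore_index=True)


def saturated_fraction(ranges: pd.DataFrame) -> float:
    """Fraction of probes whose fences cover all of [0, 1].

    Such probes (upper >= 1 and lower <= 0) can never yield an SEV whatever
    the sample's value; a high fraction signals an uninformative reference.
    """
    sat = (ranges["upper"] >= 1.0) & (ranges["lower"] <= 0.0)
    return float(sat.mean()) if len(ranges) else float("nan")
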