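"""Sliding-window hypergeometric over-representation scan for SEVs.

Raw SEV lists contain both clustered deregulations and spurious isolated
outliers. For each sample the scan walks the retained-probe universe in
manifest (chromosome, position) order; a window of ``n`` consecutive probes
(default 11) around each central probe is tested for SEV enrichment with an
exact cumulative hypergeometric upper tail, drawing x (window SEVs) out of
K (the sample's genome-wide SEV count) from a universe of N probes. A
central probe is retained only when its window is significant AND the probe
itself is an SEV of that sample; everything else is discarded. Windows
never span chromosomes, and centers lacking (n-1)/2 flanking probes on
either side are skipped so the test stays exchangeable across centers.
"""

from __future__ import annotations

from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


def hypergeom_upper_tail(x: int, K: int, n: int, N: int) -> float:
    """Exact upper tail P(X >= x) for X ~ Hypergeometric(N, K, n).

    N is the population (universe) size, K the number of marked items
    (the sample's SEVs), n the draw (window) size and x the observed count.
    Computed with exact integer combinatorics (no normal approximation);
    the result is the correctly rounded float of the rational tail sum up
    to the final division.
    """
    if not (0 <= K <= N):
        raise ValueError(f"require 0 <= K <= N, got K={K}, N={N}")
    if not (0 <= n <= N):
        raise ValueError(f"require 0 <= n <= N, got n={n}, N={N}")
    if x < 0:
        raise ValueError(f"require x >= 0, got x={x}")
    hi = min(n, K)
    if x > hi:
        return 0.0
    lo = max(x, n - (N - K))
    numerator = sum(comb(K, i) * comb(N - K, n - i) for i in range(lo, hi + 1))
    return numerator / comb(N, n)


def sliding_window_scan(
    sevs: pd.DataFrame,
    manifest: pd.DataFrame,
    universe: Sequence[str] | pd.Index,
    n: int = 11,
    alpha: float = 0.05,
    keep_all: bool = False,
    per_direction: bool = False,
) -> pd.DataFrame:
    """Run the window scan for every sample present in ``sevs``.

    Parameters
    ----------
    sevs
        SEV calls (``sample_id, probe_id, direction, ...``) as produced by
        :func:`sevscan.detection.detect_sevs`; calls outside ``universe``
        are ignored.
    manifest
        Probe annotation; defines genomic order of the universe.
    universe
        Retained probe ids (the QC-filtered set). N is its total size,
        genome-wide, matching the genome-wide K.
    n
        Window size in probes; must be odd and >= 3 so a center exists.
    alpha
        Window significance threshold (strict: retained needs p < alpha).
    keep_all
        Emit a row for every full-flank window. Default emits only windows
        containing at least one SEV (x >= 1); x = 0 windows have p = 1 and
        can never be retained, so nothing retained is lost.
    per_direction
        Run the scan separately on hyper and hypo calls (K and x counted
        within direction); adds a ``scan_direction`` column.

    Returns a DataFrame with columns ``sample_id, central_probe,
    chromosome, position, x, K, N, n, p_value, retained``, deterministic
    and invariant to the order of the input calls.
    """
    if n < 3 or n % 2 == 0:
        raise ValueError(f"window size must be odd and >= 3, got {n}")
    universe = pd.Index(universe)
    man = manifest.loc[universe]

    if per_direction:
        parts = []
        for direction in ("hyper", "hypo"):
            sub = sevs[sevs["direction"] == direction]
            part = sliding_window_scan(
                sub, manifest, universe, n=n, alpha=alpha, keep_all=keep_all
            )
            part.insert(0, "scan_direction", direction)
            parts.append(part)
        return pd.concat(parts, ignore_index=True)

    half = (n - 1) // 2
    N = len(universe)
    chrom = man["chromosome"].to_numpy()
    position = man["position"].to_numpy()
    probe_pos = {p: i for i, p in enumerate(universe)}

    # chromosome block boundaries in universe order
    change = np.flatnonzero(chrom[1:] != chrom[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [N]])

    frames = []
    for sample_id in sorted(pd.unique(sevs["sample_id"])) if len(sevs) else []:
        probes = sevs.loc[sevs["sample_id"] == sample_id, "probe_id"]
        hits = np.zeros(N, dtype=np.int64)
        idx = [probe_pos[p] for p in probes if p in probe_pos]
        hits[idx] = 1
        K = int(hits.sum())
        if K == 0 and not keep_all:
            continue
        tail_cache: dict[int, float] = {}
        kernel = np.ones(n, dtype=np.int64)
        for s, e in zip(starts, ends):
            if e - s < n:
                continue
            x = np.convolve(hits[s:e], kernel, mode="valid")  # centers s+half..e-half-1
            centers = np.arange(s + half, e - half)
            if not keep_all:
                sel = x > 0
                centers, x = centers[sel], x[sel]
            if centers.size == 0:
                continue
            p_values = np.empty(centers.size)
            for i, xi in enumerate(x):
                xi = int(xi)
                if xi not in tail_cache:
                    tail_cache[xi] = hypergeom_upper_tail(xi, K, n, N)
                p_values[i] = tail_cache[xi]
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": sample_id,
                        "central_probe": universe[centers],
                        "chromosome": chrom[centers],
                        "position": position[centers],
                        "x": x,
                        "K": K,
                        "N": N,
                        "n": n,
                        "p_value": p_values,
                        "retained": (p_values < alpha) & (hits[centers] == 1),
                    }
                )
            )
    columns = [
        "sample_id", "central_probe", "chromosome", "position",
        "x", "K", "N", "n", "p_value", "retained",
    ]
    if not frames:
        return pd.DataFrame(columns=columns)
    return pd.concat(frames, ignore_index=True)


def retained_sev_table(windows: pd.DataFrame, sevs: pd.DataFrame) -> pd.DataFrame:
    """Retained SEVs with their direction, beta and window p-value.

    Joins the retained centers of a scan back onto the original SEV calls;
    the result is a subset of ``sevs`` (one row per retained SEV).
    """
    kept = windows.loc[windows["retained"], ["sample_id", "central_probe", "p_value", "x"]]
    kept = kept.rename(columns={"central_probe": "probe_id"})
    merged = kept.merge(sevs, on=["sample_id", "probe_id"], how="inner")
    return merged.sort_values(["sample_id", "probe_id"], ignore_index=True)
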