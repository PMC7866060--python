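"""Minimal group-level site differential methylation.

Per-site case-vs-control comparison of beta-values with a Welch two-sample
t-test (optionally with empirical-Bayes variance moderation), volcano-style
filtering at a genome-wide p-value threshold combined with a minimum
absolute methylation difference, and selection of the most variable loci.
This is a deliberately simple surface for exploring group structure next to
the single-case SEV analysis; it fits no surrogate variables or region
models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats


def _moderate_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float]:
    """Empirical-Bayes squeeze of per-probe variances toward a common prior.

    Moment estimation on log variances: the scaled variances are modelled as
    scaled chi-square draws with ``df`` degrees of freedom around an
    inverse-chi-square prior (d0, s0); each variance is replaced by the
    posterior mean (d0*s0 + df*s2) / (d0 + df). Returns the moderated
    variances and the extra degrees of freedom d0.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return s2, 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        d0 = np.inf
        s0 = float(np.exp(np.mean(e)))
        return np.full_like(s2, s0), d0
    # invert trigamma(d0/2) = e_var by bisection on a wide bracket
    lo, hi = 1e-6, 1e6
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if special.polygamma(1, mid / 2.0) > e_var:
            lo = mid
        else:
            hi = mid
    d0 = float(np.sqrt(lo * hi))
    s0 = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    out = s2.copy()
    out[ok] = (d0 * s0 + df * s2[ok]) / (d0 + df)
    out[~ok] = s0 * d0 / (d0 + df) if np.isfinite(d0) else s0
    return out, d0


def site_diff_meth(
    beta: pd.DataFrame, sheet: pd.DataFrame, moderated: bool = False
) -> pd.DataFrame:
    """Per-probe two-group comparison of mean beta-values.

    Welch's unequal-variance t-test per probe by default; with
    ``moderated=True`` the per-probe pooled variances are squeezed toward a
    common prior (classic empirical-Bayes moderation) and an equal-variance
    moderated t is used instead. Probes with zero variance in both groups
    get ``p_value = 1`` and ``zero_variance = True``.

    Returns columns ``probe_id, mean_case, mean_control, diff, p_value,
    zero_variance``.
    """
    sheet = sheet.loc[beta.columns]
    case_ids = sheet.index[sheet["group"] == "case"]
    ctrl_ids = sheet.index[sheet["group"] == "control"]
    n1, n2 = len(case_ids), len(ctrl_ids)
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least two samples")
    case = beta[list(case_ids)].to_numpy(dtype=float)
    ctrl = beta[list(ctrl_ids)].to_numpy(dtype=float)
    m1, m2 = case.mean(axis=1), ctrl.mean(axis=1)
    v1, v2 = case.var(axis=1, ddof=1), ctrl.var(axis=1, ddof=1)
    diff = m1 - m2

    with np.errstate(divide="ignore", invalid="ignore"):
        if moderated:
            df = float(n1 + n2 - 2)
            s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
            s2_mod, d0 = _moderate_variances(s2, df)
            se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
            t = diff / se
            dof = np.full_like(t, df + (d0 if np.isfinite(d0) else 0.0))
        else:
            se2 = v1 / n1 + v2 / n2
            t = diff / np.sqrt(se2)
            dof = se2**2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
        p = 2.0 * stats.t.sf(np.abs(t), dof)
    zero_var = ~np.isfinite(p)
    p[zero_var] = 1.0
    return pd.DataFrame(
        {
            "probe_id": beta.index,
            "mean_case": m1,
            "mean_control": m2,
            "diff": diff,
            "p_value": p,
            "zero_variance": zero_var,
        }
    ).reset_index(drop=True)


@dataclass
class VolcanoResult:
    hyper: pd.DataFrame
    hypo: pd.DataFrame
    p_threshold: float
    diff_threshold: float

    @property
    def n_hyper(self) -> int:
        return len(self.hyper)

    @property
    def n_hypo(self) -> int:
        return len(self.hypo)

    @property
    def n_significant(self) -> int:
        return self.n_hyper + self.n_hypo


def volcano_filter(
    results: pd.DataFrame,
    p_threshold: float = 1e-7,
    diff_threshold: float = 0.10,
) -> VolcanoResult:
    """Keep sites meeting both the p-value and |difference| cutoffs.

    A site is significant iff ``p_value < p_threshold`` and
    ``|diff| > diff_threshold``; significant sites are partitioned into
    hyper- (diff > 0) and hypo-methylated (diff < 0) tables.
    """
    sig = (results["p_value"] < p_threshold) & (results["diff"].abs() > diff_threshold)
    kept = results.loc[sig]
    return VolcanoResult(
        hyper=kept.loc[kept["diff"] > 0].reset_index(drop=True),
        hypo=kept.loc[kept["diff"] < 0].reset_index(drop=True),
        p_threshold=p_threshold,
        diff_threshold=diff_threshold,
    )


def top_variable_loci(beta: pd.DataFrame, n: int = 1000) -> pd.Index:
    """The ``n`` probes with largest across-sample variance.

    Deterministic: ties are broken by probe id (ascending). Raises on
    non-positive ``n``; ``n`` larger than the probe count returns all
    probes (variance-ordered).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    variances = beta.var(axis=1, ddof=1)
    order = np.lexsort((beta.index.to_numpy(), -variances.to_numpy()))
    return beta.index[order[: min(n, len(beta))]]


def region_mean_beta(
    beta: pd.DataFrame, manifest: pd.DataFrame, by: str = "gene"
) -> pd.DataFrame:
    """Mean beta per annotation group (simple exploratory aggregator).

    Averages probes sharing a manifest label (default ``gene``; empty
    labels are dropped). Not a region-level test, just a summary.
    """
    labels = manifest.loc[beta.index, by]
    keep = labels != ""
    return beta.loc[keep].groupby(labels[keep]).mean()
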