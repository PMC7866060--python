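"""Cohort-level statistics: SEV burden GLM, covariate comparison, prevalence.

The burden test asks whether cases carry more SEVs (raw or retained) than
controls after adjusting for sex and age: a Poisson log-link GLM
``count ~ group + sex + age`` with an automatic overdispersion check
(Pearson chi^2 / df > 2 switches the covariance to the quasi-Poisson
Pearson scale). Covariates such as age are compared between groups with
the two-sided Wilcoxon rank-sum test. The prevalence table summarises
binary clinical features as n/N with conventional percent rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from math import floor

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import mannwhitneyu

#: Pearson chi^2 / residual df beyond which quasi-Poisson errors are used
OVERDISPERSION_LIMIT = 2.0


@dataclass
class BurdenResult:
    """Fitted group effect on per-sample SEV counts."""

    per_sample_counts: pd.Series
    group_coefficient: float
    p_value: float
    model: str
    overdispersion: float

    def __repr__(self) -> str:  # compact, printable summary
        return (
            f"BurdenResult(model={self.model!r}, "
            f"group_coefficient={self.group_coefficient:.4f}, "
            f"p_value={self.p_value:.3g}, "
            f"overdispersion={self.overdispersion:.2f})"
        )


def burden_test(counts: pd.Series, sheet: pd.DataFrame) -> BurdenResult:
    """Case-vs-control GLM on per-sample SEV counts, adjusted for sex and age.

    ``counts`` is indexed by sample id; ``sheet`` provides ``group``
    (case/control), ``sex`` and ``age`` for every counted sample. The group
    coefficient is the log rate ratio of cases over controls; its Wald
    p-value is returned. Constant counts or groups of fewer than two
    samples cannot support the fit and raise ``ValueError``.
    """
    sheet = sheet.loc[counts.index]
    sizes = sheet["group"].value_counts()
    if set(sizes.index) != {"case", "control"} or (sizes < 2).any():
        raise ValueError("burden_test needs >=2 cases and >=2 controls")
    if sheet[["sex", "age"]].isna().to_numpy().any():
        raise ValueError("sex and age must be available for all samples")
    if counts.nunique() == 1:
        raise ValueError(
            f"degenerate fit: all {len(counts)} samples have count {counts.iloc[0]}"
        )
    data = sheet.assign(
        count=counts.astype(int),
        is_case=(sheet["group"] == "case").astype(int),
    )
    fit = smf.glm(
        "count ~ is_case + C(sex) + age", data=data, family=sm.families.Poisson()
    ).fit()
    dispersion = float(fit.pearson_chi2 / fit.df_resid)
    model = "poisson(log) ~ group + sex + age"
    if dispersion > OVERDISPERSION_LIMIT:
        fit = smf.glm(
            "count ~ is_case + C(sex) + age", data=data, family=sm.families.Poisson()
        ).fit(scale="X2")
        model = "quasipoisson(log) ~ group + sex + age"
    return BurdenResult(
        per_sample_counts=counts,
        group_coefficient=float(fit.params["is_case"]),
        p_value=float(fit.pvalues["is_case"]),
        model=model,
        overdispersion=dispersion,
    )


@dataclass
class RankSumResult:
    p_value: float
    median_case: float
    median_control: float
    statistic: float


def covariate_compare(sheet: pd.DataFrame, values: pd.Series) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum comparison of a covariate between groups.

    Exact p-value for small untied samples (scipy's automatic policy),
    normal approximation otherwise. Being rank-based, the result is
    invariant under monotone transformations of ``values``.
    """
    sheet = sheet.loc[values.index]
    case = values[sheet["group"] == "case"].to_numpy(dtype=float)
    control = values[sheet["group"] == "control"].to_numpy(dtype=float)
    if len(case) == 0 or len(control) == 0:
        raise ValueError("both groups need at least one value")
    res = mannwhitneyu(case, control, alternative="two-sided")
    return RankSumResult(
        p_value=float(res.pvalue),
        median_case=float(np.median(case)),
        median_control=float(np.median(control)),
        statistic=float(res.statistic),
    )


def _round_percent(value: float) -> float:
    """Half-up integer percent; one decimal when the unrounded value < 10."""
    if value < 10.0:
        return floor(value * 10.0 + 0.5) / 10.0
    return float(floor(value + 0.5))


def prevalence_table(clinical: pd.DataFrame) -> pd.DataFrame:
    """Summarise boolean clinical feature columns as n/N and percent.

    One row per feature: affected count, total samples and the percent
    (half-up to the nearest integer; one decimal place for rare features
    under 10%). Output is independent of sample order.
    """
    features = [c for c in clinical.columns if clinical[c].dtype == bool]
    n_total = len(clinical)
    rows = []
    for feature in features:
        n = int(clinical[feature].sum())
        rows.append(
            {
                "feature": feature,
                "n_affected": n,
                "n_total": n_total,
                "percent": _round_percent(100.0 * n / n_total) if n_total else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["feature", "n_affected", "n_total", "percent"])


def load_clinical_fixture() -> pd.DataFrame:
    """Load the packaged 41-patient clinical feature table.

    A synthetic per-patient reconstruction: individual flag assignments are
    invented, but every marginal count (feature prevalences, 19 F / 22 M
    sex split, median age 6) matches the cohort summary the package's
    examples reproduce. Boolean feature columns plus ``sex`` and ``age``,
    indexed by sample id.
    """
    with resources.files("sevscan.data").joinpath(
        "clinical_features_synthetic.csv"
    ).open() as fh:
        df = pd.read_csv(fh, index_col="sample_id")
    for column in df.columns:
        if df[column].dtype != object and set(df[column].unique()) <= {0, 1}:
            df[column] = df[column].astype(bool)
    return df
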