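"""Genotype-dosage statistics for grain morphometric and weight traits.

Per-spike measurements (grain width, length, area in mm/mm^2 and thousand
grain weight in g) are averaged into plant means, summarized per genotype
class (mean +/- SE, percent change vs. the segregating wild-type baseline),
and compared with pooled-variance Student's t-tests, one-way ANOVA with
Tukey HSD, and a functional-copy-number dosage trend. A 2^-ddCt helper
covers qPCR relative expression.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .amplicon import functional_copies_from_code

logger = logging.getLogger(__name__)

TRAITS = ("width", "length", "area", "tgw")


def percent_change(mean: float, ref_mean: float) -> float:
    """Percent change of a group mean relative to the reference mean."""
    return 100.0 * (mean - ref_mean) / ref_mean


def significance_stars(p: float) -> str:
    """Star annotation: * 0.01<P<0.05, ** P<0.01, *** P<0.001, **** P<0.0001."""
    if math.isnan(p):
        return ""
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    degenerate: bool = False


def students_t_test(group1: Sequence[float], group2: Sequence[float]) -> TTestResult:
    """Two-tailed pooled-variance Student's t-test.

    With zero pooled variance the test is degenerate: equal means give
    p = 1, unequal means p = 0 (flagged).
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    df = x.size + y.size - 2
    sp2 = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / df
    if sp2 == 0.0:
        if x.mean() == y.mean():
            return TTestResult(0.0, df, 1.0, degenerate=True)
        return TTestResult(math.inf if x.mean() > y.mean() else -math.inf,
                           df, 0.0, degenerate=True)
    res = stats.ttest_ind(x, y, equal_var=True)
    return TTestResult(float(res.statistic), df, float(res.pvalue))


def plant_trait_means(records: pd.DataFrame, traits: Sequence[str] = TRAITS) -> pd.DataFrame:
    """Average per-spike measurements into per-plant trait means.

    Expects columns ``plant_id``, ``genotype``, ``spike`` and one column per
    trait. Missing spike values are skipped for that trait (the plant is
    excluded for a trait only when all its spikes are missing).
    """
    missing = records[list(traits)].isna().sum().sum()
    if missing:
        logger.info("plant_trait_means: skipping %d missing spike values", missing)
    return (
        records.groupby(["plant_id", "genotype"], as_index=False)[list(traits)]
        .mean()
    )


def group_summary(
    plant_means: pd.DataFrame,
    reference: str = "AABBDD",
    traits: Sequence[str] = TRAITS,
) -> pd.DataFrame:
    """Per-genotype trait summaries with percent change vs. the reference.

    Returns one row per (genotype, trait) with n, mean, SE (= SD/sqrt(n)),
    percent change relative to the reference genotype, the two-tailed
    pooled-variance t-test p-value against the reference, and star
    annotations. Groups with n < 2 get summaries but no test.
    """
    if reference not in set(plant_means["genotype"]):
        raise ValueError(f"reference genotype {reference!r} not present")
    ref_rows = plant_means[plant_means["genotype"] == reference]
    rows = []
    for genotype, grp in plant_means.groupby("genotype", sort=True):
        for trait in traits:
            vals = grp[trait].dropna().to_numpy()
            ref_vals = ref_rows[trait].dropna().to_numpy()
            n = vals.size
            mean = vals.mean()
            se = vals.std(ddof=1) / math.sqrt(n) if n > 1 else math.nan
            pct = 0.0 if genotype == reference else percent_change(mean, ref_vals.mean())
            if genotype == reference or n < 2 or ref_vals.size < 2:
                p = math.nan
            else:
                p = students_t_test(vals, ref_vals).p
            rows.append(
                {
                    "genotype": genotype,
                    "trait": trait,
                    "n": n,
                    "mean": mean,
                    "se": se,
                    "pct_change": round(pct, 2),
                    "p_value": p,
                    "stars": significance_stars(p) if not math.isnan(p) else "",
                }
            )
    return pd.DataFrame(rows)


@dataclass
class AnovaResult:
    f: float
    p: float
    tukey: pd.DataFrame | None
    degenerate: bool = False


def anova_tukey(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way ANOVA followed by Tukey's HSD post-hoc test.

    ``groups`` maps group labels to observation vectors (each n >= 2). When
    all observations are identical the F statistic is undefined and the
    result is flagged degenerate.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(groups[name], dtype=float) for name in names]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0.0:
        return AnovaResult(math.nan, math.nan, None, degenerate=True)
    f, p = stats.f_oneway(*arrays)
    hsd = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(names)):
        for j in range(len(names)):
            if i < j:
                rows.append(
                    {
                        "group1": names[i],
                        "group2": names[j],
                        "diff": arrays[i].mean() - arrays[j].mean(),
                        "p_adj": float(hsd.pvalue[i, j]),
                    }
                )
    return AnovaResult(float(f), float(p), pd.DataFrame(rows))


def dosage_trend(
    plant_means: pd.DataFrame,
    traits: Sequence[str] = TRAITS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group plants by functional gene copies (0-6) and report the trend.

    Adds a ``functional_copies`` grouping derived from the genotype code
    (count of uppercase letters), summarizes each copy-number class per
    trait, and reports the Spearman correlation of plant trait values
    against copy number as the monotonicity measure. Empty copy-number
    classes are simply absent. Returns ``(summaries, trend)``.
    """
    df = plant_means.copy()
    df["functional_copies"] = df["genotype"].map(functional_copies_from_code)
    rows = []
    for copies, grp in df.groupby("functional_copies", sort=True):
        for trait in traits:
            vals = grp[trait].dropna()
            rows.append(
                {
                    "functional_copies": copies,
                    "trait": trait,
                    "n": vals.size,
                    "mean": vals.mean(),
                    "se": vals.std(ddof=1) / math.sqrt(vals.size)
                    if vals.size > 1
                    else math.nan,
                }
            )
    trend_rows = []
    for trait in traits:
        sub = df[["functional_copies", trait]].dropna()
        if sub["functional_copies"].nunique() > 1:
            rho, p = stats.spearmanr(sub["functional_copies"], sub[trait])
        else:
            rho, p = math.nan, math.nan
        trend_rows.append(
            {"trait": trait, "spearman_rho": rho, "p_value": p,
             "direction": int(np.sign(rho)) if not math.isnan(rho) else 0}
        )
    return pd.DataFrame(rows), pd.DataFrame(trend_rows)


def qpcr_relative_expression(
    ct_target: float,
    ct_reference: float,
    calibrator: tuple[float, float] | None = None,
) -> float:
    """Relative expression by the 2^-ddCt method.

    ``dCt = Ct_target - Ct_reference`` within each sample; with a
    ``(Ct_target, Ct_reference)`` calibrator pair the result is
    ``2**-(dCt_sample - dCt_calibrator)``, otherwise the uncalibrated
    ``2**-dCt`` is returned.
    """
    if not (math.isfinite(ct_target) and math.isfinite(ct_reference)):
        raise ValueError("Ct values must be finite")
    dct = ct_target - ct_reference
    if calibrator is None:
        logger.info("qpcr_relative_expression: no calibrator, reporting 2^-dCt")
        return 2.0 ** -dct
    cal_t, cal_r = calibrator
    if not (math.isfinite(cal_t) and math.isfinite(cal_r)):
        raise ValueError("calibrator Ct values must be finite")
    return 2.0 ** -(dct - (cal_t - cal_r))
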