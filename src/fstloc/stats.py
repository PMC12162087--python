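"""Validation statistics: t tests, R1 myelin proxy, decile profiles, groups.

Vertex-level tests treat vertices as independent samples (they are
spatially correlated in real data; the degrees of freedom mirror the
per-hemisphere vertex counts). Two-sample comparisons use the pooled-
variance Student t by default — with 296 hMT/MST and 95 pFST vertices this
gives df = 389 — with Welch available behind a flag. Group-level
comparisons are paired t tests across hemispheres (18 hemispheres from 9
subjects gives df = 17). No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ROIComparison",
    "r1_from_t1",
    "one_sample_t",
    "two_sample_t",
    "paired_t",
    "decile_profile",
    "group_report",
]

#: expected direction of each validation measure, as sign of (hMTMST - pFST)
MEASURE_DIRECTIONS = {"motion2d": 1, "motion3d": -1, "opponency": 1, "r1": 1}


@dataclass
class ROIComparison:
    measure: str
    statistic: float
    df: int
    p: float
    direction: int  # sign of (hMTMST - pFST), or of the tested mean
    kind: str  # 'one_sample' | 'two_sample' | 'paired'


def r1_from_t1(t1):
    """Longitudinal relaxation rate R1 = 1/T1 (s^-1), the myelin proxy."""
    t1 = np.asarray(t1, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("T1 must be positive")
    out = 1.0 / t1
    return float(out) if out.ndim == 0 else out


def one_sample_t(values, popmean: float = 0.0, measure: str = "") -> ROIComparison:
    """Two-sided one-sample t of the mean against ``popmean`` (df = n-1)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    if np.ptp(values) == 0.0:
        raise ValueError("zero-variance sample: t statistic undefined")
    res = sps.ttest_1samp(values, popmean)
    return ROIComparison(
        measure=measure,
        statistic=float(res.statistic),
        df=values.size - 1,
        p=float(res.pvalue),
        direction=int(np.sign(values.mean() - popmean)),
        kind="one_sample",
    )


def two_sample_t(
    a, b, measure: str = "", welch: bool = False, alternative: str = "two-sided"
) -> ROIComparison:
    """Student (pooled-variance) two-sample t, df = n_a + n_b - 2.

    ``a`` is the hMT/MST-side sample by convention; the reported direction
    is the sign of mean(a) - mean(b). Set ``welch=True`` for the unequal-
    variance variant (df then follows Welch-Satterthwaite, rounded down).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per sample")
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
        raise ValueError("zero pooled variance: t statistic undefined")
    res = sps.ttest_ind(a, b, equal_var=not welch, alternative=alternative)
    if welch:
        df = int(np.floor(res.df))
    else:
        df = a.size + b.size - 2
    return ROIComparison(
        measure=measure,
        statistic=float(res.statistic),
        df=df,
        p=float(res.pvalue),
        direction=int(np.sign(a.mean() - b.mean())),
        kind="two_sample",
    )


def paired_t(a, b, measure: str = "") -> ROIComparison:
    """Two-sided paired t (one-sample t on differences), df = pairs - 1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.ptp(d) == 0.0:
        raise ValueError("zero-variance differences: t statistic undefined")
    res = sps.ttest_rel(a, b)
    return ROIComparison(
        measure=measure,
        statistic=float(res.statistic),
        df=a.size - 1,
        p=float(res.pvalue),
        direction=int(np.sign(d.mean())),
        kind="paired",
    )


def decile_profile(values_a, values_b) -> pd.DataFrame:
    """Decile-by-decile comparison of two vertex distributions.

    Returns the 10th..100th percentiles (linear interpolation) of each
    distribution and the sign of (b - a) per decile — the slope sign of the
    lines connecting matching deciles in the two ROIs.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both distributions must be non-empty")
    qs = np.arange(10, 101, 10)
    pa = np.percentile(a, qs)
    pb = np.percentile(b, qs)
    return pd.DataFrame(
        {
            "percentile": qs,
            "value_a": pa,
            "value_b": pb,
            "slope_sign": np.sign(pb - pa).astype(int),
        }
    )


def group_report(
    hemisphere_results: list[dict],
    alpha_individual: float = 0.05,
    directions: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Group-level summary across hemispheres.

    ``hemisphere_results`` is a list of dicts with keys 'hemisphere' and
    'measures' (measure -> ROI -> vertex-value array), e.g. the output of
    :func:`fstloc.synth.cohort_measures`. Per measure the report gives the
    group mean and SE of the per-hemisphere ROI means, a paired t test of
    hMT/MST against pFST across hemispheres, and the count of hemispheres
    whose individual one-tailed two-sample test is significant in the
    expected direction.
    """
    if len(hemisphere_results) < 2:
        raise ValueError("need at least 2 hemispheres")
    directions = MEASURE_DIRECTIONS if directions is None else directions
    measures = list(hemisphere_results[0]["measures"].keys())

    rows = []
    for m in measures:
        mt_means = np.array(
            [h["measures"][m]["hMTMST"].mean() for h in hemisphere_results]
        )
        fst_means = np.array(
            [h["measures"][m]["pFST"].mean() for h in hemisphere_results]
        )
        test = paired_t(mt_means, fst_means, measure=m)
        expected = directions.get(m, 1)
        alternative = "greater" if expected > 0 else "less"
        n_sig = sum(
            two_sample_t(
                h["measures"][m]["hMTMST"],
                h["measures"][m]["pFST"],
                measure=m,
                alternative=alternative,
            ).p
            < alpha_individual
            for h in hemisphere_results
        )
        n = len(hemisphere_results)
        rows.append(
            {
                "measure": m,
                "n_hemispheres": n,
                "mean_hMTMST": mt_means.mean(),
                "se_hMTMST": mt_means.std(ddof=1) / np.sqrt(n),
                "mean_pFST": fst_means.mean(),
                "se_pFST": fst_means.std(ddof=1) / np.sqrt(n),
                "paired_t": test.statistic,
                "df": test.df,
                "p": test.p,
                "direction": test.direction,
                "n_individually_significant": int(n_sig),
            }
        )
    return pd.DataFrame(rows)
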