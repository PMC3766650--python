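"""Cohort statistics: summaries, two-group tests, protected Fisher LSD,
metastasis density and tumor volume.

The unit of analysis is the FOV for image metrics and the animal for lung
metastasis density; callers record which they used. All tests are two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class GroupSummary:
    """Mean ± SEM summary of one group."""

    group: str
    values: List[float]
    n: int
    mean: float
    sem: Optional[float]  # absent (None) when n == 1


@dataclass
class TestResult:
    test_name: str                  # t_unpaired | mann_whitney | anova_fisher_lsd
    statistic: float
    p_value: float
    df: Optional[float] = None
    detail: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


def summarize(values: Sequence[float], group: str = "") -> GroupSummary:
    """Mean and standard error (sample SD with n-1 denominator over sqrt n)."""
    arr = np.asarray(list(values), dtype=np.float64)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty sample")
    if not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")
    n = int(arr.size)
    sem = float(arr.std(ddof=1) / np.sqrt(n)) if n > 1 else None
    return GroupSummary(group=group, values=[float(v) for v in arr], n=n, mean=float(arr.mean()), sem=sem)


def t_unpaired(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Unpaired two-sided Student's t-test (equal variances)."""
    a = np.asarray(list(a), dtype=np.float64)
    b = np.asarray(list(b), dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("t-test requires n >= 2 in each group")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            # identical constant samples: no evidence of difference
            return TestResult("t_unpaired", 0.0, 1.0, df=float(a.size + b.size - 2))
        raise ValueError("zero variance in both groups; t statistic undefined")
    res = sps.ttest_ind(a, b, equal_var=True, alternative="two-sided")
    stat = float(res.statistic)
    if np.isnan(stat):  # identical samples with zero pooled variance
        stat, p = 0.0, 1.0
    else:
        p = float(res.pvalue)
    return TestResult("t_unpaired", stat, p, df=float(a.size + b.size - 2))


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon-Mann-Whitney test.

    Exact null distribution when the combined sample size is <= 20 and there
    are no ties; normal approximation with tie correction otherwise.
    """
    a = np.asarray(list(a), dtype=np.float64)
    b = np.asarray(list(b), dtype=np.float64)
    if a.size < 1 or b.size < 1:
        raise ValueError("Mann-Whitney requires n >= 1 in each group")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult("mann_whitney", float(res.statistic), float(res.pvalue), detail=method)


def anova_fisher_lsd(groups: Dict[str, Sequence[float]], alpha: float = 0.05) -> List[TestResult]:
    """One-way ANOVA with protected Fisher LSD pairwise comparisons.

    The LSD t-tests use the pooled within-group mean square (df = N - k) and
    are performed only when the omnibus ANOVA is significant at ``alpha``
    ("protected"); otherwise only the omnibus result is returned.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("ANOVA requires at least two groups")
    samples = [np.asarray(list(groups[g]), dtype=np.float64) for g in names]
    if any(s.size < 2 for s in samples):
        raise ValueError("ANOVA requires n >= 2 per group")
    f_res = sps.f_oneway(*samples)
    n_total = sum(s.size for s in samples)
    k = len(samples)
    results = [
        TestResult("anova_fisher_lsd", float(f_res.statistic), float(f_res.pvalue),
                   df=float(n_total - k), detail="omnibus")
    ]
    if f_res.pvalue > alpha:
        return results
    mse = sum(((s - s.mean()) ** 2).sum() for s in samples) / (n_total - k)
    df_err = n_total - k
    for i in range(k):
        for j in range(i + 1, k):
            si, sj = samples[i], samples[j]
            se = np.sqrt(mse * (1.0 / si.size + 1.0 / sj.size))
            t = float((si.mean() - sj.mean()) / se)
            p = float(2.0 * sps.t.sf(abs(t), df_err))
            results.append(
                TestResult("anova_fisher_lsd", t, p, df=float(df_err),
                           detail=f"lsd:{names[i]} vs {names[j]}")
            )
    return results


def metastasis_density(
    counts: Sequence[int],
    section_areas_cm2: Sequence[float],
    animals: Sequence[str],
    groups: Sequence[str],
) -> Dict[str, GroupSummary]:
    """Per-group mean ± SEM of per-animal lung metastasis densities.

    Inputs align per lung section. For each animal the density is
    total counts / total sectioned area (metastases per cm^2); animals are
    then the unit of the group summary.
    """
    df = pd.DataFrame({
        "count": list(counts),
        "area": list(section_areas_cm2),
        "animal": list(animals),
        "group": list(groups),
    })
    if len(df) == 0:
        raise ValueError("no sections provided")
    if (df["area"] <= 0).any():
        raise ValueError("section areas must be positive")
    if (df["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    per_animal = df.groupby(["group", "animal"], sort=True).agg(
        total_count=("count", "sum"), total_area=("area", "sum")
    )
    if (per_animal["total_area"] <= 0).any():
        raise ValueError("zero total section area for an animal")
    per_animal["density"] = per_animal["total_count"] / per_animal["total_area"]
    return {
        g: summarize(sub["density"].tolist(), group=g)
        for g, sub in per_animal.groupby(level="group", sort=True)
    }


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Ellipsoid tumor volume estimate V = length * width^2 / 2 (mm^3).

    Caliper convention: length is the longer axis; swapped inputs are
    auto-corrected with a warning.
    """
    if length_mm <= 0 or width_mm <= 0:
        raise ValueError("dimensions must be positive")
    if width_mm > length_mm:
        warnings.warn("width exceeds length; swapping axes", UserWarning)
        length_mm, width_mm = width_mm, length_mm
    return length_mm * width_mm ** 2 / 2.0
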