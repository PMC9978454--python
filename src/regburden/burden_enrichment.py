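"""Mutability-normalized DNM burden comparisons.

Observed DNM counts per enhancer set are rescaled to a common reference
mutation rate (``observed * reference_rate / set_rate``) so sets of very
different size and sequence composition become comparable; the normalized
values feed a two-tailed t test (fetal vs adult sets), an exact two-sample
Poisson rate-ratio test, per-cell-type Fisher tests, and BH FDR correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .intervals import GenomicInterval, IntervalIndex
from .io_formats import DNMRecord

logger = logging.getLogger(__name__)

__all__ = [
    "BurdenObservation",
    "BurdenTestResult",
    "count_overlapping_dnms",
    "normalize_count",
    "fetal_vs_adult_ttest",
    "poisson_rate_ratio_test",
    "celltype_fisher",
    "fdr_adjust",
]


@dataclass
class BurdenObservation:
    set_name: str
    cohort: str
    observed: int
    set_rate: float
    normalized: float


@dataclass
class BurdenTestResult:
    statistic: float
    p: float
    method: str
    fdr: float | None = None


def count_overlapping_dnms(
    dnms: Sequence[DNMRecord], regions: Sequence[GenomicInterval]
) -> int:
    """Number of DNMs whose (0-based) position lies in the merged regions.

    DNMs on chromosomes absent from the region set's genome are logged and
    excluded only when they name a chromosome no region mentions — a DNM on
    a known chromosome that simply misses all regions counts as outside.
    """
    index = IntervalIndex(regions)
    return sum(1 for d in dnms if index.contains_point(d.chrom, d.pos0))


def normalize_count(observed: int, set_rate: float, reference_rate: float) -> float:
    """Rescale an observed count to the reference background mutation rate."""
    if set_rate <= 0:
        raise ValueError("set_rate must be positive")
    if reference_rate <= 0:
        raise ValueError("reference_rate must be positive")
    return observed * reference_rate / set_rate


def fetal_vs_adult_ttest(
    fetal_normalized: Sequence[float],
    adult_normalized: Sequence[float],
    equal_var: bool = True,
) -> BurdenTestResult:
    """Two-sample two-tailed t test on normalized counts.

    Student (equal-variance) form by default with a Welch option.  With n = 2
    in one group the test is fragile: a warning is emitted and callers should
    report the Poisson rate-ratio test alongside.
    """
    x = np.asarray(fetal_normalized, dtype=float)
    y = np.asarray(adult_normalized, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 values per group")
    if min(len(x), len(y)) == 2:
        warnings.warn(
            "t test with n=2 in one group is fragile; consider the Poisson "
            "rate-ratio test as well",
            stacklevel=2,
        )
    if x.std() == 0 and y.std() == 0:
        if x.mean() == y.mean():
            return BurdenTestResult(0.0, 1.0, "t_test")
    stat, p = stats.ttest_ind(x, y, equal_var=equal_var)
    if np.isnan(p):
        stat, p = 0.0, 1.0
    return BurdenTestResult(float(stat), float(p), "t_test")


def poisson_rate_ratio_test(
    obs1: int, opportunity1: float, obs2: int, opportunity2: float
) -> BurdenTestResult:
    """Exact two-sample Poisson rate-ratio test (conditional binomial).

    Given the total, obs1 ~ Binomial(obs1 + obs2, q) with
    q = opportunity1 / (opportunity1 + opportunity2) under the null of equal
    rates.  The two-sided p sums the probabilities of all outcomes no more
    likely than the observed one (minimum-likelihood method).
    """
    if opportunity1 <= 0 or opportunity2 <= 0:
        raise ValueError("opportunities must be positive")
    if obs1 < 0 or obs2 < 0:
        raise ValueError("counts must be non-negative")
    n = obs1 + obs2
    if n == 0:
        return BurdenTestResult(np.nan, 1.0, "poisson_rate_ratio")
    q = opportunity1 / (opportunity1 + opportunity2)
    pmf = stats.binom.pmf(np.arange(n + 1), n, q)
    p_obs = pmf[obs1]
    # relative tolerance guards against ties lost to floating point
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    rate_ratio = (obs1 / opportunity1) / (obs2 / opportunity2) if obs2 else np.inf
    return BurdenTestResult(float(rate_ratio), min(p, 1.0), "poisson_rate_ratio")


def celltype_fisher(
    case_in: int, case_out: int, control_in: int, control_out: int
) -> BurdenTestResult:
    """Two-sided Fisher exact test on the 2x2 inside/outside x cohort table."""
    table = np.array([[case_in, case_out], [control_in, control_out]])
    if table.min() < 0:
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return BurdenTestResult(np.nan, 1.0, "fisher_exact")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return BurdenTestResult(float(odds), float(p), "fisher_exact")


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out
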