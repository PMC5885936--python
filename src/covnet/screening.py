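"""Variance-homogeneity pre-filter.

Regions whose thickness variance differs between any pair of groups are
excluded before network construction, using two-sample F tests for equal
variances at a configurable significance level (default 1%).  No
multiple-testing correction is applied: the filter is a plain per-region,
per-pair screen, and a region failing ANY pair is dropped globally.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
from scipy import stats

from covnet.cohort import ThicknessCohort


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of the variance screen."""

    excluded_regions: tuple[str, ...]
    #: (region, group_a, group_b) -> (F, two-sided p)
    tests: Mapping[tuple[str, str, str], tuple[float, float]]
    alpha: float

    def apply(self, cohort: ThicknessCohort) -> ThicknessCohort:
        """Cohort view with the excluded regions dropped everywhere."""
        return cohort.drop_regions(self.excluded_regions)


def f_test_equal_variance(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sample F test for equality of variances.

    ``F = s2_x / s2_y`` with unbiased sample variances and a two-sided p
    obtained by doubling the smaller tail of F(n_x - 1, n_y - 1), capped
    at 1.  Requires at least two observations per sample and nonzero
    variance in both.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two observations per sample")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0 or vy == 0:
        raise ValueError("zero-variance sample in F test")
    f = vx / vy
    dist = stats.f(x.size - 1, y.size - 1)
    p = 2.0 * min(dist.cdf(f), dist.sf(f))
    return float(f), float(min(p, 1.0))


def screen_regions(cohort: ThicknessCohort, alpha: float = 0.01) -> ScreenResult:
    """Screen every region over every unordered pair of groups.

    A region is excluded iff any pairwise comparison has p <= ``alpha``.
    The result is independent of the order in which groups are listed.
    """
    groups = sorted(cohort.group_labels)
    if len(groups) < 2:
        raise ValueError("variance screen needs at least two groups")
    slices = {g: cohort.group_slice(g)[0] for g in groups}
    tests: dict[tuple[str, str, str], tuple[float, float]] = {}
    excluded: list[str] = []
    for j, region in enumerate(cohort.regions.labels):
        drop = False
        for ga, gb in combinations(groups, 2):
            f, p = f_test_equal_variance(slices[ga][:, j], slices[gb][:, j])
            tests[(region, ga, gb)] = (f, p)
            if p <= alpha:
                drop = True
        if drop:
            excluded.append(region)
    return ScreenResult(tuple(excluded), tests, alpha)
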