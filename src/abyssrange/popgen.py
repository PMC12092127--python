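"""Genetic diversity statistics: segregating sites, nucleotide and haplotype
diversity, and Tajima's D with its beta-approximation significance test.

All site-based statistics are computed over the columns admitted by a
:class:`~abyssrange.alignment.SiteFilter`, so that the segregating-site count
and the mean pairwise difference share one site universe.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import beta as beta_dist

from .alignment import Alignment, HaplotypeTable, SiteFilter
from .errors import UndefinedStatisticError

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class TajimaComponents:
    """The sample-size constants of Tajima's D (1989 formulation)."""

    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


@dataclass(frozen=True)
class DiversityStats:
    n: int
    H: int
    h: float
    pi: float
    ss: int
    k_hat: float
    D: float
    p_value: float
    stars: str


def tajima_components(n: int) -> TajimaComponents:
    if n < 2:
        raise UndefinedStatisticError("Tajima components need n >= 2")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaComponents(a1, a2, b1, b2, c1, c2, e1, e2)


def segregating_sites(alignment: Alignment, site_filter: SiteFilter) -> int:
    """Number of retained columns carrying two or more distinct symbols."""
    if alignment.n < 2:
        raise UndefinedStatisticError("segregating sites need >= 2 sequences")
    sub = site_filter.apply(alignment)
    return int(np.count_nonzero((sub != sub[0]).any(axis=0)))


def nucleotide_diversity(
    alignment: Alignment, site_filter: SiteFilter
) -> tuple[float, float]:
    """Return (pi, k_hat).

    k_hat is the mean pairwise difference count over all C(n,2) sequence
    pairs on the retained columns; pi divides it by the retained length.
    """
    if alignment.n < 2:
        raise UndefinedStatisticError("nucleotide diversity needs >= 2 sequences")
    if site_filter.L_retained < 1:
        raise UndefinedStatisticError("no retained columns")
    sub = site_filter.apply(alignment)
    n = alignment.n
    total = 0
    for i in range(n - 1):
        total += int((sub[i] != sub[i + 1 :]).sum())
    k_hat = total / (n * (n - 1) / 2)
    return k_hat / site_filter.L_retained, k_hat


def haplotype_diversity(table: HaplotypeTable) -> float:
    """Nei's unbiased haplotype diversity h = n/(n-1) * (1 - sum p_i^2)."""
    n = table.n
    if n < 2:
        raise UndefinedStatisticError("haplotype diversity needs n >= 2")
    sum_sq = sum((f / n) ** 2 for f in table.frequencies)
    return n / (n - 1) * (1.0 - sum_sq)


def tajimas_d(ss: int, k_hat: float, n: int) -> tuple[float, TajimaComponents]:
    """Tajima's D from the segregating-site count and mean pairwise differences.

    Returns NaN (with a warning, without raising) when ss == 0, where the
    statistic's variance estimate vanishes.
    """
    if n < 2:
        raise UndefinedStatisticError("Tajima's D needs n >= 2")
    if n < 4:
        warnings.warn(f"Tajima's D is unreliable at n={n} (< 4)", stacklevel=2)
    comp = tajima_components(n)
    if ss == 0:
        warnings.warn("Tajima's D undefined at ss=0; returning NaN", stacklevel=2)
        return math.nan, comp
    var = comp.e1 * ss + comp.e2 * ss * (ss - 1)
    if var <= 0:  # identically zero at n=3, where c1 = c2 = 0
        warnings.warn("Tajima's D variance is zero; returning NaN", stacklevel=2)
        return math.nan, comp
    d = (k_hat - ss / comp.a1) / math.sqrt(var)
    return d, comp


def tajima_d_bounds(n: int) -> tuple[float, float]:
    """Support [D_min, D_max] of the beta approximation to D's null density."""
    comp = tajima_components(n)
    sqrt_e2 = math.sqrt(comp.e2)
    d_min = (2.0 / n - 1.0 / comp.a1) / sqrt_e2
    d_max = ((n + 1) / (2.0 * n) - 1.0 / comp.a1) / sqrt_e2
    return d_min, d_max


def tajima_p_value(D: float, n: int) -> tuple[float, str]:
    """Two-sided p for Tajima's D under the scaled-beta null approximation.

    The null density is a beta rescaled to [D_min, D_max] with mean 0 and
    variance 1; D outside the support is clamped with a warning.  Stars follow
    the {0.05, 0.01, 0.001} thresholds ('ns' when not significant).
    """
    if not math.isfinite(D):
        raise UndefinedStatisticError("p-value undefined for non-finite D")
    d_min, d_max = tajima_d_bounds(n)
    if D < d_min or D > d_max:
        warnings.warn(
            f"D={D:.5f} outside beta support [{d_min:.5f}, {d_max:.5f}]; clamped",
            stacklevel=2,
        )
        D = min(max(D, d_min), d_max)
    span = d_max - d_min
    # shape parameters give the rescaled density mean 0 and variance 1
    alpha = -(1.0 + d_min * d_max) * d_max / span
    bshape = (1.0 + d_min * d_max) * d_min / span
    cdf = beta_dist.cdf((D - d_min) / span, bshape, alpha)
    p = 2.0 * min(cdf, 1.0 - cdf)
    p = min(p, 1.0)
    stars = "ns"
    for thresh, label in STAR_THRESHOLDS:
        if p <= thresh:
            stars = label
            break
    return p, stars


def diversity_summary(
    alignment: Alignment, site_filter: SiteFilter, table: HaplotypeTable
) -> DiversityStats:
    """Assemble the per-locus diversity row from the individual statistics."""
    ss = segregating_sites(alignment, site_filter)
    pi, k_hat = nucleotide_diversity(alignment, site_filter)
    h = haplotype_diversity(table)
    D, _ = tajimas_d(ss, k_hat, alignment.n)
    if math.isfinite(D):
        p, stars = tajima_p_value(D, alignment.n)
    else:
        p, stars = math.nan, "ns"
    return DiversityStats(
        n=alignment.n,
        H=table.H,
        h=h,
        pi=pi,
        ss=ss,
        k_hat=k_hat,
        D=D,
        p_value=p,
        stars=stars,
    )
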