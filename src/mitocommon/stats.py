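"""Forensic and population-genetic summary statistics.

Given an identity partition with group sizes :math:`n_i` and denominator
:math:`N`:

.. math::

    \\mathrm{RMP} = \\sum_i n_i^2 / N^2, \\qquad
    \\mathrm{HD} = \\frac{N}{N-1}\\Bigl(1 - \\sum_i (n_i/N)^2\\Bigr),

with haplotype diversity (HD) used interchangeably with the power of
discrimination (PD), and discrimination capacity DC = k/N for k distinct
haplotypes.  Under the double-match convention a heteroplasmic sample sits
in two groups, so :math:`\\sum_i n_i` may exceed N while N stays at the
number of physical samples.

Binomial proportions carry two-sided Clopper–Pearson (exact) confidence
intervals, and observed MCH counts are converted into the equivalent
number of individuals screened via the population MCH frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import pandas as pd
from scipy import stats as sps

from .matching import (
    DEFAULT_RULES,
    IdentityPartition,
    MatchRules,
    Scenario,
    build_identity_partition,
)


def round_half_up(x: float, digits: int = 1) -> float:
    """Presentation rounding, half away from zero (as in the study tables)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def as_percent(x: float, digits: int = 1) -> float:
    return round_half_up(100.0 * x, digits)


@dataclass(frozen=True)
class ForensicParams:
    """Forensic parameters of one identity partition (unrounded)."""

    N: int
    k: int
    group_sizes: tuple[int, ...]
    RMP: float
    HD: float
    DC: float
    unique_count: int
    unique_sample_fraction: float

    @property
    def PD(self) -> float:  # power of discrimination == haplotype diversity
        return self.HD

    @property
    def non_unique_members(self) -> int:
        """Members of non-singleton groups (double assignments included)."""
        return sum(s for s in self.group_sizes if s > 1)

    def summary(self) -> dict:
        """Presentation-rounded view (percents to one decimal)."""
        return {
            "N": self.N,
            "haplotypes": self.k,
            "unique_haplotypes": self.unique_count,
            "RMP_percent": as_percent(self.RMP),
            "PD_percent": as_percent(self.HD),
            "DC": round_half_up(self.DC, 3),
            "DC_percent": as_percent(self.DC),
            "unique_sample_percent": as_percent(self.unique_sample_fraction),
            "non_unique_members": self.non_unique_members,
        }


def forensic_params(p: IdentityPartition) -> ForensicParams:
    """Compute RMP/HD(PD)/DC from an identity partition.

    Group sizes may sum to more than N under the double-match convention;
    the denominator is always the partition's N.
    """
    if p.N < 2:
        raise ValueError("N must be >= 2 (haplotype diversity undefined)")
    sizes = tuple(p.group_sizes)
    if not sizes:
        raise ValueError("empty partition")
    N = p.N
    rmp = sum(s * s for s in sizes) / (N * N)
    hd = (N / (N - 1)) * (1.0 - rmp)
    k = len(sizes)
    unique = sum(1 for s in sizes if s == 1)
    return ForensicParams(
        N=N,
        k=k,
        group_sizes=sizes,
        RMP=rmp,
        HD=hd,
        DC=k / N,
        unique_count=unique,
        unique_sample_fraction=unique / N,
    )


@dataclass(frozen=True)
class BinomialCI:
    """Two-sided exact (Clopper–Pearson) binomial confidence interval."""

    k: int
    n: int
    level: float
    lower: float
    upper: float

    @property
    def point(self) -> float:
        return self.k / self.n


def clopper_pearson(k: int, n: int, level: float = 0.95) -> BinomialCI:
    """Exact binomial CI from Beta quantiles.

    lower = BetaInv(alpha/2; k, n-k+1) (0 when k = 0) and
    upper = BetaInv(1-alpha/2; k+1, n-k) (1 when k = n).
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"invalid binomial counts k={k}, n={n}")
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return BinomialCI(k=k, n=n, level=level, lower=lower, upper=upper)


@dataclass(frozen=True)
class ScreeningEquivalent:
    """How many individuals a screened-positive sample set represents."""

    point: int
    lower: int
    upper: int
    note: str = ""


def screening_equivalent(
    sample_size: int,
    frequency: float,
    frequency_ci: Optional[tuple[float, float]] = None,
) -> ScreeningEquivalent:
    """Invert a screening frequency into an equivalent screened count.

    ``sample_size`` positives at population frequency ``frequency``
    represent ``sample_size / frequency`` screened individuals; the count
    CI inverts the frequency CI (lower count from the upper frequency).
    Frequencies printed at one-decimal percent precision can leave the last
    digit of a bound unstable; a note flags that case.
    """
    if frequency <= 0 or frequency > 1:
        raise ValueError("frequency must be in (0, 1]")
    point = round(sample_size / frequency)
    if frequency_ci is None:
        return ScreeningEquivalent(point=point, lower=point, upper=point)
    lo_f, hi_f = frequency_ci
    if not (0 < lo_f <= frequency <= hi_f <= 1):
        raise ValueError("CI bounds must bracket the frequency")
    lower = round(sample_size / hi_f)
    upper = round(sample_size / lo_f)
    note = ""
    for f in (lo_f, hi_f, frequency):
        # one-decimal-percent inputs: bound within 1 of a rounding boundary
        exact = sample_size / f
        if abs(exact - round(exact)) > 0.45:
            note = (
                "count bound derived from a printed-precision frequency; "
                "last digit unstable"
            )
    return ScreeningEquivalent(point=point, lower=lower, upper=upper, note=note)


def scenario_report(
    hs: Sequence,
    rules: MatchRules = DEFAULT_RULES,
    reference=None,
) -> pd.DataFrame:
    """Forensic parameters across all four double-match scenarios.

    The study observed that the scenarios differ only at higher decimal
    places; this table makes that check directly.
    """
    rows = []
    for scenario in Scenario:
        p = build_identity_partition(hs, rules, scenario, reference)
        fp = forensic_params(p)
        rows.append(
            {
                "scenario": scenario.value,
                "N": fp.N,
                "haplotypes": fp.k,
                "RMP": fp.RMP,
                "HD": fp.HD,
                "DC": fp.DC,
                "unique": fp.unique_count,
            }
        )
    return pd.DataFrame(rows).set_index("scenario")
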