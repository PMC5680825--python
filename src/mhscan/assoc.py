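"""Carrier-mating classification and litter-trait contrasts.

For a candidate lethal haplotype, litters are classified by the carrier
status of both parents: C x C (both carry at least one copy), C x NC
(exactly one carries), NC x NC, or unknown when either parent is
ungenotyped or has undetermined phase in the window.  Trait contrasts
compare C x C against C x NC litters with a two-sided Welch t-test;
C x NC is the comparison class, so NC x NC and unknown litters never
enter a contrast.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io import HaplotypePanel, LitterRecord
from .scan import UNDETERMINED, HaplotypeTag

TRAITS = ("TNB", "NBA", "NSB", "MUM")

CXC = "CxC"
CXNC = "CxNC"
NCXNC = "NCxNC"
UNKNOWN = "unknown"


@dataclass(frozen=True)
class MatingClass:
    litter: LitterRecord
    mating: str  # CxC / CxNC / NCxNC / unknown


@dataclass
class TraitEffect:
    """C x C vs C x NC contrast for one litter trait.

    percent_difference is 100 * (mean_CxC - mean_CxNC) / mean_CxNC, so a
    lethal that suppresses litter size gives a negative value for TNB
    and a large positive value for MUM.
    """

    trait: str
    mean_cxc: float
    mean_cxnc: float
    n_cxc: int
    n_cxnc: int
    percent_difference: float
    welch_t: float
    welch_df: float
    welch_p: float
    testable: bool = True


def classify_matings(
    litters: Sequence[LitterRecord],
    tag: HaplotypeTag,
    panel: HaplotypePanel,
    copies: np.ndarray | None = None,
) -> list[MatingClass]:
    """Assign each litter a mating class from parental copy numbers."""
    if copies is None:
        copies = tag.copies_vector(panel.n_animals)
    out: list[MatingClass] = []
    for litter in litters:
        states = []
        for parent in (litter.sow, litter.boar):
            if parent in panel:
                states.append(int(copies[panel.animal_index(parent)]))
            else:
                states.append(UNDETERMINED)
        if UNDETERMINED in states:
            mating = UNKNOWN
        else:
            carriers = sum(1 for s in states if s >= 1)
            mating = {2: CXC, 1: CXNC, 0: NCXNC}[carriers]
        out.append(MatingClass(litter=litter, mating=mating))
    return out


def percent_difference(mean_cxc: float, mean_cxnc: float) -> float:
    """Signed percent difference of the C x C mean relative to C x NC."""
    if mean_cxnc == 0:
        return float("nan")
    return 100.0 * (mean_cxc - mean_cxnc) / mean_cxnc


def welch_t(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float]:
    """Two-sided Welch two-sample t-test: (t, df, p).

    Requires at least two observations per sample and a nonzero pooled
    variance term; degenerate inputs yield NaN results.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("welch_t requires >= 2 observations per sample")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            # no variance, no difference: nothing to test
            return 0.0, float(len(x) + len(y) - 2), 1.0
        return float("nan"), float("nan"), float("nan")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def trait_effect(
    classes: Sequence[MatingClass], trait: str
) -> TraitEffect:
    """Contrast one trait between C x C and C x NC litters."""
    if trait not in TRAITS:
        raise ValueError(f"unknown trait {trait!r}")
    cxc = [m.litter.trait(trait) for m in classes if m.mating == CXC]
    cxnc = [m.litter.trait(trait) for m in classes if m.mating == CXNC]
    if len(cxc) < 2 or len(cxnc) < 2:
        return TraitEffect(
            trait=trait,
            mean_cxc=float(np.mean(cxc)) if cxc else float("nan"),
            mean_cxnc=float(np.mean(cxnc)) if cxnc else float("nan"),
            n_cxc=len(cxc),
            n_cxnc=len(cxnc),
            percent_difference=float("nan"),
            welch_t=float("nan"),
            welch_df=float("nan"),
            welch_p=float("nan"),
            testable=False,
        )
    mean_cxc = float(np.mean(cxc))
    mean_cxnc = float(np.mean(cxnc))
    t, df, p = welch_t(cxc, cxnc)
    return TraitEffect(
        trait=trait,
        mean_cxc=mean_cxc,
        mean_cxnc=mean_cxnc,
        n_cxc=len(cxc),
        n_cxnc=len(cxnc),
        percent_difference=percent_difference(mean_cxc, mean_cxnc),
        welch_t=t,
        welch_df=df,
        welch_p=p,
        testable=math.isfinite(p),
    )


def mum_distribution(
    classes: Sequence[MatingClass],
) -> dict[str, dict[int, float]]:
    """Per-class empirical distribution of mummified piglets per litter.

    Returns, for each mating class present, the fraction of its litters
    with exactly x mummified piglets; fractions sum to 1 per class.
    """
    counters: dict[str, Counter] = {}
    for m in classes:
        counters.setdefault(m.mating, Counter())[m.litter.mum] += 1
    out: dict[str, dict[int, float]] = {}
    for mating, counter in counters.items():
        total = sum(counter.values())
        out[mating] = {x: c / total for x, c in sorted(counter.items())}
    return out


def ratio_chisq(
    classes: Sequence[MatingClass],
) -> tuple[float, float, list[str]]:
    """Pearson chi-square on the MUM/NSB/NBA composition of C x C vs
    C x NC litters.

    The 2x3 contingency table is built from the summed integer counts
    per class, never from means.  Returns (statistic, p, warnings);
    expected cells below 1 produce a warning instead of an error.
    """
    sums = {CXC: [0, 0, 0], CXNC: [0, 0, 0]}
    n_litters = {CXC: 0, CXNC: 0}
    for m in classes:
        if m.mating in sums:
            sums[m.mating][0] += m.litter.mum
            sums[m.mating][1] += m.litter.nsb
            sums[m.mating][2] += m.litter.nba
            n_litters[m.mating] += 1
    if n_litters[CXC] == 0 or n_litters[CXNC] == 0:
        raise ValueError("ratio_chisq requires litters in both classes")
    table = np.array([sums[CXC], sums[CXNC]], dtype=float)
    warnings: list[str] = []
    stat, p, _, expected = stats.chi2_contingency(table, correction=False)
    if (expected < 1).any():
        warnings.append("expected cell count below 1; chi-square unreliable")
    return float(stat), float(p), warnings


@dataclass(frozen=True)
class CarrierHaplotypeSummary:
    """Population-level rates implied by a fully penetrant recessive
    lethal at a given carrier frequency, plus mummy accounting."""

    carrier_frequency_pct: float
    affected_litter_pct: float
    affected_piglet_pct: float
    mummies_per_cxc_litter: float
    population_mummy_share_pct: float


def lethal_rate_summary(
    carrier_freq: float,
    mum_cxc_total: int,
    litters_cxc: int,
    mum_population_total: int,
) -> CarrierHaplotypeSummary:
    """Derived rates for a recessive lethal under random mating.

    With carrier frequency q, a fraction q^2 of litters are C x C and,
    at full penetrance, a quarter of their piglets (q^2/4 of all
    piglets) are affected.  The mummy accounting divides the C x C
    mummy total by the C x C litter count and by the population-wide
    mummy total.
    """
    if carrier_freq <= 0 or litters_cxc <= 0 or mum_population_total <= 0:
        raise ValueError("inputs must be positive")
    return CarrierHaplotypeSummary(
        carrier_frequency_pct=100.0 * carrier_freq,
        affected_litter_pct=100.0 * carrier_freq**2,
        affected_piglet_pct=100.0 * carrier_freq**2 / 4.0,
        mummies_per_cxc_litter=mum_cxc_total / litters_cxc,
        population_mummy_share_pct=100.0 * mum_cxc_total
        / mum_population_total,
    )
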