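"""Marker and animal quality filters, plus the per-animal inbreeding F.

Thresholds are strict inequalities: a marker is kept only if its MAF is
*greater than* the minimum and its call rate *greater than* the minimum;
an animal is discarded only if its missing fraction is *greater than*
the maximum.  Filter order is fixed — markers first, then animals —
because marker removal changes per-animal missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, HaplotypePanel


@dataclass(frozen=True)
class QCParams:
    """Pre-processing thresholds.

    maf_min : markers kept need minor allele frequency > maf_min.
    marker_callrate_min : markers kept need call rate > this value.
    animal_max_missing : animals kept need missing fraction <= this value.
    autosomes : chromosome labels to keep; ``None`` keeps all.
    """

    maf_min: float = 0.01
    marker_callrate_min: float = 0.85
    animal_max_missing: float = 0.30
    autosomes: frozenset[str] | None = None

    def __post_init__(self) -> None:
        for v in (self.maf_min, self.marker_callrate_min,
                  self.animal_max_missing):
            if not 0.0 <= v <= 1.0:
                raise ValueError("QC thresholds must lie in [0, 1]")


@dataclass
class FReport:
    """Per-animal inbreeding coefficients from genotype homozygosity.

    F = (O_hom - E_hom) / (L - E_hom) with O_hom the observed and E_hom
    the Hardy-Weinberg expected homozygous genotype count over the L
    non-missing markers of the animal.  NaN where L <= E_hom.
    """

    animals: list[str]
    observed_hom: np.ndarray
    expected_hom: np.ndarray
    n_markers: np.ndarray
    f: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal": self.animals,
                "observed_hom": self.observed_hom,
                "expected_hom": self.expected_hom,
                "n_markers": self.n_markers,
                "F": self.f,
            }
        )


def marker_stats(panel: HaplotypePanel) -> tuple[np.ndarray, np.ndarray]:
    """(MAF, call rate) per marker, computed on non-missing genotypes."""
    h = panel.haplotypes
    called = (h >= 0).all(axis=1)  # (N, M) genotype non-missing
    n_called = called.sum(axis=0)
    alt_count = np.where(called, h.sum(axis=1), 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, alt_count / (2.0 * n_called), 0.0)
    maf = np.minimum(p, 1.0 - p)
    call_rate = n_called / max(panel.n_animals, 1)
    return maf, call_rate


def filter_markers(
    panel: HaplotypePanel, params: QCParams
) -> tuple[HaplotypePanel, pd.DataFrame]:
    """Apply marker filters; returns the filtered panel and a removal log.

    Keeps autosomal markers with MAF > maf_min, call rate >
    marker_callrate_min, and a unique (chromosome, position); the first
    marker at a duplicated position (in input order) is retained.
    Chromosome/position filters are applied before the call-rate and MAF
    computation.
    """
    m = panel.markers
    n = len(m)
    keep = np.ones(n, dtype=bool)
    reasons: list[tuple[str, str]] = []

    if params.autosomes is not None:
        non_auto = ~np.isin(m.chroms.astype(str), list(params.autosomes))
        for j in np.flatnonzero(non_auto & keep):
            reasons.append((str(m.names[j]), "non_autosomal"))
        keep &= ~non_auto

    seen: set[tuple[str, int]] = set()
    for j in np.flatnonzero(keep):
        key = (str(m.chroms[j]), int(m.positions[j]))
        if key in seen:
            keep[j] = False
            reasons.append((str(m.names[j]), "duplicate_position"))
        else:
            seen.add(key)

    maf, call_rate = marker_stats(panel)
    low_cr = keep & ~(call_rate > params.marker_callrate_min)
    for j in np.flatnonzero(low_cr):
        reasons.append((str(m.names[j]), "low_call_rate"))
    keep &= ~low_cr
    low_maf = keep & ~(maf > params.maf_min)
    for j in np.flatnonzero(low_maf):
        reasons.append((str(m.names[j]), "low_maf"))
    keep &= ~low_maf

    log = pd.DataFrame(reasons, columns=["marker", "reason"])
    return panel.subset_markers(keep), log


def filter_animals(
    panel: HaplotypePanel, params: QCParams
) -> tuple[HaplotypePanel, pd.DataFrame]:
    """Drop animals whose missing-genotype fraction exceeds the threshold."""
    h = panel.haplotypes
    if panel.n_markers == 0:
        missing_frac = np.zeros(panel.n_animals)
    else:
        missing_frac = (h < 0).any(axis=1).mean(axis=1)
    keep = ~(missing_frac > params.animal_max_missing)
    log = pd.DataFrame(
        {
            "animal": [panel.animals[i] for i in np.flatnonzero(~keep)],
            "reason": "high_missingness",
        }
    )
    return panel.subset_animals(keep), log


def f_coefficient(
    panel: HaplotypePanel, allele_freqs: np.ndarray | None = None
) -> FReport:
    """Per-animal inbreeding F from observed vs expected homozygosity.

    *allele_freqs* is the per-marker alternate-allele frequency; when not
    supplied it is computed from the panel itself.
    """
    if allele_freqs is None:
        h = panel.haplotypes
        called = (h >= 0).all(axis=1)
        n_called = called.sum(axis=0)
        alt = np.where(called, h.sum(axis=1), 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            allele_freqs = np.where(n_called > 0, alt / (2.0 * n_called), 0.0)
    p = np.asarray(allele_freqs, dtype=float)
    if p.shape != (panel.n_markers,):
        raise ValueError("allele_freqs length must equal marker count")

    g = panel.genotypes()  # (N, M)
    nonmiss = g >= 0
    hom = (g == 0) | (g == 2)
    obs = (hom & nonmiss).sum(axis=1).astype(float)
    e_marker = 1.0 - 2.0 * p * (1.0 - p)  # per-marker P(homozygous) under HWE
    exp = (nonmiss * e_marker).sum(axis=1)
    L = nonmiss.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(L > exp, (obs - exp) / (L - exp), np.nan)
    return FReport(
        animals=list(panel.animals),
        observed_hom=obs.astype(int),
        expected_hom=exp,
        n_markers=L.astype(int),
        f=f,
    )
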