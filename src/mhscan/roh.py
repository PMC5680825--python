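"""Runs of homozygosity with deterministic maximal-interval semantics.

A ROH segment is a maximal stretch of consecutive markers on one
chromosome of one animal containing at most ``max_het`` heterozygous
calls, at least ``min_markers`` markers, and spanning at least
``min_length`` base pairs.  Missing calls neither count as heterozygous
nor break a stretch.  "Maximal" means extending the stretch by one
marker in either direction would exceed the heterozygote allowance (or
run off the chromosome); when a heterozygous call sits near a stretch
boundary two maximal stretches can overlap, and both are reported.

This is a deliberate dialect difference from scanning-window ROH
callers, whose extra window-level parameters are not part of this
model; the three constraints above fully determine the maximal-interval
formulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import HaplotypePanel, MarkerMap


@dataclass(frozen=True)
class ROHSegment:
    animal: str
    chrom: str
    start: int  # bp of first marker
    end: int  # bp of last marker
    n_markers: int
    het_calls: int


def _segments_for_calls(
    calls: np.ndarray, max_het: int
) -> list[tuple[int, int]]:
    """Maximal half-open index intervals with <= max_het heterozygous
    calls; calls use 0 hom, 1 het, -1 missing."""
    m = len(calls)
    het = calls == 1
    out: list[tuple[int, int]] = []
    r = 0
    n_het = 0
    prev_r = -1
    for left in range(m):
        if r < left:
            r = left
            n_het = 0
        while r < m and n_het + het[r] <= max_het:
            n_het += het[r]
            r += 1
        if r > prev_r:  # not contained in the previous interval
            out.append((left, r))
            prev_r = r
        if het[left]:
            n_het -= 1
        if r == m:
            break
    return out


def roh_segments(
    panel_or_genotypes: HaplotypePanel | np.ndarray,
    marker_map: MarkerMap | None = None,
    animals: Sequence[str] | None = None,
    min_markers: int = 20,
    max_het: int = 1,
    min_length: int = 1_000_000,
) -> list[ROHSegment]:
    """Call ROH segments for every animal and chromosome.

    Accepts a phased panel or an unphased genotype matrix (N x M with
    codes 0 hom-ref / 1 het / 2 hom-alt / -1 missing) plus its marker
    map and animal identifiers.
    """
    if isinstance(panel_or_genotypes, HaplotypePanel):
        panel = panel_or_genotypes
        genotypes = panel.genotypes()
        marker_map = panel.markers
        animals = panel.animals
    else:
        genotypes = np.asarray(panel_or_genotypes)
        if marker_map is None or animals is None:
            raise ValueError(
                "marker_map and animals are required with a raw matrix"
            )

    # recode to 0 hom, 1 het, -1 missing
    calls = np.where(genotypes < 0, -1, np.where(genotypes == 1, 1, 0))
    out: list[ROHSegment] = []
    for chrom, lo, hi in marker_map.chrom_blocks():
        pos = marker_map.positions[lo:hi]
        for i, animal in enumerate(animals):
            c = calls[i, lo:hi]
            for left, right in _segments_for_calls(c, max_het):
                n = right - left
                start = int(pos[left])
                end = int(pos[right - 1])
                if n >= min_markers and end - start >= min_length:
                    out.append(
                        ROHSegment(
                            animal=animal,
                            chrom=chrom,
                            start=start,
                            end=end,
                            n_markers=n,
                            het_calls=int((c[left:right] == 1).sum()),
                        )
                    )
    return out
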