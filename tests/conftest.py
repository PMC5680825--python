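"""Shared fixtures: hand-built panels and a small simulated population."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mhscan import HaplotypePanel, MarkerMap, PedigreeTable
from mhscan.sim import LethalSpec, SimConfig, simulate


def make_marker_map(chroms, positions, names=None):
    n = len(positions)
    if names is None:
        names = [f"M{i}" for i in range(n)]
    return MarkerMap(
        names=np.array(names, dtype=object),
        chroms=np.array(chroms, dtype=object),
        positions=np.array(positions, dtype=np.int64),
        ref=np.array(["A"] * n, dtype=object),
        alt=np.array(["C"] * n, dtype=object),
    )


def make_panel(animals, haplotypes, chroms=None, positions=None,
               marker_map=None):
    haps = np.asarray(haplotypes, dtype=np.int8)
    if marker_map is None:
        m = haps.shape[2]
        if positions is None:
            positions = [100_000 * (i + 1) for i in range(m)]
        if chroms is None:
            chroms = ["1"] * m
        marker_map = make_marker_map(chroms, positions)
    return HaplotypePanel(animals=list(animals), haplotypes=haps,
                          markers=marker_map)


def make_pedigree(rows):
    """rows: (animal, sire, dam, line, sex) tuples."""
    return PedigreeTable(
        pd.DataFrame(rows, columns=["animal", "sire", "dam", "line", "sex"])
    )


@pytest.fixture(scope="session")
def lethal_sim():
    """Small population with one planted fully penetrant mid-gestation
    lethal at 15% founder-haplotype frequency on a window aligned with
    the scan grid."""
    cfg = SimConfig(
        seed=11,
        generations=1,
        founder_males=16,
        founder_females=200,
        markers_per_chromosome=120,
        n_chromosomes=1,
        chromosome_length=20_000_000,
        genotyped_fraction=0.95,
        lethals=(
            LethalSpec(chrom="1", start=10_000_000, end=11_000_000,
                       frequency=0.15, penetrance=1.0,
                       stage="mid_gestation"),
        ),
    )
    return simulate(cfg)
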