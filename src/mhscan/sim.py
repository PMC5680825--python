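"""Gene-drop simulator of a closed breeding line with embedded
recessive lethal haplotypes and litter phenotypes.

The simulator emulates the statistical structure of a commercial pig
nucleus line: a multi-generation pedigree of large litters, a biallelic
SNP map, founder chromosomes drawn intact from a small pool of distinct
haplotypes, Mendelian transmission with recombination, prenatal death
of fetuses homozygous for a planted lethal haplotype (early loss,
mid-gestation mummification, or stillbirth), baseline non-genetic
mummy/stillbirth rates, and selective genotyping of a subset of
offspring with trio enrichment.

Recombination follows a Haldane (no-interference) model: between
consecutive markers the gamete switches parental strand with
probability (1 - exp(-2d)) / 2 where d is the inter-marker distance in
Morgans; chromosomes assort independently.

All randomness flows from the single config seed, so identical configs
produce identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    MISSING,
    UNKNOWN_PARENT,
    HaplotypePanel,
    LitterRecord,
    MarkerMap,
    PedigreeTable,
    write_litters,
    write_pedigree,
    write_phased_vcf,
)

STAGES = ("early", "mid_gestation", "stillbirth")

# fetus fate codes
LIVE, EARLY, MUMMY, STILLBORN = 0, 1, 2, 3


@dataclass(frozen=True)
class LethalSpec:
    """One planted recessive lethal haplotype.

    The lethal is tied to a single founder-pool haplotype whose window
    allele string is forced to be unique in the pool, so a scan tag
    maps one-to-one onto it.  ``stage`` controls the phenotypic trace:
    ``early`` losses silently shrink the litter, ``mid_gestation``
    deaths are recorded as mummified piglets, ``stillbirth`` deaths
    enter TNB and NSB.
    """

    chrom: str
    start: int  # bp, half-open window [start, end)
    end: int
    frequency: float
    penetrance: float = 1.0
    stage: str = "mid_gestation"

    def __post_init__(self) -> None:
        if not 0 < self.frequency < 0.5:
            raise ValueError("lethal frequency must lie in (0, 0.5)")
        if not 0 <= self.penetrance <= 1:
            raise ValueError("penetrance must lie in [0, 1]")
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}")


@dataclass(frozen=True)
class SimConfig:
    """Full specification of the synthetic population.

    Defaults describe a closed dam line at desk scale: litters of ~16
    conceived fetuses (Poisson, truncated at one) so that total-born
    means land near 13-15 after baseline losses, a two-chromosome map
    of 250 markers per 30 Mb chromosome, and 90% of offspring
    genotyped with parents of genotyped offspring always included.
    """

    seed: int = 1
    generations: int = 2
    founder_males: int = 25
    founder_females: int = 150
    litters_per_sow: int = 1
    litter_size_mean: float = 16.0
    n_chromosomes: int = 2
    chromosome_length: int = 30_000_000
    markers_per_chromosome: int = 250
    morgans_per_chromosome: float = 1.0
    founder_pool_size: int = 30
    lethals: tuple[LethalSpec, ...] = ()
    base_mummy_rate: float = 0.02
    base_stillbirth_rate: float = 0.09
    genotyped_fraction: float = 0.9
    missing_rate: float = 0.0
    mum_in_tnb: bool = False
    trio_enrichment: bool = True
    line: str = "SIM"

    def __post_init__(self) -> None:
        for v in (self.base_mummy_rate, self.base_stillbirth_rate,
                  self.genotyped_fraction, self.missing_rate):
            if not 0 <= v <= 1:
                raise ValueError("rates and fractions must lie in [0, 1]")
        if self.founder_males < 1 or self.founder_females < 1:
            raise ValueError("need at least one founder of each sex")
        if self.founder_pool_size < 2 + len(self.lethals):
            raise ValueError("founder pool too small for the lethal specs")
        chroms = {str(c + 1) for c in range(self.n_chromosomes)}
        for spec in self.lethals:
            if spec.chrom not in chroms:
                raise ValueError(f"lethal chromosome {spec.chrom} not on map")
            if not 0 <= spec.start < spec.end <= self.chromosome_length:
                raise ValueError("lethal interval outside the chromosome")


@dataclass
class LitterTruth:
    litter: str
    sow: str
    boar: str
    conceived: int
    early_losses: int
    mummified: int
    stillborn: int

    @property
    def live(self) -> int:
        return (self.conceived - self.early_losses - self.mummified
                - self.stillborn)


@dataclass
class TruthSet:
    """Ground truth for parameter-recovery tests."""

    lethal_specs: tuple[LethalSpec, ...]
    lethal_labels: tuple[int, ...]  # pool label per lethal spec
    litters: list[LitterTruth]
    lethal_copies: dict[str, tuple[int, ...]]  # per live animal

    def carriers_of(self, spec_index: int) -> set[str]:
        return {
            a for a, c in self.lethal_copies.items() if c[spec_index] >= 1
        }


@dataclass
class SimResult:
    config: SimConfig
    marker_map: MarkerMap
    panel: HaplotypePanel
    pedigree: PedigreeTable
    litters: list[LitterRecord]
    truth: TruthSet
    pool_alleles: np.ndarray  # (pool size, n markers) int8

    def lethal_window_alleles(self, spec_index: int = 0) -> tuple[int, ...]:
        """Allele string of the planted lethal over its window markers."""
        spec = self.truth.lethal_specs[spec_index]
        label = self.truth.lethal_labels[spec_index]
        idx = _window_marker_idx(self.marker_map, spec)
        return tuple(int(a) for a in self.pool_alleles[label, idx])

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_phased_vcf(self.panel, outdir / "genotypes.vcf")
        write_pedigree(self.pedigree, outdir / "pedigree.tsv")
        write_litters(self.litters, outdir / "litters.tsv")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth_to_dict(self.truth), fh, indent=1)


def truth_to_dict(truth: TruthSet) -> dict:
    return {
        "lethal_specs": [asdict(s) for s in truth.lethal_specs],
        "lethal_labels": list(truth.lethal_labels),
        "litters": [asdict(t) for t in truth.litters],
        "lethal_copies": {a: list(c) for a, c in truth.lethal_copies.items()},
    }


# ---------------------------------------------------------------------------
# Map, founder pool, transmission
# ---------------------------------------------------------------------------


def _build_marker_map(config: SimConfig, rng: np.random.Generator) -> MarkerMap:
    names, chroms, positions = [], [], []
    for c in range(config.n_chromosomes):
        chrom = str(c + 1)
        pos = np.sort(
            rng.choice(
                np.arange(1, config.chromosome_length + 1),
                size=config.markers_per_chromosome,
                replace=False,
            )
        )
        for j, p in enumerate(pos):
            names.append(f"SNP_{chrom}_{j}")
            chroms.append(chrom)
            positions.append(int(p))
    n = len(names)
    return MarkerMap(
        names=np.array(names, dtype=object),
        chroms=np.array(chroms, dtype=object),
        positions=np.array(positions, dtype=np.int64),
        ref=np.array(["A"] * n, dtype=object),
        alt=np.array(["C"] * n, dtype=object),
    )


def _window_marker_idx(marker_map: MarkerMap, spec: LethalSpec) -> np.ndarray:
    on_chrom = np.asarray(marker_map.chroms, dtype=object) == spec.chrom
    pos = marker_map.positions
    return np.flatnonzero(on_chrom & (pos >= spec.start) & (pos < spec.end))


def _founder_pool(
    config: SimConfig, rng: np.random.Generator, marker_map: MarkerMap
) -> tuple[np.ndarray, tuple[int, ...], list[np.ndarray]]:
    """(pool allele matrix, lethal label per spec, lethal marker indices).

    Pool haplotype alleles are Bernoulli draws around per-marker base
    frequencies; the lethal labels claim the top of the pool and their
    window allele strings are forced to be unique within the pool.
    """
    K, M = config.founder_pool_size, len(marker_map)
    base_freq = rng.uniform(0.1, 0.9, size=M)
    pool = (rng.random((K, M)) < base_freq).astype(np.int8)

    labels = tuple(K - 1 - i for i in range(len(config.lethals)))
    lethal_idx: list[np.ndarray] = []
    for spec, label in zip(config.lethals, labels):
        idx = _window_marker_idx(marker_map, spec)
        if idx.size < 2:
            raise ValueError(
                f"lethal window {spec.chrom}:{spec.start}-{spec.end} covers "
                f"fewer than 2 markers"
            )
        lethal_idx.append(idx)
        target = pool[label, idx]
        for other in range(K):
            if other == label:
                continue
            guard = 0
            while np.array_equal(pool[other, idx], target):
                pool[other, idx] = (
                    rng.random(idx.size) < base_freq[idx]
                ).astype(np.int8)
                guard += 1
                if guard > 1000:
                    raise RuntimeError(
                        "could not make lethal window haplotype unique"
                    )
    return pool, labels, lethal_idx


def _founder_label_probs(
    config: SimConfig, chrom: str
) -> np.ndarray:
    """Pool-label sampling probabilities for one chromosome."""
    K = config.founder_pool_size
    probs = np.zeros(K)
    lethal_here = [
        (i, spec) for i, spec in enumerate(config.lethals)
        if spec.chrom == chrom
    ]
    labels = tuple(K - 1 - i for i in range(len(config.lethals)))
    lethal_mass = 0.0
    lethal_labels_here = []
    for i, spec in lethal_here:
        probs[labels[i]] = spec.frequency
        lethal_mass += spec.frequency
        lethal_labels_here.append(labels[i])
    rest = [k for k in range(K) if k not in labels]
    probs[rest] = (1.0 - lethal_mass) / len(rest)
    return probs


def _recomb_probs(marker_map: MarkerMap, config: SimConfig) -> np.ndarray:
    """Per-interval strand-switch probabilities (Haldane); the first
    marker of each chromosome switches with probability 0.5 so that
    chromosomes assort independently."""
    M = len(marker_map)
    r = np.empty(M)
    morgans_per_bp = config.morgans_per_chromosome / config.chromosome_length
    for chrom, lo, hi in marker_map.chrom_blocks():
        pos = marker_map.positions[lo:hi]
        r[lo] = 0.5
        if hi - lo > 1:
            d = np.diff(pos) * morgans_per_bp
            r[lo + 1: hi] = 0.5 * (1.0 - np.exp(-2.0 * d))
    return r


def _transmit(
    parent_labels: np.ndarray,  # (2, M)
    n_gametes: int,
    rvec: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample gametes (n, M) from a parent by Haldane recombination."""
    M = parent_labels.shape[1]
    switches = rng.random((n_gametes, M)) < rvec
    source = np.cumsum(switches, axis=1) % 2
    return np.take_along_axis(
        np.broadcast_to(parent_labels, (n_gametes, 2, M)),
        source[:, None, :],
        axis=1,
    )[:, 0, :]


def gene_drop_gametes(
    sire_labels: np.ndarray,
    dam_labels: np.ndarray,
    n_offspring: int,
    rvec: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Offspring label arrays (n, 2, M): paternal strand first."""
    pat = _transmit(sire_labels, n_offspring, rvec, rng)
    mat = _transmit(dam_labels, n_offspring, rvec, rng)
    return np.stack([pat, mat], axis=1)


def _lethal_hom_mask(
    labels: np.ndarray, idx: np.ndarray, label: int,
    pool: np.ndarray | None = None,
) -> np.ndarray:
    """Which of (n, 2, M) genomes are homozygous for a lethal haplotype
    across its whole window.

    With the founder pool allele matrix supplied, homozygosity is judged
    on the marker-allele string (identity by state): a recombinant that
    reconstitutes the lethal's allele string carries the haplotype.
    Without it, homozygosity falls back to founder-label identity.
    """
    win = labels[:, :, idx]
    if pool is None:
        return (win == label).all(axis=(1, 2))
    target = pool[label, idx]
    alleles = pool[win, idx[None, None, :]]
    return (alleles == target).all(axis=(1, 2))


def _lethal_copy_count(
    labels: np.ndarray, idx: np.ndarray, label: int
) -> np.ndarray:
    win = labels[:, :, idx]
    return (win == label).all(axis=2).sum(axis=1)


# ---------------------------------------------------------------------------
# Fates and litter accounting
# ---------------------------------------------------------------------------

_STAGE_FATE = {"early": EARLY, "mid_gestation": MUMMY, "stillbirth": STILLBORN}


def assign_fates(
    offspring_labels: np.ndarray,
    config: SimConfig,
    lethal_idx: Sequence[np.ndarray],
    lethal_labels: Sequence[int],
    rng: np.random.Generator,
    pool: np.ndarray | None = None,
) -> np.ndarray:
    """Per-fetus fate codes: lethal homozygotes die at their spec's
    stage with probability = penetrance; baseline mummy/stillbirth
    rates apply independently to the remaining fetuses."""
    n = offspring_labels.shape[0]
    fate = np.full(n, LIVE, dtype=np.int8)
    for spec, idx, label in zip(config.lethals, lethal_idx, lethal_labels):
        hom = _lethal_hom_mask(offspring_labels, idx, label, pool)
        dies = hom & (rng.random(n) < spec.penetrance) & (fate == LIVE)
        fate[dies] = _STAGE_FATE[spec.stage]
    u = rng.random(n)
    base_mum = (fate == LIVE) & (u < config.base_mummy_rate)
    base_still = (
        (fate == LIVE)
        & ~base_mum
        & (u < config.base_mummy_rate + config.base_stillbirth_rate)
    )
    fate[base_mum] = MUMMY
    fate[base_still] = STILLBORN
    return fate


def litter_record_from_truth(t: LitterTruth, config: SimConfig) -> LitterRecord:
    tnb = t.live + t.stillborn + (t.mummified if config.mum_in_tnb else 0)
    return LitterRecord(
        sow=t.sow,
        boar=t.boar,
        litter=t.litter,
        tnb=tnb,
        nba=t.live,
        nsb=t.stillborn,
        mum=t.mummified,
    )


def make_litters(truth: TruthSet, config: SimConfig) -> list[LitterRecord]:
    """Litter phenotype records consistent with the truth set under the
    configured TNB/MUM accounting convention."""
    return [litter_record_from_truth(t, config) for t in truth.litters]


def _truncated_poisson(lam: float, rng: np.random.Generator) -> int:
    x = int(rng.poisson(lam))
    while x == 0:
        x = int(rng.poisson(lam))
    return x


# ---------------------------------------------------------------------------
# Integrated driver
# ---------------------------------------------------------------------------


class _Registry:
    """Internal animal bookkeeping for one simulation run."""

    def __init__(self) -> None:
        self.ids: list[str] = []
        self.sex: list[str] = []
        self.sire: list[str] = []
        self.dam: list[str] = []
        self.labels: list[np.ndarray] = []  # (2, M) per animal

    def add(self, sex: str, sire: str, dam: str, labels: np.ndarray) -> int:
        i = len(self.ids)
        self.ids.append(f"A{i + 1:06d}")
        self.sex.append(sex)
        self.sire.append(sire)
        self.dam.append(dam)
        self.labels.append(labels)
        return i


def simulate(config: SimConfig) -> SimResult:
    """Run the full gene-drop simulation.

    Generations do not overlap; each generation's breeding sows and
    boars are sampled from the live-born animals of the previous one
    (founders for the first), mated at random within the line.  Fetuses
    that die prenatally never enter the pedigree, are never genotyped,
    and never breed; founders are sampled conditional on viability
    (a recessive lethal homozygote would not have survived to enter the
    breeding herd).
    """
    rng = np.random.default_rng(config.seed)
    marker_map = _build_marker_map(config, rng)
    pool, lethal_labels, lethal_idx = _founder_pool(config, rng, marker_map)
    rvec = _recomb_probs(marker_map, config)
    M = len(marker_map)
    blocks = marker_map.chrom_blocks()

    reg = _Registry()
    truth_litters: list[LitterTruth] = []
    lethal_copies: dict[str, tuple[int, ...]] = {}

    # founders -------------------------------------------------------------
    chrom_probs = {
        chrom: _founder_label_probs(config, chrom) for chrom, _, _ in blocks
    }
    founder_sexes = ["male"] * config.founder_males + (
        ["female"] * config.founder_females
    )
    males: list[int] = []
    females: list[int] = []
    for sex in founder_sexes:
        labels = np.empty((2, M), dtype=np.int16)
        for chrom, lo, hi in blocks:
            probs = chrom_probs[chrom]
            while True:
                pair = rng.choice(config.founder_pool_size, size=2, p=probs)
                viable = True
                for spec, label in zip(config.lethals, lethal_labels):
                    if spec.chrom != chrom:
                        continue
                    if (pair == label).all() and (
                        rng.random() < spec.penetrance
                    ):
                        viable = False
                        break
                if viable:
                    break
            labels[0, lo:hi] = pair[0]
            labels[1, lo:hi] = pair[1]
        i = reg.add(sex, UNKNOWN_PARENT, UNKNOWN_PARENT, labels)
        (males if sex == "male" else females).append(i)

    _record_lethal_copies(reg, range(len(reg.ids)), config, lethal_idx,
                          lethal_labels, lethal_copies)

    # generations ----------------------------------------------------------
    litter_no = 0
    for _g in range(config.generations):
        if not males or not females:
            raise RuntimeError("breeding pool went extinct")
        sow_pool = np.array(females)
        if len(sow_pool) > config.founder_females:
            sow_pool = rng.choice(
                sow_pool, size=config.founder_females, replace=False
            )
        boar_pool = np.array(males)
        if len(boar_pool) > config.founder_males:
            boar_pool = rng.choice(
                boar_pool, size=config.founder_males, replace=False
            )
        next_males: list[int] = []
        next_females: list[int] = []
        for sow in sow_pool:
            for _lit in range(config.litters_per_sow):
                boar = int(boar_pool[rng.integers(len(boar_pool))])
                n = _truncated_poisson(config.litter_size_mean, rng)
                kids = gene_drop_gametes(
                    reg.labels[boar], reg.labels[int(sow)], n, rvec, rng
                )
                fate = assign_fates(kids, config, lethal_idx, lethal_labels,
                                    rng, pool)
                kid_sex = np.where(rng.random(n) < 0.5, "male", "female")
                litter_no += 1
                lid = f"L{litter_no:05d}"
                truth_litters.append(
                    LitterTruth(
                        litter=lid,
                        sow=reg.ids[int(sow)],
                        boar=reg.ids[boar],
                        conceived=n,
                        early_losses=int((fate == EARLY).sum()),
                        mummified=int((fate == MUMMY).sum()),
                        stillborn=int((fate == STILLBORN).sum()),
                    )
                )
                new_idx = []
                for k in range(n):
                    if fate[k] != LIVE:
                        continue
                    i = reg.add(
                        str(kid_sex[k]),
                        reg.ids[boar],
                        reg.ids[int(sow)],
                        kids[k],
                    )
                    new_idx.append(i)
                    (next_males if kid_sex[k] == "male"
                     else next_females).append(i)
                _record_lethal_copies(reg, new_idx, config, lethal_idx,
                                      lethal_labels, lethal_copies)
        males, females = next_males, next_females

    truth = TruthSet(
        lethal_specs=config.lethals,
        lethal_labels=lethal_labels,
        litters=truth_litters,
        lethal_copies=lethal_copies,
    )
    litters = make_litters(truth, config)

    pedigree = PedigreeTable(
        pd.DataFrame(
            {
                "animal": reg.ids,
                "sire": reg.sire,
                "dam": reg.dam,
                "line": config.line,
                "sex": reg.sex,
            }
        )
    )

    panel = emit_markers(reg, pool, config, marker_map, rng)
    return SimResult(
        config=config,
        marker_map=marker_map,
        panel=panel,
        pedigree=pedigree,
        litters=litters,
        truth=truth,
        pool_alleles=pool,
    )


def _record_lethal_copies(
    reg: _Registry,
    indices,
    config: SimConfig,
    lethal_idx: Sequence[np.ndarray],
    lethal_labels: Sequence[int],
    out: dict[str, tuple[int, ...]],
) -> None:
    for i in indices:
        copies = tuple(
            int(_lethal_copy_count(reg.labels[i][None], idx, label)[0])
            for idx, label in zip(lethal_idx, lethal_labels)
        )
        out[reg.ids[i]] = copies


def emit_markers(
    reg: "_Registry",
    pool: np.ndarray,
    config: SimConfig,
    marker_map: MarkerMap,
    rng: np.random.Generator,
) -> HaplotypePanel:
    """Translate founder-label mosaics into a phased SNP panel for the
    genotyped subset of animals.

    Each animal is genotyped independently with probability
    ``genotyped_fraction``; with trio enrichment both parents of every
    genotyped animal are genotyped as well.  Missing calls (both
    alleles of a genotype) are injected at ``missing_rate``.
    """
    n = len(reg.ids)
    genotyped = rng.random(n) < config.genotyped_fraction
    if config.trio_enrichment:
        id_to_idx = {a: i for i, a in enumerate(reg.ids)}
        for i in np.flatnonzero(genotyped):
            for parent in (reg.sire[i], reg.dam[i]):
                if parent != UNKNOWN_PARENT:
                    genotyped[id_to_idx[parent]] = True

    idx = np.flatnonzero(genotyped)
    M = pool.shape[1]
    col = np.arange(M)
    haps = np.empty((idx.size, 2, M), dtype=np.int8)
    for out_i, i in enumerate(idx):
        lab = reg.labels[i]
        haps[out_i, 0] = pool[lab[0], col]
        haps[out_i, 1] = pool[lab[1], col]
    if config.missing_rate > 0:
        miss = rng.random((idx.size, M)) < config.missing_rate
        haps[np.broadcast_to(miss[:, None, :], haps.shape)] = MISSING
    return HaplotypePanel(
        animals=[reg.ids[i] for i in idx],
        haplotypes=haps,
        markers=marker_map,
    )


def panel_from_labels(
    labels: dict[str, np.ndarray],
    pool: np.ndarray,
    marker_map: MarkerMap,
    config: SimConfig,
    exclude: set[str] | None = None,
    seed: int | None = None,
) -> HaplotypePanel:
    """Phased panel from per-animal label arrays (standalone path).

    Subsamples animals to ``genotyped_fraction``, injects missing calls
    at ``missing_rate``, and never genotypes animals in *exclude*
    (e.g. prenatal deaths).
    """
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    exclude = exclude or set()
    candidates = [a for a in labels if a not in exclude]
    keep = [a for a in candidates
            if rng.random() < config.genotyped_fraction]
    M = pool.shape[1]
    col = np.arange(M)
    haps = np.empty((len(keep), 2, M), dtype=np.int8)
    for i, a in enumerate(keep):
        lab = labels[a]
        haps[i, 0] = pool[lab[0], col]
        haps[i, 1] = pool[lab[1], col]
    if config.missing_rate > 0:
        miss = rng.random((len(keep), M)) < config.missing_rate
        haps[np.broadcast_to(miss[:, None, :], haps.shape)] = MISSING
    return HaplotypePanel(animals=keep, haplotypes=haps, markers=marker_map)


# ---------------------------------------------------------------------------
# Standalone building blocks (modular use on external pedigrees)
# ---------------------------------------------------------------------------


@dataclass
class Mating:
    sire: str
    dam: str
    litter: str
    offspring: list[str]


def build_pedigree(config: SimConfig) -> tuple[PedigreeTable, list[Mating]]:
    """Neutral pedigree scaffold: the generational mating structure with
    every conceived fetus recorded, no lethality applied.

    Useful for testing transmission on its own; :func:`simulate` is the
    integrated driver in which prenatal deaths never breed.
    """
    rng = np.random.default_rng(config.seed)
    ids: list[str] = []
    sex: list[str] = []
    sire: list[str] = []
    dam: list[str] = []

    def add(s: str, si: str, da: str) -> str:
        a = f"A{len(ids) + 1:06d}"
        ids.append(a)
        sex.append(s)
        sire.append(si)
        dam.append(da)
        return a

    males = [add("male", UNKNOWN_PARENT, UNKNOWN_PARENT)
             for _ in range(config.founder_males)]
    females = [add("female", UNKNOWN_PARENT, UNKNOWN_PARENT)
               for _ in range(config.founder_females)]
    matings: list[Mating] = []
    litter_no = 0
    for _g in range(config.generations):
        sow_pool = (
            rng.choice(females, size=config.founder_females, replace=False)
            if len(females) > config.founder_females
            else list(females)
        )
        boar_pool = (
            rng.choice(males, size=config.founder_males, replace=False)
            if len(males) > config.founder_males
            else list(males)
        )
        next_m: list[str] = []
        next_f: list[str] = []
        for sow in sow_pool:
            for _lit in range(config.litters_per_sow):
                boar = boar_pool[int(rng.integers(len(boar_pool)))]
                n = _truncated_poisson(config.litter_size_mean, rng)
                litter_no += 1
                kids = []
                for _k in range(n):
                    s = "male" if rng.random() < 0.5 else "female"
                    a = add(s, str(boar), str(sow))
                    kids.append(a)
                    (next_m if s == "male" else next_f).append(a)
                matings.append(
                    Mating(str(boar), str(sow), f"L{litter_no:05d}", kids)
                )
        males, females = next_m, next_f
    ped = PedigreeTable(
        pd.DataFrame(
            {"animal": ids, "sire": sire, "dam": dam,
             "line": config.line, "sex": sex}
        )
    )
    return ped, matings


def gene_drop(
    pedigree: PedigreeTable, config: SimConfig
) -> tuple[dict[str, np.ndarray], MarkerMap, np.ndarray]:
    """Drop founder-pool labels through an arbitrary pedigree.

    Returns (per-animal label arrays, marker map, pool allele matrix).
    Animals with an unknown parent receive a founder-drawn gamete for
    that side.  Processing follows topological (parents-first) order.
    """
    rng = np.random.default_rng(config.seed)
    marker_map = _build_marker_map(config, rng)
    pool, lethal_labels, lethal_idx = _founder_pool(config, rng, marker_map)
    rvec = _recomb_probs(marker_map, config)
    M = len(marker_map)
    blocks = marker_map.chrom_blocks()
    chrom_probs = {
        chrom: _founder_label_probs(config, chrom) for chrom, _, _ in blocks
    }

    def founder_gamete() -> np.ndarray:
        g = np.empty(M, dtype=np.int16)
        for chrom, lo, hi in blocks:
            g[lo:hi] = rng.choice(
                config.founder_pool_size, p=chrom_probs[chrom]
            )
        return g

    order = _topological_order(pedigree)
    labels: dict[str, np.ndarray] = {}
    for animal in order:
        s, d = pedigree.parents_of(animal)
        pat = (
            _transmit(labels[s], 1, rvec, rng)[0].astype(np.int16)
            if s != UNKNOWN_PARENT and s in labels
            else founder_gamete()
        )
        mat = (
            _transmit(labels[d], 1, rvec, rng)[0].astype(np.int16)
            if d != UNKNOWN_PARENT and d in labels
            else founder_gamete()
        )
        labels[animal] = np.stack([pat, mat])
    return labels, marker_map, pool


def _topological_order(pedigree: PedigreeTable) -> list[str]:
    animals = list(pedigree.df["animal"])
    present = set(animals)
    done: set[str] = set()
    order: list[str] = []
    pending = animals
    while pending:
        rest = []
        for a in pending:
            s, d = pedigree.parents_of(a)
            if all(p == UNKNOWN_PARENT or p not in present or p in done
                   for p in (s, d)):
                order.append(a)
                done.add(a)
            else:
                rest.append(a)
        if len(rest) == len(pending):  # unreachable given acyclicity check
            raise RuntimeError("pedigree is not topologically sortable")
        pending = rest
    return order


def apply_lethality(
    matings: Sequence[Mating],
    labels: dict[str, np.ndarray],
    config: SimConfig,
    marker_map: MarkerMap,
    seed: int | None = None,
    pool: np.ndarray | None = None,
) -> tuple[TruthSet, set[str]]:
    """Apply lethal and baseline mortality to conceived fetuses.

    Returns the truth set and the set of dead fetus identifiers (these
    should be excluded from genotyping and breeding downstream).  With
    the founder pool allele matrix supplied, lethality is judged on the
    window allele string rather than founder-haplotype identity.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    lethal_labels = tuple(
        config.founder_pool_size - 1 - i for i in range(len(config.lethals))
    )
    lethal_idx = [_window_marker_idx(marker_map, s) for s in config.lethals]

    truth_litters: list[LitterTruth] = []
    dead: set[str] = set()
    lethal_copies: dict[str, tuple[int, ...]] = {}
    for m in matings:
        if m.offspring:
            kid_labels = np.stack([labels[a] for a in m.offspring])
            fate = assign_fates(kid_labels, config, lethal_idx, lethal_labels,
                                rng, pool)
        else:
            fate = np.zeros(0, dtype=np.int8)
        truth_litters.append(
            LitterTruth(
                litter=m.litter,
                sow=m.dam,
                boar=m.sire,
                conceived=len(m.offspring),
                early_losses=int((fate == EARLY).sum()),
                mummified=int((fate == MUMMY).sum()),
                stillborn=int((fate == STILLBORN).sum()),
            )
        )
        for a, f in zip(m.offspring, fate):
            if f != LIVE:
                dead.add(a)
            else:
                lethal_copies[a] = tuple(
                    int(_lethal_copy_count(labels[a][None], idx, lab)[0])
                    for idx, lab in zip(lethal_idx, lethal_labels)
                )
    truth = TruthSet(
        lethal_specs=config.lethals,
        lethal_labels=lethal_labels,
        litters=truth_litters,
        lethal_copies=lethal_copies,
    )
    return truth, dead
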