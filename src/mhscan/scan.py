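"""Sliding-window scan for haplotypes with missing or deficit homozygosity.

The scan slides windows of 0.5-4 Mb (overlapping by half their length)
along each chromosome, tabulates phased haplotypes per window, and tests
whether each sufficiently common haplotype is observed in homozygous
state as often as Mendelian transmission through genotyped parent-
offspring trios predicts.  A recessive lethal shows up as a haplotype
whose carriers are abundant but whose homozygotes are missing (MH) or
strongly depleted (DH).

The expected homozygote count is accumulated over trio offspring whose
sire and dam both carry the haplotype: each such offspring contributes
(c_sire/2) * (c_dam/2), the probability that both parents transmit a
copy, where c is the parental copy number.  With exclusively
heterozygous carrier parents this is the classical n/4.  The observed
count is taken over *all* phased animals, not only trio offspring, so
the binomial test statistic is clamped to k = min(O, n).

The significance test is an exact two-sided binomial test by the
point-probability method: the p-value sums Pr(j | n, p) over all
outcomes j no more probable than the observed k (with relative
tolerance 1e-7), evaluated in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .io import HaplotypePanel, MarkerMap, PedigreeTable, UNKNOWN_PARENT

UNDETERMINED = -1

MH = "MH"
DH = "DH"
NOT_SIGNIFICANT = "not_significant"
UNTESTABLE = "untestable"


# ---------------------------------------------------------------------------
# Parameters and result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScanParams:
    """Scan configuration.

    window_sizes : window lengths in bp (default 0.5/1/2/4 Mb).
    step_factor : slide step as a fraction of the window size.
    min_freq : haplotypes retained need frequency strictly above this.
    mh_alpha : significance threshold for missing homozygosity (O = 0).
    dh_alpha : significance threshold for deficit homozygosity (O > 0).
    null_p : optional fixed binomial null probability; by default the
        null is E/n from the trio expectation (0.25 when every carrier
        parent is heterozygous).
    """

    window_sizes: tuple[int, ...] = (500_000, 1_000_000, 2_000_000, 4_000_000)
    step_factor: float = 0.5
    min_freq: float = 0.005
    mh_alpha: float = 5e-3
    dh_alpha: float = 5e-6
    null_p: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.mh_alpha < 1 or not 0 < self.dh_alpha < 1:
            raise ValueError("significance thresholds must lie in (0, 1)")
        if not 0 <= self.min_freq < 1:
            raise ValueError("min_freq must lie in [0, 1)")


@dataclass(frozen=True)
class GenomicWindow:
    """Half-open genomic interval [start, end) with its marker span."""

    chrom: str
    start: int
    end: int
    size: int
    i0: int  # first marker index (into the panel's marker map)
    i1: int  # one past the last marker index

    @property
    def n_markers(self) -> int:
        return self.i1 - self.i0

    def overlaps(self, other: "GenomicWindow") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True, eq=False)
class HaplotypeTag:
    """One distinct haplotype (allele string) within a window.

    Frequency is counted over the chromosomes of animals whose phase is
    complete in the window; animals with any missing allele there are
    excluded from the denominator and from carrier/homozygote sets.
    """

    window: GenomicWindow
    alleles: tuple[int, ...]
    frequency: float
    carrier_idx: np.ndarray  # panel indices of 1-copy animals
    hom_idx: np.ndarray  # panel indices of 2-copy animals
    complete_idx: np.ndarray  # panel indices with complete phase in window

    def carriers(self, panel: HaplotypePanel) -> frozenset[str]:
        return frozenset(panel.animals[i] for i in self.carrier_idx)

    def homozygotes(self, panel: HaplotypePanel) -> frozenset[str]:
        return frozenset(panel.animals[i] for i in self.hom_idx)

    def copies_vector(self, n_animals: int) -> np.ndarray:
        """Per-animal copy count; UNDETERMINED for incomplete phase."""
        copies = np.full(n_animals, UNDETERMINED, dtype=np.int8)
        copies[self.complete_idx] = 0
        copies[self.carrier_idx] = 1
        copies[self.hom_idx] = 2
        return copies


@dataclass
class TrioSet:
    """Offspring with both parents genotyped and phased in the panel."""

    trios: list[tuple[str, str, str]]  # (offspring, sire, dam)
    off_idx: np.ndarray
    sire_idx: np.ndarray
    dam_idx: np.ndarray

    def __len__(self) -> int:
        return len(self.trios)


@dataclass
class ScanRecord:
    """Scan result for a single haplotype, mirroring one table row."""

    window: GenomicWindow
    alleles: tuple[int, ...]
    frequency: float
    expected: float
    observed: int
    n_progeny: int
    p_value: float
    cxc_matings: int
    het_carriers: int
    het_percent: float
    classification: str
    label: str | None = None
    population: str | None = None
    note: str = ""

    @property
    def testable(self) -> bool:
        return self.classification != UNTESTABLE

    @property
    def significant(self) -> bool:
        return self.classification in (MH, DH)


# ---------------------------------------------------------------------------
# Window enumeration and haplotype tabulation
# ---------------------------------------------------------------------------


def enumerate_windows(
    marker_map: MarkerMap, params: ScanParams
) -> list[GenomicWindow]:
    """Grid of overlapping windows per chromosome and size class.

    For each size w the grid is anchored at coordinate 0 and advances by
    ``step_factor * w`` while the window start lies before the last
    marker of the chromosome.  Windows covering fewer than two markers
    are skipped.
    """
    windows: list[GenomicWindow] = []
    for chrom, lo, hi in marker_map.chrom_blocks():
        pos = marker_map.positions[lo:hi]
        last = int(pos[-1])
        for w in params.window_sizes:
            step = int(round(w * params.step_factor))
            if step <= 0:
                raise ValueError("window step must be positive")
            start = 0
            while start < last:
                end = start + w
                i0 = lo + int(np.searchsorted(pos, start, side="left"))
                i1 = lo + int(np.searchsorted(pos, end, side="left"))
                if i1 - i0 >= 2:
                    windows.append(
                        GenomicWindow(chrom, start, end, w, i0, i1)
                    )
                start += step
    return windows


def window_from_coords(
    marker_map: MarkerMap, chrom: str, start: int, end: int
) -> GenomicWindow:
    """Reconstruct a window (with its marker span) from coordinates."""
    for c, lo, hi in marker_map.chrom_blocks():
        if c == chrom:
            pos = marker_map.positions[lo:hi]
            i0 = lo + int(np.searchsorted(pos, start, side="left"))
            i1 = lo + int(np.searchsorted(pos, end, side="left"))
            return GenomicWindow(chrom, start, end, end - start, i0, i1)
    raise KeyError(f"chromosome {chrom!r} not in marker map")


def window_haplotypes(
    panel: HaplotypePanel, window: GenomicWindow, min_freq: float = 0.005
) -> list[HaplotypeTag]:
    """Distinct haplotypes in a window with frequency strictly > min_freq.

    Returned sorted by descending frequency (ties broken by allele
    string) so the ordering is deterministic.
    """
    H = panel.haplotypes[:, :, window.i0: window.i1]
    complete = (H >= 0).all(axis=(1, 2))
    complete_idx = np.flatnonzero(complete)
    if complete_idx.size == 0:
        return []
    rows = np.ascontiguousarray(
        H[complete_idx].reshape(2 * complete_idx.size, window.n_markers)
    )
    # unique on a byte view: one memcmp per row instead of a column-wise
    # lexsort, which dominates the scan otherwise
    void = rows.view(
        np.dtype((np.void, rows.shape[1] * rows.itemsize))
    ).ravel()
    _, first_idx, inv, counts = np.unique(
        void, return_index=True, return_inverse=True, return_counts=True
    )
    uniq = rows[first_idx]
    inv = inv.reshape(complete_idx.size, 2)
    denom = 2.0 * complete_idx.size
    order = np.argsort(-counts, kind="stable")  # unique() is lex-sorted
    tags: list[HaplotypeTag] = []
    for t in order:
        freq = counts[t] / denom
        if not freq > min_freq:
            continue
        ncopies = (inv == t).sum(axis=1)
        tags.append(
            HaplotypeTag(
                window=window,
                alleles=tuple(int(a) for a in uniq[t]),
                frequency=float(freq),
                carrier_idx=complete_idx[ncopies == 1],
                hom_idx=complete_idx[ncopies == 2],
                complete_idx=complete_idx,
            )
        )
    return tags


def diplotype_state(
    panel: HaplotypePanel, animal: str, tag: HaplotypeTag
) -> int:
    """Copy count (0/1/2) of *tag* in *animal*; UNDETERMINED if the
    animal has missing phase anywhere in the window.

    Computed directly from the allele arrays, independently of the
    bookkeeping stored on the tag.
    """
    i = panel.animal_index(animal)
    w = tag.window
    h = panel.haplotypes[i, :, w.i0: w.i1]
    if (h < 0).any():
        return UNDETERMINED
    target = np.asarray(tag.alleles, dtype=h.dtype)
    return int((h == target).all(axis=1).sum())


def diplotype_states(
    panel: HaplotypePanel, window: GenomicWindow, alleles: Sequence[int]
) -> np.ndarray:
    """Vectorized copy counts of an allele string for every panel
    animal; UNDETERMINED where phase is incomplete in the window."""
    H = panel.haplotypes[:, :, window.i0: window.i1]
    target = np.asarray(alleles, dtype=H.dtype)
    if target.shape != (window.n_markers,):
        raise ValueError("allele string length does not match window")
    eq = (H == target).all(axis=2)
    copies = eq.sum(axis=1).astype(np.int8)
    copies[(H < 0).any(axis=(1, 2))] = UNDETERMINED
    return copies


# ---------------------------------------------------------------------------
# Trios and expectations
# ---------------------------------------------------------------------------


def collect_trios(pedigree: PedigreeTable, panel: HaplotypePanel) -> TrioSet:
    """All (offspring, sire, dam) with every member present in the panel."""
    trios: list[tuple[str, str, str]] = []
    for row in pedigree.df.itertuples():
        if (
            row.animal in panel
            and row.sire != UNKNOWN_PARENT
            and row.dam != UNKNOWN_PARENT
            and row.sire in panel
            and row.dam in panel
        ):
            trios.append((row.animal, row.sire, row.dam))
    off = np.array([panel.animal_index(t[0]) for t in trios], dtype=np.int64)
    sire = np.array([panel.animal_index(t[1]) for t in trios], dtype=np.int64)
    dam = np.array([panel.animal_index(t[2]) for t in trios], dtype=np.int64)
    return TrioSet(trios=trios, off_idx=off, sire_idx=sire, dam_idx=dam)


def _tag_copies(
    tag: HaplotypeTag, panel: HaplotypePanel, copies: np.ndarray | None
) -> np.ndarray:
    if copies is None:
        return tag.copies_vector(panel.n_animals)
    return copies


def _cxc_mask(
    tag: HaplotypeTag,
    trios: TrioSet,
    panel: HaplotypePanel,
    copies: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    """(copies vector, trio mask for carrier x carrier offspring).

    An offspring counts only when both parents carry >= 1 determined
    copy and its own diplotype in the window is determined.
    """
    c = _tag_copies(tag, panel, copies)
    if len(trios) == 0:
        return c, np.zeros(0, dtype=bool)
    cs = c[trios.sire_idx]
    cd = c[trios.dam_idx]
    co = c[trios.off_idx]
    mask = (cs >= 1) & (cd >= 1) & (co >= 0)
    return c, mask


def expected_homozygotes(
    tag: HaplotypeTag,
    trios: TrioSet,
    panel: HaplotypePanel,
    copies: np.ndarray | None = None,
) -> tuple[float, int, int]:
    """(E, n, carrier-mating count) from genotyped trios.

    E sums the per-offspring transmission product (c_sire/2)(c_dam/2)
    over offspring of carrier x carrier trios; n is the number of such
    genotyped offspring and the mating count is the number of distinct
    (sire, dam) pairs among them.
    """
    c, mask = _cxc_mask(tag, trios, panel, copies)
    if not mask.any():
        return 0.0, 0, 0
    cs = c[trios.sire_idx[mask]].astype(float)
    cd = c[trios.dam_idx[mask]].astype(float)
    e = float(np.sum((cs / 2.0) * (cd / 2.0)))
    pairs = set(
        zip(trios.sire_idx[mask].tolist(), trios.dam_idx[mask].tolist())
    )
    return e, int(mask.sum()), len(pairs)


def observed_homozygotes(
    tag: HaplotypeTag,
    panel: HaplotypePanel,
    copies: np.ndarray | None = None,
) -> int:
    """Homozygote count over all phased animals in the panel."""
    c = _tag_copies(tag, panel, copies)
    return int((c == 2).sum())


def het_carrier_fraction(
    tag: HaplotypeTag,
    trios: TrioSet,
    panel: HaplotypePanel,
    copies: np.ndarray | None = None,
) -> tuple[int, float]:
    """Heterozygous offspring among genotyped carrier-mating progeny.

    Returns (count, percent); percent is NaN when there are no such
    progeny.  Under Hardy-Weinberg the percentage is 50; a fully lethal
    haplotype pushes it towards 66.7 because homozygotes are missing.
    """
    c, mask = _cxc_mask(tag, trios, panel, copies)
    n = int(mask.sum())
    if n == 0:
        return 0, float("nan")
    het = int((c[trios.off_idx[mask]] == 1).sum())
    return het, 100.0 * het / n


# ---------------------------------------------------------------------------
# Exact binomial test
# ---------------------------------------------------------------------------

_POINT_RTOL = 1e-7


def binom_two_sided(k: int, n: int, p: float) -> float:
    """Two-sided exact binomial p-value by the point-probability method.

    Sums Pr(j | n, p) over all j whose point probability does not exceed
    Pr(k | n, p) * (1 + 1e-7).  Evaluated in log space; the result is
    clamped to at most 1.
    """
    if not (isinstance(k, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise TypeError("k and n must be integers")
    if n < 0 or not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 < p < 1.0:
        raise ValueError(f"require 0 < p < 1, got p={p}")
    j = np.arange(n + 1)
    logpmf = (
        gammaln(n + 1)
        - gammaln(j + 1)
        - gammaln(n - j + 1)
        + j * np.log(p)
        + (n - j) * np.log1p(-p)
    )
    keep = logpmf[logpmf <= logpmf[k] + np.log1p(_POINT_RTOL)]
    m = keep.max()
    total = m + np.log(np.exp(keep - m).sum())
    return float(min(1.0, np.exp(total)))


# ---------------------------------------------------------------------------
# Per-haplotype test and classification
# ---------------------------------------------------------------------------


def test_haplotype(
    tag: HaplotypeTag,
    trios: TrioSet,
    panel: HaplotypePanel,
    params: ScanParams,
    copies: np.ndarray | None = None,
) -> ScanRecord:
    """Full per-haplotype result: expectation, observation, test, class.

    The binomial null success probability is E/n (0.25 when all carrier
    parents are heterozygous) unless overridden in *params*.  Records
    with no carrier-mating progeny (n = 0) are flagged untestable.
    Homozygotes found outside trio progeny can push O above n; the test
    then uses k = min(O, n) and the record carries a note.
    """
    c = _tag_copies(tag, panel, copies)
    e, n, cxc = expected_homozygotes(tag, trios, panel, copies=c)
    o = observed_homozygotes(tag, panel, copies=c)
    het, het_pct = het_carrier_fraction(tag, trios, panel, copies=c)

    note = ""
    if n == 0:
        record = ScanRecord(
            window=tag.window,
            alleles=tag.alleles,
            frequency=tag.frequency,
            expected=e,
            observed=o,
            n_progeny=0,
            p_value=float("nan"),
            cxc_matings=cxc,
            het_carriers=het,
            het_percent=het_pct,
            classification=UNTESTABLE,
        )
        return record

    p_null = params.null_p if params.null_p is not None else e / n
    k = min(o, n)
    if o > n:
        note = f"{o - n} homozygotes outside genotyped trio progeny"
    if p_null >= 1.0:
        # all carrier parents homozygous: the only outcome is k = n
        p_value = 1.0
    else:
        p_value = binom_two_sided(k, n, p_null)
    record = ScanRecord(
        window=tag.window,
        alleles=tag.alleles,
        frequency=tag.frequency,
        expected=e,
        observed=o,
        n_progeny=n,
        p_value=p_value,
        cxc_matings=cxc,
        het_carriers=het,
        het_percent=het_pct,
        classification=NOT_SIGNIFICANT,
        note=note,
    )
    record.classification = classify(record, params)
    return record


def classify(record: ScanRecord, params: ScanParams) -> str:
    """MH / DH / not-significant thresholds.

    MH requires zero observed homozygotes and p < mh_alpha; DH requires
    at least one observed homozygote, a deficit (O < E), and
    p < dh_alpha.  The deficit condition keeps the two-sided test from
    flagging homozygote excess, which is outside the scan's target (and
    arises spuriously because O is counted panel-wide while E covers
    trio offspring only).
    """
    if record.classification == UNTESTABLE or not np.isfinite(record.p_value):
        return UNTESTABLE
    if record.observed == 0 and record.p_value < params.mh_alpha:
        return MH
    if (
        0 < record.observed < record.expected
        and record.p_value < params.dh_alpha
    ):
        return DH
    return NOT_SIGNIFICANT


# ---------------------------------------------------------------------------
# Whole-panel driver
# ---------------------------------------------------------------------------


def scan_panel(
    panel: HaplotypePanel,
    pedigree: PedigreeTable,
    params: ScanParams = ScanParams(),
    population: str | None = None,
) -> list[ScanRecord]:
    """Run the full scan: every window, every retained haplotype."""
    trios = collect_trios(pedigree, panel)
    records: list[ScanRecord] = []
    for window in enumerate_windows(panel.markers, params):
        for tag in window_haplotypes(panel, window, params.min_freq):
            copies = tag.copies_vector(panel.n_animals)
            rec = test_haplotype(tag, trios, panel, params, copies=copies)
            rec.population = population
            records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Locus collapsing and cross-population sharing
# ---------------------------------------------------------------------------


def collapse_loci(records: Sequence[ScanRecord]) -> list[ScanRecord]:
    """One haplotype per locus: group significant windows by transitive
    base-pair overlap on each chromosome and keep the record with the
    lowest p-value (ties: smaller window, then leftmost start).
    """
    significant = [r for r in records if r.significant]
    by_chrom: dict[str, list[ScanRecord]] = {}
    for r in significant:
        by_chrom.setdefault(r.window.chrom, []).append(r)

    selected: list[ScanRecord] = []
    for chrom in sorted(by_chrom):
        recs = sorted(by_chrom[chrom], key=lambda r: (r.window.start,
                                                      r.window.end))
        group: list[ScanRecord] = []
        max_end = None
        for r in recs:
            if max_end is not None and r.window.start < max_end:
                group.append(r)
                max_end = max(max_end, r.window.end)
            else:
                if group:
                    selected.append(_best_of_locus(group))
                group = [r]
                max_end = r.window.end
        if group:
            selected.append(_best_of_locus(group))
    return selected


def _best_of_locus(group: list[ScanRecord]) -> ScanRecord:
    return min(
        group,
        key=lambda r: (r.p_value, r.window.end - r.window.start,
                       r.window.start),
    )


def shared_loci(
    per_population_records: Sequence[Sequence[ScanRecord]],
    labels: Sequence[str] | None = None,
) -> list[tuple[tuple[str, int, int], frozenset[str]]]:
    """Maximal regions where significant loci of >= 2 populations overlap.

    Returns ((chromosome, start, end), population labels) with half-open
    base-pair intervals.
    """
    if len(per_population_records) < 2:
        raise ValueError("shared_loci requires at least two populations")
    if labels is None:
        labels = [
            (recs[0].population if recs and recs[0].population else f"pop{i}")
            for i, recs in enumerate(per_population_records)
        ]
    # per chromosome: list of (start, end, label)
    intervals: dict[str, list[tuple[int, int, str]]] = {}
    for lab, recs in zip(labels, per_population_records):
        for r in recs:
            if r.significant:
                w = r.window
                intervals.setdefault(w.chrom, []).append((w.start, w.end, lab))

    regions: list[tuple[tuple[str, int, int], frozenset[str]]] = []
    for chrom in sorted(intervals):
        ivs = intervals[chrom]
        bounds = sorted({b for s, e, _ in ivs for b in (s, e)})
        run_start = None
        run_end = None
        run_labels: set[str] = set()
        for s, e in zip(bounds[:-1], bounds[1:]):
            covering = {lab for (a, b, lab) in ivs if a <= s and e <= b}
            if len(covering) >= 2:
                if run_start is None:
                    run_start = s
                    run_labels = set()
                run_end = e
                run_labels |= covering
            else:
                if run_start is not None:
                    regions.append(
                        ((chrom, run_start, run_end), frozenset(run_labels))
                    )
                    run_start = None
        if run_start is not None:
            regions.append(((chrom, run_start, run_end), frozenset(run_labels)))
    return regions
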