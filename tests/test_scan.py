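"""Window enumeration, haplotype tabulation, trio expectation, exact
binomial test, classification, locus collapsing and sharing."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binomtest

from conftest import make_marker_map, make_panel, make_pedigree
from mhscan import (
    ScanParams,
    binom_two_sided,
    classify,
    collapse_loci,
    collect_trios,
    diplotype_state,
    diplotype_states,
    enumerate_windows,
    expected_homozygotes,
    het_carrier_fraction,
    observed_homozygotes,
    scan_panel,
    shared_loci,
    window_haplotypes,
)
from mhscan import test_haplotype as score_haplotype
from mhscan.io import MISSING, UNKNOWN_PARENT
from mhscan.scan import (
    DH,
    MH,
    NOT_SIGNIFICANT,
    UNDETERMINED,
    UNTESTABLE,
    GenomicWindow,
    ScanRecord,
    window_from_coords,
)
from oracles import (
    binom_two_sided_oracle,
    expected_homozygotes_oracle,
    group_overlapping_oracle,
)

# ---------------------------------------------------------------------------
# Window enumeration
# ---------------------------------------------------------------------------


def test_window_grid_anchored_at_zero():
    # markers every 100 kb from 50 kb to 2.55 Mb; 1 Mb windows slide by
    # 0.5 Mb; the window starting at 2.5 Mb covers a single marker and
    # is skipped
    positions = list(range(50_000, 2_560_000, 100_000))
    mm = make_marker_map(["1"] * len(positions), positions)
    wins = enumerate_windows(mm, ScanParams(window_sizes=(1_000_000,)))
    assert [(w.start, w.end) for w in wins] == [
        (0, 1_000_000),
        (500_000, 1_500_000),
        (1_000_000, 2_000_000),
        (1_500_000, 2_500_000),
        (2_000_000, 3_000_000),
    ]
    assert all(w.n_markers >= 2 for w in wins)
    # the 0-1 Mb window covers the ten markers at 50k..950k
    assert (wins[0].i0, wins[0].i1) == (0, 10)


def test_window_grid_matches_brute_force_on_random_maps():
    rng = np.random.default_rng(21)
    params = ScanParams(window_sizes=(500_000, 2_000_000))
    for _ in range(20):
        positions = np.sort(
            rng.choice(np.arange(1, 8_000_000), size=40, replace=False)
        )
        mm = make_marker_map(["1"] * 40, positions.tolist())
        wins = enumerate_windows(mm, params)
        expect = []
        for w in params.window_sizes:
            start = 0
            while start < positions[-1]:
                covered = [p for p in positions if start <= p < start + w]
                if len(covered) >= 2:
                    expect.append((start, start + w, w))
                start += w // 2
        got = sorted((w.start, w.end, w.size) for w in wins)
        assert got == sorted(expect)


def test_consecutive_windows_overlap_by_half():
    positions = list(range(10_000, 10_000_000, 50_000))
    mm = make_marker_map(["1"] * len(positions), positions)
    for size in (500_000, 1_000_000, 4_000_000):
        wins = [
            w for w in enumerate_windows(mm, ScanParams(window_sizes=(size,)))
        ]
        for a, b in zip(wins, wins[1:]):
            assert b.start - a.start == size // 2
            assert a.overlaps(b)


def test_windows_respect_chromosome_boundaries():
    mm = make_marker_map(
        ["1", "1", "2", "2"], [100_000, 400_000, 100_000, 400_000]
    )
    wins = enumerate_windows(mm, ScanParams(window_sizes=(500_000,)))
    assert [(w.chrom, w.i0, w.i1) for w in wins] == [
        ("1", 0, 2), ("2", 2, 4)
    ]


def test_window_from_coords_round_trip():
    positions = list(range(50_000, 3_000_000, 100_000))
    mm = make_marker_map(["1"] * len(positions), positions)
    for w in enumerate_windows(mm, ScanParams()):
        w2 = window_from_coords(mm, w.chrom, w.start, w.end)
        assert (w2.i0, w2.i1) == (w.i0, w.i1)
    with pytest.raises(KeyError):
        window_from_coords(mm, "9", 0, 1_000_000)


# ---------------------------------------------------------------------------
# Haplotype tabulation within a window
# ---------------------------------------------------------------------------


def two_marker_window(panel):
    return window_from_coords(panel.markers, "1", 100_000, 300_000)


def test_single_haplotype_frequency_one():
    h = np.zeros((4, 2, 2), dtype=np.int8)
    panel = make_panel(["A", "B", "C", "D"], h)
    tags = window_haplotypes(panel, two_marker_window(panel), min_freq=0.0)
    assert len(tags) == 1
    assert tags[0].frequency == 1.0
    assert tags[0].alleles == (0, 0)
    assert sorted(tags[0].hom_idx) == [0, 1, 2, 3]
    assert len(tags[0].carrier_idx) == 0


def test_min_freq_is_strict():
    # 10 animals = 20 chromosomes; one chromosome carries a unique
    # haplotype: frequency exactly 0.05
    h = np.zeros((10, 2, 2), dtype=np.int8)
    h[0, 0] = (1, 1)
    panel = make_panel([f"A{i}" for i in range(10)], h)
    win = two_marker_window(panel)
    freqs = {t.alleles: t.frequency for t in
             window_haplotypes(panel, win, min_freq=0.04)}
    assert freqs[(1, 1)] == pytest.approx(0.05)
    assert (1, 1) not in {
        t.alleles for t in window_haplotypes(panel, win, min_freq=0.05)
    }


def test_missing_phase_excluded_from_denominator():
    h = np.zeros((4, 2, 2), dtype=np.int8)
    h[0, 0, 0] = MISSING  # animal 0 incomplete in the window
    h[1, 0] = (1, 1)
    panel = make_panel(["A", "B", "C", "D"], h)
    tags = window_haplotypes(panel, two_marker_window(panel), min_freq=0.0)
    by_alleles = {t.alleles: t for t in tags}
    # 3 complete animals -> 6 chromosomes, one of them (1,1)
    assert by_alleles[(1, 1)].frequency == pytest.approx(1 / 6)
    assert 0 not in by_alleles[(1, 1)].complete_idx
    assert sorted(by_alleles[(1, 1)].carrier_idx) == [1]


def test_planted_frequency_recovered():
    rng = np.random.default_rng(3)
    n = 1000
    h = np.zeros((n, 2, 2), dtype=np.int8)
    draws = rng.random((n, 2)) < 0.3
    h[draws] = 1  # each chromosome is (1,1) w.p. 0.3, else (0,0)
    panel = make_panel([f"A{i}" for i in range(n)], h)
    tags = window_haplotypes(panel, two_marker_window(panel))
    freq = {t.alleles: t.frequency for t in tags}[(1, 1)]
    assert freq == pytest.approx(0.3, abs=0.02)


def test_window_haplotypes_bookkeeping_matches_diplotype_states():
    rng = np.random.default_rng(17)
    n, m = 80, 6
    h = rng.integers(0, 2, size=(n, 2, m)).astype(np.int8)
    h[rng.random((n, 2, m)) < 0.05] = MISSING
    panel = make_panel([f"A{i}" for i in range(n)], h)
    win = window_from_coords(panel.markers, "1", 100_000, 500_000)
    for tag in window_haplotypes(panel, win, min_freq=0.0):
        copies = diplotype_states(panel, win, tag.alleles)
        np.testing.assert_array_equal(
            copies, tag.copies_vector(panel.n_animals)
        )
        for i, animal in enumerate(panel.animals):
            assert diplotype_state(panel, animal, tag) == copies[i]


# ---------------------------------------------------------------------------
# Trios and the expectation
# ---------------------------------------------------------------------------

LETHAL = (1, 1)


def build_population(parent_pairs, offspring):
    """Panel + pedigree from copy-number specs.

    parent_pairs: list of (sire_copies, dam_copies); offspring: list of
    (pair_index, copies) with copies None for undetermined phase.  The
    scored window holds markers 1 and 2 (positions 1.05 and 1.15 Mb).
    """

    def hap(c):
        h = np.zeros((2, 4), dtype=np.int8)
        if c is None:
            h[0, 1] = MISSING
            return h
        if c >= 1:
            h[0, 1:3] = 1
        if c == 2:
            h[1, 1:3] = 1
        return h

    animals, haps, rows = [], [], []
    for i, (cs, cd) in enumerate(parent_pairs):
        for name, c, sex in ((f"S{i}", cs, "male"), (f"D{i}", cd, "female")):
            animals.append(name)
            haps.append(hap(c))
            rows.append((name, UNKNOWN_PARENT, UNKNOWN_PARENT, "L", sex))
    for k, (pair, c) in enumerate(offspring):
        name = f"O{k}"
        animals.append(name)
        haps.append(hap(c))
        rows.append((name, f"S{pair}", f"D{pair}", "L", "female"))
    panel = make_panel(
        animals, np.stack(haps),
        positions=[100_000, 1_050_000, 1_150_000, 2_500_000],
    )
    pedigree = make_pedigree(rows)
    win = window_from_coords(panel.markers, "1", 1_000_000, 2_000_000)
    tag = next(
        t for t in window_haplotypes(panel, win, min_freq=0.0)
        if t.alleles == LETHAL
    )
    return panel, pedigree, tag


def test_collect_trios_requires_all_members_genotyped():
    panel, pedigree, _ = build_population([(1, 1)], [(0, 1)])
    # add a pedigree-only offspring whose dam is not in the panel
    pedigree.df.loc[len(pedigree.df)] = ["O9", "S0", "DX", "L", "male"]
    pedigree.df.loc[len(pedigree.df)] = ["DX", "0", "0", "L", "female"]
    trios = collect_trios(pedigree.__class__(pedigree.df), panel)
    assert trios.trios == [("O0", "S0", "D0")]


def test_expectation_all_het_pairs_is_quarter_per_offspring():
    # 75 heterozygous carrier pairs with one offspring each: E = 75/4
    pairs = [(1, 1)] * 75
    offspring = [(i, 1) for i in range(75)]
    panel, pedigree, tag = build_population(pairs, offspring)
    trios = collect_trios(pedigree, panel)
    e, n, matings = expected_homozygotes(tag, trios, panel)
    assert (e, n, matings) == (18.75, 75, 75)


def test_expectation_homozygous_parent_contributes_half():
    panel, pedigree, tag = build_population([(2, 1)], [(0, 1)])
    trios = collect_trios(pedigree, panel)
    e, n, matings = expected_homozygotes(tag, trios, panel)
    assert (e, n, matings) == (0.5, 1, 1)


def test_expectation_skips_noncarrier_and_undetermined():
    pairs = [(1, 1), (1, 0), (1, 1)]
    offspring = [(0, 1), (1, 1), (2, None), (0, 0)]
    panel, pedigree, tag = build_population(pairs, offspring)
    trios = collect_trios(pedigree, panel)
    e, n, matings = expected_homozygotes(tag, trios, panel)
    # pair 1 has a non-carrier dam; pair 2's offspring is undetermined;
    # pair 0 contributes its two determined offspring
    assert (e, n, matings) == (0.5, 2, 1)


def test_expectation_matches_loop_oracle_on_random_population():
    rng = np.random.default_rng(31)
    n_pairs = 30
    pairs = [tuple(rng.integers(0, 3, size=2)) for _ in range(n_pairs)]
    offspring = []
    for _ in range(200):
        pair = int(rng.integers(n_pairs))
        c = rng.choice([0, 1, 2, None], p=[0.4, 0.35, 0.15, 0.1])
        offspring.append((pair, None if c is None else int(c)))
    panel, pedigree, tag = build_population(pairs, offspring)
    trios = collect_trios(pedigree, panel)
    copies = tag.copies_vector(panel.n_animals)
    idx_trios = [
        (panel.animal_index(o), panel.animal_index(s), panel.animal_index(d))
        for o, s, d in trios.trios
    ]
    expect = expected_homozygotes_oracle(idx_trios, copies)
    got = expected_homozygotes(tag, trios, panel)
    assert got[0] == pytest.approx(expect[0], abs=1e-12)
    assert got[1:] == expect[1:]
    # observed count equals a direct recount over the copies vector
    assert observed_homozygotes(tag, panel) == int((copies == 2).sum())


def test_het_carrier_fraction_cases():
    pairs = [(1, 1)]
    offspring = [(0, 1), (0, 1), (0, 1), (0, 2), (0, 0), (0, 0)]
    panel, pedigree, tag = build_population(pairs, offspring)
    trios = collect_trios(pedigree, panel)
    het, pct = het_carrier_fraction(tag, trios, panel)
    assert (het, pct) == (3, pytest.approx(50.0))


def test_het_carrier_fraction_empty_is_nan():
    panel, pedigree, tag = build_population([(0, 0)], [(0, 1)])
    trios = collect_trios(pedigree, panel)
    het, pct = het_carrier_fraction(tag, trios, panel)
    assert het == 0 and np.isnan(pct)


# ---------------------------------------------------------------------------
# Exact binomial test
# ---------------------------------------------------------------------------


def test_binom_matches_rational_oracle_small_n():
    for n in range(1, 13):
        for p in (Fraction(1, 10), Fraction(1, 4), Fraction(1, 2)):
            for k in range(n + 1):
                got = binom_two_sided(k, n, float(p))
                want = binom_two_sided_oracle(k, n, p)
                assert got == pytest.approx(want, rel=1e-9), (k, n, p)


@settings(max_examples=200, deadline=None)
@given(
    n=st.integers(min_value=1, max_value=300),
    kf=st.floats(min_value=0.0, max_value=1.0),
    p=st.sampled_from([0.05, 0.1, 0.25, 0.5, 0.75, 0.9]),
)
def test_binom_matches_scipy_binomtest(n, kf, p):
    k = int(round(kf * n))
    got = binom_two_sided(k, n, p)
    want = binomtest(k, n, p, alternative="two-sided").pvalue
    assert got == pytest.approx(want, rel=1e-9)


def test_binom_at_mode_is_one():
    assert binom_two_sided(25, 100, 0.25) == pytest.approx(1.0, rel=1e-10)
    assert binom_two_sided(1, 2, 0.5) == pytest.approx(1.0, rel=1e-10)


def test_binom_monotone_below_mode():
    ps = [binom_two_sided(k, 100, 0.25) for k in range(0, 26)]
    assert all(a <= b for a, b in zip(ps, ps[1:]))


def test_binom_symmetric_null():
    for k in range(0, 9):
        assert binom_two_sided(k, 8, 0.5) == pytest.approx(
            binom_two_sided(8 - k, 8, 0.5), rel=1e-12
        )


def test_binom_input_validation():
    with pytest.raises(ValueError):
        binom_two_sided(5, 4, 0.25)
    with pytest.raises(ValueError):
        binom_two_sided(-1, 4, 0.25)
    with pytest.raises(ValueError):
        binom_two_sided(1, 4, 0.0)
    with pytest.raises(TypeError):
        binom_two_sided(1.0, 4, 0.25)


# ---------------------------------------------------------------------------
# Per-haplotype test and classification
# ---------------------------------------------------------------------------


def test_haplotype_no_progeny_untestable():
    panel, pedigree, tag = build_population([(0, 0)], [(0, 1)])
    trios = collect_trios(pedigree, panel)
    rec = score_haplotype(tag, trios, panel, ScanParams())
    assert rec.classification == UNTESTABLE
    assert not rec.testable
    assert np.isnan(rec.p_value)


def test_haplotype_null_is_expected_over_n():
    # one hom x het pair: E/n = 0.5, not the naive 0.25
    panel, pedigree, tag = build_population(
        [(2, 1)], [(0, 1), (0, 1), (0, 1), (0, 1)]
    )
    trios = collect_trios(pedigree, panel)
    rec = score_haplotype(tag, trios, panel, ScanParams())
    # O counts the homozygous sire itself
    assert rec.observed == 1
    assert rec.p_value == pytest.approx(binom_two_sided(1, 4, 0.5))


def test_haplotype_null_override():
    panel, pedigree, tag = build_population(
        [(1, 1)] * 4, [(i, 1) for i in range(4)]
    )
    trios = collect_trios(pedigree, panel)
    rec = score_haplotype(tag, trios, panel, ScanParams(null_p=0.5))
    assert rec.p_value == pytest.approx(binom_two_sided(0, 4, 0.5))


def test_haplotype_observed_can_exceed_progeny():
    # homozygotes outside trio progeny: k clamps to n and a note is set
    pairs = [(1, 1)]
    offspring = [(0, 2), (0, 2)]
    panel, pedigree, tag = build_population(pairs, offspring)
    # add three unrelated homozygous animals
    extra = np.zeros((3, 2, 4), dtype=np.int8)
    extra[:, :, 1:3] = 1
    panel2 = make_panel(
        panel.animals + ["U1", "U2", "U3"],
        np.concatenate([panel.haplotypes, extra]),
        positions=list(panel.markers.positions),
    )
    win = window_from_coords(panel2.markers, "1", 1_000_000, 2_000_000)
    tag2 = next(
        t for t in window_haplotypes(panel2, win, min_freq=0.0)
        if t.alleles == LETHAL
    )
    trios = collect_trios(pedigree, panel2)
    rec = score_haplotype(tag2, trios, panel2, ScanParams())
    assert rec.observed == 5 and rec.n_progeny == 2
    assert "outside genotyped trio progeny" in rec.note
    assert rec.p_value == pytest.approx(binom_two_sided(2, 2, 0.25))


def test_haplotype_all_hom_parents_degenerate_null():
    panel, pedigree, tag = build_population([(2, 2)], [(0, 2)])
    trios = collect_trios(pedigree, panel)
    rec = score_haplotype(tag, trios, panel, ScanParams())
    assert rec.p_value == 1.0
    assert rec.classification == NOT_SIGNIFICANT


def _rec(observed, expected, p):
    w = GenomicWindow("1", 0, 1_000_000, 1_000_000, 0, 2)
    return ScanRecord(
        window=w, alleles=(0, 0), frequency=0.1, expected=expected,
        observed=observed, n_progeny=50, p_value=p, cxc_matings=5,
        het_carriers=10, het_percent=60.0, classification=NOT_SIGNIFICANT,
    )


def test_classify_thresholds():
    params = ScanParams()
    assert classify(_rec(0, 12.0, 1.4e-4), params) == MH
    assert classify(_rec(0, 3.0, 6e-3), params) == NOT_SIGNIFICANT
    assert classify(_rec(1, 17.25, 8.22e-8), params) == DH
    assert classify(_rec(3, 15.0, 1e-5), params) == NOT_SIGNIFICANT  # > alpha
    # excess homozygosity never counts as a deficit, however significant
    assert classify(_rec(40, 10.0, 1e-12), params) == NOT_SIGNIFICANT
    untest = _rec(0, 0.0, float("nan"))
    untest.classification = UNTESTABLE
    assert classify(untest, params) == UNTESTABLE


# ---------------------------------------------------------------------------
# Whole-panel scan on the simulated fixture
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def lethal_scan(lethal_sim):
    return scan_panel(
        lethal_sim.panel, lethal_sim.pedigree, ScanParams(), population="SIM"
    )


def test_scan_flags_planted_window(lethal_sim, lethal_scan):
    planted = [
        r for r in lethal_scan
        if r.window.start == 10_000_000 and r.window.size == 1_000_000
        and r.alleles == lethal_sim.lethal_window_alleles(0)
    ]
    assert len(planted) == 1
    rec = planted[0]
    # MH in the typical case; a recombinant chromosome can reconstitute
    # the lethal's allele string without carrying the lethal haplotype
    # itself, leaving a viable string-homozygote and a DH call instead
    assert rec.classification in (MH, DH)
    assert rec.observed < 0.2 * rec.expected
    assert rec.expected > 10
    assert rec.p_value < 5e-6


def test_scan_carriers_match_truth(lethal_sim, lethal_scan):
    """Every truth carrier is a string carrier; string carriers that are
    not truth carriers (recombinants matching by state, not descent)
    stay rare."""
    rec = next(
        r for r in lethal_scan
        if r.window.start == 10_000_000 and r.window.size == 1_000_000
        and r.alleles == lethal_sim.lethal_window_alleles(0)
    )
    panel = lethal_sim.panel
    copies = diplotype_states(panel, rec.window, rec.alleles)
    truth_carriers = lethal_sim.truth.carriers_of(0)
    false_carriers = 0
    for i, animal in enumerate(panel.animals):
        if copies[i] == UNDETERMINED:
            continue
        if animal in truth_carriers:
            assert copies[i] >= 1
        elif copies[i] >= 1:
            false_carriers += 1
    assert false_carriers <= 0.02 * panel.n_animals


def test_collapse_recovers_single_planted_locus(lethal_scan):
    loci = collapse_loci(lethal_scan)
    assert len(loci) == 1
    # the single locus' overlap group contains the planted window: some
    # significant window covers the planted interval
    assert any(
        r.window.start <= 10_000_000 and r.window.end >= 11_000_000
        for r in lethal_scan
        if r.significant
    )
    best = loci[0]
    assert 8_000_000 <= best.window.start and best.window.end <= 13_000_000


# ---------------------------------------------------------------------------
# Locus collapsing and sharing
# ---------------------------------------------------------------------------


def sig_rec(chrom, start, end, p, classification=MH):
    w = GenomicWindow(chrom, start, end, end - start, 0, 2)
    return ScanRecord(
        window=w, alleles=(0,), frequency=0.1, expected=5.0, observed=0,
        n_progeny=20, p_value=p, cxc_matings=2, het_carriers=5,
        het_percent=55.0, classification=classification,
    )


def test_collapse_hand_case():
    records = [
        sig_rec("1", 0, 10, 1e-5),
        sig_rec("1", 5, 15, 1e-8),   # overlaps first: same locus, better p
        sig_rec("1", 20, 30, 1e-4),  # separate locus
        sig_rec("2", 0, 10, 1e-6),   # other chromosome
        sig_rec("1", 40, 50, 0.5, classification=NOT_SIGNIFICANT),
    ]
    loci = collapse_loci(records)
    key = sorted((r.window.chrom, r.window.start) for r in loci)
    assert key == [("1", 5), ("1", 20), ("2", 0)]


def test_collapse_tie_breaks_smaller_then_leftmost():
    records = [
        sig_rec("1", 0, 40, 1e-7),
        sig_rec("1", 10, 20, 1e-7),  # same p, smaller window: wins
        sig_rec("1", 30, 40, 1e-7),
    ]
    loci = collapse_loci(records)
    assert len(loci) == 1
    assert (loci[0].window.start, loci[0].window.end) == (10, 20)


def test_collapse_matches_union_find_oracle():
    rng = np.random.default_rng(53)
    for _ in range(200):
        records = []
        for _ in range(rng.integers(1, 12)):
            start = int(rng.integers(0, 40))
            end = start + int(rng.integers(1, 12))
            records.append(sig_rec("1", start, end, float(rng.random())))
        got = {
            (r.window.start, r.window.end, r.p_value)
            for r in collapse_loci(records)
        }
        groups = group_overlapping_oracle(
            [(r.window.start, r.window.end) for r in records]
        )
        want = set()
        for g in groups:
            best = min(
                (records[i] for i in g),
                key=lambda r: (
                    r.p_value,
                    r.window.end - r.window.start,
                    r.window.start,
                ),
            )
            want.add((best.window.start, best.window.end, best.p_value))
        assert got == want


def test_shared_loci_hand_case():
    pop_a = [sig_rec("1", 0, 10, 1e-6)]
    pop_b = [sig_rec("1", 5, 15, 1e-6), sig_rec("2", 0, 5, 1e-6)]
    for r in pop_a:
        r.population = "A"
    for r in pop_b:
        r.population = "B"
    regions = shared_loci([pop_a, pop_b])
    assert regions == [(("1", 5, 10), frozenset({"A", "B"}))]


def test_shared_loci_requires_two_populations():
    with pytest.raises(ValueError):
        shared_loci([[sig_rec("1", 0, 10, 1e-6)]])


def test_shared_loci_matches_unit_segment_brute_force():
    rng = np.random.default_rng(77)
    for _ in range(50):
        pops = []
        labels = []
        for p in range(int(rng.integers(2, 4))):
            recs = []
            for _ in range(int(rng.integers(0, 4))):
                start = int(rng.integers(0, 28))
                end = start + int(rng.integers(1, 8))
                recs.append(sig_rec("1", start, end, 1e-6))
            pops.append(recs)
            labels.append(f"P{p}")
        got = shared_loci(pops, labels=labels)

        # brute force over unit-length segments [x, x+1)
        cover = []
        for x in range(0, 40):
            labs = {
                lab
                for lab, recs in zip(labels, pops)
                for r in recs
                if r.window.start <= x and x + 1 <= r.window.end
            }
            cover.append(labs if len(labs) >= 2 else None)
        want = []
        x = 0
        while x < 40:
            if cover[x] is None:
                x += 1
                continue
            start = x
            labs = set()
            while x < 40 and cover[x] is not None:
                labs |= cover[x]
                x += 1
            want.append((("1", start, x), frozenset(labs)))
        assert got == want
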