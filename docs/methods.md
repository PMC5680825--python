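# Methods

## Statistical model

Let a window haplotype *h* have copy number c(a) ∈ {0, 1, 2} for each
phased animal *a*. For every genotyped trio (offspring, sire, dam) in
which both parents carry *h* (c ≥ 1, phase determined), the offspring's
prior probability of being homozygous is
(c(sire)/2)·(c(dam)/2). Summing over the *n* such offspring gives the
expected homozygote count *E*; the observed count *O* is taken over all
phased animals in the panel (homozygotes can appear outside genotyped
trios, so restricting *O* to trio offspring would discard evidence,
while the trio restriction on *E*/*n* keeps the expectation exact).

*O* is tested against Binomial(*n*, *E*/*n*). Because *O* is panel-wide
it can exceed *n*; the test statistic is clamped to min(*O*, *n*) and
the record is annotated. The two-sided p-value uses the
point-probability method: p = Σ P(X = k) over all k with
P(X = k) ≤ P(X = O)·(1 + 10⁻⁷). The relative tie tolerance absorbs
floating-point noise in log-space binomial coefficients (computed via
`gammaln`, stable up to n in the tens of thousands). On exact rational
enumeration the implementation agrees to < 10⁻⁹ relative error for all
k, n ≤ 12, p ∈ {0.1, 0.25, 0.5}, and to printed precision on published
pairs: (0, 75, 0.25) → 5.70E-10, (1, 69, 0.25) → 8.22E-08,
(0, 33, 0.25) → 1.44E-04.

Classification:

- **MH** — *O* = 0 and p < 5×10⁻³;
- **DH** — 0 < *O* < *E* and p < 5×10⁻⁶;
- otherwise not significant; windows with *n* = 0 are untestable.

The DH branch requires a homozygote *deficit* (*O* < *E*). A literal
"p small and O > 0" rule would also flag homozygote *excess*, which is
common for high-frequency haplotypes precisely because *O* is
panel-wide while *n* is trio-limited; the deficit condition keeps the
null calibration honest (0 significant calls across 5,000+ testable
haplotypes in a neutral population).

Under Hardy–Weinberg, carrier×carrier progeny are 50% heterozygous;
removing the dead homozygote class pushes this to 2/3. The
heterozygous-carrier-progeny percentage is reported per haplotype as a
consistency check (it converges to 66.7% in simulation).

## Windows, loci

Windows of 0.5, 1, 2 and 4 Mb slide with step = half the window size,
anchored at coordinate 0 on each chromosome; windows with fewer than
two markers are skipped. Overlapping significant windows (transitive
overlap, any size) collapse into one locus represented by the record
with the smallest p-value, ties broken toward the smaller and then the
leftmost window. Locus resolution is therefore one window grid cell:
the reported window need not coincide with, or even contain, the causal
interval — it sits inside the surrounding LD block.

## Phenotype contrasts

Litters are classified by parental carrier status into
carrier×carrier, carrier×non-carrier and non-carrier×non-carrier
(unknown when a parent is ungenotyped or phase-ambiguous in the
window). TNB, NBA, NSB and MUM are compared between carrier×carrier
and carrier×non-carrier litters with Welch's unequal-variance t-test
(≥ 2 litters per class required), reporting
percent difference = 100·(mean₍CxC₎ − mean₍CxNC₎)/mean₍CxNC₎. A χ²
test on pooled litter composition and the per-litter mummy-count
distribution are also available. `lethal_rate_summary` propagates a
carrier frequency into expected affected-litter and affected-piglet
rates and the population-level share of mummified fetuses.

## Runs of homozygosity

A reported ROH is a *maximal* marker interval with ≥ 20 markers
(configurable), ≤ 1 heterozygous call, and base-pair span ≥ 1 Mb;
missing calls are neutral (neither homozygous nor heterozygous).
Maximality means the interval can be extended in neither direction
without violating the heterozygote allowance; two maximal stretches may
overlap (each spending its allowance on a different heterozygous call),
and both are reported. A two-pointer sweep computes this in linear
time per animal and chromosome; it is verified against a quadratic
brute-force oracle on randomized instances.

## QC

Marker filters, in order: autosomes only → duplicate positions (keep
first) → call rate (drop when missing fraction > 15%) → MAF (drop when
< 1%, strict). Animal filter: drop when > 30% missing. Per-animal
inbreeding F is the excess-homozygosity coefficient over the filtered
markers.

## Gene-drop simulator

The simulator produces a phased panel, pedigree, litter records and a
truth set from one integer seed (byte-identical reruns):

- A founder pool of K (default 30) haplotypes with per-marker Bernoulli
  alleles around base frequencies drawn from U(0.1, 0.9). Each planted
  lethal claims one pool haplotype; its window allele string is forced
  unique within the pool.
- Founders draw pool haplotypes i.i.d.; the lethal's sampling weight is
  its specified frequency. Founders are conditioned on viability (no
  lethal homozygotes enter the herd).
- Meiosis: marker-to-marker recombination via Haldane's map from a
  uniform Morgan density (default 1 Morgan / 30 Mb chromosome);
  independent assortment between chromosomes.
- Litters: truncated-Poisson(16, ≥ 1) conceptions per sow and litter;
  each fetus is LIVE, EARLY (early loss), MUMMY or STILLBORN. A fetus
  homozygous for a lethal dies at the lethal's stage (early /
  mid-gestation / stillbirth) with probability = penetrance; baseline
  mummy (2%) and stillbirth (9%) rates apply to the rest. Dead fetuses
  never enter the pedigree, are never genotyped, never breed.
  Lethality is judged on the window marker-allele string (identity by
  state): a recombinant that reconstitutes the lethal's allele string
  carries the lethal haplotype — the haplotype is the causal unit,
  which is also exactly what the scan measures.
- Genotyping: a configurable fraction of live animals (default 0.9),
  with parents of genotyped offspring preferentially included (trio
  enrichment), plus optional random missingness.

What it deliberately omits: genotyping error, phasing error (phase is
known by construction), selection on phenotype, overlapping
generations, X chromosome, mutation.

## Default problem sizes

The acceptance-scale population (25 boars, 240 sows, one generation,
2 × 30 Mb chromosomes, 500 markers) yields ≈ 3,400 conceived fetuses,
≈ 3,000+ genotyped trios, and scans in a few seconds. A planted fully
penetrant lethal at 10% founder frequency is recovered as MH in 48/50
replicates (the 2 misses are power failures where founder drift leaves
E ≈ 3); the same scan on a neutral population makes 0 significant
calls among 5,000+ testable haplotypes, and Welch p-values on neutral
haplotype contrasts are KS-uniform.

## Numerical and design choices

- Binomial tail sums run in log space with a 10⁻⁷ relative tie
  tolerance; p-values are printed as `%.2E`.
- Phased VCF input: unphased *heterozygous* genotypes are rejected by
  default (tolerate-and-drop is available); unphased homozygotes are
  accepted since their phase is unambiguous.
- A haplotype's copy number is `undetermined` for an animal with any
  missing allele in the window; undetermined animals are excluded from
  carrier logic rather than guessed.
- Observed homozygotes are counted panel-wide; expectation is
  trio-restricted (see above).
- Gene annotation treats a window [s, e) as covering 1-based positions
  s..e−1 and reports genes with any overlap; BED and GFF3 dialects are
  supported.
- All randomness flows from a single integer seed per run; derived
  seeds stay below 2³¹.
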