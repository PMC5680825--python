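"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates are held internally as 1-based closed intervals
(the VCF/GFF3 convention).  BED input is converted on read.  Marker
positions follow the VCF convention (1-based).

Unknown parents in pedigree files are encoded with the single token "0",
the dominant convention in livestock pedigrees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1  # allele code for a missing call
UNKNOWN_PARENT = "0"

PEDIGREE_COLUMNS = ["animal", "sire", "dam", "line", "sex"]
LITTER_COLUMNS = ["sow", "boar", "litter", "TNB", "NBA", "NSB", "MUM"]

SCAN_TABLE_COLUMNS = [
    "haplotype",
    "chromosome",
    "start",
    "end",
    "frequency",
    "expected",
    "observed",
    "p_value",
    "cxc_matings",
    "genotyped_progeny",
    "het_carrier_progeny",
    "classification",
]


class ValidationError(ValueError):
    """Input violates a format or domain constraint."""


class ParseError(ValueError):
    """Input could not be parsed at all."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarkerMap:
    """Ordered biallelic SNP map.

    Markers are sorted by (chromosome block, position); chromosome blocks
    appear in input order and positions increase within a block.
    """

    names: np.ndarray
    chroms: np.ndarray
    positions: np.ndarray  # 1-based bp
    ref: np.ndarray
    alt: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.names)
        for arr in (self.chroms, self.positions, self.ref, self.alt):
            if len(arr) != n:
                raise ValidationError("marker map arrays differ in length")
        # positions strictly... non-decreasing within each chromosome block;
        # duplicates are tolerated on load and removed by QC.
        for chrom, lo, hi in self.chrom_blocks():
            pos = self.positions[lo:hi]
            if np.any(np.diff(pos) < 0):
                raise ValidationError(
                    f"markers on chromosome {chrom} are not position-sorted"
                )

    def __len__(self) -> int:
        return len(self.names)

    def chrom_blocks(self) -> list[tuple[str, int, int]]:
        """Contiguous (chromosome, start_index, stop_index) blocks."""
        blocks: list[tuple[str, int, int]] = []
        if len(self.chroms) == 0:
            return blocks
        seen: set[str] = set()
        start = 0
        for i in range(1, len(self.chroms) + 1):
            if i == len(self.chroms) or self.chroms[i] != self.chroms[start]:
                chrom = str(self.chroms[start])
                if chrom in seen:
                    raise ValidationError(
                        f"chromosome {chrom} appears in non-contiguous blocks"
                    )
                seen.add(chrom)
                blocks.append((chrom, start, i))
                start = i
        return blocks

    def subset(self, idx: np.ndarray) -> "MarkerMap":
        return MarkerMap(
            names=self.names[idx],
            chroms=self.chroms[idx],
            positions=self.positions[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
        )


@dataclass
class HaplotypePanel:
    """Phased diploid genotypes over an ordered marker map.

    ``haplotypes`` has shape (n_animals, 2, n_markers) with allele codes
    0/1 and :data:`MISSING` (-1) for missing calls.
    """

    animals: list[str]
    haplotypes: np.ndarray
    markers: MarkerMap

    def __post_init__(self) -> None:
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[1] != 2:
            raise ValidationError("haplotypes must have shape (N, 2, M)")
        if self.haplotypes.shape[0] != len(self.animals):
            raise ValidationError("animal list does not match haplotype array")
        if self.haplotypes.shape[2] != len(self.markers):
            raise ValidationError("marker count does not match haplotype array")
        if len(set(self.animals)) != len(self.animals):
            dup = pd.Series(self.animals).value_counts()
            raise ValidationError(
                f"duplicate animal identifiers: {list(dup[dup > 1].index)[:5]}"
            )
        self._index = {a: i for i, a in enumerate(self.animals)}

    @property
    def n_animals(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[2]

    def animal_index(self, animal: str) -> int:
        try:
            return self._index[animal]
        except KeyError:
            raise KeyError(f"animal {animal!r} not in panel") from None

    def __contains__(self, animal: str) -> bool:
        return animal in self._index

    def subset_animals(self, keep: np.ndarray) -> "HaplotypePanel":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return HaplotypePanel(
            animals=[self.animals[i] for i in keep],
            haplotypes=self.haplotypes[keep],
            markers=self.markers,
        )

    def subset_markers(self, idx: np.ndarray) -> "HaplotypePanel":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return HaplotypePanel(
            animals=list(self.animals),
            haplotypes=self.haplotypes[:, :, idx],
            markers=self.markers.subset(idx),
        )

    def genotypes(self) -> np.ndarray:
        """Unphased genotype codes: 0 hom-ref, 1 het, 2 hom-alt, -1 missing."""
        h = self.haplotypes
        g = h.sum(axis=1)
        g[(h < 0).any(axis=1)] = MISSING
        return g


@dataclass
class PedigreeTable:
    """Pedigree with per-animal line and sex annotations."""

    df: pd.DataFrame  # columns: animal, sire, dam, line, sex

    def __post_init__(self) -> None:
        missing = [c for c in PEDIGREE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"pedigree missing columns: {missing}")
        dup = self.df["animal"].duplicated()
        if dup.any():
            raise ValidationError(
                f"duplicate animals in pedigree: "
                f"{sorted(self.df.loc[dup, 'animal'].unique())[:5]}"
            )
        self._check_acyclic()
        self._check_parent_sex()
        self._parents = {
            row.animal: (row.sire, row.dam) for row in self.df.itertuples()
        }

    def _check_acyclic(self) -> None:
        parents = {
            row.animal: [p for p in (row.sire, row.dam) if p != UNKNOWN_PARENT]
            for row in self.df.itertuples()
        }
        WHITE, GREY, BLACK = 0, 1, 2
        color = {a: WHITE for a in parents}
        for root in parents:
            if color[root] != WHITE:
                continue
            stack: list[tuple[str, int]] = [(root, 0)]
            path: list[str] = []
            while stack:
                node, pi = stack.pop()
                if pi == 0:
                    color[node] = GREY
                    path.append(node)
                kids = [p for p in parents.get(node, []) if p in parents]
                if pi < len(kids):
                    stack.append((node, pi + 1))
                    nxt = kids[pi]
                    if color[nxt] == GREY:
                        cycle = path[path.index(nxt):] + [nxt]
                        raise ValidationError(
                            "pedigree cycle detected: " + " -> ".join(cycle)
                        )
                    if color[nxt] == WHITE:
                        stack.append((nxt, 0))
                else:
                    color[node] = BLACK
                    path.pop()

    def _check_parent_sex(self) -> None:
        sex = dict(zip(self.df["animal"], self.df["sex"]))
        for row in self.df.itertuples():
            if row.sire != UNKNOWN_PARENT and sex.get(row.sire) == "female":
                raise ValidationError(f"sire {row.sire} is recorded as female")
            if row.dam != UNKNOWN_PARENT and sex.get(row.dam) == "male":
                raise ValidationError(f"dam {row.dam} is recorded as male")

    def parents_of(self, animal: str) -> tuple[str, str]:
        """(sire, dam) of *animal*, :data:`UNKNOWN_PARENT` when unrecorded."""
        return self._parents.get(animal, (UNKNOWN_PARENT, UNKNOWN_PARENT))

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class LitterRecord:
    """One farrowing: parents plus per-litter offspring counts.

    MUM is recorded independently of TNB — whether mummified piglets are
    included in the total born varies between farms, so only the
    ``NBA + NSB <= TNB`` identity is enforced.
    """

    sow: str
    boar: str
    litter: str
    tnb: int
    nba: int
    nsb: int
    mum: int

    def __post_init__(self) -> None:
        if min(self.tnb, self.nba, self.nsb, self.mum) < 0:
            raise ValidationError(f"negative count in litter {self.litter}")
        if self.nba + self.nsb > self.tnb:
            raise ValidationError(
                f"litter {self.litter}: NBA+NSB={self.nba + self.nsb} exceeds "
                f"TNB={self.tnb}"
            )

    def trait(self, name: str) -> int:
        return {"TNB": self.tnb, "NBA": self.nba, "NSB": self.nsb,
                "MUM": self.mum}[name]


# ---------------------------------------------------------------------------
# Phased VCF
# ---------------------------------------------------------------------------


def read_phased_vcf(
    path: str | Path, require_phase: bool = True
) -> tuple[HaplotypePanel, MarkerMap]:
    """Load a phased, biallelic, diploid VCF into a haplotype panel.

    Heterozygous genotypes written with the unphased "/" separator are
    rejected when *require_phase* is set, otherwise loaded with both
    alleles marked missing.  Unphased homozygous genotypes are accepted:
    their phase is unambiguous.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise ValidationError("duplicate sample name in VCF header")

    names, chroms, positions, ref, alt = [], [], [], [], []
    columns: list[np.ndarray] = []
    for i, variant in enumerate(vcf):
        if len(variant.ALT) != 1:
            raise ValidationError(
                f"multi-allelic site at {variant.CHROM}:{variant.POS} "
                f"(record {i + 1})"
            )
        gts = variant.genotypes  # [a0, a1, phased] per sample
        col = np.empty((len(samples), 2), dtype=np.int8)
        for s, gt in enumerate(gts):
            if len(gt) < 3:
                raise ParseError(
                    f"non-diploid genotype for sample {samples[s]} at "
                    f"{variant.CHROM}:{variant.POS}"
                )
            a0, a1, phased = gt[0], gt[1], gt[-1]
            if a0 < 0 or a1 < 0:
                col[s] = (MISSING, MISSING)
            elif not phased and a0 != a1:
                if require_phase:
                    raise ValidationError(
                        f"unphased heterozygous genotype for sample "
                        f"{samples[s]} at {variant.CHROM}:{variant.POS}"
                    )
                col[s] = (MISSING, MISSING)
            else:
                col[s] = (a0, a1)
        names.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        chroms.append(variant.CHROM)
        positions.append(variant.POS)
        ref.append(variant.REF)
        alt.append(variant.ALT[0])
        columns.append(col)

    marker_map = MarkerMap(
        names=np.array(names, dtype=object),
        chroms=np.array(chroms, dtype=object),
        positions=np.array(positions, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
    )
    if columns:
        haps = np.stack(columns, axis=2)  # (N, 2, M)
    else:
        haps = np.empty((len(samples), 2, 0), dtype=np.int8)
    panel = HaplotypePanel(animals=samples, haplotypes=haps, markers=marker_map)
    return panel, marker_map


def write_phased_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    """Write a panel as a minimal phased VCF 4.2 text file."""
    m = panel.markers
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, lo, hi in m.chrom_blocks():
            length = int(m.positions[hi - 1]) + 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.animals)
            + "\n"
        )
        h = panel.haplotypes
        for j in range(len(m)):
            cells = []
            for i in range(panel.n_animals):
                a0, a1 = h[i, 0, j], h[i, 1, j]
                s0 = "." if a0 < 0 else str(int(a0))
                s1 = "." if a1 < 0 else str(int(a1))
                cells.append(f"{s0}|{s1}")
            fh.write(
                f"{m.chroms[j]}\t{m.positions[j]}\t{m.names[j]}\t{m.ref[j]}\t"
                f"{m.alt[j]}\t.\tPASS\t.\tGT\t" + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# Pedigree and litter files
# ---------------------------------------------------------------------------


def read_pedigree(path: str | Path) -> PedigreeTable:
    """Read a tab-separated pedigree (animal/sire/dam/line/sex)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PEDIGREE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"pedigree file missing columns: {missing}")
    df = df[PEDIGREE_COLUMNS].copy()
    df["sire"] = df["sire"].replace("", UNKNOWN_PARENT)
    df["dam"] = df["dam"].replace("", UNKNOWN_PARENT)
    df["sex"] = df["sex"].replace("", "unknown")
    bad_sex = ~df["sex"].isin(["male", "female", "unknown"])
    if bad_sex.any():
        raise ValidationError(
            f"invalid sex values: {sorted(df.loc[bad_sex, 'sex'].unique())}"
        )
    return PedigreeTable(df)


def write_pedigree(pedigree: PedigreeTable, path: str | Path) -> None:
    pedigree.df.to_csv(path, sep="\t", index=False)


def read_litters(path: str | Path) -> list[LitterRecord]:
    """Read litter phenotype records, dropping rows violating count rules.

    Rows with negative counts or NBA+NSB > TNB are dropped and counted in
    a log message rather than aborting the run — farm recording errors are
    common and must not sink a whole scan.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in LITTER_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"litter file missing columns: {missing}")
    records: list[LitterRecord] = []
    dropped = 0
    for row in df.itertuples():
        try:
            rec = LitterRecord(
                sow=row.sow,
                boar=row.boar,
                litter=row.litter,
                tnb=int(row.TNB),
                nba=int(row.NBA),
                nsb=int(row.NSB),
                mum=int(row.MUM),
            )
        except (ValidationError, ValueError):
            dropped += 1
            continue
        records.append(rec)
    if dropped:
        log.warning("read_litters: dropped %d invalid litter rows", dropped)
    return records


def write_litters(records: Sequence[LitterRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (r.sow, r.boar, r.litter, r.tnb, r.nba, r.nsb, r.mum)
            for r in records
        ],
        columns=LITTER_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Scan result tables
# ---------------------------------------------------------------------------


def format_pvalue(p: float) -> str:
    """Scientific notation with 3 significant digits, e.g. ``5.70E-10``."""
    return f"{p:.2E}"


def write_scan_table(records: Iterable, path: str | Path) -> None:
    """Write scan records as TSV mirroring the published table layout.

    Accepts any iterable of objects exposing the ScanRecord interface
    (see :mod:`mhscan.scan`).
    """
    rows = []
    for r in records:
        w = r.window
        rows.append(
            {
                "haplotype": r.label or "",
                "chromosome": w.chrom,
                "start": w.start,
                "end": w.end,
                "frequency": f"{r.frequency:.6g}",
                "expected": f"{r.expected:.6g}",
                "observed": r.observed,
                "p_value": format_pvalue(r.p_value) if r.testable else "NA",
                "cxc_matings": r.cxc_matings,
                "genotyped_progeny": r.n_progeny,
                "het_carrier_progeny": r.het_carriers,
                "classification": r.classification,
            }
        )
    df = pd.DataFrame(rows, columns=SCAN_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_scan_table(path: str | Path) -> pd.DataFrame:
    """Read back a scan TSV written by :func:`write_scan_table`."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "haplotype": str,
            "chromosome": str,
            "classification": str,
        },
        keep_default_na=False,
    )
    for col in ("start", "end", "observed", "cxc_matings",
                "genotyped_progeny", "het_carrier_progeny"):
        df[col] = df[col].astype(int)
    for col in ("frequency", "expected"):
        df[col] = df[col].astype(float)
    df["p_value"] = pd.to_numeric(df["p_value"], errors="coerce")
    return df


# ---------------------------------------------------------------------------
# Gene annotation intervals
# ---------------------------------------------------------------------------


def read_gene_intervals(
    path: str | Path, dialect: str
) -> list[tuple[str, int, int, str]]:
    """Read gene intervals from BED or GFF3 into 1-based closed coordinates.

    BED is 0-based half-open; GFF3 is 1-based closed.  The same physical
    interval expressed in either dialect yields an identical tuple.
    """
    dialect = dialect.upper()
    if dialect not in {"BED", "GFF3"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    out: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if dialect == "BED":
                if len(fields) < 3:
                    raise ParseError(f"{path}:{ln}: too few BED fields")
                chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else f"interval{ln}"
                if start0 < 0 or end0 < start0:
                    raise ValidationError(f"{path}:{ln}: invalid BED interval")
                out.append((chrom, start0 + 1, end0, name))
            else:
                if len(fields) < 9:
                    raise ParseError(f"{path}:{ln}: too few GFF3 fields")
                chrom, start1, end1 = fields[0], int(fields[3]), int(fields[4])
                if start1 < 1 or end1 < start1:
                    raise ValidationError(f"{path}:{ln}: invalid GFF3 interval")
                name = _gff3_name(fields[8]) or f"interval{ln}"
                out.append((chrom, start1, end1, name))
    return out


def _gff3_name(attributes: str) -> str | None:
    attrs = {}
    for item in attributes.split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs.get("Name") or attrs.get("gene_name") or attrs.get("ID")


def write_gene_intervals_bed(
    intervals: Sequence[tuple[str, int, int, str]], path: str | Path
) -> None:
    """Write 1-based closed intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\n")
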