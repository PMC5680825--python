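"""Pipeline orchestration: qc -> scan -> collapse -> assoc -> report.

The pipeline is a pure function of (inputs, configuration): repeated
runs write byte-identical outputs.  Every stage's counts go into a
structured run log; a failure in any stage raises :class:`StageError`
naming the stage while earlier outputs are retained on disk.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import assoc as assoc_mod
from .assoc import TRAITS, TraitEffect, classify_matings, mum_distribution, trait_effect
from .io import (
    HaplotypePanel,
    read_gene_intervals,
    read_litters,
    read_pedigree,
    read_phased_vcf,
    write_scan_table,
)
from .qc import QCParams, f_coefficient, filter_animals, filter_markers
from .scan import (
    ScanParams,
    ScanRecord,
    collapse_loci,
    diplotype_states,
    scan_panel,
)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    vcf: str
    pedigree: str
    litters: str | None = None
    genes: str | None = None
    gene_dialect: str = "BED"
    population: str = "POP"
    traits: tuple[str, ...] = TRAITS
    qc: QCParams = field(default_factory=QCParams)
    scan: ScanParams = field(default_factory=ScanParams)
    out: str = "mhscan_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        qc_raw = raw.pop("qc", {})
        if "autosomes" in qc_raw and qc_raw["autosomes"] is not None:
            qc_raw["autosomes"] = frozenset(str(c) for c in qc_raw["autosomes"])
        scan_raw = raw.pop("scan", {})
        if "window_sizes" in scan_raw:
            scan_raw["window_sizes"] = tuple(
                int(w) for w in scan_raw["window_sizes"]
            )
        if "traits" in raw:
            raw["traits"] = tuple(raw["traits"])
        return cls(qc=QCParams(**qc_raw), scan=ScanParams(**scan_raw), **raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["qc"]["autosomes"] = (
            sorted(self.qc.autosomes) if self.qc.autosomes else None
        )
        data["scan"]["window_sizes"] = list(self.scan.window_sizes)
        data["traits"] = list(self.traits)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Gene annotation and report assembly
# ---------------------------------------------------------------------------


def annotate_genes(
    records: Sequence[ScanRecord],
    intervals: Sequence[tuple[str, int, int, str]],
) -> list[list[str]]:
    """Gene names overlapping each record's window (1-based closed
    comparison; a window [start, end) covers positions start..end-1)."""
    out: list[list[str]] = []
    for r in records:
        w = r.window
        hits = [
            name
            for chrom, gs, ge, name in intervals
            if chrom == w.chrom and gs <= w.end - 1 and ge >= w.start
        ]
        out.append(hits)
    return out


def _chrom_sort_key(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


def summary_table(
    records: Sequence[ScanRecord],
    effects: dict[str, dict[str, TraitEffect]] | None = None,
    genes: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """One row per selected locus and trait, joining scan statistics and
    trait contrasts; sorted by population, trait, chromosome, start.

    Loci without a trait effect appear once with empty effect cells.
    """
    effects = effects or {}
    genes = genes or {}
    rows = []
    for r in records:
        label = r.label or ""
        locus_effects = effects.get(label, {})
        traits = sorted(locus_effects) if locus_effects else [""]
        for trait in traits:
            eff = locus_effects.get(trait)
            rows.append(
                {
                    "population": r.population or "",
                    "haplotype": label,
                    "trait": trait,
                    "chromosome": r.window.chrom,
                    "start": r.window.start,
                    "end": r.window.end,
                    "frequency": r.frequency,
                    "carrier_frequency": 2.0 * r.frequency,
                    "expected": r.expected,
                    "observed": r.observed,
                    "p_value": r.p_value,
                    "cxc_matings": r.cxc_matings,
                    "genotyped_progeny": r.n_progeny,
                    "het_carrier_progeny": r.het_carriers,
                    "het_carrier_percent": r.het_percent,
                    "classification": r.classification,
                    "n_cxc_litters": eff.n_cxc if eff else "",
                    "n_cxnc_litters": eff.n_cxnc if eff else "",
                    "mean_cxc": eff.mean_cxc if eff else "",
                    "mean_cxnc": eff.mean_cxnc if eff else "",
                    "percent_difference": (
                        eff.percent_difference if eff else ""
                    ),
                    "welch_p": eff.welch_p if eff else "",
                    "genes": ",".join(genes.get(label, [])),
                }
            )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["_ck"] = df["chromosome"].map(_chrom_sort_key)
        df = df.sort_values(
            ["population", "trait", "_ck", "start"], kind="stable"
        ).drop(columns="_ck")
        df = df.reset_index(drop=True)
    return df


def assign_labels(
    selected: Sequence[ScanRecord], population: str
) -> list[ScanRecord]:
    """Deterministic haplotype labels ``<population><rank>`` assigned
    after sorting loci by chromosome and start."""
    ordered = sorted(
        selected, key=lambda r: (_chrom_sort_key(r.window.chrom),
                                 r.window.start)
    )
    for rank, r in enumerate(ordered, start=1):
        r.label = f"{population}{rank}"
        r.population = population
    return ordered


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the output directory."""
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    log: dict = {"population": config.population, "stages": {}}

    def fail(stage: str, exc: Exception):
        log["stages"].setdefault(stage, {})["error"] = str(exc)
        _write_log(log, outdir)
        raise StageError(stage, exc)

    # qc -------------------------------------------------------------------
    try:
        panel, _ = read_phased_vcf(config.vcf, require_phase=True)
        n0_markers, n0_animals = panel.n_markers, panel.n_animals
        panel, marker_log = filter_markers(panel, config.qc)
        panel, animal_log = filter_animals(panel, config.qc)
        marker_log.to_csv(outdir / "removed_markers.tsv", sep="\t",
                          index=False)
        animal_log.to_csv(outdir / "removed_animals.tsv", sep="\t",
                          index=False)
        f_coefficient(panel).to_frame().to_csv(
            outdir / "f_coefficient.tsv", sep="\t", index=False,
            float_format="%.6g",
        )
        log["stages"]["qc"] = {
            "markers_in": n0_markers,
            "markers_removed": len(marker_log),
            "animals_in": n0_animals,
            "animals_removed": len(animal_log),
        }
    except Exception as exc:  # noqa: BLE001 - stage boundary
        fail("qc", exc)

    # scan -----------------------------------------------------------------
    try:
        pedigree = read_pedigree(config.pedigree)
        records = scan_panel(panel, pedigree, config.scan,
                             population=config.population)
        testable = [r for r in records if r.testable]
        write_scan_table(records, outdir / "scan_all.tsv")
        log["stages"]["scan"] = {
            "haplotypes": len(records),
            "testable": len(testable),
            "significant": sum(r.significant for r in records),
        }
    except Exception as exc:  # noqa: BLE001
        fail("scan", exc)

    # collapse -------------------------------------------------------------
    try:
        selected = assign_labels(collapse_loci(records), config.population)
        write_scan_table(selected, outdir / "loci.tsv")
        log["stages"]["collapse"] = {"loci": len(selected)}
    except Exception as exc:  # noqa: BLE001
        fail("collapse", exc)

    # assoc ----------------------------------------------------------------
    effects: dict[str, dict[str, TraitEffect]] = {}
    if config.litters is None:
        log["stages"]["assoc"] = {"skipped": "no litter file supplied"}
    else:
        try:
            litters = read_litters(config.litters)
            effect_rows = []
            dist_rows = []
            for r in selected:
                copies = diplotype_states(panel, r.window, r.alleles)
                classes = classify_matings(litters, _tag_stub(r), panel,
                                           copies=copies)
                effects[r.label] = {}
                for trait in config.traits:
                    eff = trait_effect(classes, trait)
                    effects[r.label][trait] = eff
                    effect_rows.append(
                        {"haplotype": r.label, **asdict(eff)}
                    )
                for mating, dist in mum_distribution(classes).items():
                    for x, frac in dist.items():
                        dist_rows.append(
                            {
                                "haplotype": r.label,
                                "mating": mating,
                                "mummified": x,
                                "fraction": frac,
                            }
                        )
            pd.DataFrame(effect_rows).to_csv(
                outdir / "effects.tsv", sep="\t", index=False,
                float_format="%.6g",
            )
            pd.DataFrame(dist_rows).to_csv(
                outdir / "mum_distribution.tsv", sep="\t", index=False,
                float_format="%.6g",
            )
            log["stages"]["assoc"] = {
                "litters": len(litters),
                "loci_tested": len(selected),
            }
        except Exception as exc:  # noqa: BLE001
            fail("assoc", exc)

    # report ---------------------------------------------------------------
    try:
        gene_map: dict[str, list[str]] = {}
        if config.genes is not None:
            intervals = read_gene_intervals(config.genes, config.gene_dialect)
            for r, hits in zip(selected, annotate_genes(selected, intervals)):
                gene_map[r.label] = hits
        table = summary_table(selected, effects, gene_map)
        table.to_csv(outdir / "report.tsv", sep="\t", index=False,
                     float_format="%.6g")
        log["stages"]["report"] = {"rows": len(table)}
    except Exception as exc:  # noqa: BLE001
        fail("report", exc)

    _write_log(log, outdir)
    return outdir


def _tag_stub(record: ScanRecord):
    """Minimal tag-like object for classify_matings when only the
    record (window + alleles) is available; copy vectors are supplied
    explicitly so the stub's index arrays are never consulted."""
    from .scan import HaplotypeTag

    empty = np.zeros(0, dtype=np.int64)
    return HaplotypeTag(
        window=record.window,
        alleles=record.alleles,
        frequency=record.frequency,
        carrier_idx=empty,
        hom_idx=empty,
        complete_idx=empty,
    )


def _write_log(log: dict, outdir: Path) -> None:
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)
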