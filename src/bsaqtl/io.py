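"""File formats, configuration and the end-to-end pipeline runner.

Tables travel as TSV; allele counts can also round-trip through minimal
VCFv4.2 with per-sample AD (allele depth) fields, read and written with
pysam.  Internal coordinates are 1-based inclusive (the VCF convention);
BED output is converted to 0-based half-open at the boundary only.

A single integer seed drives every stochastic stage: per-stage seeds are
derived deterministically with :func:`stage_seed`, so individual stages can
be reproduced in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from . import calling, simulate, snpindex
from .errors import ConfigError, DataError, FormatError

__all__ = [
    "PipelineConfig",
    "stage_seed",
    "read_allele_counts",
    "write_allele_counts",
    "write_bed",
    "run_pipeline",
]

COUNT_COLUMNS = ["chromosome", "position_bp", "cab_allele", "dar_allele",
                 "cab_count", "dar_count"]


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global one.

    CRC32 of the stage name is folded into the global seed; the result is a
    31-bit integer, stable across runs and platforms.
    """
    return (int(seed) * 0x9E3779B1 + zlib.crc32(stage.encode())) % (2**31)


# ---------------------------------------------------------------------------
# allele-count tables
# ---------------------------------------------------------------------------

def write_allele_counts(counts: pd.DataFrame, path, format: str = "tsv",
                        sample: str = "sample") -> None:
    """Write an allele-count table as TSV or minimal VCFv4.2.

    In VCF mode the Darmor allele is REF, the Cabriolet allele ALT and the
    per-sample AD field holds (REF depth, ALT depth) = (dar_count, cab_count).
    """
    path = Path(path)
    if format == "tsv":
        counts[COUNT_COLUMNS].to_csv(path, sep="\t", index=False)
    elif format == "vcf":
        header = pysam.VariantHeader()
        header.add_line("##source=bsaqtl")
        for chrom, block in counts.groupby("chromosome", sort=False):
            header.contigs.add(str(chrom), length=int(block["position_bp"].max()) + 1)
        header.formats.add("AD", "R", "Integer",
                           "Allelic depths for the ref and alt alleles")
        header.add_sample(sample)
        with pysam.VariantFile(str(path), "w", header=header) as vcf:
            for row in counts.itertuples(index=False):
                rec = vcf.new_record(
                    contig=str(row.chromosome),
                    start=int(row.position_bp) - 1,
                    alleles=(str(row.dar_allele), str(row.cab_allele)),
                )
                rec.samples[sample]["AD"] = (int(row.dar_count), int(row.cab_count))
                vcf.write(rec)
    else:
        raise ConfigError(f"unknown format {format!r}")


def read_allele_counts(path, format: str = "tsv", sample: str | None = None,
                       cab_allele: str = "alt") -> pd.DataFrame:
    """Read an allele-count table from TSV or minimal VCF.

    ``cab_allele`` declares the orientation of a VCF: ``"alt"`` (default,
    the writer's convention — REF is the Darmor allele) or ``"ref"``.
    Malformed TSV rows are reported with their line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t")
        missing = set(COUNT_COLUMNS) - set(df.columns)
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        for col in ("cab_count", "dar_count"):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").fillna(-1) < 0]
            if len(bad):
                # +2: one for the header line, one for 1-based numbering
                raise DataError(f"{path}: negative or non-numeric {col} "
                                f"on line {int(bad[0]) + 2}")
        return df[COUNT_COLUMNS]
    if format == "vcf":
        if cab_allele not in ("ref", "alt"):
            raise ConfigError("cab_allele must be 'ref' or 'alt'")
        rows = []
        with pysam.VariantFile(str(path)) as vcf:
            if "AD" not in vcf.header.formats:
                raise FormatError(f"{path}: VCF lacks the AD FORMAT field")
            samples = list(vcf.header.samples)
            if not samples:
                raise FormatError(f"{path}: VCF has no samples")
            use = sample or samples[0]
            if use not in samples:
                raise FormatError(f"{path}: sample {use!r} not in VCF")
            for rec in vcf:
                ad = rec.samples[use].get("AD")
                if ad is None or ad[0] is None:
                    raise FormatError(f"{path}: record {rec.chrom}:{rec.pos} lacks AD")
                ref_n, alt_n = int(ad[0]), int(ad[1])
                ref_allele, alt_allele = rec.ref, rec.alts[0]
                if cab_allele == "alt":
                    cab_a, dar_a, cab_n, dar_n = alt_allele, ref_allele, alt_n, ref_n
                else:
                    cab_a, dar_a, cab_n, dar_n = ref_allele, alt_allele, ref_n, alt_n
                rows.append((rec.chrom, rec.pos, cab_a, dar_a, cab_n, dar_n))
        return pd.DataFrame(rows, columns=COUNT_COLUMNS)
    raise ConfigError(f"unknown format {format!r}")


def write_bed(intervals: pd.DataFrame, path) -> None:
    """Write QTL intervals as BED (0-based half-open, converted here only)."""
    with open(path, "w") as fh:
        for row in intervals.itertuples(index=False):
            name = f"peak@{int(row.peak_bp)}" if hasattr(row, "peak_bp") else "."
            fh.write(f"{row.chromosome}\t{int(row.start_bp) - 1}\t{int(row.end_bp)}\t{name}\n")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All knobs of the simulate-to-scan pipeline, with the study defaults."""

    # simulation
    n_chromosomes: int = 19
    variants_per_chromosome: int = 2000
    chromosome_length_bp: int = 30_000_000
    map_length_cm: float = 100.0
    n_lines: int = 720
    treatment: str = simulate.VERN
    bulk_fraction: float = 0.05
    mean_depth: float = 30.0
    error_rate: float = 0.001
    noise_sd: float = 8.0
    censor_days: int = 170
    # variant calling
    min_depth: int = 20
    min_alt_fraction: float = 0.95
    max_indel_length: int = 8
    # scan
    low_index_bound: float = 0.3
    top_fraction: float = 0.01
    window_size: int = 100
    window_step: int = 1
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        calling.CallingThresholds(self.min_depth, self.min_alt_fraction,
                                  self.max_indel_length)
        snpindex.ScanParameters(self.min_depth, self.low_index_bound,
                                self.top_fraction, self.window_size, self.window_step)
        if not 0 < self.bulk_fraction < 0.5:
            raise ConfigError("bulk_fraction must lie in (0, 0.5)")
        if self.treatment not in (simulate.VERN, simulate.NVERN):
            raise ConfigError(f"treatment must be VERN or NVERN, got {self.treatment!r}")
        if self.mean_depth <= 0 or not 0 <= self.error_rate < 0.5:
            raise ConfigError("invalid read-model parameters")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise FormatError(f"{path}: config must be a mapping")
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, outdir=None) -> dict:
    """Run simulate -> call-variants -> snp-index -> scan end to end.

    Returns a bundle with every intermediate (variant map, genotypes,
    phenotypes, bulks, counts, calls, SNP-index track, windows, intervals,
    threshold) and, when ``outdir`` is given, persists the tables plus a
    machine-readable run manifest.
    """
    config.validate()
    seed = config.seed

    variant_map = simulate.build_variant_map(
        config.n_chromosomes, config.variants_per_chromosome,
        config.chromosome_length_bp, config.map_length_cm,
        seed=stage_seed(seed, "map"),
    )
    genotypes = simulate.simulate_f2_genotypes(
        variant_map, config.n_lines, seed=stage_seed(seed, "genotypes")
    )
    chroms = list(dict.fromkeys(variant_map["chromosome"]))
    qtl_chrom = "A02" if "A02" in chroms else chroms[min(1, len(chroms) - 1)]
    model = simulate.snap_model_to_map(
        simulate.default_qtl_model(config.noise_sd, config.censor_days, qtl_chrom),
        variant_map,
    )
    phenotypes = simulate.simulate_phenotypes(
        genotypes, model, config.treatment, seed=stage_seed(seed, "phenotypes")
    )
    bulks = simulate.select_bulks(
        phenotypes, config.bulk_fraction, seed=stage_seed(seed, "bulks")
    )

    def counts(source, lines, stage):
        return simulate.simulate_allele_counts(
            source, lines, variant_map=variant_map, mean_depth=config.mean_depth,
            error_rate=config.error_rate, seed=stage_seed(seed, stage),
        )

    cab_parent = counts("cabriolet", None, "cab-parent")
    dar_parent = counts("darmor", None, "dar-parent")
    early = counts(genotypes, bulks.early_lines, "early-bulk")
    late = counts(genotypes, bulks.late_lines, "late-bulk")

    thresholds = calling.CallingThresholds(config.min_depth, config.min_alt_fraction,
                                           config.max_indel_length)
    cab_calls = calling.call_high_confidence(calling.counts_to_ref_alt(cab_parent), thresholds)
    dar_calls = calling.call_high_confidence(calling.counts_to_ref_alt(dar_parent), thresholds)
    informative = calling.subtract_background(cab_calls, dar_calls)

    records = snpindex.compute_snp_index(early, late, variants=informative,
                                         min_depth=config.min_depth)
    records = snpindex.delta_snp_index(records)
    records = snpindex.low_index_filter(records, config.low_index_bound)
    threshold, records = snpindex.percentile_threshold(records, config.top_fraction)
    windows = snpindex.window_scan(records, config.window_size, config.window_step)
    intervals = snpindex.call_qtl_intervals(windows, threshold)

    bundle = {
        "variant_map": variant_map,
        "genotypes": genotypes,
        "qtl_model": model,
        "phenotypes": phenotypes,
        "bulks": bulks,
        "counts_early": early,
        "counts_late": late,
        "variant_calls": informative,
        "snp_index": records,
        "threshold": threshold,
        "windows": windows,
        "qtl_intervals": intervals,
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        variant_map.to_csv(outdir / "variant_map.tsv", sep="\t", index=False)
        phenotypes.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"line_id": bulks.early_lines + bulks.late_lines,
             "bulk": ["early"] * len(bulks.early_lines) + ["late"] * len(bulks.late_lines)}
        ).to_csv(outdir / "bulks.tsv", sep="\t", index=False)
        write_allele_counts(early, outdir / "counts_early.tsv")
        write_allele_counts(late, outdir / "counts_late.tsv")
        informative.to_csv(outdir / "variant_calls.tsv", sep="\t", index=False)
        records.to_csv(outdir / "snp_index.tsv", sep="\t", index=False)
        windows.to_csv(outdir / "windows.tsv", sep="\t", index=False)
        intervals.to_csv(outdir / "qtl_intervals.tsv", sep="\t", index=False)
        if len(intervals):
            write_bed(intervals, outdir / "qtl_intervals.bed")
        manifest = {
            "tool": "bsaqtl",
            "config": config.to_dict(),
            "stage_seeds": {s: stage_seed(seed, s) for s in
                            ("map", "genotypes", "phenotypes", "bulks", "cab-parent",
                             "dar-parent", "early-bulk", "late-bulk")},
            "delta_threshold": threshold,
            "n_variants_called": int(len(informative)),
            "n_variants_scanned": int(len(records)),
            "n_windows": int(len(windows)),
            "n_intervals": int(len(intervals)),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return bundle
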