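"""SNP-index statistics and the sliding-window QTL genome scan.

At each informative variant the SNP index of a bulk is the proportion of its
reads carrying the Cabriolet (alternative) allele: 1 means every read is of
Cabriolet origin, 0 every read Darmor, 0.5 equal parental contribution.  The
ΔSNP index is the late-bulk index minus the early-bulk index, so values near
−1 indicate the early bulk fixed for Cabriolet and the late bulk fixed for
Darmor alleles.

The scan proceeds in the order the statistics are defined: per-variant
indices at positions covered to at least ``min_depth`` in *both* bulks, the
dual-bulk low-index exclusion (both indices < 0.3, an artefact of
sequencing error), a genome-wide nearest-rank top-1% threshold on |Δ|, a
100-variant sliding-window mean of Δ per chromosome, and finally merging of
consecutive above-threshold windows into QTL intervals with peak
coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

__all__ = [
    "ScanParameters",
    "compute_snp_index",
    "delta_snp_index",
    "low_index_filter",
    "percentile_threshold",
    "window_scan",
    "call_qtl_intervals",
]


@dataclass
class ScanParameters:
    min_depth: int = 20
    low_index_bound: float = 0.3
    top_fraction: float = 0.01
    window_size: int = 100
    window_step: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.top_fraction < 1:
            raise ConfigError("top_fraction must lie in (0, 1)")
        if self.window_size < 1 or self.window_step < 1:
            raise ConfigError("window_size and window_step must be >= 1")
        if self.min_depth < 1:
            raise ConfigError("min_depth must be >= 1")


def compute_snp_index(
    early_counts: pd.DataFrame,
    late_counts: pd.DataFrame,
    variants: pd.DataFrame | None = None,
    min_depth: int = 20,
) -> pd.DataFrame:
    """Per-variant SNP indices for the two bulks.

    The two count tables must cover the same positions in the same order
    (the alignment produced by the simulator or the readers).  If
    ``variants`` is given, positions are first restricted to that map.
    Variants with depth below ``min_depth`` in either bulk are dropped.
    """
    key = ["chromosome", "position_bp"]
    if len(early_counts) != len(late_counts) or not (
        early_counts[key].reset_index(drop=True).equals(late_counts[key].reset_index(drop=True))
    ):
        raise DataError("early and late count tables are not aligned")
    early = early_counts.reset_index(drop=True)
    late = late_counts.reset_index(drop=True)
    if variants is not None:
        wanted = pd.MultiIndex.from_frame(variants[key])
        mask = pd.MultiIndex.from_frame(early[key]).isin(wanted)
        early, late = early[mask].reset_index(drop=True), late[mask].reset_index(drop=True)

    depth_e = early["cab_count"].to_numpy() + early["dar_count"].to_numpy()
    depth_l = late["cab_count"].to_numpy() + late["dar_count"].to_numpy()
    keep = (depth_e >= min_depth) & (depth_l >= min_depth)
    out = pd.DataFrame(
        {
            "chromosome": early["chromosome"].to_numpy()[keep],
            "position_bp": early["position_bp"].to_numpy()[keep],
            "depth_early": depth_e[keep],
            "depth_late": depth_l[keep],
            "index_early": early["cab_count"].to_numpy()[keep] / depth_e[keep],
            "index_late": late["cab_count"].to_numpy()[keep] / depth_l[keep],
        }
    )
    return out


def delta_snp_index(records: pd.DataFrame) -> pd.DataFrame:
    """Attach ``delta`` = late-bulk index minus early-bulk index."""
    out = records.copy()
    out["delta"] = out["index_late"] - out["index_early"]
    return out


def low_index_filter(records: pd.DataFrame, bound: float = 0.3) -> pd.DataFrame:
    """Drop variants whose SNP index is below ``bound`` in *both* bulks.

    A variant is kept as soon as one bulk reaches the bound (the comparison
    is strict: indices exactly at the bound are retained).
    """
    drop = (records["index_early"] < bound) & (records["index_late"] < bound)
    return records[~drop].reset_index(drop=True)


def percentile_threshold(
    records: pd.DataFrame, top_fraction: float = 0.01
) -> tuple[float, pd.DataFrame]:
    """Genome-wide top-|Δ| threshold by the nearest-rank quantile.

    The threshold is the nearest-rank (1 − top_fraction) empirical quantile
    of |Δ| over all retained variants (ascending rank ⌈(1 − f)·n⌉); records
    with |Δ| at or above it are flagged ``above_threshold``, so when every
    |Δ| is equal the flagged set is the whole genome rather than empty.
    """
    if len(records) == 0:
        raise DataError("cannot take a percentile of an empty record set")
    if not 0 < top_fraction < 1:
        raise ConfigError("top_fraction must lie in (0, 1)")
    absd = np.abs(records["delta"].to_numpy())
    rank = math.ceil((1.0 - top_fraction) * absd.size)  # 1-based nearest rank
    threshold = float(np.sort(absd)[rank - 1])
    out = records.copy()
    out["above_threshold"] = absd >= threshold
    return threshold, out


def window_scan(records: pd.DataFrame, window_size: int = 100, step: int = 1) -> pd.DataFrame:
    """Mean Δ over sliding windows of ``window_size`` consecutive variants.

    Windows never span chromosomes; a chromosome with fewer than
    ``window_size`` retained variants contributes no windows.  Returns one
    row per window: ``chromosome``, ``start_bp``/``end_bp`` (positions of the
    first and last variant, 1-based inclusive), ``n_variants``,
    ``mean_delta``.
    """
    if window_size < 1:
        raise ConfigError("window_size must be >= 1")
    if step < 1:
        raise ConfigError("window_step must be >= 1")
    frames = []
    for chrom, block in records.groupby("chromosome", sort=False):
        block = block.sort_values("position_bp", kind="stable")
        n = len(block)
        if n < window_size:
            continue
        delta = block["delta"].to_numpy(dtype=float)
        pos = block["position_bp"].to_numpy()
        csum = np.concatenate([[0.0], np.cumsum(delta)])
        starts = np.arange(0, n - window_size + 1, step)
        frames.append(
            pd.DataFrame(
                {
                    "chromosome": chrom,
                    "start_bp": pos[starts],
                    "end_bp": pos[starts + window_size - 1],
                    "n_variants": window_size,
                    "mean_delta": (csum[starts + window_size] - csum[starts]) / window_size,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["chromosome", "start_bp", "end_bp", "n_variants", "mean_delta"]
        )
    return pd.concat(frames, ignore_index=True)


def call_qtl_intervals(windows: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Merge runs of consecutive above-threshold windows into QTL intervals.

    Windows are above threshold when |mean Δ| ≥ ``threshold``.  Maximal runs
    of such windows that are consecutive in the per-chromosome window order
    become one interval each; an interleaved below-threshold window splits a
    run even where the window footprints overlap in bp, so interval
    boundaries always track the scan statistic itself.  Each interval
    reports its peak window (largest |mean Δ|, leftmost on ties) as the
    window's bp midpoint, the peak mean Δ and its sign.
    """
    cols = ["chromosome", "start_bp", "end_bp", "peak_bp", "peak_mean_delta", "sign"]
    if len(windows) == 0:
        return pd.DataFrame(columns=cols)
    rows = []
    for chrom, block in windows.groupby("chromosome", sort=False):
        mean = block["mean_delta"].to_numpy(dtype=float)
        flagged = np.abs(mean) >= threshold
        if not flagged.any():
            continue
        idx = np.flatnonzero(flagged)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        for run in np.split(idx, breaks + 1):
            sub = block.iloc[run]
            peak_row = sub.iloc[int(np.argmax(np.abs(sub["mean_delta"].to_numpy())))]
            peak_delta = float(peak_row["mean_delta"])
            rows.append(
                {
                    "chromosome": chrom,
                    "start_bp": int(sub["start_bp"].iloc[0]),
                    "end_bp": int(sub["end_bp"].iloc[-1]),
                    "peak_bp": int((peak_row["start_bp"] + peak_row["end_bp"]) // 2),
                    "peak_mean_delta": peak_delta,
                    "sign": int(np.sign(peak_delta)),
                }
            )
    return pd.DataFrame(rows, columns=cols)
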