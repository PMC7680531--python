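"""High-confidence parental variant calling from per-position allele counts.

The pipeline's contract starts downstream of alignment: the input is a table
of per-position reference and alternative read counts for one parental
sample against the reference genome.  A position is retained as a
high-confidence variant when the read depth is at least 20 and at least 95%
of reads carry the alternative allele (both configurable), the alternative
allele differs from the reference, and any indel is shorter than 9 bp.

Because the reference genome (Darmor-*bzh*) is itself an imperfect proxy for
the Darmor parent, :func:`subtract_background` intersects the two parental
call sets and keeps only positions where the inferred Cabriolet allele
differs from the inferred Darmor allele, removing reference-vs-Darmor
background variation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

__all__ = [
    "CallingThresholds",
    "counts_to_ref_alt",
    "call_high_confidence",
    "subtract_background",
    "anchor_filter",
]

_COUNT_COLUMNS = ["chromosome", "position_bp", "ref_allele", "alt_allele",
                  "ref_count", "alt_count"]


@dataclass
class CallingThresholds:
    min_depth: int = 20
    min_alt_fraction: float = 0.95
    max_indel_length: int = 8  # indels of up to this many bp pass ("< 9 bp")

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ConfigError("min_depth must be >= 1")
        if not 0.5 < self.min_alt_fraction <= 1:
            raise ConfigError("min_alt_fraction must lie in (0.5, 1]")


def counts_to_ref_alt(counts: pd.DataFrame) -> pd.DataFrame:
    """Reorient a Cabriolet/Darmor allele-count table against the reference.

    The Darmor allele plays the role of the reference (the study's reference
    variety), the Cabriolet allele the alternative.
    """
    return pd.DataFrame(
        {
            "chromosome": counts["chromosome"],
            "position_bp": counts["position_bp"],
            "ref_allele": counts["dar_allele"],
            "alt_allele": counts["cab_allele"],
            "ref_count": counts["dar_count"],
            "alt_count": counts["cab_count"],
        }
    )


def _indel_length(ref: pd.Series, alt: pd.Series) -> np.ndarray:
    return np.abs(ref.str.len().to_numpy() - alt.str.len().to_numpy())


def call_high_confidence(
    counts: pd.DataFrame, thresholds: CallingThresholds | None = None
) -> pd.DataFrame:
    """Filter per-position ref/alt counts to high-confidence variant calls.

    Multi-allelic positions (several rows at one coordinate) are first
    reduced to the single most-supported alternative allele.  Returns a
    DataFrame with columns ``chromosome``, ``position_bp``, ``ref_allele``,
    ``alt_allele``, ``depth``, ``alt_fraction``.
    """
    thresholds = thresholds or CallingThresholds()
    missing = set(_COUNT_COLUMNS) - set(counts.columns)
    if missing:
        raise DataError(f"count table lacks columns: {sorted(missing)}")
    if (counts["ref_count"] < 0).any() or (counts["alt_count"] < 0).any():
        raise DataError("negative read counts")

    df = counts.loc[:, _COUNT_COLUMNS]
    if df.duplicated(["chromosome", "position_bp"]).any():
        df = (
            df.sort_values("alt_count", kind="stable")
            .drop_duplicates(["chromosome", "position_bp"], keep="last")
            .sort_index()
        )

    depth = df["ref_count"].to_numpy() + df["alt_count"].to_numpy()
    with np.errstate(invalid="ignore"):
        frac = np.where(depth > 0, df["alt_count"].to_numpy() / np.maximum(depth, 1), 0.0)
    keep = (
        (depth >= thresholds.min_depth)
        & (frac >= thresholds.min_alt_fraction)
        & (df["alt_allele"].to_numpy() != df["ref_allele"].to_numpy())
        & (_indel_length(df["ref_allele"], df["alt_allele"]) <= thresholds.max_indel_length)
    )
    out = df.loc[keep, ["chromosome", "position_bp", "ref_allele", "alt_allele"]].copy()
    out["depth"] = depth[keep]
    out["alt_fraction"] = frac[keep]
    return out.reset_index(drop=True)


def subtract_background(cab_vs_ref: pd.DataFrame, dar_vs_ref: pd.DataFrame) -> pd.DataFrame:
    """Keep positions where the inferred parental alleles differ.

    Each parent's allele is its called alternative where it varies from the
    reference and the reference allele otherwise; positions where both
    parents carry the same allele (including the same non-reference allele —
    reference-vs-Darmor background variation) are removed.

    Returns columns ``chromosome``, ``position_bp``, ``ref_allele``,
    ``cab_allele``, ``dar_allele``.
    """
    cab = cab_vs_ref[["chromosome", "position_bp", "ref_allele", "alt_allele"]].rename(
        columns={"alt_allele": "cab_alt"}
    )
    dar = dar_vs_ref[["chromosome", "position_bp", "ref_allele", "alt_allele"]].rename(
        columns={"alt_allele": "dar_alt"}
    )
    merged = cab.merge(
        dar, on=["chromosome", "position_bp"], how="outer", suffixes=("_cab", "_dar")
    )
    both = merged["ref_allele_cab"].notna() & merged["ref_allele_dar"].notna()
    if (merged.loc[both, "ref_allele_cab"] != merged.loc[both, "ref_allele_dar"]).any():
        raise DataError("inconsistent reference alleles between parental call sets")
    ref = merged["ref_allele_cab"].fillna(merged["ref_allele_dar"])
    cab_allele = merged["cab_alt"].fillna(ref)
    dar_allele = merged["dar_alt"].fillna(ref)
    out = pd.DataFrame(
        {
            "chromosome": merged["chromosome"],
            "position_bp": merged["position_bp"],
            "ref_allele": ref,
            "cab_allele": cab_allele,
            "dar_allele": dar_allele,
        }
    )
    out = out[out["cab_allele"] != out["dar_allele"]]
    return out.sort_values(["chromosome", "position_bp"], kind="stable").reset_index(drop=True)


def anchor_filter(calls: pd.DataFrame, anchored_chromosomes) -> pd.DataFrame:
    """Drop calls on unanchored scaffolds, preserving relative order."""
    anchored = set(anchored_chromosomes)
    return calls[calls["chromosome"].isin(anchored)].reset_index(drop=True)
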