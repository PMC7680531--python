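"""Coverage-based screen for homeologous exchanges (HEs) in an allopolyploid.

In *B. napus*, segments of one subgenome are occasionally replaced by the
homeologous segment of the other (A replacing C or vice versa).  In
resequencing data such an exchange appears as a reciprocal coverage change
across a run of homeologous gene pairs: the retained copy doubles in
relative coverage while the lost copy drops toward zero.

This module implements a deliberately simple screen: per-gene coverage is
normalised by its subgenome median, a pair is HE-like when one copy falls
below a low threshold while the other exceeds a high threshold, and maximal
same-direction runs of at least ``min_run`` HE-like pairs along a
chromosome are called as segments.  Segments can then be intersected with
QTL intervals to ask whether an exchange coincides with an association
signal.  Thresholds are screen parameters, not literature values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

__all__ = [
    "normalize_pair_coverage",
    "call_he_segments",
    "overlap_with_intervals",
]

_LONG_COLUMNS = {"pair_id", "subgenome", "chromosome", "order_index", "coverage"}


def normalize_pair_coverage(coverage: pd.DataFrame) -> pd.DataFrame:
    """Median-normalise per-gene coverage and pivot to one row per pair.

    ``coverage`` is long-form with columns ``pair_id``, ``subgenome`` (A or
    C), ``chromosome``, ``order_index``, ``coverage`` and optionally
    ``position_bp`` (carried through from the C-genome copy for coordinate
    work).  Each gene's coverage is divided by the median coverage of its
    subgenome, cancelling differences in sequencing effort.  The output has
    one row per pair, ordered by ``order_index`` along the C-genome
    chromosome, with columns ``cov_a`` and ``cov_c`` (normalised).
    """
    missing = _LONG_COLUMNS - set(coverage.columns)
    if missing:
        raise DataError(f"coverage table lacks columns: {sorted(missing)}")
    if (coverage["coverage"] < 0).any():
        raise DataError("negative coverage values")
    bad = ~coverage["subgenome"].isin(["A", "C"])
    if bad.any():
        raise DataError(f"subgenome labels must be 'A' or 'C', got "
                        f"{sorted(coverage.loc[bad, 'subgenome'].unique())}")

    df = coverage.copy()
    for sub, block in df.groupby("subgenome"):
        med = float(block["coverage"].median())
        if med <= 0:
            raise DataError(f"subgenome {sub!r} has non-positive median coverage")
        df.loc[block.index, "norm"] = block["coverage"] / med

    wide = df.pivot_table(index="pair_id", columns="subgenome", values="norm").rename(
        columns={"A": "cov_a", "C": "cov_c"}
    )
    if wide[["cov_a", "cov_c"]].isna().any().any():
        raise DataError("every pair needs one A-genome and one C-genome gene")
    c_copy = df[df["subgenome"] == "C"].set_index("pair_id")
    wide["chromosome"] = c_copy["chromosome"]
    wide["order_index"] = c_copy["order_index"]
    if "position_bp" in df.columns:
        wide["position_bp"] = c_copy["position_bp"]
    out = wide.reset_index().sort_values(["chromosome", "order_index"], kind="stable")
    return out.reset_index(drop=True)


def call_he_segments(
    pairs: pd.DataFrame,
    low: float = 0.25,
    high: float = 1.5,
    min_run: int = 3,
) -> pd.DataFrame:
    """Call HE segments as runs of reciprocally unbalanced gene pairs.

    A pair is HE-like in direction ``A-replaces-C`` when the A copy's
    normalised coverage exceeds ``high`` while the C copy's falls below
    ``low``, and vice versa.  Maximal runs of at least ``min_run``
    consecutive (by ``order_index``) same-direction pairs become segments.
    Returns one row per segment with first/last order indices (and bp
    coordinates when ``position_bp`` is available), direction and the mean
    normalised coverages.
    """
    if not 0 <= low < high:
        raise ConfigError("need 0 <= low < high")
    if min_run < 1:
        raise ConfigError("min_run must be >= 1")
    has_bp = "position_bp" in pairs.columns
    cols = ["chromosome", "first_index", "last_index", "n_pairs", "direction",
            "mean_cov_a", "mean_cov_c"] + (["start_bp", "end_bp"] if has_bp else [])
    rows = []
    for chrom, block in pairs.groupby("chromosome", sort=False):
        block = block.sort_values("order_index", kind="stable")
        a = block["cov_a"].to_numpy(dtype=float)
        c = block["cov_c"].to_numpy(dtype=float)
        state = np.where((a > high) & (c < low), 1, np.where((c > high) & (a < low), -1, 0))
        n = state.size
        i = 0
        while i < n:
            if state[i] == 0:
                i += 1
                continue
            j = i
            while j + 1 < n and state[j + 1] == state[i]:
                j += 1
            if j - i + 1 >= min_run:
                seg = block.iloc[i: j + 1]
                row = {
                    "chromosome": chrom,
                    "first_index": int(seg["order_index"].iloc[0]),
                    "last_index": int(seg["order_index"].iloc[-1]),
                    "n_pairs": j - i + 1,
                    "direction": "A-replaces-C" if state[i] == 1 else "C-replaces-A",
                    "mean_cov_a": float(seg["cov_a"].mean()),
                    "mean_cov_c": float(seg["cov_c"].mean()),
                }
                if has_bp:
                    row["start_bp"] = int(seg["position_bp"].min())
                    row["end_bp"] = int(seg["position_bp"].max())
                rows.append(row)
            i = j + 1
    return pd.DataFrame(rows, columns=cols)


def overlap_with_intervals(
    segments: pd.DataFrame,
    intervals: pd.DataFrame,
    segment_cols: tuple[str, str] = ("start_bp", "end_bp"),
    interval_cols: tuple[str, str] = ("start_bp", "end_bp"),
) -> pd.DataFrame:
    """Intersect HE segments with QTL intervals (1-based inclusive).

    Both tables must carry a ``chromosome`` column plus 1-based inclusive
    start/end columns; shared boundaries count as overlap, adjacency does
    not.  Returns one row per segment with ``overlaps`` and, when true, the
    intersection coordinates of the first overlapping interval.
    """
    for df, (s, e), what in ((segments, segment_cols, "segment"),
                             (intervals, interval_cols, "interval")):
        if len(df) and ((df[s] < 1).any() or (df[s] > df[e]).any()):
            raise DataError(
                f"{what} coordinates must be 1-based inclusive with start <= end"
            )
    rows = []
    for _, seg in segments.iterrows():
        s1, e1 = int(seg[segment_cols[0]]), int(seg[segment_cols[1]])
        hit = None
        for _, iv in intervals.iterrows():
            if iv["chromosome"] != seg["chromosome"]:
                continue
            s2, e2 = int(iv[interval_cols[0]]), int(iv[interval_cols[1]])
            lo, hi = max(s1, s2), min(e1, e2)
            if lo <= hi:
                hit = (lo, hi)
                break
        rows.append(
            {
                "chromosome": seg["chromosome"],
                "start_bp": s1,
                "end_bp": e1,
                "overlaps": hit is not None,
                "overlap_start_bp": hit[0] if hit else pd.NA,
                "overlap_end_bp": hit[1] if hit else pd.NA,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chromosome", "start_bp", "end_bp", "overlaps",
                 "overlap_start_bp", "overlap_end_bp"],
    )
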