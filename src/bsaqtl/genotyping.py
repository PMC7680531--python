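"""KASP-style marker validation analyses for the bulked F2 lines.

Individual lines from the DNA bulks are genotyped at targeted SNP markers,
yielding three-state calls (Cab / Dar homozygote, Het) plus undetermined
(NA).  This module summarises genotype proportions per bulk, classifies
lines by their two-marker genotype (nine classes, including the homozygous
recombinants Cab:Dar and Dar:Cab), compares per-line homozygosity between
two markers with an exact matched-pairs sign test, and compares flowering
times between genotype classes with pairwise two-sided rank-sum tests
summarised as a compact letter display.
"""

from __future__ import annotations

import itertools
import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError

__all__ = [
    "CALLS",
    "summarize_bulk_genotypes",
    "classify_two_marker_genotypes",
    "paired_homozygosity_test",
    "rank_sum_compare",
    "mann_whitney_exact",
]

CALLS = ("Cab", "Dar", "Het", "NA")
_HOMOZYGOUS = {"Cab", "Dar"}


def _check_calls(calls: pd.DataFrame) -> pd.DataFrame:
    required = {"line_id", "marker_id", "call"}
    missing = required - set(calls.columns)
    if missing:
        raise DataError(f"marker call table lacks columns: {sorted(missing)}")
    bad = ~calls["call"].isin(CALLS)
    if bad.any():
        raise DataError(f"unknown genotype calls: {sorted(calls.loc[bad, 'call'].unique())}")
    if calls.duplicated(["line_id", "marker_id"]).any():
        raise DataError("more than one call per (line, marker)")
    return calls


def _restrict_to_bulk(calls: pd.DataFrame, bulk) -> pd.DataFrame:
    """``bulk`` is either a label matched against a ``bulk`` column or an
    iterable of line ids."""
    if bulk is None:
        return calls
    if isinstance(bulk, str):
        if "bulk" not in calls.columns:
            raise DataError("bulk label given but call table has no 'bulk' column")
        return calls[calls["bulk"] == bulk]
    return calls[calls["line_id"].isin(set(bulk))]


def summarize_bulk_genotypes(calls: pd.DataFrame, bulk=None) -> pd.DataFrame:
    """Genotype proportions per marker over one bulk's non-NA calls.

    Returns one row per marker with ``p_cab``, ``p_dar``, ``p_het`` (summing
    to 1 over called lines), ``n_called`` and ``n_na``.  A marker with no
    determined call in the bulk is an error.
    """
    calls = _check_calls(calls)
    sub = _restrict_to_bulk(calls, bulk)
    if len(sub) == 0:
        raise DataError("bulk selects no marker calls")
    rows = []
    for marker, block in sub.groupby("marker_id", sort=False):
        determined = block[block["call"] != "NA"]
        n = len(determined)
        if n == 0:
            raise DataError(f"marker {marker!r} has no determined calls in this bulk")
        counts = determined["call"].value_counts()
        rows.append(
            {
                "marker_id": marker,
                "p_cab": counts.get("Cab", 0) / n,
                "p_dar": counts.get("Dar", 0) / n,
                "p_het": counts.get("Het", 0) / n,
                "n_called": n,
                "n_na": int((block["call"] == "NA").sum()),
            }
        )
    return pd.DataFrame(rows)


def classify_two_marker_genotypes(
    calls: pd.DataFrame, marker_a: str, marker_b: str
) -> pd.DataFrame:
    """Label each line by its ordered two-marker genotype, e.g. ``"Cab:Dar"``.

    Lines with an NA at either marker are labelled ``"unclassified"``.  The
    homozygous recombinant classes are ``Cab:Dar`` and ``Dar:Cab``.
    """
    calls = _check_calls(calls)
    present = set(calls["marker_id"])
    for marker in (marker_a, marker_b):
        if marker not in present:
            raise DataError(f"unknown marker {marker!r}")
    wide = (
        calls[calls["marker_id"].isin([marker_a, marker_b])]
        .pivot(index="line_id", columns="marker_id", values="call")
        .reindex(columns=[marker_a, marker_b])
    )
    a, b = wide[marker_a], wide[marker_b]
    determined = a.isin(_HOMOZYGOUS | {"Het"}) & b.isin(_HOMOZYGOUS | {"Het"})
    label = np.where(determined, a.astype(str) + ":" + b.astype(str), "unclassified")
    return pd.DataFrame({"line_id": wide.index, "class_label": label}).reset_index(drop=True)


class SignTestResult(NamedTuple):
    n_a_only: int          # homozygous at marker_a but not marker_b
    n_b_only: int
    n_discordant: int
    pvalue: float


def paired_homozygosity_test(
    calls: pd.DataFrame, marker_a: str, marker_b: str, bulk=None
) -> SignTestResult:
    """Exact matched-pairs comparison of homozygosity between two markers.

    Each line contributes a binary indicator per marker (1 when the call is
    Cab or Dar).  On paired binary data the Wilcoxon matched-pairs procedure
    reduces to the exact two-sided sign (binomial) test on the discordant
    pairs; concordant pairs carry no information and are dropped.  With zero
    discordant pairs the p-value is 1.
    """
    classes = classify_two_marker_genotypes(_restrict_to_bulk(_check_calls(calls), bulk),
                                            marker_a, marker_b)
    pairs = classes[classes["class_label"] != "unclassified"]["class_label"]
    a_hom = pairs.str.split(":").str[0].isin(_HOMOZYGOUS)
    b_hom = pairs.str.split(":").str[1].isin(_HOMOZYGOUS)
    n_a_only = int((a_hom & ~b_hom).sum())
    n_b_only = int((~a_hom & b_hom).sum())
    n = n_a_only + n_b_only
    p = 1.0 if n == 0 else float(stats.binomtest(n_a_only, n, 0.5, alternative="two-sided").pvalue)
    return SignTestResult(n_a_only, n_b_only, n, p)


def mann_whitney_exact(a, b) -> tuple[float, float]:
    """Exact two-sided Mann–Whitney test by full enumeration, tie-safe.

    Enumerates every assignment of the pooled observations to the two group
    sizes; U is computed from midranks, so tied data are handled exactly.
    The two-sided p-value is the null probability of a U at least as far
    from its mean mn/2 as observed.  Intended for small groups (the number
    of assignments is C(m+n, m)).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    m, n = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:m].sum() - m * (m + 1) / 2.0
    center = m * n / 2.0
    hits = total = 0
    for subset in itertools.combinations(range(m + n), m):
        u = ranks[list(subset)].sum() - m * (m + 1) / 2.0
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            hits += 1
    return float(u_obs), hits / total


_EXACT_MAX = 8  # both groups at or below this size use full enumeration


def rank_sum_compare(groups: dict, alpha: float = 0.05):
    """Pairwise two-sided rank-sum tests plus a compact letter display.

    ``groups`` maps group label to an array of flowering times.  Pairs where
    both groups have at most 8 observations use exact enumeration
    (:func:`mann_whitney_exact`); larger pairs use the normal approximation
    with tie correction and continuity correction.  Empty groups are dropped
    with a warning.  Returns ``(pvalues, letters)``: a symmetric DataFrame of
    p-values and a dict mapping group label to its letter string, where
    groups sharing a letter are not significantly different at ``alpha``.
    """
    if not 0 < alpha < 1:
        raise ConfigError("alpha must lie in (0, 1)")
    clean = {}
    for name, values in groups.items():
        arr = np.asarray(values, dtype=float)
        if arr.size == 0:
            warnings.warn(f"group {name!r} has no observations and is excluded", stacklevel=2)
            continue
        clean[name] = arr
    if len(clean) < 2:
        raise DataError("need at least two non-empty groups")

    names = list(clean)
    pmat = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for i, j in itertools.combinations(range(len(names)), 2):
        a, b = clean[names[i]], clean[names[j]]
        if a.size <= _EXACT_MAX and b.size <= _EXACT_MAX:
            _, p = mann_whitney_exact(a, b)
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                         method="asymptotic").pvalue)
        pmat.iloc[i, j] = pmat.iloc[j, i] = p

    letters = _compact_letter_display(clean, pmat, alpha)
    return pmat, letters


def _compact_letter_display(groups: dict, pmat: pd.DataFrame, alpha: float) -> dict:
    """Greedy letters over groups sorted by median: each maximal run of
    mutually non-significant groups shares one letter."""
    order = sorted(groups, key=lambda g: np.median(groups[g]))
    runs = []
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and all(
            pmat.loc[order[k], order[j + 1]] >= alpha for k in range(i, j + 1)
        ):
            j += 1
        runs.append((i, j))
        i = i + 1 if j + 1 < len(order) else j + 1
    # drop runs nested inside another
    maximal = [r for r in runs if not any(o[0] <= r[0] and r[1] <= o[1] and o != r for o in runs)]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in order}
    for letter, (lo, hi) in zip(alphabet, maximal):
        for g in order[lo: hi + 1]:
            letters[g] += letter
    return letters
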