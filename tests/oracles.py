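"""Independent brute-force reference implementations used only by tests.

Each oracle is written as explicit loops over sorted copies, deliberately
avoiding the vectorised code paths of the package it checks.
"""

import itertools
import math


def windows_bruteforce(records, window_size, step):
    """(chromosome, start_bp, end_bp, mean_delta) per window, by plain loops."""
    out = []
    by_chrom = {}
    for rec in records:  # rec: (chromosome, position_bp, delta)
        by_chrom.setdefault(rec[0], []).append(rec)
    for chrom, recs in by_chrom.items():
        recs = sorted(recs, key=lambda r: r[1])
        i = 0
        while i + window_size <= len(recs):
            chunk = recs[i: i + window_size]
            mean = sum(r[2] for r in chunk) / window_size
            out.append((chrom, chunk[0][1], chunk[-1][1], mean))
            i += step
    return out


def nearest_rank_threshold(abs_deltas, top_fraction):
    """Nearest-rank (1 - f) quantile of the absolute deltas."""
    ordered = sorted(abs_deltas)
    rank = math.ceil((1.0 - top_fraction) * len(ordered))
    return ordered[rank - 1]


def merge_flagged_runs(window_means, threshold):
    """Segments of consecutive above-threshold windows: list of (first, last)
    window indices per run, for a single chromosome's ordered window means."""
    runs = []
    current = None
    for i, m in enumerate(window_means):
        if abs(m) >= threshold:
            if current is None:
                current = [i, i]
            else:
                current[1] = i
        else:
            if current is not None:
                runs.append(tuple(current))
                current = None
    if current is not None:
        runs.append(tuple(current))
    return runs


def sign_test_p(k, n):
    """Exact two-sided sign-test p-value for k successes of n at p=1/2,
    via the minimum-likelihood tail-sum definition."""
    if n == 0:
        return 1.0
    pmf = [math.comb(n, j) / 2.0**n for j in range(n + 1)]
    return min(1.0, sum(p for p in pmf if p <= pmf[k] + 1e-12))


def mwu_enumeration_p(a, b):
    """Exact two-sided Mann-Whitney p by direct pairwise-count enumeration
    (no ranks), tie-safe."""
    pooled = list(a) + list(b)
    m = len(a)

    def ustat(group_a, group_b):
        u = 0.0
        for x in group_a:
            for y in group_b:
                if x > y:
                    u += 1.0
                elif x == y:
                    u += 0.5
        return u

    center = m * len(b) / 2.0
    u_obs = ustat(a, b)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), m):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        total += 1
        if abs(ustat(ga, gb) - center) >= abs(u_obs - center) - 1e-12:
            hits += 1
    return hits / total


def intervals_overlap_bruteforce(segments, intervals):
    """All-pairs 1-based inclusive overlap test: list of bools per segment."""
    flags = []
    for chrom_s, s1, e1 in segments:
        hit = False
        for chrom_i, s2, e2 in intervals:
            if chrom_s == chrom_i and max(s1, s2) <= min(e1, e2):
                hit = True
                break
        flags.append(hit)
    return flags
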