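"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected result by the most literal route available
(exact integer arithmetic, naive double loops, textbook formulas applied
step by step) and never calls the implementation path it checks.
"""

import math

import numpy as np


def exact_binomial_sf_table(n: int, p: float) -> np.ndarray:
    """P(X >= k) for k = 0..n, X ~ Binomial(n, p), by exact summation.

    p is interpreted as the exact dyadic rational the float represents, so
    every pmf term C(n,k) a^k (d-a)^(n-k) / d^n is an exact integer ratio;
    the suffix sums are exact and only the final conversion to float rounds.
    """
    a, den = float(p).as_integer_ratio()  # den is a power of two
    b = den - a
    shift = den.bit_length() - 1
    apow = [1] * (n + 1)
    bpow = [1] * (n + 1)
    for j in range(1, n + 1):
        apow[j] = apow[j - 1] * a
        bpow[j] = bpow[j - 1] * b
    total_shift = shift * n
    out = [0.0] * (n + 1)
    acc = 0
    for k in range(n, -1, -1):
        acc += math.comb(n, k) * apow[k] * bpow[n - k]
        bl = acc.bit_length()
        sh = max(bl - 80, 0)
        try:
            out[k] = math.ldexp(acc >> sh, sh - total_shift)
        except OverflowError:  # only for p outside [0,1]; not reachable here
            raise
    return np.minimum(np.array(out), 1.0)


def bh_step_up(pvalues) -> np.ndarray:
    """Benjamini-Hochberg by the literal step-up definition.

    q_(i) = min_{j >= i} (p_(j) * m / j), capped at 1, mapped back to the
    input order.
    """
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def naive_overlap_matrix(universe_df, tracks) -> np.ndarray:
    """SNP x sample overlap matrix by a naive double loop over point tests."""
    from snpenrich.tracks import snp_overlaps

    out = np.zeros((len(universe_df), len(tracks)), dtype=np.uint8)
    for i, (chrom, pos) in enumerate(zip(universe_df["chrom"], universe_df["pos"])):
        for j, t in enumerate(tracks):
            out[i, j] = snp_overlaps((chrom, int(pos)), t.intervals)
    return out


def naive_complete_linkage_cophenetic(data: np.ndarray) -> np.ndarray:
    """Cophenetic distance matrix from a naive O(n^3) complete-linkage loop."""
    n = len(data)
    clusters = {i: [i] for i in range(n)}
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(np.linalg.norm(data[i] - data[j]))

    def complete(ca, cb):
        return max(dist[tuple(sorted((x, y)))]
                   for x in clusters[ca] for y in clusters[cb])

    coph = np.zeros((n, n))
    next_id = n
    while len(clusters) > 1:
        ids = sorted(clusters)
        best = None
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                d = complete(ids[ai], ids[bi])
                if best is None or d < best[0]:
                    best = (d, ids[ai], ids[bi])
        d, ca, cb = best
        for x in clusters[ca]:
            for y in clusters[cb]:
                coph[x, y] = coph[y, x] = d
        clusters[next_id] = clusters.pop(ca) + clusters.pop(cb)
        next_id += 1
    return coph


def decile_bin_by_rank(values) -> np.ndarray:
    """Expected decile bins for all-distinct values: from sorted rank.

    With n distinct values, the k-th smallest (1-based) must land in decile
    ceil(10 * k / n) under equal-mass empirical-decile binning.  Only valid
    when n is a multiple of 10 and all values are distinct.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    assert n % 10 == 0 and len(np.unique(v)) == n
    ranks = np.argsort(np.argsort(v)) + 1
    return np.ceil(10 * ranks / n).astype(int)
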