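"""Independent reference implementations used as test oracles.

These deliberately avoid the code paths they check: structure enumeration
and a right-anchored recursion for the folding DP, a naive substring scan
for the mapper, an O(n^3) pairwise-average UPGMA for the clustering, and a
direct window scorer for the target scan.
"""

from functools import lru_cache

import numpy as np

from hexamir._seq import pair_score, revcomp_dna


def enumerate_structures(seq, min_loop=3):
    """Every pseudoknot-free pair set (loop >= 3) as a list of (i, j) pairs."""
    n = len(seq)

    def rec(i, j):
        if j - i < min_loop + 1:
            yield []
            return
        yield from rec(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if pair_score(seq[i], seq[k]) > 0:
                for left in rec(i + 1, k - 1):
                    for right in rec(k + 1, j):
                        yield [(i, k)] + left + right

    if n == 0:
        yield []
        return
    yield from rec(0, n - 1)


def enumeration_best_score(seq, min_loop=3):
    return max(
        (sum(pair_score(seq[i], seq[j]) for i, j in pairs)
         for pairs in enumerate_structures(seq, min_loop)),
        default=0,
    )


def right_anchored_best(seq, min_loop=3):
    """Max pairing score via a recursion anchored at the right end."""

    @lru_cache(maxsize=None)
    def best(i, j):
        if j - i < min_loop + 1:
            return 0
        out = best(i, j - 1)
        for k in range(i, j - min_loop):
            s = pair_score(seq[k], seq[j])
            if s:
                out = max(out, best(i, k - 1) + s + best(k + 1, j - 1))
        return out

    return best(0, len(seq) - 1) if seq else 0


def naive_scan(read, contigs):
    """All forward/reverse exact occurrences by direct O(n*m) scanning."""
    hits = set()
    q = read.upper().replace("U", "T")
    rc = revcomp_dna(q)
    for rec in contigs:
        seq = rec.seq.upper().replace("U", "T")
        for i in range(len(seq) - len(q) + 1):
            if seq[i : i + len(q)] == q:
                hits.add((rec.id, i, i + len(q), "+"))
            if seq[i : i + len(q)] == rc:
                hits.add((rec.id, i, i + len(q), "-"))
    return sorted(hits)


def brute_upgma_cophenetic(D):
    """Cophenetic distance matrix from a direct UPGMA over distance matrix D.

    Cluster distance = arithmetic mean of all pairwise original distances;
    at each step the closest pair of clusters merges at that distance.
    """
    n = len(D)
    clusters = [[i] for i in range(n)]
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean([D[i][j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i][j] = coph[j][i] = d
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return coph


def uncentered_distance_matrix(X):
    n = len(X)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = float(np.sum(X[i] * X[j]))
            den = np.sqrt(float(np.sum(X[i] ** 2)) * float(np.sum(X[j] ** 2)))
            D[i][j] = 1.0 - num / den
    np.fill_diagonal(D, 0.0)
    return D


TARGET_CORE = set(range(2, 14))


def ungapped_window_penalty(mirna, site):
    """Direct per-position expectation penalty of an equal-length window."""
    lm = len(mirna)
    total = 0.0
    for i in range(1, lm + 1):
        a, b = mirna[i - 1], site[lm - i]
        duo = a + b
        if duo in ("AU", "UA", "GC", "CG"):
            p = 0.0
        elif duo in ("GU", "UG"):
            p = 0.5
        else:
            p = 1.0
        total += 2 * p if i in TARGET_CORE else p
    return total
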