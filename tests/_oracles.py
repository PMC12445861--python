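"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results through the simplest possible route
(exhaustive dynamic programming, literal re-implementation of the greedy
rule) and share no code with the package implementation.
"""

from __future__ import annotations


def dp_identity(a: str, b: str) -> float:
    """Exhaustive DP for global end-to-end identity.

    State value is the lexicographic pair (matches, -alignment_length);
    maximising it maximises matches and, among those, minimises the
    alignment length. Identity = matches / alignment_length.
    """
    m, n = len(a), len(b)
    dp = [[None] * (n + 1) for _ in range(m + 1)]
    dp[0][0] = (0, 0)
    for i in range(m + 1):
        for j in range(n + 1):
            if i == 0 and j == 0:
                continue
            cands = []
            if i > 0 and j > 0:
                mm, neg = dp[i - 1][j - 1]
                cands.append((mm + (a[i - 1] == b[j - 1]), neg - 1))
            if i > 0:
                mm, neg = dp[i - 1][j]
                cands.append((mm, neg - 1))
            if j > 0:
                mm, neg = dp[i][j - 1]
                cands.append((mm, neg - 1))
            dp[i][j] = max(cands)
    matches, neg_len = dp[m][n]
    return matches / (-neg_len)


def brute_greedy_cluster(records, threshold: float):
    """Literal simulation of the abundance-ranked greedy rule.

    ``records`` is any iterable of objects with read_id / sequence /
    abundance attributes. Uses :func:`dp_identity`, not the package's
    aligner. Returns (centroid ids in creation order, membership dict).
    """
    order = sorted(records, key=lambda r: (-r.abundance, r.read_id))
    centroids, membership = [], {}
    for rec in order:
        for cen in centroids:
            if dp_identity(rec.sequence, cen.sequence) >= threshold:
                membership[rec.read_id] = cen.read_id
                break
        else:
            centroids.append(rec)
            membership[rec.read_id] = rec.read_id
    return [c.read_id for c in centroids], membership
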