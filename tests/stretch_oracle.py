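"""Brute-force reference for gap-tolerant outlier-stretch assembly.

Enumerates every candidate interval [i, j] of a boolean flag vector and
keeps those that literally satisfy the stretch rule — both ends flagged
and no two consecutive unflagged positions inside — then takes the
containment-maximal ones and applies the minimum flagged-window count.
Deliberately quadratic and independent of the package's linear scan.
"""

from __future__ import annotations


def valid_interval(flags, i, j):
    if not (flags[i] and flags[j]):
        return False
    for k in range(i, j):
        if not flags[k] and not flags[k + 1]:
            return False
    return True


def brute_force_stretches(flags, min_outliers):
    """All maximal valid intervals with >= min_outliers flagged positions,
    as (start, end, n_flagged) tuples in positional order."""
    n = len(flags)
    candidates = [
        (i, j) for i in range(n) for j in range(i, n)
        if valid_interval(flags, i, j)
    ]
    maximal = [
        (i, j) for (i, j) in candidates
        if not any((a <= i and j <= b and (a, b) != (i, j))
                   for (a, b) in candidates)
    ]
    out = []
    for i, j in sorted(maximal):
        n_flagged = sum(flags[i:j + 1])
        if n_flagged >= min_outliers:
            out.append((i, j, n_flagged))
    return out
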