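"""Compiled inner loops for template-match counting.

Pair counting is O(n^2) with a short-circuit on the first coordinate
that exceeds the tolerance; for tolerances of practical size most
pairs fail immediately, so the loops run close to one comparison per
pair.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def count_template_matches(x, m, r):
    """Ordered-pair match counts for sample entropy.

    Templates of length m and m+1 both start at positions
    0 .. n-m-1 (0-based), so the two orders are counted over the same
    index set.  Self-pairs (i == j) are excluded; a distance exactly
    equal to r counts as a match.  Returns (a, b): ordered (m+1)- and
    m-template match counts.
    """
    n = x.shape[0]
    nt = n - m
    a = 0
    b = 0
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            matched = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) > r:
                    matched = False
                    break
            if matched:
                b += 2
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 2
    return a, b


@njit(cache=True)
def mean_log_match_fraction(x, m, r):
    """Phi^m(r): mean over i of log of the self-inclusive match fraction.

    Used by approximate entropy; templates run over all n-m+1 start
    positions and the i == j self-match is included, so every fraction
    is at least 1/(n-m+1) and the logarithm is always defined.
    Returns (phi, total_matches).
    """
    n = x.shape[0]
    nt = n - m + 1
    total = 0
    acc = 0.0
    for i in range(nt):
        c = 0
        for j in range(nt):
            matched = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) > r:
                    matched = False
                    break
            if matched:
                c += 1
        total += c
        acc += np.log(c / nt)
    return acc / nt, total
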