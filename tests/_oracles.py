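"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as plain per-row Python loops so it
shares no code path with the vectorized implementation it checks.
"""
from __future__ import annotations


def brute_counts(values, h):
    """Marginal counts per list and the common count at one threshold."""
    n = len(values)
    L = len(values[0])
    marginals = [0] * L
    common = 0
    for row in values:
        all_called = True
        for l in range(L):
            if row[l] <= h:
                marginals[l] += 1
            else:
                all_called = False
        if all_called:
            common += 1
    return marginals, common


def brute_curve(values, h_values):
    """Per-threshold (marginals, common, expected, T) by row enumeration."""
    n = len(values)
    L = len(values[0])
    out = []
    for h in h_values:
        marginals, common = brute_counts(values, h)
        expected = 1.0
        for m in marginals:
            expected *= m
        expected /= n ** (L - 1)
        T = common / expected if expected > 0 else None
        out.append((marginals, common, expected, T))
    return out


def brute_cells(values, h):
    """Tally of the 2**L significance patterns at one threshold."""
    L = len(values[0])
    cells = [0] * (2**L)
    for row in values:
        pattern = 0
        for l in range(L):
            if row[l] <= h:
                pattern |= 1 << l
        cells[pattern] += 1
    return cells
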