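"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations


def smith_waterman_affine(a: str, b: str, match: float = 1.0, mismatch: float = -2.0,
                          open_gap: float = -5.0, extend_gap: float = -2.0) -> float:
    """Full Gotoh dynamic-programming local alignment score.

    A gap of length L costs ``open_gap + (L - 1) * extend_gap`` (the first
    gapped column pays the open score).  Cell-by-cell, no heuristics.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    h_prev = [0.0] * (m + 1)
    f_prev = [NEG] * (m + 1)
    best = 0.0
    for i in range(1, n + 1):
        h_cur = [0.0] * (m + 1)
        f_cur = [NEG] * (m + 1)
        e = NEG
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            e = max(h_cur[j - 1] + open_gap, e + extend_gap)
            f_cur[j] = max(h_prev[j] + open_gap, f_prev[j] + extend_gap)
            h = max(0.0, h_prev[j - 1] + s, e, f_cur[j])
            h_cur[j] = h
            if h > best:
                best = h
        h_prev, f_prev = h_cur, f_cur
    return best


def hamming_identity_percent(a: str, b: str) -> float:
    """Per-site identity of two equal-length sequences, as a percentage."""
    assert len(a) == len(b)
    return 100.0 * sum(1 for x, y in zip(a, b) if x == y) / len(a)
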