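"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately naive: plain-Python dynamic programming and sorting,
no shared code with the package's alignment or statistics paths.
"""
from __future__ import annotations


def n50_bruteforce(lengths) -> int:
    """N50 by definition: descending cumulative sum, first half-total cross."""
    lens = sorted(lengths, reverse=True)
    total = sum(lens)
    acc = 0
    for length in lens:
        acc += length
        if 2 * acc >= total:
            return length
    raise ValueError("empty input")


def smith_waterman_score(
    a: str,
    b: str,
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = 5,
    gap_extend: int = 2,
) -> float:
    """Optimal local alignment score, affine gaps (gap of g costs open+g*extend).

    Exhaustive O(len(a)*len(b)) dynamic programming over three state
    matrices; returns the maximal cell of the match/mismatch matrix.
    """
    n, m = len(a), len(b)
    neg = float("-inf")
    open_cost = gap_open + gap_extend
    h_prev = [0.0] * (m + 1)
    e_prev = [neg] * (m + 1)  # gap in a (horizontal)
    f_prev = [neg] * (m + 1)  # gap in b (vertical)
    best = 0.0
    for i in range(1, n + 1):
        h_cur = [0.0] * (m + 1)
        e_cur = [neg] * (m + 1)
        f_cur = [neg] * (m + 1)
        ai = a[i - 1]
        for j in range(1, m + 1):
            e_cur[j] = max(h_cur[j - 1] - open_cost, e_cur[j - 1] - gap_extend)
            f_cur[j] = max(h_prev[j] - open_cost, f_prev[j] - gap_extend)
            score = match if ai == b[j - 1] else mismatch
            h = max(0.0, h_prev[j - 1] + score, e_cur[j], f_cur[j])
            h_cur[j] = h
            if h > best:
                best = h
        h_prev, e_prev, f_prev = h_cur, e_cur, f_cur
    return best


def kmer_set(seq: str, k: int) -> set[str]:
    comp = str.maketrans("ACGT", "TGCA")
    rc = seq.translate(comp)[::-1]
    n = len(seq)
    out = set()
    for i in range(n - k + 1):
        fwd = seq[i : i + k]
        out.add(min(fwd, rc[n - i - k : n - i]))
    return out
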