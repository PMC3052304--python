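"""Independent reference implementations used only as test oracles.

Deliberately naive: plain-Python quadratic dynamic programming and
linear-scan string search, sharing no code with the package's engine.
"""

from __future__ import annotations

NEG = -(10 ** 9)


def sw_local_score(query: str, ref: str, match: int = 1, mismatch: int = 3,
                   gap_open: int = 5, gap_extend: int = 2) -> int:
    """Unbanded affine-gap Smith-Waterman best local score.

    Gap of length L costs gap_open + L * gap_extend; N never matches.
    """
    m, n = len(query), len(ref)
    goe = gap_open + gap_extend
    H_prev = [0] * (n + 1)
    E_prev = [NEG] * (n + 1)
    best = 0
    for i in range(1, m + 1):
        H_cur = [0] * (n + 1)
        E_cur = [NEG] * (n + 1)
        F = NEG  # horizontal state within the row
        qc = query[i - 1]
        for j in range(1, n + 1):
            E_cur[j] = max(H_prev[j] - goe, E_prev[j] - gap_extend)
            F = max(H_cur[j - 1] - goe, F - gap_extend)
            ok = qc == ref[j - 1] and qc in "ACGT"
            s = match if ok else -mismatch
            h = max(0, H_prev[j - 1] + s, E_cur[j], F)
            H_cur[j] = h
            if h > best:
                best = h
        H_prev, E_prev = H_cur, E_cur
    return best


def naive_occurrences(pattern: str, text: str) -> list[int]:
    """All 0-based occurrences of pattern in text by linear scan."""
    out = []
    start = 0
    while True:
        i = text.find(pattern, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def naive_kmer_seeds(query: str, text: str, k: int) -> set[tuple[int, int]]:
    """(query offset, text position) pairs of exact k-mer matches."""
    seeds = set()
    for q in range(len(query) - k + 1):
        kmer = query[q:q + k]
        if any(c not in "ACGT" for c in kmer):
            continue
        for p in naive_occurrences(kmer, text):
            seeds.add((q, p))
    return seeds
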