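"""Independent brute-force oracles used only by the test suite."""
from __future__ import annotations

import edlib


def sw_score_oracle(query: str, target: str, match: int = 2,
                    mismatch: int = -3, gap_open: int = 5,
                    gap_extend: int = 2) -> int:
    """Plain quadratic-time affine-gap local alignment DP (three
    matrices, no rolling storage, no banding).  A gap of length L costs
    gap_open + (L-1)*gap_extend."""
    n, m = len(query), len(target)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            both = query[i - 1] == target[j - 1] and query[i - 1] != "N"
            s = match if both else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return int(best)


_RC = str.maketrans("ACGTN", "TGCAN")


def kmer_min_edist_oracle(read: str, gene: str, k: int,
                          both_strands: bool = True,
                          cap: int = 10) -> int:
    """Minimum Levenshtein distance between any k-window of the read (or
    its reverse complement) and any k-mer of the gene, by exhaustive
    pairwise edlib alignment."""
    best = cap
    views = [read]
    if both_strands:
        views.append(read.translate(_RC)[::-1])
    kmers = [gene[g:g + k] for g in range(len(gene) - k + 1)]
    for view in views:
        for w in range(len(view) - k + 1):
            window = view[w:w + k]
            for kmer in kmers:
                d = edlib.align(window, kmer, task="distance",
                                k=best - 1)["editDistance"]
                if d >= 0 and d < best:
                    best = d
                    if best == 0:
                        return 0
    return best
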