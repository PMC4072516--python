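"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (full-matrix DP, exhaustive scans,
direct tallies) and shares no code with the package's fast paths.
"""

from __future__ import annotations

NEG = float("-inf")


def sw_affine_local(q: str, t: str, match: int = 1, mismatch: int = -1,
                    gap_open: int = -2, gap_extend: int = -1):
    """Textbook affine-gap Smith-Waterman with traceback.

    Returns (score, identities, mismatches, gaps, (qs, qe), (ts, te)).
    """
    n, m = len(q), len(t)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in t (deletion)
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in q (insertion)
    ptr = [[None] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            Ix[i][j] = max(M[i - 1][j] + gap_open, Ix[i - 1][j] + gap_extend)
            Iy[i][j] = max(M[i][j - 1] + gap_open, Iy[i][j - 1] + gap_extend)
            s = match if q[i - 1] == t[j - 1] else mismatch
            diag = M[i - 1][j - 1] + s
            M[i][j] = max(0.0, diag, Ix[i][j], Iy[i][j])
            if M[i][j] == 0:
                ptr[i][j] = None
            elif M[i][j] == diag:
                ptr[i][j] = "D"
            elif M[i][j] == Ix[i][j]:
                ptr[i][j] = "U"
            else:
                ptr[i][j] = "L"
            if M[i][j] > best:
                best, bi, bj = M[i][j], i, j
    ident = mism = gaps = 0
    i, j = bi, bj
    while i > 0 and j > 0 and ptr[i][j] is not None:
        if ptr[i][j] == "D":
            if q[i - 1] == t[j - 1]:
                ident += 1
            else:
                mism += 1
            i, j = i - 1, j - 1
        elif ptr[i][j] == "U":
            # walk the whole gap run
            while i > 0 and M[i][j] != 0 and \
                    M[i][j] == Ix[i][j]:
                gaps += 1
                i -= 1
            # gap run origin was M[i][j]
        else:
            while j > 0 and M[i][j] != 0 and M[i][j] == Iy[i][j]:
                gaps += 1
                j -= 1
    return best, ident, mism, gaps, (i, bi), (j, bj)


def all_orfs(seq: str):
    """Every ATG->stop span on the plus strand, all frames, exhaustively."""
    stops = {"TAA", "TAG", "TGA"}
    seq = seq.upper()
    out = []
    for start in range(len(seq) - 2):
        if seq[start:start + 3] != "ATG":
            continue
        for end in range(start + 3, len(seq) - 2, 3):
            codon = seq[end:end + 3]
            if codon in stops:
                out.append((start, end + 3))
                break
    return out


def two_longest_nonoverlapping(spans):
    """Exhaustive search over all ordered pairs, mirroring the stated rule:
    the longest span first (ties to 5'-most), then the longest compatible."""
    if not spans:
        return None, None
    ranked = sorted(spans, key=lambda s: (-(s[1] - s[0]), s[0]))
    first = ranked[0]
    second = None
    for s in ranked[1:]:
        if s[1] <= first[0] or s[0] >= first[1]:
            second = s
            break
    if second is None:
        return first, None
    return tuple(sorted([first, second]))


def cooccurrence_2x2(flags_a, flags_b):
    """Exact 2x2 tabulation of two boolean member flags."""
    n11 = n10 = n01 = n00 = 0
    for a, b in zip(flags_a, flags_b):
        if a and b:
            n11 += 1
        elif a:
            n10 += 1
        elif b:
            n01 += 1
        else:
            n00 += 1
    return n11, n10, n01, n00


def hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))
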