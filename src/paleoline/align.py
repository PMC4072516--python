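"""Pairwise alignment engine: seed-and-extend with an affine-gap DP core.

Detection of decayed retroelement fragments in reads uses exact k-mer seeds
to nominate (read, strand, window) candidates, then scores each candidate
window with an affine-gap local alignment (match +1, mismatch -1, gap open
-2, gap extend -1 by default).  Percent identity is defined end-to-end as
matches / alignment columns, where gap columns count as mismatches; query
coverage is the aligned query span over the query length.

An exhaustive mode (no seeding, full-matrix DP over the whole read) exists
for oracle-style cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align

from ._seq import revcomp

_BASE_CODE = np.full(128, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


@dataclass(frozen=True)
class Scoring:
    """Alignment scores; gap of length L costs open + (L-1)*extend."""

    match: int = 1
    mismatch: int = -1
    gap_open: int = -2
    gap_extend: int = -1


@lru_cache(maxsize=8)
def _aligner(scoring: Scoring, mode: str, free_end_gaps: bool) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    al.match_score = scoring.match
    al.mismatch_score = scoring.mismatch
    al.open_gap_score = scoring.gap_open
    al.extend_gap_score = scoring.gap_extend
    if mode == "global" and free_end_gaps:
        try:
            al.end_insertion_score = 0.0
            al.end_deletion_score = 0.0
        except AttributeError:  # older Biopython
            al.target_end_gap_score = 0.0
            al.query_end_gap_score = 0.0
    return al


@dataclass
class LocalAlignment:
    """One local alignment of a query against a target window."""

    query_start: int
    query_end: int
    target_start: int
    target_end: int
    identities: int
    mismatches: int
    gaps: int
    insertions: int  # target bases inserted relative to the query
    projection: str  # target residues in query coordinates; '-' = deletion
    score: float

    @property
    def columns(self) -> int:
        return self.identities + self.mismatches + self.gaps

    @property
    def identity(self) -> float:
        """Percent identity; gap columns count against identity."""
        return 100.0 * self.identities / self.columns if self.columns else 0.0

    def query_span(self) -> int:
        return self.query_end - self.query_start


def _summarize(aln, query: str, target: str) -> LocalAlignment:
    qblocks, tblocks = aln.aligned
    qs, qe = int(qblocks[0][0]), int(qblocks[-1][1])
    ts, te = int(tblocks[0][0]), int(tblocks[-1][1])
    proj = np.full(qe - qs, ord("-"), dtype=np.uint8)
    identities = mismatches = insertions = 0
    prev_t = None
    for (q0, q1), (t0, t1) in zip(qblocks, tblocks):
        if prev_t is not None:
            insertions += t0 - prev_t
        prev_t = t1
        seg_q = np.frombuffer(query[q0:q1].encode(), dtype=np.uint8)
        seg_t = np.frombuffer(target[t0:t1].encode(), dtype=np.uint8)
        proj[q0 - qs:q1 - qs] = seg_t
        eq = int((seg_q == seg_t).sum())
        identities += eq
        mismatches += (q1 - q0) - eq
    deletions = (qe - qs) - sum(q1 - q0 for q0, q1 in qblocks)
    return LocalAlignment(
        query_start=qs, query_end=qe, target_start=ts, target_end=te,
        identities=identities, mismatches=mismatches,
        gaps=deletions + insertions, insertions=insertions,
        projection=proj.tobytes().decode(), score=float(aln.score),
    )


def _xdrop_extent(pairs: list[tuple[str, str]], xdrop: int) -> int:
    """How many leading columns of an ungapped extension to keep.

    Walks outward scoring +1/-1; if the sequence end is reached the whole
    extension is kept (trailing mismatches included - clipping them is what
    biases identity), but a score collapse > ``xdrop`` marks a homology
    boundary and the extension is trimmed back to its best point.
    """
    score = best = 0
    best_at = 0
    for i, (a, b) in enumerate(pairs):
        score += 1 if a == b else -1
        if score > best:
            best, best_at = score, i + 1
        elif best - score > xdrop:
            return best_at
    return len(pairs)


def _extend_overlap(res: LocalAlignment, query: str, target: str,
                    xdrop: int = 25) -> LocalAlignment:
    """Grow a local alignment ungapped toward the full query/target overlap.

    Smith-Waterman clips low-scoring ends, which biases percent identity
    upward (increasingly so at higher divergence).  For substitution-
    dominated data the unbiased measure extends the aligned span column by
    column until either sequence runs out; an X-drop rule stops at genuine
    homology boundaries (e.g. the flank of a truncated insertion) instead
    of absorbing unrelated sequence.
    """
    left_room = min(res.query_start, res.target_start)
    right_room = min(len(query) - res.query_end,
                     len(target) - res.target_end)
    pre = [(query[res.query_start - 1 - i], target[res.target_start - 1 - i])
           for i in range(left_room)]
    post = [(query[res.query_end + i], target[res.target_end + i])
            for i in range(right_room)]
    left = _xdrop_extent(pre, xdrop)
    right = _xdrop_extent(post, xdrop)
    if left == 0 and right == 0:
        return res
    qs, ts = res.query_start - left, res.target_start - left
    qe, te = res.query_end + right, res.target_end + right
    pre_t = target[ts:res.target_start]
    post_t = target[res.target_end:te]
    add_ident = sum(a == b for a, b in pre[:left]) + \
        sum(a == b for a, b in post[:right])
    return LocalAlignment(
        query_start=qs, query_end=qe, target_start=ts, target_end=te,
        identities=res.identities + add_ident,
        mismatches=res.mismatches + (left + right) - add_ident,
        gaps=res.gaps, insertions=res.insertions,
        projection=pre_t + res.projection + post_t,
        score=res.score)


def local_align(query: str, target: str, scoring: Scoring = Scoring(),
                extend_overlap: bool = True) -> LocalAlignment | None:
    """Best affine-gap local alignment of ``query`` against ``target``.

    With ``extend_overlap`` (default) the aligned span is then extended
    ungapped to the full mutual overlap, removing the end-clipping bias of
    plain Smith-Waterman identity.  Returns None when no positive-scoring
    alignment exists.
    """
    if not query or not target:
        return None
    al = _aligner(scoring, "local", False)
    try:
        aln = al.align(query, target)[0]
    except IndexError:
        return None
    if aln.score <= 0 or len(aln.aligned[0]) == 0:
        return None
    res = _summarize(aln, query, target)
    if extend_overlap:
        res = _extend_overlap(res, query, target)
    return res


def global_identity(a: str, b: str, scoring: Scoring = Scoring(),
                    free_end_gaps: bool = True) -> float:
    """Percent identity of a global alignment (terminal gaps excluded)."""
    if not a or not b:
        return 0.0
    al = _aligner(scoring, "global", free_end_gaps)
    aln = al.align(a, b)[0]
    c = aln.counts()
    internal = c.gaps - c.left_gaps - c.right_gaps
    cols = c.identities + c.mismatches + internal
    return 100.0 * c.identities / cols if cols else 0.0


def _kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(codes, positions) of all valid k-mers of ``seq``; ambiguous bases skipped."""
    arr = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8) & 0x7F]
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(arr, k)
    valid = (win < 4).all(axis=1)
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    codes = win.astype(np.int64) @ powers
    pos = np.nonzero(valid)[0]
    return codes[valid], pos


def _low_complexity_mask(codes: np.ndarray, k: int) -> np.ndarray:
    """True where a k-mer code uses <= 2 distinct bases (seeding skip-list)."""
    present = np.zeros(len(codes), dtype=np.uint8)
    for i in range(k):
        present |= np.uint8(1) << ((codes >> (2 * i)) & 3).astype(np.uint8)
    n_distinct = ((present & 1) + ((present >> 1) & 1) +
                  ((present >> 2) & 1) + ((present >> 3) & 1))
    return n_distinct <= 2


class KmerIndex:
    """Sorted-array exact k-mer index over a collection of sequences.

    Stores forward-strand k-mers only; minus-strand hits are found by
    looking up the reverse complement of the query.
    """

    def __init__(self, seqs: list[str], k: int = 12):
        self.k = k
        self.n_seqs = len(seqs)
        self.seq_lengths = np.array([len(s) for s in seqs], dtype=np.int64)
        starts = np.concatenate([[0], np.cumsum(self.seq_lengths)])
        self.starts = starts
        codes_all, pos_all = [], []
        for i, s in enumerate(seqs):
            codes, pos = _kmer_codes(s, k)
            codes_all.append(codes)
            pos_all.append(pos + starts[i])
        codes = np.concatenate(codes_all) if codes_all else np.empty(0, np.int64)
        pos = np.concatenate(pos_all) if pos_all else np.empty(0, np.int64)
        order = np.argsort(codes, kind="stable")
        self.codes = codes[order]
        self.pos = pos[order]

    def lookup_many(self, qcodes: np.ndarray, qpos: np.ndarray,
                    skip_low_complexity: bool = True
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All (seq_idx, target_pos, query_pos) seed matches for query k-mers."""
        if skip_low_complexity and len(qcodes):
            keep = ~_low_complexity_mask(qcodes, self.k)
            qcodes, qpos = qcodes[keep], qpos[keep]
        lo = np.searchsorted(self.codes, qcodes, side="left")
        hi = np.searchsorted(self.codes, qcodes, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            e = np.empty(0, np.int64)
            return e, e, e
        tpos = np.empty(total, dtype=np.int64)
        qout = np.empty(total, dtype=np.int64)
        at = 0
        for i in range(len(qcodes)):
            c = counts[i]
            if c:
                tpos[at:at + c] = self.pos[lo[i]:hi[i]]
                qout[at:at + c] = qpos[i]
                at += c
        seq_idx = np.searchsorted(self.starts, tpos, side="right") - 1
        tpos = tpos - self.starts[seq_idx]
        return seq_idx, tpos, qout


@dataclass
class CandidateWindow:
    seq_index: int
    strand: str  # '+' if the query matches the stored sequence forward
    start: int   # window on the stored (forward) sequence
    end: int
    n_seeds: int


def candidate_windows(query: str, index: KmerIndex, margin: int = 60,
                      min_seeds: int = 1) -> list[CandidateWindow]:
    """Nominate (sequence, strand, window) candidates for ``query`` by k-mer seeds.

    At most one window per (sequence, strand): the union of all seed-projected
    query extents, clipped to the sequence and padded by ``margin``.
    """
    out: list[CandidateWindow] = []
    qlen = len(query)
    for strand, qseq in (("+", query), ("-", revcomp(query))):
        qcodes, qpos = _kmer_codes(qseq, index.k)
        si, tp, qp = index.lookup_many(qcodes, qpos)
        if len(si) == 0:
            continue
        lo = np.full(index.n_seqs, np.iinfo(np.int64).max, dtype=np.int64)
        hi = np.full(index.n_seqs, -1, dtype=np.int64)
        nseed = np.zeros(index.n_seqs, dtype=np.int64)
        np.minimum.at(lo, si, tp - qp)
        np.maximum.at(hi, si, tp - qp + qlen)
        np.add.at(nseed, si, 1)
        for idx in np.nonzero(nseed >= min_seeds)[0]:
            start = max(0, int(lo[idx]) - margin)
            end = min(int(index.seq_lengths[idx]), int(hi[idx]) + margin)
            out.append(CandidateWindow(int(idx), strand, start, end,
                                       int(nseed[idx])))
    return out
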