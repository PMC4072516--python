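"""Iterative consensus walking: reconstruct a master element from reads.

Starting from a seed (a conserved window of the element), reads matching
the current frontier at high identity (default >=92%, to keep older
lineages out) and overhanging it by >=100 bp are collected; their overhangs
are anchored at the frontier and a majority-rule consensus extends the
sequence 100-500 bp per step.  The walk runs in both directions until the
3' end reaches the poly-A tail and the 5' end runs out of support (most
copies are 5'-truncated, so coverage collapses towards the promoter).
Finally, hypermutable CpG dinucleotides - which decay to TG/CA in the
copies and can therefore be voted away - are restored from the per-column
dinucleotide spectrum, and the whole reconstruction is verified by
re-running the walk from an internal seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._seq import longest_run, revcomp, shannon_entropy
from .align import KmerIndex, Scoring, candidate_windows, global_identity, \
    local_align

_DINUC_OK = ("CG", "CA", "TG", "TA")


@dataclass
class WalkConfig:
    min_candidate_identity: float = 92.0
    min_overhang: int = 100
    step_min: int = 100
    step_max: int = 500
    next_seed_length: int = 400        # 300-500 bp frontier seed
    min_column_depth: int = 5
    min_majority_fraction: float = 0.7
    verify_seed_length: int = 500
    polya_run_min: int = 15
    min_anchor: int = 100              # aligned seed bases required
    edge_tolerance: int = 5            # unaligned seed tail tolerated
    # mapping reads back for column support tolerates slightly more
    # divergence than the walk: per-copy identity straddles the candidate
    # floor, and consensus errors must not starve the very columns that
    # need correcting
    profile_identity_margin: float = 4.0
    cpg_majority_cutoff: float = 0.8   # "high variation" threshold
    cpg_dinucleotide_fraction: float = 0.9
    max_low_quality_run: int = 10      # consecutive low-majority columns;
                                       # must clear chance runs of CpGs
    k: int = 12
    min_seeds: int = 2                 # k-mer seeds to nominate a read
    max_candidates_per_step: int = 100
    max_steps: int = 120
    scoring: Scoring = field(default_factory=Scoring)

    def __post_init__(self):
        if self.step_min > self.step_max:
            raise ValueError("step_min must be <= step_max")
        if self.min_overhang > self.step_max:
            raise ValueError("min_overhang must be <= step_max")


@dataclass
class CandidateOverhang:
    read_id: str
    seed_start: int       # aligned interval on the frontier seed
    seed_end: int
    identity: float
    overhang: str         # bases beyond the frontier, walk orientation
    direction: str        # '3p' or '5p'


@dataclass
class WalkState:
    consensus: str
    left_open: bool = True
    right_open: bool = True
    step_log: list[tuple[str, int, int]] = field(default_factory=list)
    seed_origin: tuple[int, int] = (0, 0)

    @property
    def closed(self) -> bool:
        return not (self.left_open or self.right_open)


@dataclass
class ColumnSupport:
    """Per-column evidence from reads mapped back onto a consensus."""

    counts: np.ndarray     # columns x 5 (A, C, G, T, gap)
    coverage: np.ndarray
    dinuc: np.ndarray      # columns-1 x 16 member dinucleotide counts
    n_rows: int

    def majority_fraction(self) -> np.ndarray:
        tot = self.counts[:, :4].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.counts[:, :4].max(axis=1) /
                            np.maximum(tot, 1), 0.0)


@dataclass
class VerificationReport:
    identity: float
    rerun_length: int
    seed_interval: tuple[int, int]
    reseeds: int
    low_support_intervals: list[tuple[int, int]]


def _right_candidates(seed: str, reads: Sequence[tuple[str, str]],
                      config: WalkConfig, index: KmerIndex,
                      direction: str) -> list[CandidateOverhang]:
    """Reads matching ``seed`` and overhanging its right (3') edge."""
    out = []
    windows = candidate_windows(seed, index, margin=60,
                                min_seeds=config.min_seeds)
    attempts = 0
    for cw in windows:  # read order is unbiased w.r.t. overhang length
        if len(out) >= config.max_candidates_per_step or \
                attempts >= 3 * config.max_candidates_per_step:
            break
        attempts += 1
        rid, rseq = reads[cw.seq_index]
        oread = rseq if cw.strand == "+" else revcomp(rseq)
        aln = local_align(seed, oread, config.scoring)
        if aln is None or aln.identity < config.min_candidate_identity:
            continue
        if aln.query_span() < config.min_anchor:
            continue
        tail = len(seed) - aln.query_end
        if tail > config.edge_tolerance:
            continue
        start = aln.target_end + tail
        overhang = oread[start:]
        if len(overhang) < config.min_overhang:
            continue
        out.append(CandidateOverhang(
            read_id=rid, seed_start=aln.query_start, seed_end=aln.query_end,
            identity=aln.identity, overhang=overhang, direction=direction))
    return out


def find_candidates(frontier_seed: str, reads: Sequence[tuple[str, str]],
                    config: WalkConfig = WalkConfig(),
                    direction: str = "3p",
                    index: KmerIndex | None = None
                    ) -> list[CandidateOverhang]:
    """Candidate overhangs extending the frontier in ``direction``.

    For the 5' direction the search runs on the reverse complement; the
    returned overhang strings always read *away* from the frontier, so
    ``overhang[0]`` abuts the seed in both directions.
    """
    if len(frontier_seed) < 100:
        raise ValueError("frontier seed must be >= 100 bp")
    if index is None:
        index = KmerIndex([s for _, s in reads], k=config.k)
    if direction == "3p":
        return _right_candidates(frontier_seed, reads, config, index, "3p")
    if direction == "5p":
        return _right_candidates(revcomp(frontier_seed), reads, config,
                                 index, "5p")
    raise ValueError(f"unknown direction {direction!r}")


def _majority_extension(overhangs: Sequence[str], config: WalkConfig
                        ) -> str:
    """Column-wise majority over frontier-anchored overhangs.

    Extension stops at the first column failing the depth rule, or after
    ``max_low_quality_run`` consecutive columns failing the majority rule
    (trailing failures are trimmed).  Isolated low-majority columns - the
    signature of hypermutated CpG sites, whose most common residue can drop
    below the floor - receive their majority base and are left for the CpG
    correction pass rather than terminating the walk.
    """
    if not overhangs:
        return ""
    limit = min(config.step_max, max(len(o) for o in overhangs))
    ext: list[str] = []
    fail_run = 0
    for j in range(limit):
        col = [o[j] for o in overhangs if len(o) > j and o[j] in "ACGT"]
        if len(col) < config.min_column_depth:
            break
        vals, counts = np.unique(col, return_counts=True)
        best = int(np.argmax(counts))  # unique() sorts, so ties go A>C>G>T
        ext.append(vals[best])
        if counts[best] / len(col) < config.min_majority_fraction:
            fail_run += 1
            if fail_run >= config.max_low_quality_run:
                break
        else:
            fail_run = 0
    if fail_run:
        del ext[-fail_run:]
    return "".join(ext)


def extend_step(state: WalkState, direction: str,
                candidates: Sequence[CandidateOverhang],
                config: WalkConfig = WalkConfig()) -> WalkState:
    """Extend the consensus in one direction from candidate overhangs.

    Adds up to ``step_max`` bases passing the per-column quality rule; a
    zero-length extension closes the direction.
    """
    ext = _majority_extension([c.overhang for c in candidates], config)
    if direction == "3p":
        if ext:
            state.consensus = state.consensus + ext
        else:
            state.right_open = False
    elif direction == "5p":
        if ext:
            state.consensus = revcomp(ext) + state.consensus
            s, e = state.seed_origin
            state.seed_origin = (s + len(ext), e + len(ext))
        else:
            state.left_open = False
    else:
        raise ValueError(f"unknown direction {direction!r}")
    state.step_log.append((direction, len(ext), len(candidates)))
    return state


def detect_termination(state: WalkState,
                       config: WalkConfig = WalkConfig()) -> WalkState:
    """Close the 3' direction when the consensus has grown a poly-A tail."""
    tail = state.consensus[-(config.polya_run_min + 85):]
    if longest_run(tail, "A") >= config.polya_run_min:
        state.right_open = False
    return state


def walk(seed: str, reads: Sequence[tuple[str, str]],
         config: WalkConfig = WalkConfig(),
         index: KmerIndex | None = None) -> WalkState:
    """Run the bidirectional walk to completion."""
    if len(seed) < 100:
        raise ValueError("seed must be >= 100 bp")
    if index is None:
        index = KmerIndex([s for _, s in reads], k=config.k)
    state = WalkState(consensus=seed, seed_origin=(0, len(seed)))
    for _ in range(config.max_steps):
        if state.closed:
            break
        if state.right_open:
            fs = state.consensus[-config.next_seed_length:]
            cands = find_candidates(fs, reads, config, "3p", index)
            extend_step(state, "3p", cands, config)
            detect_termination(state, config)
        if state.left_open:
            fs = state.consensus[:config.next_seed_length]
            cands = find_candidates(fs, reads, config, "5p", index)
            extend_step(state, "5p", cands, config)
    return state


def profile_support(consensus: str, reads: Sequence[tuple[str, str]],
                    config: WalkConfig = WalkConfig()) -> ColumnSupport:
    """Map reads back onto the consensus and tally per-column evidence.

    Only reads matching at ``min_candidate_identity`` contribute, mirroring
    the candidate filter of the walk itself.
    """
    L = len(consensus)
    counts = np.zeros((L, 5), dtype=np.int64)
    coverage = np.zeros(L, dtype=np.int64)
    dinuc = np.zeros((max(L - 1, 0), 16), dtype=np.int64)
    cons_index = KmerIndex([consensus], k=config.k)
    code = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        code[ord(b)] = i
    min_identity = max(config.min_candidate_identity -
                       config.profile_identity_margin, 0.0)
    n_rows = 0
    for rid, rseq in reads:
        windows = candidate_windows(rseq, cons_index, margin=60,
                                    min_seeds=config.min_seeds)
        windows.sort(key=lambda w: -w.n_seeds)
        for cw in windows[:1]:  # best-seeded placement only
            oread = rseq if cw.strand == "+" else revcomp(rseq)
            window = consensus[cw.start:cw.end]
            aln = local_align(window, oread, config.scoring)
            if aln is None or aln.identity < min_identity:
                continue
            if aln.query_span() < config.min_anchor:
                continue
            n_rows += 1
            start = cw.start + aln.query_start
            proj = np.frombuffer(aln.projection.encode(), dtype=np.uint8)
            span = slice(start, start + len(proj))
            coverage[span] += 1
            c = code[proj]
            for row in range(5):
                np.add.at(counts[:, row], start + np.nonzero(c == row)[0], 1)
            if len(c) > 1:
                a, b = c[:-1], c[1:]
                ok = (a < 4) & (b < 4)
                idx = start + np.nonzero(ok)[0]
                np.add.at(dinuc, (idx, (a[ok] * 4 + b[ok]).astype(np.int64)), 1)
            break  # one placement per read
    return ColumnSupport(counts, coverage, dinuc, n_rows)


def correct_cpg(consensus: str, support: ColumnSupport,
                config: WalkConfig = WalkConfig()
                ) -> tuple[str, list[tuple[int, str]]]:
    """Restore decayed CpG dinucleotides in the consensus.

    A column pair is rewritten to CG when (a) at least one column is highly
    variable (majority fraction below the cutoff), and (b) the member
    dinucleotides fall almost entirely (default >=90%) in {CG, CA, TG, TA}
    with both CA and TG observed - the fingerprint of methyl-C deamination
    on the two strands.
    """
    maj = support.majority_fraction()
    depth = support.counts[:, :4].sum(axis=1)
    out = list(consensus)
    corrections: list[tuple[int, str]] = []
    dn_index = {d: "ACGT".index(d[0]) * 4 + "ACGT".index(d[1])
                for d in ("CG", "CA", "TG", "TA")}
    i = 0
    while i < len(consensus) - 1:
        if depth[i] >= config.min_column_depth and \
                depth[i + 1] >= config.min_column_depth and \
                (maj[i] < config.cpg_majority_cutoff or
                 maj[i + 1] < config.cpg_majority_cutoff):
            row = support.dinuc[i]
            total = int(row.sum())
            good = int(sum(row[dn_index[d]] for d in _DINUC_OK))
            if total >= config.min_column_depth and \
                    good / total >= config.cpg_dinucleotide_fraction and \
                    row[dn_index["CA"]] > 0 and row[dn_index["TG"]] > 0:
                old = consensus[i:i + 2]
                if old != "CG":
                    out[i], out[i + 1] = "C", "G"
                    corrections.append((i, old))
                i += 2
                continue
        i += 1
    return "".join(out), corrections


def low_support_intervals(support: ColumnSupport, min_depth: int
                          ) -> list[tuple[int, int]]:
    low = support.coverage < min_depth
    out = []
    start = None
    for i, flag in enumerate(low):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(low)))
    return out


def reconstruct(seed: str, reads: Sequence[tuple[str, str]],
                config: WalkConfig = WalkConfig(),
                apply_cpg_correction: bool = True
                ) -> tuple[WalkState, ColumnSupport,
                           list[tuple[int, str]], str]:
    """Walk, profile, and (optionally) CpG-correct; the full reconstruction.

    Returns (state, support, corrections, uncorrected_consensus); the last
    lets callers quantify what the CpG correction contributed without
    re-running the walk.
    """
    index = KmerIndex([s for _, s in reads], k=config.k)
    state = walk(seed, reads, config, index)
    support = profile_support(state.consensus, reads, config)
    corrections: list[tuple[int, str]] = []
    uncorrected = state.consensus
    if apply_cpg_correction:
        corrected, corrections = correct_cpg(state.consensus, support, config)
        state.consensus = corrected
    return state, support, corrections, uncorrected


def verify_reconstruction(final_consensus: str,
                          reads: Sequence[tuple[str, str]],
                          config: WalkConfig = WalkConfig(),
                          rng_seed: int = 0,
                          entropy_floor: float = 1.2) -> VerificationReport:
    """Re-run the pipeline from a pseudo-random internal seed and compare.

    Low-complexity seed windows (entropy below the floor, e.g. inside the
    poly-A tail) are re-drawn; the report carries the rerun identity and
    any consensus intervals with support below ``min_column_depth``.
    """
    L = len(final_consensus)
    k = config.verify_seed_length
    if L < k:
        raise ValueError("consensus shorter than verify_seed_length")
    rng = np.random.default_rng([rng_seed, 23])
    reseeds = 0
    start = 0
    for _ in range(50):
        start = int(rng.integers(0, L - k + 1))
        if shannon_entropy(final_consensus[start:start + k]) >= entropy_floor:
            break
        reseeds += 1
    seed = final_consensus[start:start + k]
    state, support, _, _ = reconstruct(seed, reads, config)
    ident = global_identity(state.consensus, final_consensus, config.scoring)
    return VerificationReport(
        identity=ident, rerun_length=len(state.consensus),
        seed_interval=(start, start + k), reseeds=reseeds,
        low_support_intervals=low_support_intervals(
            support, config.min_column_depth))
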