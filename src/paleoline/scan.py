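"""Detection of L1 3'-end fragments in reads and subfamily assignment.

A query consensus (by convention a 575 bp window from the 3' end of ORF2,
where 5'-truncated copies still carry sequence) is searched against every
read on both strands.  Hits below the configured identity/coverage floors
(defaults: >60% identity, >90% query coverage) are discarded.  Each
retained hit carries its alignment projected into query coordinates, which
later stages (co-segregation, age landscapes) consume directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from ._seq import read_fasta, revcomp, validate_iupac, write_fasta
from .align import (CandidateWindow, KmerIndex, LocalAlignment, Scoring,
                    candidate_windows, local_align)


@dataclass
class ScanConfig:
    min_identity: float = 60.0
    min_coverage: float = 90.0
    query_region_length: int = 575
    k: int = 12
    seed_margin: int = 60
    min_seeds: int = 1
    scoring: Scoring = field(default_factory=Scoring)
    exhaustive: bool = False  # full-DP over whole reads, no seeding

    def __post_init__(self):
        if not (0 < self.min_identity <= 100):
            raise ValueError("min_identity must be in (0, 100]")
        if not (0 < self.min_coverage <= 100):
            raise ValueError("min_coverage must be in (0, 100]")


@dataclass
class ScanHit:
    """One detected fragment, with its query-frame projection."""

    read_id: str
    read_start: int
    read_end: int
    strand: str
    query_id: str
    identity: float        # percent, gaps count as mismatch
    coverage: float        # percent of the query aligned
    aligned_fragment: str  # read segment oriented to the query strand
    query_start: int
    projection: str        # query-frame string, '-' = deletion
    mismatch_count: int    # mismatches + gap columns
    insertions: int
    assigned_subfamily: str | None = None

    @property
    def query_end(self) -> int:
        return self.query_start + len(self.projection)

    @property
    def columns(self) -> int:
        return len(self.projection) + self.insertions


def _as_pairs(obj, what: str) -> list[tuple[str, str]]:
    if obj is None:
        raise ValueError(f"{what} must be non-empty")
    if hasattr(obj, "reads"):          # TraceReadSet
        obj = obj.reads
    if isinstance(obj, (str, Path)):
        obj = read_fasta(obj)
    if isinstance(obj, str):
        raise TypeError(f"{what}: expected pairs or FASTA path")
    pairs = []
    for item in obj:
        if isinstance(item, str):
            pairs.append((f"{what}_{len(pairs)}", item))
        else:
            pairs.append((item[0], item[1]))
    if not pairs:
        raise ValueError(f"{what} must be non-empty")
    return pairs


def _hit_from_alignment(aln: LocalAlignment, read_id: str, window_start: int,
                        window_seq: str, window_len: int, strand: str,
                        query_id: str, query_len: int) -> ScanHit:
    if strand == "+":
        r0 = window_start + aln.target_start
        r1 = window_start + aln.target_end
    else:
        r0 = window_start + window_len - aln.target_end
        r1 = window_start + window_len - aln.target_start
    return ScanHit(
        read_id=read_id, read_start=r0, read_end=r1, strand=strand,
        query_id=query_id,
        identity=aln.identity,
        coverage=100.0 * aln.query_span() / query_len,
        aligned_fragment=window_seq[aln.target_start:aln.target_end],
        query_start=aln.query_start, projection=aln.projection,
        mismatch_count=aln.mismatches + aln.gaps, insertions=aln.insertions)


def _greedy_nonoverlapping(hits: list[ScanHit]) -> list[ScanHit]:
    kept: list[ScanHit] = []
    for h in sorted(hits, key=lambda h: (-h.identity, h.read_start)):
        if all(h.read_end <= k.read_start or h.read_start >= k.read_end
               for k in kept):
            kept.append(h)
    return sorted(kept, key=lambda h: h.read_start)


def scan_reads(reads, queries, config: ScanConfig = ScanConfig(),
               index: KmerIndex | None = None) -> list[ScanHit]:
    """Local-align every query (both strands) against every read.

    ``reads``/``queries`` accept (id, seq) pairs, a TraceReadSet, or a FASTA
    path.  Returns retained hits; overlapping hits on one read are resolved
    greedily by identity.
    """
    read_pairs = _as_pairs(reads, "reads")
    query_pairs = _as_pairs(queries, "queries")
    for qid, qseq in query_pairs:
        if not qseq:
            raise ValueError(f"query {qid} is empty")
    for rid, rseq in read_pairs:
        validate_iupac(rseq, name=f"read {rid}")

    seqs = [s for _, s in read_pairs]
    per_read: dict[int, list[ScanHit]] = {}
    for qid, qseq in query_pairs:
        if config.exhaustive:
            cands = [CandidateWindow(i, s, 0, len(seqs[i]), 0)
                     for i in range(len(seqs)) for s in "+-"]
        else:
            if index is None:
                index = KmerIndex(seqs, k=config.k)
            cands = candidate_windows(qseq, index, margin=config.seed_margin,
                                      min_seeds=config.min_seeds)
        for cw in cands:
            window = seqs[cw.seq_index][cw.start:cw.end]
            target = window if cw.strand == "+" else revcomp(window)
            aln = local_align(qseq, target, config.scoring)
            if aln is None:
                continue
            hit = _hit_from_alignment(aln, read_pairs[cw.seq_index][0],
                                      cw.start, target, len(window),
                                      cw.strand, qid, len(qseq))
            if hit.identity >= config.min_identity and \
                    hit.coverage >= config.min_coverage:
                per_read.setdefault(cw.seq_index, []).append(hit)
    out: list[ScanHit] = []
    for i in sorted(per_read):
        out.extend(_greedy_nonoverlapping(per_read[i]))
    return out


def _projection_identity(hit: ScanHit, consensus: str) -> float:
    """Identity of the hit against another consensus in the same frame."""
    seg = consensus[hit.query_start:hit.query_end]
    proj = np.frombuffer(hit.projection.encode(), dtype=np.uint8)
    ref = np.frombuffer(seg.encode(), dtype=np.uint8)
    matches = int(((proj == ref) & (proj != ord("-"))).sum())
    cols = len(proj) + hit.insertions
    return 100.0 * matches / cols if cols else 0.0


def assign_subfamily(hit: ScanHit,
                     subfamily_consensuses: Sequence) -> ScanHit:
    """Assign the hit to the consensus of maximal percent identity.

    Ties break to the lowest subfamily index.  When every consensus lives in
    the hit's query coordinate frame (equal length), identity is computed by
    direct column comparison on the stored projection; otherwise each
    consensus is aligned to the hit fragment.
    """
    cons = _as_pairs(subfamily_consensuses, "consensuses")
    frame_len = max(len(s) for _, s in cons)
    best_id, best_name, best_pct = None, None, -1.0
    for idx, (name, seq) in enumerate(cons):
        if len(seq) == frame_len and hit.query_end <= len(seq):
            pct = _projection_identity(hit, seq)
        else:
            aln = local_align(seq, hit.aligned_fragment)
            pct = aln.identity if aln else 0.0
        if pct > best_pct + 1e-12:
            best_id, best_name, best_pct = idx, name, pct
    return replace(hit, assigned_subfamily=best_name, identity=best_pct)


def assign_all(hits: Sequence[ScanHit],
               subfamily_consensuses: Sequence) -> list[ScanHit]:
    """Vectorized best-identity assignment for hits sharing one frame."""
    cons = _as_pairs(subfamily_consensuses, "consensuses")
    L = len(cons[0][1])
    if any(len(s) != L for _, s in cons) or \
            any(h.query_end > L for h in hits):
        return [assign_subfamily(h, cons) for h in hits]
    n = len(hits)
    proj = np.full((n, L), 0, dtype=np.uint8)
    cols = np.empty(n, dtype=np.int64)
    for i, h in enumerate(hits):
        proj[i, h.query_start:h.query_end] = np.frombuffer(
            h.projection.encode(), dtype=np.uint8)
        cols[i] = h.columns
    pct = np.empty((len(cons), n))
    for k, (_, seq) in enumerate(cons):
        ref = np.frombuffer(seq.encode(), dtype=np.uint8)
        matches = ((proj == ref) & (proj != 0) & (proj != ord("-"))).sum(axis=1)
        pct[k] = 100.0 * matches / cols
    best = np.argmax(pct, axis=0)  # argmax takes the first max on ties
    out = []
    for i, h in enumerate(hits):
        k = int(best[i])
        out.append(replace(h, assigned_subfamily=cons[k][0],
                           identity=float(pct[k, i])))
    return out


def write_hits_tsv(hits: Sequence[ScanHit], path: str | Path,
                   header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("read_id\tstart\tend\tstrand\tquery_id\tidentity\tcoverage"
                 "\tsubfamily\n")
        for h in hits:
            fh.write(f"{h.read_id}\t{h.read_start}\t{h.read_end}\t{h.strand}"
                     f"\t{h.query_id}\t{h.identity:.2f}\t{h.coverage:.2f}"
                     f"\t{h.assigned_subfamily or '.'}\n")


def write_fragments_fasta(hits: Sequence[ScanHit], path: str | Path,
                          header_comment: str | None = None) -> None:
    recs = [(f"{h.read_id}:{h.read_start}-{h.read_end}({h.strand})",
             h.aligned_fragment) for h in hits]
    write_fasta(recs, path, header_comment=header_comment)
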