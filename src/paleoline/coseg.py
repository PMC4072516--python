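"""Subfamily discovery from shared, co-segregating variant sites.

Copies descended from distinct source elements share the private mutations
of their source.  Within a pool of aligned fragments, a pair of polymorphic
columns whose minor variants ride in the same members far beyond
independence marks such a cohort: the members carrying both variants are
split off as a candidate subfamily and the procedure recurses.  The
co-occurrence test is a one-sided Fisher/hypergeometric exact test with
Bonferroni correction over the tested column pairs; candidate groups (and
remainders) below ``min_subfamily_size`` are never split off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from ._seq import write_fasta
from .scan import ScanConfig, ScanHit, _projection_identity, assign_all, \
    scan_reads

_BASES = "ACGT"
_BASE_TO_ROW = {b: i for i, b in enumerate(_BASES + "-")}


@dataclass
class CosegConfig:
    min_subfamily_size: int = 250
    cosegregation_min_count: int = 10
    significance_alpha: float = 0.05
    max_rounds: int = 10  # recursion depth of the splitting
    # hypermutable CpG columns correlate through per-copy age, not through
    # shared ancestry, so they are excluded from the co-segregation test
    exclude_cpg_columns: bool = True
    cpg_majority_cutoff: float = 0.8
    cpg_dinucleotide_fraction: float = 0.9

    def __post_init__(self):
        if self.min_subfamily_size < 2:
            raise ValueError("min_subfamily_size must be >= 2")


@dataclass
class SubfamilyModel:
    subfamily_id: int
    consensus: str
    members: list[int]  # indices into the fragment list
    diagnostic_sites: list[tuple[int, str, int, str]]
    member_identities: list[float] = field(default_factory=list)


def column_matrix(fragments: Sequence[ScanHit], reference: str
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Per-column base counts in reference coordinates.

    Returns (counts, coverage): counts is columns x 5 (A, C, G, T, gap) and
    coverage the number of fragments whose alignment spans each column.
    """
    L = len(reference)
    counts = np.zeros((L, 5), dtype=np.int64)
    coverage = np.zeros(L, dtype=np.int64)
    for frag in fragments:
        if not isinstance(frag, ScanHit) or frag.projection is None:
            raise ValueError("fragment without an alignment to the reference")
        proj = np.frombuffer(frag.projection.encode(), dtype=np.uint8)
        qs = frag.query_start
        coverage[qs:qs + len(proj)] += 1
        for row, base in enumerate(_BASES + "-"):
            pos = qs + np.nonzero(proj == ord(base))[0]
            np.add.at(counts[:, row], pos, 1)
    return counts, coverage


def consensus_from_counts(counts: np.ndarray, reference: str) -> str:
    """Majority base per column (ties break A>C>G>T); reference fills
    columns with no base observations."""
    base_counts = counts[:, :4]
    best = np.argmax(base_counts, axis=1)  # first max -> A>C>G>T
    have = base_counts.sum(axis=1) > 0
    out = np.array(list(reference))
    out[have] = np.array(list(_BASES))[best[have]]
    return "".join(out)


def _model_from_members(fragments, members, reference, subfamily_id=0,
                        diagnostic_sites=None) -> SubfamilyModel:
    counts, _ = column_matrix([fragments[i] for i in members], reference)
    cons = consensus_from_counts(counts, reference)
    return SubfamilyModel(subfamily_id, cons, list(members),
                          list(diagnostic_sites or []))


def _cpg_suspect_columns(proj: np.ndarray, config: CosegConfig) -> np.ndarray:
    """Columns showing the CpG-decay fingerprint, to mask from splitting.

    A column pair is flagged when at least one column is highly variable
    and the member dinucleotides are almost all CG/CA/TG/TA with both CA
    and TG present (deamination on the two strands).
    """
    code = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate(_BASES):
        code[ord(b)] = i
    c = code[proj]
    n, L = c.shape
    counts = np.stack([(c == r).sum(axis=0) for r in range(4)])  # 4 x L
    depth = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        maj = np.where(depth > 0, counts.max(axis=0) / np.maximum(depth, 1),
                       1.0)
    a, b = c[:, :-1], c[:, 1:]
    ok = (a < 4) & (b < 4)
    dinuc = np.zeros((L - 1, 16), dtype=np.int64)
    rows, cols = np.nonzero(ok)
    np.add.at(dinuc, (cols, (a[ok] * 4 + b[ok]).astype(np.int64)), 1)
    di = {d: _BASES.index(d[0]) * 4 + _BASES.index(d[1])
          for d in ("CG", "CA", "TG", "TA")}
    total = dinuc.sum(axis=1)
    good = sum(dinuc[:, di[d]] for d in ("CG", "CA", "TG", "TA"))
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, good / np.maximum(total, 1), 0.0)
    pair_flag = ((np.minimum(maj[:-1], maj[1:]) < config.cpg_majority_cutoff)
                 & (total > 0)
                 & (frac >= config.cpg_dinucleotide_fraction)
                 & (dinuc[:, di["CA"]] > 0) & (dinuc[:, di["TG"]] > 0))
    excluded = np.zeros(L, dtype=bool)
    excluded[:-1] |= pair_flag
    excluded[1:] |= pair_flag
    return excluded


def _cosegregation_best_pair(fragments, members, consensus, config):
    """Most significant co-occurring variant pair, or None.

    Returns (p_bonferroni, (col_u, base_u), (col_v, base_v), member_mask).
    """
    L = len(consensus)
    n = len(members)
    proj = np.zeros((n, L), dtype=np.uint8)
    for r, i in enumerate(members):
        h = fragments[i]
        proj[r, h.query_start:h.query_end] = np.frombuffer(
            h.projection.encode(), dtype=np.uint8)
    cov = proj != 0
    cons_arr = np.frombuffer(consensus.encode(), dtype=np.uint8)
    excluded = (_cpg_suspect_columns(proj, config)
                if config.exclude_cpg_columns
                else np.zeros(L, dtype=bool))

    variants: list[tuple[int, str]] = []
    vmat_cols = []
    for base in _BASES:
        is_base = proj == ord(base)
        cnt = is_base.sum(axis=0)
        cols = np.nonzero((cnt >= config.cosegregation_min_count) &
                          (cons_arr != ord(base)) & ~excluded)[0]
        for c in cols:
            variants.append((int(c), base))
            vmat_cols.append(is_base[:, c])
    if len(variants) < 2:
        return None
    V = np.array(vmat_cols, dtype=np.float32).T          # members x variants
    C = cov.astype(np.float32)                           # members x columns
    CO = V.T @ V                                         # co-occurrence k
    KV = V.T @ C                                         # variant u covering col c
    NN = C.T @ C                                         # both-covered totals
    vcols = np.array([c for c, _ in variants])

    nv = len(variants)
    iu, iv = np.triu_indices(nv, k=1)
    same_col = vcols[iu] == vcols[iv]
    k = CO[iu, iv]
    testable = (~same_col) & (k >= config.cosegregation_min_count)
    m_tests = int(testable.sum())
    floor_ok = testable & (k >= config.min_subfamily_size)
    N = NN[vcols[iu], vcols[iv]]
    floor_ok &= (N - k) >= config.min_subfamily_size
    if m_tests == 0 or not floor_ok.any():
        return None
    sel = np.nonzero(floor_ok)[0]
    K = KV[iu[sel], vcols[iv[sel]]]
    draw = KV[iv[sel], vcols[iu[sel]]]
    p = hypergeom.sf(k[sel] - 1, np.round(N[sel]).astype(np.int64),
                     np.round(K).astype(np.int64),
                     np.round(draw).astype(np.int64))
    best = int(np.argmin(p))
    p_bonf = float(p[best]) * m_tests
    if p_bonf >= config.significance_alpha:
        return None
    u, v = int(iu[sel[best]]), int(iv[sel[best]])
    mask = V[:, u].astype(bool) & V[:, v].astype(bool)
    return p_bonf, variants[u], variants[v], mask


def split_by_cosegregation(model: SubfamilyModel, fragments: Sequence[ScanHit],
                           config: CosegConfig, _depth: int = 0
                           ) -> list[SubfamilyModel]:
    """Recursively split a subfamily on co-segregating variant pairs."""
    if len(model.members) < 2 * config.min_subfamily_size or \
            _depth >= config.max_rounds:
        return [model]
    found = _cosegregation_best_pair(fragments, model.members,
                                     model.consensus, config)
    if found is None:
        return [model]
    _, (cu, bu), (cv, bv), mask = found
    members = np.asarray(model.members)
    child = _model_from_members(
        fragments, members[mask].tolist(), model.consensus,
        diagnostic_sites=model.diagnostic_sites + [(cu, bu, cv, bv)])
    rest = _model_from_members(fragments, members[~mask].tolist(),
                               model.consensus,
                               diagnostic_sites=model.diagnostic_sites)
    out = split_by_cosegregation(child, fragments, config, _depth + 1)
    out += split_by_cosegregation(rest, fragments, config, _depth + 1)
    return out


def filter_subfamilies(models: Sequence[SubfamilyModel], min_size: int,
                       fragments: Sequence[ScanHit] | None = None
                       ) -> list[SubfamilyModel]:
    """Drop undersized subfamilies, reassigning their members to the nearest
    surviving consensus by identity."""
    models = list(models)
    if not models:
        return []
    survivors = [m for m in models if len(m.members) >= min_size]
    if not survivors:
        raise ValueError(
            f"all {len(models)} subfamilies fall below min size {min_size}; "
            "lower min_subfamily_size for this dataset")
    dropped = [m for m in models if len(m.members) < min_size]
    if dropped and fragments is not None:
        for m in dropped:
            for i in m.members:
                best = max(range(len(survivors)), key=lambda k: (
                    _projection_identity(fragments[i], survivors[k].consensus),
                    -k))
                survivors[best].members.append(i)
    for sid, m in enumerate(survivors):
        m.subfamily_id = sid
        m.members.sort()
    return survivors


def support_from_members(fragments: Sequence[ScanHit], members,
                         reference: str):
    """ColumnSupport (counts, coverage, member dinucleotides) for a member
    set projected onto the reference frame; feeds CpG correction."""
    from .walker import ColumnSupport
    frags = [fragments[i] for i in members]
    counts, coverage = column_matrix(frags, reference)
    L = len(reference)
    dinuc = np.zeros((max(L - 1, 0), 16), dtype=np.int64)
    code = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate(_BASES):
        code[ord(b)] = i
    for h in frags:
        c = code[np.frombuffer(h.projection.encode(), dtype=np.uint8)]
        if len(c) < 2:
            continue
        a, b = c[:-1], c[1:]
        ok = (a < 4) & (b < 4)
        idx = h.query_start + np.nonzero(ok)[0]
        np.add.at(dinuc, (idx, (a[ok] * 4 + b[ok]).astype(np.int64)), 1)
    return ColumnSupport(counts, coverage, dinuc, len(frags))


def _cpg_correct_models(models, fragments):
    """Restore decayed CpG dinucleotides in every subfamily consensus.

    Raw majority consensuses carry T/A at hypermutated CpG columns; which
    way a near-even column falls is member-set noise that inflates
    subfamily-to-subfamily distances and biases identities upward, so the
    correction is applied before clustering and assignment.
    """
    from .walker import WalkConfig, correct_cpg
    cfg = WalkConfig()
    for m in models:
        support = support_from_members(fragments, m.members, m.consensus)
        m.consensus, _ = correct_cpg(m.consensus, support, cfg)
    return models


def _refresh_identities(models, fragments):
    for m in models:
        m.member_identities = [
            _projection_identity(fragments[i], m.consensus)
            for i in m.members]
    return models


def iterate_discovery(reads, seed_query: str,
                      scan_config: ScanConfig = ScanConfig(),
                      coseg_config: CosegConfig = CosegConfig(),
                      rounds: int = 2, cpg_correct: bool = True
                      ) -> tuple[list[SubfamilyModel], list[ScanHit]]:
    """Alternate scanning and subfamily refinement.

    Round 1 scans with the seed query and splits the pooled fragments by
    co-segregation; each further discovery round rescans with the refined
    pooled consensus as the query and re-partitions from scratch; a final
    assignment pass scores every fragment against every surviving consensus
    by projection.  With ``rounds=0`` the single seed-defined subfamily is
    returned as-is.
    """
    hits = scan_reads(reads, [("seed", seed_query)], scan_config)
    if not hits:
        raise ValueError("seed query detected no fragments in the reads")
    root = _model_from_members(hits, range(len(hits)), seed_query)
    if rounds == 0:
        root.subfamily_id = 0
        if cpg_correct:
            _cpg_correct_models([root], hits)
        _refresh_identities([root], hits)
        return [root], hits
    models = split_by_cosegregation(root, hits, coseg_config)
    models = filter_subfamilies(models, coseg_config.min_subfamily_size, hits)

    for _ in range(1, rounds):
        # rescan with the refined pooled consensus: one query keeps the
        # cost linear in reads; per-subfamily identity is recovered by the
        # projection-based assignment below
        if cpg_correct:
            _cpg_correct_models([root], hits)
        hits = scan_reads(reads, [("refined", root.consensus)], scan_config)
        if not hits:
            break
        root = _model_from_members(hits, range(len(hits)), root.consensus)
        models = split_by_cosegregation(root, hits, coseg_config)
        models = filter_subfamilies(models, coseg_config.min_subfamily_size,
                                    hits)

    if cpg_correct:
        _cpg_correct_models(models, hits)
    consensuses = [(f"sf{m.subfamily_id}", m.consensus) for m in models]
    hits = assign_all(hits, consensuses)
    by_name = {name: m for (name, _), m in zip(consensuses, models)}
    for m in models:
        m.members, m.member_identities = [], []
    for i, h in enumerate(hits):
        m = by_name[h.assigned_subfamily]
        m.members.append(i)
        m.member_identities.append(h.identity)
    return models, hits


def assignments_frame(hits: Sequence[ScanHit]) -> pd.DataFrame:
    return pd.DataFrame({
        "hit": range(len(hits)),
        "read_id": [h.read_id for h in hits],
        "subfamily": [h.assigned_subfamily for h in hits],
        "identity": [h.identity for h in hits],
        "mismatches": [h.mismatch_count for h in hits],
        "columns": [h.columns for h in hits],
    })


def write_subfamilies(models: Sequence[SubfamilyModel], outdir: str | Path,
                      header_comment: str | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta([(f"sf{m.subfamily_id}", m.consensus) for m in models],
                outdir / "subfamily_consensuses.fa",
                header_comment=header_comment)
    with open(outdir / "subfamily_members.tsv", "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("subfamily\tmember\tidentity\n")
        for m in models:
            ids = m.member_identities or [float("nan")] * len(m.members)
            for i, pct in zip(m.members, ids):
                fh.write(f"sf{m.subfamily_id}\t{i}\t{pct:.2f}\n")
    with open(outdir / "diagnostic_sites.tsv", "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("subfamily\tcolumn\tvariant\tpartner_column\tpartner_variant\n")
        for m in models:
            for cu, bu, cv, bv in m.diagnostic_sites:
                fh.write(f"sf{m.subfamily_id}\t{cu}\t{bu}\t{cv}\t{bv}\n")
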